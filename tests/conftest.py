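import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from svscape import rs_features, svc
from svscape.allele_frequency import adjust_segments, annotate_svaf
from svscape.io_formats import AnnotationTrack
from svscape.synthetic_data import archetype_cohort_config, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("ci")


def make_sv_frame(rows):
    """Build a valid SV table from compact tuples.

    Each row: (sample, chrom1, pos1, chrom2, pos2, type, o1, o2[, svaf]).
    """
    recs = []
    for i, r in enumerate(rows):
        rec = dict(zip(
            ["sample_id", "chrom1", "pos1", "chrom2", "pos2", "sv_type",
             "orientation1", "orientation2"], r[:8]))
        rec.update(rsv=30, rref1=50, rref2=50)
        if len(r) > 8:
            rec["svaf"] = r[8]
        recs.append(rec)
    columns = ["sample_id", "chrom1", "pos1", "chrom2", "pos2", "sv_type",
               "orientation1", "orientation2", "rsv", "rref1", "rref2", "svaf"]
    df = pd.DataFrame(recs, columns=columns) if not recs else pd.DataFrame(recs)
    df.index = pd.Index([f"sv{i}" for i in range(len(df))], name="sv_id")
    return df


def make_segments(sample, chrom, pieces):
    """Segment frame from (start, end, acn) pieces (cnr set equal to acn)."""
    return pd.DataFrame([
        {"sample_id": sample, "chrom": chrom, "start": s, "end": e,
         "cnr": a, "acn": a} for s, e, a in pieces])


@pytest.fixture(scope="session")
def empty_track():
    return AnnotationTrack.from_intervals("empty", [])


@pytest.fixture(scope="session")
def archetype_analysis():
    """Classified archetype cohort (40 planted SVCs per mechanism class)."""
    cohort = simulate_cohort(archetype_cohort_config(n_per_class=40, seed=2))
    segments = adjust_segments(cohort.segments, cohort.meta)
    sv = annotate_svaf(cohort.sv.set_index("sv_id"), segments, cohort.meta)
    regions = rs_features.detect_clustered_regions_cohort(sv)
    svc_table, annotations, clusters = svc.classify_cohort(
        sv, segments, regions, cohort.tracks["line1"])
    reintegration = svc.detect_reintegration(sv, clusters, regions, segments)
    return dict(cohort=cohort, sv=sv, segments=segments, regions=regions,
                svc_table=svc_table, annotations=annotations,
                clusters=clusters, reintegration=reintegration)


def archetype_accuracy(analysis):
    """Per-class recovery of planted SVC archetypes."""
    truth = analysis["cohort"].truth["svc"]
    svc_table = analysis["svc_table"]
    correct = {cls: 0 for cls in truth["svc_class"].unique()}
    totals = truth["svc_class"].value_counts().to_dict()
    for _, t in truth.iterrows():
        hits = svc_table[svc_table["sample_id"] == t["sample_id"]]
        found = False
        for _, h in hits.iterrows():
            if h["label"] != t["svc_class"]:
                continue
            for fp in h["footprints"].split(";"):
                chrom, span = fp.split(":")
                s, e = map(int, span.split("-"))
                if chrom == t["chrom"] and s <= t["end"] and t["start"] <= e:
                    found = True
        correct[t["svc_class"]] += found
    return {cls: correct[cls] / totals[cls] for cls in totals}
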