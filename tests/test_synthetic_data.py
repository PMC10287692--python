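import numpy as np
import pandas as pd
import pytest

from svscape import rs_features
from svscape.allele_frequency import adjust_segments
from svscape.io_formats import read_segments, read_sv_table, validate_segments, validate_sv_table
from svscape.rs_features import CATEGORIES
from svscape.synthetic_data import (SimConfig, default_profiles,
                                    simulate_catalog, simulate_cohort,
                                    write_cohort)


@pytest.fixture(scope="module")
def small_cohort():
    return simulate_cohort(SimConfig(seed=5, n_samples=12, sv_count_mean=60,
                                     archetypes_per_class=2))


def test_same_seed_reproduces_cohort_exactly(small_cohort):
    again = simulate_cohort(SimConfig(seed=5, n_samples=12, sv_count_mean=60,
                                      archetypes_per_class=2))
    pd.testing.assert_frame_equal(small_cohort.sv, again.sv)
    pd.testing.assert_frame_equal(small_cohort.segments, again.segments)
    pd.testing.assert_frame_equal(small_cohort.meta, again.meta)
    for name in small_cohort.truth:
        pd.testing.assert_frame_equal(small_cohort.truth[name],
                                      again.truth[name])


def test_emitted_tables_satisfy_schema_invariants(small_cohort):
    validate_sv_table(small_cohort.sv)
    validate_segments(small_cohort.segments)
    assert small_cohort.meta["purity"].between(0.3, 0.95).all()


def test_truth_covers_every_emitted_entity(small_cohort):
    truth = small_cohort.truth
    assert set(truth["sv"]["sv_id"]) == set(small_cohort.sv["sv_id"])
    assert set(truth["exposures"]["sample_id"]) == set(
        small_cohort.meta["sample_id"])
    genome = small_cohort.genome
    for _, h in truth["hotspots"].iterrows():
        assert 1 <= h["start"] <= h["end"] <= genome[h["chrom"]]
    # archetype truth labels partition the planted clusters
    assert truth["svc"]["archetype"].is_unique
    assert truth["svc"]["svc_class"].value_counts().min() == 2


def test_read_count_model_matches_expected_vaf(small_cohort):
    """Observed vaf at the chosen breakpoint is binomial around its truth."""
    sv = small_cohort.sv.set_index("sv_id")
    truth = small_cohort.truth["sv"].set_index("sv_id")
    rref = np.minimum(sv["rref1"], sv["rref2"])  # chosen side has depth-rsv
    vaf = sv["rsv"] / (sv["rsv"] + rref)
    resid = vaf - truth["expected_vaf"]
    assert abs(resid.mean()) < 0.02
    assert resid.abs().quantile(0.95) < 0.2


def test_category_frequencies_track_planted_mixture():
    profiles = default_profiles(4)
    cfg = SimConfig(seed=9, n_samples=15, sv_count_mean=200, sv_count_disp=50,
                    profiles=profiles, archetypes_per_class=0,
                    hotspot_plan=[])
    cohort = simulate_cohort(cfg)
    truth_sv = cohort.truth["sv"]
    expo = cohort.truth["exposures"].set_index("sample_id")
    prof = profiles.to_numpy()
    rs = []
    for sample, grp in truth_sv.groupby("sample_id"):
        counts = grp["category"].value_counts().reindex(CATEGORIES,
                                                        fill_value=0)
        freq = counts.to_numpy() / counts.sum()
        mix = expo.loc[sample].to_numpy() @ prof
        rs.append(np.corrcoef(freq, mix)[0, 1])
    assert np.mean(rs) > 0.9


def test_copy_number_steps_consistent_with_planted_dels_and_dups(small_cohort):
    seg = adjust_segments(small_cohort.segments, small_cohort.meta)
    from svscape.allele_frequency import _SegmentIndex, delta_cn_at_breakpoint
    idx = _SegmentIndex(seg)
    truth = small_cohort.truth["sv"].set_index("sv_id")
    background = truth[(truth["archetype"] == "") & (truth["hotspot"] == "")]
    checked = ok = 0
    for sv_id, row in small_cohort.sv.set_index("sv_id").iterrows():
        if sv_id not in background.index or row["sv_type"] not in ("DEL", "DUP"):
            continue
        d = delta_cn_at_breakpoint(idx, row["sample_id"], row["chrom1"],
                                   row["pos1"])
        if np.isnan(d):
            continue
        checked += 1
        ok += (d > 0) if row["sv_type"] == "DUP" else (d < 0)
    assert checked > 20
    assert ok / checked >= 0.95   # clamp floor can flatten deep del stacks


def test_planted_cluster_regions_are_detected():
    from svscape.synthetic_data import archetype_cohort_config
    cohort = simulate_cohort(archetype_cohort_config(n_per_class=15, seed=3))
    regions = rs_features.detect_clustered_regions_cohort(
        cohort.sv.set_index("sv_id"))
    truth = cohort.truth["svc"]
    hit = 0
    for _, t in truth.iterrows():
        r = regions[t["sample_id"]].regions
        hit += bool(((r["chrom"] == t["chrom"]) & (r["start"] <= t["end"])
                     & (t["start"] <= r["end"])).any())
    assert hit / len(truth) >= 0.95


def test_archetype_constructions_satisfy_their_defining_shapes(small_cohort):
    sv = small_cohort.sv.merge(small_cohort.truth["sv"][["sv_id", "archetype"]],
                               on="sv_id")
    # NAHRD: a nested duplication pair exists by construction
    for arch, grp in sv[sv["archetype"].str.startswith("NAHRD")].groupby("archetype"):
        dups = grp[grp["sv_type"] == "DUP"].sort_values("pos1")
        outer, inner = dups.iloc[0], dups.iloc[-1]
        assert outer["pos1"] < inner["pos1"] and inner["pos2"] < outer["pos2"]
    # assembled amplicon: the junction spans more than 2 Mb
    for arch, grp in sv[sv["archetype"].str.startswith("ASSEMBLED")].groupby("archetype"):
        intra = grp[grp["chrom1"] == grp["chrom2"]]
        assert (intra["pos2"] - intra["pos1"]).max() > 2_000_000
    # BFBC: all inversions short enough to be fold-back candidates
    bfbc = sv[sv["archetype"].str.startswith("BFBC")]
    assert ((bfbc["pos2"] - bfbc["pos1"]) < 30_000).all()


def test_simulate_catalog_poisson_counts():
    profiles = default_profiles(5)
    catalog, exposures = simulate_catalog(profiles, 30, 300, seed=1)
    assert catalog.shape == (30, 80)
    assert (catalog.to_numpy() >= 0).all()
    np.testing.assert_allclose(exposures.sum(axis=1), 1.0, atol=1e-9)
    # mean count tracks the requested intensity
    assert catalog.sum(axis=1).mean() == pytest.approx(300, rel=0.1)


def test_write_cohort_round_trips(tmp_path, small_cohort):
    write_cohort(small_cohort, tmp_path)
    sv = read_sv_table(tmp_path / "sv.tsv")
    seg = read_segments(tmp_path / "segments.tsv")
    assert len(sv) == len(small_cohort.sv)
    assert len(seg) == len(small_cohort.segments)
    assert (tmp_path / "truth" / "sv.tsv").exists()
    assert (tmp_path / "tracks" / "line1.bed").exists()
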