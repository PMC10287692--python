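import numpy as np
import pandas as pd
import pytest

from svscape.allele_frequency import _SegmentIndex
from svscape.io_formats import AnnotationTrack
from svscape.rs_features import RegionSet
from svscape.svc import (AmplifiedSegment, build_svcs, classify_svc,
                         compute_profile, detect_foldback_inversions,
                         detect_reintegration, find_amplified_segments)

from conftest import archetype_accuracy, make_segments, make_sv_frame


def regions_of(sample, rows):
    return RegionSet(sample, pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_breakpoints"]))


@pytest.fixture
def empty_line1():
    return AnnotationTrack.from_intervals("line1", [])


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def test_svs_in_one_region_form_one_cluster():
    sv = make_sv_frame([("s1", "chr1", 1_000 + 100 * i, "chr1",
                         2_000 + 100 * i, "DEL", "+", "-") for i in range(6)])
    svcs = build_svcs(sv, regions_of("s1", [("chr1", 900, 2_700, 12)]))
    assert len(svcs) == 1 and len(svcs[0].members) == 6


def test_translocation_bridges_two_regions_into_one_cluster():
    sv = make_sv_frame([
        ("s1", "chr1", 1_000, "chr1", 1_200, "INV", "+", "+"),
        ("s1", "chr2", 5_000, "chr2", 5_100, "INV", "-", "-"),
        ("s1", "chr1", 1_100, "chr2", 5_050, "TRA", "+", "-"),
    ])
    regions = regions_of("s1", [("chr1", 900, 1_300, 3),
                                ("chr2", 4_900, 5_200, 3)])
    svcs = build_svcs(sv, regions)
    assert len(svcs) == 1
    assert len(svcs[0].footprints) == 2
    assert len(svcs[0].members) == 3


def test_no_regions_no_clusters():
    sv = make_sv_frame([("s1", "chr1", 1, "chr1", 10, "DEL", "+", "-")])
    assert build_svcs(sv, regions_of("s1", [])) == []


# ---------------------------------------------------------------------------
# amplified segments
# ---------------------------------------------------------------------------

def test_flat_profile_has_no_amplified_segments():
    seg = make_segments("s1", "chr1", [(1, 10_000_000, 2.0)])
    assert find_amplified_segments(seg) == []


def test_amplified_segment_with_boundary_delta():
    seg = make_segments("s1", "chr1", [(1, 1_000_000, 2.0),
                                       (1_000_001, 2_000_000, 8.0),
                                       (2_000_001, 3_000_000, 2.0)])
    amps = find_amplified_segments(seg)
    assert len(amps) == 1
    assert amps[0].start == 1_000_001 and amps[0].end == 2_000_000
    assert amps[0].boundary_delta == pytest.approx(6.0)


def test_step_without_high_mean_is_not_amplified():
    # step of 3 up to acn 3.9: boundary passes, the mean threshold does not
    seg = make_segments("s1", "chr1", [(1, 1_000_000, 0.9),
                                       (1_000_001, 2_000_000, 3.9),
                                       (2_000_001, 3_000_000, 0.9)])
    assert find_amplified_segments(seg) == []


# ---------------------------------------------------------------------------
# fold-back inversions
# ---------------------------------------------------------------------------

@pytest.fixture
def step_segments():
    return make_segments("s1", "chr1", [(1, 100_000, 2.0),
                                        (100_001, 400_000, 6.0),
                                        (400_001, 1_000_000, 2.0)])


def test_lone_short_inversion_at_cn_step_is_foldback(step_segments):
    sv = make_sv_frame([("s1", "chr1", 100_000, "chr1", 112_000, "INV",
                         "+", "+")])
    flags = detect_foldback_inversions(sv, _SegmentIndex(step_segments))
    assert flags == {"sv0"}


def test_reciprocal_partner_vetoes_foldback(step_segments):
    sv = make_sv_frame([
        ("s1", "chr1", 100_000, "chr1", 112_000, "INV", "+", "+"),
        ("s1", "chr1", 101_000, "chr1", 113_000, "INV", "-", "-"),
    ])
    flags = detect_foldback_inversions(sv, _SegmentIndex(step_segments))
    assert flags == set()


def test_long_span_vetoes_foldback(step_segments):
    sv = make_sv_frame([("s1", "chr1", 100_000, "chr1", 180_000, "INV",
                         "+", "+")])
    assert detect_foldback_inversions(sv, _SegmentIndex(step_segments)) == set()


def test_foldback_depth_path_uses_bh_adjusted_flank_comparison(step_segments):
    """With per-bin depth, the flanking-depth test decides the CN criterion."""
    rng = np.random.default_rng(0)
    # 5 kb bins over 1 Mb: depth doubles right of bin 20 (pos 100 kb)
    depth = np.concatenate([rng.normal(40, 1, 20), rng.normal(80, 1, 180)])
    sv = make_sv_frame([
        ("s1", "chr1", 100_000, "chr1", 112_000, "INV", "+", "+"),  # at step
        ("s1", "chr1", 700_000, "chr1", 712_000, "INV", "+", "+"),  # flat depth
    ])
    flags = detect_foldback_inversions(sv, _SegmentIndex(step_segments),
                                       depth={"chr1": depth})
    assert flags == {"sv0"}


# ---------------------------------------------------------------------------
# classification rules on constructed clusters
# ---------------------------------------------------------------------------

def classify_constructed(sv, seg, regions, line1=None, amplified=None,
                         foldback=frozenset()):
    line1 = line1 or AnnotationTrack.from_intervals("line1", [])
    idx = _SegmentIndex(seg)
    if amplified is None:
        amplified = find_amplified_segments(seg)
    svcs = build_svcs(sv, regions)
    assert len(svcs) == 1
    svcs[0].profile = compute_profile(svcs[0], sv, idx, seg)
    return classify_svc(svcs[0], sv, idx, amplified, line1, set(foldback)), svcs[0]


def test_recurrent_deletions_with_stepwise_drop_are_cfs_like():
    sv = make_sv_frame([
        ("s1", "chr1", 100_000, "chr1", 300_000, "DEL", "+", "-", 0.5),
        ("s1", "chr1", 120_000, "chr1", 280_000, "DEL", "+", "-", 0.4),
        ("s1", "chr1", 140_000, "chr1", 260_000, "DEL", "+", "-", 0.3),
    ])
    seg = make_segments("s1", "chr1", [
        (1, 100_000, 2.0), (100_001, 120_000, 1.6), (120_001, 140_000, 1.2),
        (140_001, 260_000, 0.8), (260_001, 280_000, 1.2),
        (280_001, 300_000, 1.6), (300_001, 1_000_000, 2.0)])
    regions = regions_of("s1", [("chr1", 90_000, 310_000, 6)])
    label, cluster = classify_constructed(sv, seg, regions)
    assert label == "CFS_LIKE"
    assert cluster.profile["stepwise_down"]


def test_nested_spacer_sharing_duplications_over_amplicon_are_nahrd():
    sv = make_sv_frame([
        ("s1", "chr1", 400_000, "chr1", 800_000, "DUP", "-", "+", 0.8),
        ("s1", "chr1", 410_000, "chr1", 790_000, "DUP", "-", "+", 0.6),
        ("s1", "chr1", 420_000, "chr1", 780_000, "DUP", "-", "+", 0.5),
        ("s1", "chr1", 430_000, "chr1", 770_000, "DUP", "-", "+", 0.4),
    ])
    seg = make_segments("s1", "chr1", [(1, 399_999, 1.0),
                                       (400_000, 800_000, 6.0),
                                       (800_001, 2_000_000, 1.0)])
    regions = regions_of("s1", [("chr1", 400_000, 800_000, 8)])
    label, _ = classify_constructed(sv, seg, regions)
    assert label == "NAHRD"


def test_foldback_majority_over_amplicon_is_bfbc():
    sv = make_sv_frame([
        ("s1", "chr1", 300_000, "chr1", 312_000, "INV", "+", "+", 0.5),
        ("s1", "chr1", 370_000, "chr1", 382_000, "INV", "+", "+", 0.6),
        ("s1", "chr1", 440_000, "chr1", 452_000, "INV", "+", "+", 0.7),
    ])
    seg = make_segments("s1", "chr1", [(1, 299_999, 1.0),
                                       (300_000, 370_000, 4.5),
                                       (370_001, 440_000, 6.0),
                                       (440_001, 510_000, 7.5),
                                       (510_001, 2_000_000, 1.0)])
    regions = regions_of("s1", [("chr1", 300_000, 452_000, 6)])
    label, _ = classify_constructed(sv, seg, regions,
                                    foldback={"sv0", "sv1", "sv2"})
    assert label == "BFBC"


def test_concentrated_l1_translocations_are_l1_type():
    line1 = AnnotationTrack.from_intervals("line1", [("chr1", 499_900, 506_000)])
    sv = make_sv_frame([
        ("s1", "chr1", 500_000 + 90 * i, "chr2", 5_000_000 * (i + 1), "TRA",
         "+", "-", 0.3) for i in range(4)])
    seg = make_segments("s1", "chr1", [(1, 2_000_000, 1.0)])
    regions = regions_of("s1", [("chr1", 500_000, 500_270, 4)])
    label, _ = classify_constructed(sv, seg, regions, line1=line1)
    assert label == "L1_TRANSPOSITION"


def test_high_svaf_junction_demarcating_amplicon_is_self_joining():
    sv = make_sv_frame([
        ("s1", "chr1", 400_000, "chr1", 700_000, "DUP", "-", "+", 0.9),
        ("s1", "chr1", 450_000, "chr1", 480_000, "DEL", "+", "-", 0.12),
        ("s1", "chr1", 500_000, "chr1", 512_000, "INV", "+", "+", 0.15),
        ("s1", "chr1", 550_000, "chr1", 610_000, "INV", "-", "-", 0.10),
        ("s1", "chr1", 640_000, "chr1", 660_000, "DEL", "+", "-", 0.14),
    ])
    seg = make_segments("s1", "chr1", [(1, 399_999, 1.0),
                                       (400_000, 700_000, 8.0),
                                       (700_001, 2_000_000, 1.0)])
    regions = regions_of("s1", [("chr1", 400_000, 700_000, 10)])
    label, _ = classify_constructed(sv, seg, regions)
    assert label == "SELF_JOINING_AMPLICON"


def test_junction_connecting_distant_amplicons_is_assembled():
    sv = make_sv_frame([
        ("s1", "chr1", 800_000, "chr1", 3_800_000, "INV", "+", "+", 0.92),
        ("s1", "chr1", 700_000, "chr1", 3_880_000, "INV", "-", "-", 0.2),
        ("s1", "chr1", 740_000, "chr1", 770_000, "DEL", "+", "-", 0.15),
        ("s1", "chr1", 3_830_000, "chr1", 3_860_000, "DEL", "+", "-", 0.12),
    ])
    seg = make_segments("s1", "chr1", [
        (1, 499_999, 1.0), (500_000, 800_000, 8.0),
        (800_001, 3_799_999, 1.0), (3_800_000, 4_100_000, 8.0),
        (4_100_001, 6_000_000, 1.0)])
    regions = regions_of("s1", [("chr1", 700_000, 800_000, 4),
                                ("chr1", 3_800_000, 3_880_000, 4)])
    label, cluster = classify_constructed(sv, seg, regions)
    assert label == "ASSEMBLED_AMPLICON"
    assert len(cluster.footprints) == 2   # bridged by the intra junction


def test_cluster_failing_every_rule_is_unclassified():
    sv = make_sv_frame([
        ("s1", "chr1", 100_000, "chr1", 150_000, "DEL", "+", "-", 0.3),
        ("s1", "chr1", 120_000, "chr1", 170_000, "DUP", "-", "+", 0.3),
        ("s1", "chr1", 140_000, "chr1", 190_000, "INV", "+", "+", 0.3),
    ])
    seg = make_segments("s1", "chr1", [(1, 2_000_000, 1.0)])
    regions = regions_of("s1", [("chr1", 100_000, 190_000, 6)])
    label, _ = classify_constructed(sv, seg, regions)
    assert label == "UNCLASSIFIED"


# ---------------------------------------------------------------------------
# reintegration
# ---------------------------------------------------------------------------

@pytest.fixture
def amplicon_context():
    sv = make_sv_frame([
        ("s1", "chr1", 400_000, "chr1", 700_000, "DUP", "-", "+", 0.9),
        ("s1", "chr1", 450_000, "chr1", 480_000, "DEL", "+", "-", 0.12),
        ("s1", "chr1", 500_000, "chr1", 512_000, "INV", "+", "+", 0.15),
        ("s1", "chr1", 550_000, "chr1", 610_000, "INV", "-", "-", 0.10),
        ("s1", "chr1", 640_000, "chr1", 660_000, "DEL", "+", "-", 0.14),
        # candidate reintegration SVs out of the amplicon:
        ("s1", "chr1", 520_000, "chr2", 9_000_000, "TRA", "+", "-", 0.3),
        ("s1", "chr1", 530_000, "chr1", 1_030_000, "DEL", "+", "-", 0.3),
        ("s1", "chr1", 540_000, "chr2", 20_000_000, "TRA", "+", "-", 0.3),
    ])
    seg = pd.concat([
        make_segments("s1", "chr1", [(1, 399_999, 1.0),
                                     (400_000, 700_000, 8.0),
                                     (700_001, 2_000_000, 1.0)]),
        make_segments("s1", "chr2", [(1, 19_999_999, 1.0),
                                     (20_000_000, 30_000_000, 2.2)]),
    ], ignore_index=True)
    regions = {"s1": regions_of("s1", [("chr1", 400_000, 700_000, 14)])}
    idx = _SegmentIndex(seg)
    svcs = build_svcs(sv, regions["s1"])
    for c in svcs:
        c.profile = compute_profile(c, sv, idx, seg)
        c.label = "SELF_JOINING_AMPLICON"
    return sv, seg, regions, svcs


def test_reintegration_requires_tra_or_large_span_and_flat_landing(amplicon_context):
    sv, seg, regions, svcs = amplicon_context
    flags = detect_reintegration(sv, svcs, regions, seg)
    assert flags.loc["sv5"]           # TRA to a flat, non-clustered locus
    assert not flags.loc["sv6"]       # 500 kb span, not a translocation
    assert not flags.loc["sv7"]       # lands on a CN step (|dACN| >= 0.5)


def test_reintegration_needs_amplicon_labelled_cluster(amplicon_context):
    sv, seg, regions, svcs = amplicon_context
    for c in svcs:
        c.label = "NAHRD"
    flags = detect_reintegration(sv, svcs, regions, seg)
    assert not flags.any()


# ---------------------------------------------------------------------------
# planted-archetype recovery (synthetic cohort, end to end)
# ---------------------------------------------------------------------------

def test_planted_archetypes_recovered_per_class(archetype_analysis):
    accuracy = archetype_accuracy(archetype_analysis)
    assert set(accuracy) == {"CFS_LIKE", "L1_TRANSPOSITION", "NAHRD", "BFBC",
                             "SELF_JOINING_AMPLICON", "ASSEMBLED_AMPLICON"}
    for cls, acc in accuracy.items():
        assert acc >= 0.90, f"{cls}: {acc}"


def test_amplicon_labels_imply_amplified_segment_overlap(archetype_analysis):
    from svscape.svc import find_amplified_segments, _overlaps
    seg = archetype_analysis["segments"]
    for _, row in archetype_analysis["svc_table"].iterrows():
        if row["label"] not in ("NAHRD", "BFBC"):
            continue
        amps = find_amplified_segments(seg[seg["sample_id"] == row["sample_id"]])
        fps = []
        for fp in row["footprints"].split(";"):
            chrom, span = fp.split(":")
            s, e = map(int, span.split("-"))
            fps.append((chrom, s, e))
        assert any(_overlaps(fp, a) for fp in fps for a in amps)


def test_foldback_fraction_strictly_highest_in_bfbc(archetype_analysis):
    by_label = archetype_analysis["svc_table"].groupby("label")["frac_foldback"].mean()
    assert by_label.idxmax() == "BFBC"
    others = by_label.drop("BFBC")
    assert (by_label["BFBC"] > others).all()


def test_planted_reintegrations_recovered(archetype_analysis):
    truth = archetype_analysis["cohort"].truth["sv"].set_index("sv_id")
    flags = archetype_analysis["reintegration"]
    planted = truth.index[truth["reintegration"]]
    assert flags.loc[planted].mean() >= 0.9
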