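import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from svscape.config import DEFAULTS
from svscape.io_formats import AnnotationTrack
from svscape.rs_features import (BASE_CLASSES, CATEGORIES, build_catalog,
                                 breakpoints_by_chrom, chromatin_enrichment,
                                 classify_sv_table, detect_clustered_regions,
                                 size_bin)

from conftest import make_sv_frame


def brute_force_regions(breakpoints, factor=10.0, min_size=3):
    """Exhaustive-scan oracle for clustered-region detection.

    Computes the threshold from all intra-chromosomal gaps, then checks every
    candidate index run directly for the maximal-run property.
    """
    gaps = [np.diff(np.sort(p)) for p in breakpoints.values() if len(p) >= 2]
    if not gaps:
        return []
    mean_gap = np.concatenate(gaps).mean()
    if mean_gap == 0:
        return []
    thr = mean_gap / factor
    out = []
    for chrom in sorted(breakpoints):
        pos = np.sort(breakpoints[chrom])
        n = len(pos)
        for i in range(n):
            for j in range(i + min_size - 1, n):
                if all(pos[k + 1] - pos[k] <= thr for k in range(i, j)):
                    left_open = i == 0 or pos[i] - pos[i - 1] > thr
                    right_open = j == n - 1 or pos[j + 1] - pos[j] > thr
                    if left_open and right_open:
                        out.append((chrom, int(pos[i]), int(pos[j]), j - i + 1))
    return out


def test_exactly_80_categories():
    assert len(CATEGORIES) == 80
    assert len(set(CATEGORIES)) == 80
    assert len(BASE_CLASSES) == 20


@pytest.mark.parametrize("span, expected", [
    (500, "<1kb"), (999, "<1kb"), (1_000, "1-10kb"), (9_999, "1-10kb"),
    (100_000, "100kb-1Mb"), (10_000_000, ">10Mb"), (50_000_000, ">10Mb"),
])
def test_size_bins_half_open_upward(span, expected):
    assert size_bin(span) == expected


def test_cluster_detection_matches_brute_force_oracle():
    """Exact agreement with the exhaustive-scan oracle on random instances."""
    rng = np.random.default_rng(5)
    for _ in range(100):
        n = int(rng.integers(2, 51))
        chroms = rng.choice(["chr1", "chr2"], size=n)
        bps = {}
        for c in ("chr1", "chr2"):
            pos = rng.integers(1, 10_000_000, size=(chroms == c).sum())
            if len(pos):
                bps[c] = np.sort(pos)
        got = detect_clustered_regions(bps, "s")
        got_rows = [tuple(r) for r in got.regions.itertuples(index=False)]
        assert sorted(got_rows) == sorted(brute_force_regions(bps))


def test_uniform_breakpoints_yield_no_clusters():
    bps = {"chr1": np.arange(1, 100_000_001, 5_000_000)}
    assert len(detect_clustered_regions(bps, "s").regions) == 0


def test_dense_run_among_scattered_is_one_cluster():
    dense = np.arange(1_000_000, 1_050_000, 5_000)     # 10 bps in 50 kb
    sparse = np.arange(10_000_000, 100_000_000, 10_000_000)
    regions = detect_clustered_regions(
        {"chr1": np.sort(np.concatenate([dense, sparse]))}, "s").regions
    assert len(regions) == 1
    assert regions.iloc[0]["n_breakpoints"] == 10
    assert regions.iloc[0]["start"] == 1_000_000
    assert regions.iloc[0]["end"] == 1_045_000


def test_two_breakpoints_never_cluster():
    assert len(detect_clustered_regions({"chr1": np.array([5, 10])}, "s").regions) == 0


@pytest.fixture
def tracks():
    active = AnnotationTrack.from_intervals("chromatin_active",
                                            [("chr1", 0, 100_000)])
    line1 = AnnotationTrack.from_intervals("line1",
                                           [("chr2", 500_000, 506_000)])
    return active, line1


def test_classification_is_total_and_either_breakpoint_semantics(tracks):
    active, line1 = tracks
    sv = make_sv_frame([
        ("s1", "chr1", 500, "chr1", 1_000, "DEL", "+", "-"),      # active
        ("s1", "chr1", 200_000, "chr1", 201_000, "DUP", "-", "+"),  # inactive, 1 kb
        ("s1", "chr1", 99_000, "chr1", 250_000, "INV", "+", "+"),   # bp1 active
        ("s1", "chr1", 1, "chr2", 505_000, "TRA", "+", "-"),       # inside LINE-1
        ("s1", "chr1", 200, "chr2", 506_900, "TRA", "+", "-"),     # 900 bp away
        ("s1", "chr1", 300, "chr2", 600_000, "TRA", "+", "-"),     # far from LINE-1
    ])
    out = classify_sv_table(sv, {}, active, line1)
    assert set(out["category"]).issubset(set(CATEGORIES))
    assert out["category"].iloc[0] == "DEL:<1kb:nonclustered:active"
    assert out["category"].iloc[1] == "DUP:1-10kb:nonclustered:inactive"
    assert out["chromatin"].iloc[2] == "active"
    assert out["base_class"].iloc[3] == "TRANSPOSITION"
    assert out["base_class"].iloc[4] == "TRANSPOSITION"   # < 1.0 kb
    assert out["base_class"].iloc[5] == "TRA"


@given(st.integers(1, 10**8), st.integers(1, 10**7),
       st.sampled_from(["DEL", "DUP", "INV"]))
def test_every_intra_sv_gets_exactly_one_category(pos, span, sv_type):
    active = AnnotationTrack.from_intervals("a", [("chr1", 0, 50_000_000)])
    line1 = AnnotationTrack.from_intervals("l", [])
    sv = make_sv_frame([("s1", "chr1", pos, "chr1", pos + span, sv_type,
                         "+", "-")])
    out = classify_sv_table(sv, {}, active, line1)
    assert out["category"].iloc[0] in CATEGORIES


def test_catalog_row_sums_and_exclusion(tracks):
    active, line1 = tracks
    rows = [("s1", "chr1", 1_000 * i, "chr1", 1_000 * i + 500, "DEL", "+", "-")
            for i in range(1, 13)]
    rows += [("s2", "chr1", 10_000 * i, "chr1", 10_000 * i + 500, "DUP", "-", "+")
             for i in range(1, 10)]
    sv = classify_sv_table(make_sv_frame(rows), {}, active, line1)
    catalog, excluded = build_catalog(sv)
    assert list(catalog.columns) == list(CATEGORIES)
    assert catalog.loc["s1"].sum() == 12
    assert catalog.loc["s2"].sum() == 9
    assert excluded == ["s2"]          # below the 10-SV floor


def test_empty_cohort_catalog():
    catalog, excluded = build_catalog(make_sv_frame([]).assign(category=[]))
    assert catalog.shape == (0, 80)
    assert excluded == []


def test_chromatin_enrichment_null_and_skewed(tracks):
    active, line1 = tracks
    rng = np.random.default_rng(1)
    # null: SV active share equals the genomic share
    sv = pd.DataFrame({
        "base_class": "DEL:<1kb",
        "chromatin": ["active"] * 17 + ["inactive"] * 83,
    })
    res = chromatin_enrichment(sv, active_bp=17, inactive_bp=83)
    assert res["odds_ratio"].iloc[0] == pytest.approx(1.0, abs=0.05)
    assert res["p_value"].iloc[0] > 0.5
    # derived: (30, 70) against a 17:83 genomic share
    sv2 = pd.DataFrame({"base_class": "DUP:<1kb",
                        "chromatin": ["active"] * 30 + ["inactive"] * 70})
    res2 = chromatin_enrichment(sv2, active_bp=170_000, inactive_bp=830_000)
    from scipy.stats import fisher_exact
    odds, p = fisher_exact([[30, 70], [17, 83]])
    assert res2["odds_ratio"].iloc[0] == pytest.approx(odds)
    assert res2["p_value"].iloc[0] == pytest.approx(p)


def test_chromatin_enrichment_rejects_zero_track():
    with pytest.raises(ValueError):
        chromatin_enrichment(pd.DataFrame(), 0, 10)


def test_breakpoints_by_chrom_collects_both_ends():
    sv = make_sv_frame([("s1", "chr1", 10, "chr2", 20, "TRA", "+", "-")])
    bps = breakpoints_by_chrom(sv)
    assert list(bps["chr1"]) == [10] and list(bps["chr2"]) == [20]
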