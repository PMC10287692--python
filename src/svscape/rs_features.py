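"""Rearrangement-signature features: clustered regions and the 80-category catalog.

Category schema
---------------
Each SV receives exactly one of 80 categories::

    (DEL | DUP | INV) x (<1kb | 1-10kb | 10-100kb | 100kb-1Mb | 1-10Mb | >10Mb)
        + TRA + TRANSPOSITION                       -> 20 base classes
    x (non-clustered | clustered)                   -> 40
    x (active | inactive chromatin)                 -> 80

Size bins are half-open with the exact power assigned upward (a 1,000 bp event
falls in "1-10kb"). A translocation becomes TRANSPOSITION when either
breakpoint lies within 1.0 kb of a LINE-1 element. "Clustered" and "active"
use either-breakpoint semantics.

Clustered regions
-----------------
A sample's rearrangement breakpoints are locally clustered where their density
is at least 10-fold the sample's whole-genome average: maximal runs of
consecutive intra-chromosomal breakpoints whose gaps are all at most
(mean inter-breakpoint distance) / 10, kept when the run holds at least
``min_cluster_size`` breakpoints.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULTS
from .io_formats import AnnotationTrack

SIZE_BIN_NAMES = ("<1kb", "1-10kb", "10-100kb", "100kb-1Mb", "1-10Mb", ">10Mb")

#: The 20 base classes in fixed order.
BASE_CLASSES = tuple(f"{t}:{b}" for t in ("DEL", "DUP", "INV")
                     for b in SIZE_BIN_NAMES) + ("TRA", "TRANSPOSITION")

#: The 80 category labels in fixed, documented column order.
CATEGORIES = tuple(f"{base}:{dist}:{chrom}"
                   for base in BASE_CLASSES
                   for dist in ("nonclustered", "clustered")
                   for chrom in ("active", "inactive"))

assert len(CATEGORIES) == 80


def size_bin(span: int, edges: tuple[int, ...] | None = None) -> str:
    """Size-bin label for an intra-chromosomal SV of ``span = pos2 - pos1`` bp."""
    edges = edges or DEFAULTS["size_bin_edges"]
    return SIZE_BIN_NAMES[int(np.searchsorted(edges, span, side="right"))]


# ---------------------------------------------------------------------------
# Clustered-region detection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RegionSet:
    """Per-sample clustered regions with point lookup by region id."""

    sample_id: str
    regions: pd.DataFrame  # columns chrom, start, end, n_breakpoints (1-based)

    def region_id_at(self, chrom: str, pos: int) -> int:
        """Index of the region containing a 1-based position, or -1."""
        sub = self.regions
        mask = (sub["chrom"] == chrom) & (sub["start"] <= pos) & (pos <= sub["end"])
        idx = np.flatnonzero(mask.to_numpy())
        return int(sub.index[idx[0]]) if len(idx) else -1

    def contains(self, chrom: str, pos: int) -> bool:
        return self.region_id_at(chrom, pos) >= 0


def breakpoints_by_chrom(sv: pd.DataFrame) -> dict[str, np.ndarray]:
    """All breakpoint positions of one sample's SV table, keyed by chromosome."""
    out: dict[str, list[int]] = {}
    for chrom, pos in zip(sv["chrom1"], sv["pos1"]):
        out.setdefault(str(chrom), []).append(int(pos))
    for chrom, pos in zip(sv["chrom2"], sv["pos2"]):
        out.setdefault(str(chrom), []).append(int(pos))
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in out.items()}


def detect_clustered_regions(breakpoints: Mapping[str, np.ndarray],
                             sample_id: str = "",
                             thresholds: Mapping[str, float] | None = None,
                             ) -> RegionSet:
    """Find a sample's SV-clustered regions.

    Parameters
    ----------
    breakpoints
        Chromosome -> sorted breakpoint positions (1-based), both ends of
        every SV (see :func:`breakpoints_by_chrom`).

    Notes
    -----
    The genome-average inter-breakpoint distance is the mean of all
    intra-chromosomal consecutive gaps; a region is a maximal run whose gaps
    are all <= average / ``cluster_density_factor`` containing at least
    ``min_cluster_size`` breakpoints. Fewer than two breakpoints genome-wide
    yields no regions.
    """
    cfg = thresholds or DEFAULTS
    gaps: list[np.ndarray] = []
    for pos in breakpoints.values():
        if len(pos) >= 2:
            gaps.append(np.diff(np.sort(pos)))
    empty = pd.DataFrame(columns=["chrom", "start", "end", "n_breakpoints"])
    if not gaps:
        return RegionSet(sample_id, empty)
    mean_gap = float(np.concatenate(gaps).mean())
    if mean_gap == 0:
        return RegionSet(sample_id, empty)
    max_gap = mean_gap / cfg["cluster_density_factor"]
    min_size = int(cfg["min_cluster_size"])
    rows = []
    for chrom in sorted(breakpoints):
        pos = np.sort(breakpoints[chrom])
        if len(pos) < 2:
            continue
        close = np.diff(pos) <= max_gap
        # maximal runs of consecutive close gaps
        i = 0
        while i < len(close):
            if close[i]:
                j = i
                while j < len(close) and close[j]:
                    j += 1
                n = j - i + 1  # breakpoints in the run
                if n >= min_size:
                    rows.append((chrom, int(pos[i]), int(pos[j]), n))
                i = j
            else:
                i += 1
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_breakpoints"])
    return RegionSet(sample_id, regions)


def detect_clustered_regions_cohort(sv: pd.DataFrame,
                                    thresholds: Mapping[str, float] | None = None,
                                    ) -> dict[str, RegionSet]:
    """Clustered regions per sample for a cohort SV table."""
    return {
        str(sample): detect_clustered_regions(
            breakpoints_by_chrom(grp), str(sample), thresholds)
        for sample, grp in sv.groupby("sample_id", sort=True)
    }


# ---------------------------------------------------------------------------
# Per-SV classification and catalog
# ---------------------------------------------------------------------------

def classify_sv_table(sv: pd.DataFrame, regions: Mapping[str, RegionSet],
                      chromatin: AnnotationTrack, line1: AnnotationTrack,
                      thresholds: Mapping[str, float] | None = None,
                      ) -> pd.DataFrame:
    """Assign each SV its category, adding ``clustered``/``chromatin``/
    ``base_class``/``category`` columns."""
    cfg = thresholds or DEFAULTS
    out = sv.copy()
    clustered, chrom_state, base = [], [], []
    for row in out.itertuples(index=False):
        rs = regions.get(str(row.sample_id))
        is_clust = bool(rs is not None and (
            rs.contains(str(row.chrom1), int(row.pos1))
            or rs.contains(str(row.chrom2), int(row.pos2))))
        active = bool(chromatin.contains(str(row.chrom1), int(row.pos1))
                      or chromatin.contains(str(row.chrom2), int(row.pos2)))
        if row.sv_type == "TRA":
            near_l1 = (line1.distance(str(row.chrom1), int(row.pos1))
                       < cfg["l1_transposition_dist"]
                       or line1.distance(str(row.chrom2), int(row.pos2))
                       < cfg["l1_transposition_dist"])
            b = "TRANSPOSITION" if near_l1 else "TRA"
        else:
            b = f"{row.sv_type}:{size_bin(int(row.pos2) - int(row.pos1), cfg['size_bin_edges'])}"
        clustered.append(is_clust)
        chrom_state.append("active" if active else "inactive")
        base.append(b)
    out["clustered"] = clustered
    out["chromatin"] = chrom_state
    out["base_class"] = base
    out["category"] = [
        f"{b}:{'clustered' if c else 'nonclustered'}:{s}"
        for b, c, s in zip(base, clustered, chrom_state)
    ]
    return out


def build_catalog(sv: pd.DataFrame,
                  min_sv: int | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Samples x 80 category count matrix.

    Returns the catalog (all samples, fixed :data:`CATEGORIES` column order)
    and the list of samples excluded from signature extraction because they
    carry fewer than ``min_sv`` (default 10) SVs.
    """
    min_sv = DEFAULTS["min_sv_per_sample"] if min_sv is None else min_sv
    counts = (sv.groupby(["sample_id", "category"]).size()
              .unstack(fill_value=0) if len(sv) else pd.DataFrame())
    catalog = counts.reindex(columns=list(CATEGORIES), fill_value=0)
    catalog = catalog.fillna(0).astype(int)
    catalog.index = catalog.index.astype(str)
    catalog = catalog.sort_index()
    excluded = [s for s in catalog.index if catalog.loc[s].sum() < min_sv]
    return catalog, excluded


def chromatin_enrichment(sv: pd.DataFrame, active_bp: int,
                         inactive_bp: int) -> pd.DataFrame:
    """Per-category active-chromatin enrichment (odds ratio + Fisher p).

    For each base class the 2x2 table compares the SV split between active
    and inactive chromatin against the genomic share of the two compartments
    scaled to the same total, mirroring a goodness-of-fit Fisher test.
    """
    if active_bp <= 0 or inactive_bp <= 0:
        raise ValueError("track lengths must be positive")
    frac_active = active_bp / (active_bp + inactive_bp)
    rows = []
    for base, grp in sv.groupby("base_class"):
        a = int((grp["chromatin"] == "active").sum())
        b = int((grp["chromatin"] == "inactive").sum())
        n = a + b
        exp_a = int(round(n * frac_active))
        table = [[a, b], [exp_a, n - exp_a]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append((base, a, b, float(odds), float(p)))
    return pd.DataFrame(rows, columns=["base_class", "n_active", "n_inactive",
                                       "odds_ratio", "p_value"])
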