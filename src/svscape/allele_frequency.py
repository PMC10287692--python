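"""Purity-adjusted copy number and SV allele frequency (SVAF).

The SVAF of a somatic SV is the fraction of tumor cells carrying the
rearranged allele, estimated from breakpoint read support and corrected for
tumor purity and the local copy-number state:

* raw variant fraction  ``vaf = rsv / (rsv + rref)``;
* purity scaling        ``base = vaf / purity``;
* adjusted copy number  ``acn = 1 + (cnr - 1) / purity`` (1.0 = diploid);
* if ``acn < 0.75`` the locus is treated as LOH and
  ``svaf = base * (2 - purity) * 0.5``;
* if ``acn > 1.25`` and ``base >= 0.60`` the locus is treated as amplified
  and ``svaf = base * acn / (acn - 0.5) * 0.5``;
* otherwise ``svaf = base``.

Of the two breakpoints the one whose adjusted copy number is closer to 1 is
used, and an SVAF is only reported when that breakpoint carries at least 10
reads. Results are capped at 1.0.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .config import DEFAULTS

REGIMES = ("normal", "loh", "amplified", "insufficient_reads")


def adjust_copy_number(cnr: float, purity: float) -> float:
    """Purity-adjusted copy number ratio ``1 + (cnr - 1) / purity``."""
    if purity <= 0:
        raise ValueError("purity must be positive")
    return 1.0 + (cnr - 1.0) / purity


def raw_vaf(rsv: int, rref: int) -> float:
    """Raw variant-supporting read fraction ``rsv / (rsv + rref)``."""
    total = rsv + rref
    if total <= 0:
        raise ValueError("zero total reads at breakpoint")
    return rsv / total


def select_breakpoint_acn(acn1: float, acn2: float) -> tuple[float, int]:
    """Pick the breakpoint whose adjusted CN is closer to 1.

    Returns ``(acn, which)`` with ``which`` 0 for the first (lower-coordinate)
    breakpoint, 1 for the second. Ties go to the first.
    """
    if not (math.isfinite(acn1) and math.isfinite(acn2)):
        raise ValueError("non-finite adjusted copy number")
    if abs(acn2 - 1.0) < abs(acn1 - 1.0):
        return acn2, 1
    return acn1, 0


def compute_svaf(rsv: int, rref: int, purity: float, acn: float,
                 thresholds: Mapping[str, float] | None = None,
                 ) -> tuple[float | None, str]:
    """SVAF at one breakpoint, with the regime that produced it.

    Parameters
    ----------
    rsv, rref
        SV- and reference-supporting read counts at the chosen breakpoint.
    purity
        Tumor purity in (0, 1].
    acn
        Adjusted copy number at the chosen breakpoint
        (:func:`select_breakpoint_acn`).

    Returns
    -------
    (svaf, regime)
        ``svaf`` is ``None`` when the read gate fails
        (``regime == "insufficient_reads"``); otherwise a value in [0, 1].
    """
    cfg = thresholds or DEFAULTS
    if purity <= 0:
        raise ValueError("purity must be positive")
    if rsv + rref < cfg["min_breakpoint_reads"]:
        return None, "insufficient_reads"
    base = raw_vaf(rsv, rref) / purity
    if acn < cfg["loh_acn_max"]:
        svaf = base * (2.0 - purity) * 0.5
        regime = "loh"
    elif acn > cfg["amp_acn_min"] and base >= cfg["amp_base_min"]:
        if acn <= 0.5:  # unreachable with amp_acn_min > 0.5; division guard
            raise ValueError("amplified branch requires acn > 0.5")
        svaf = base * (acn / (acn - 0.5)) * 0.5
        regime = "amplified"
    else:
        svaf = base
        regime = "normal"
    return min(svaf, 1.0), regime


def invert_svaf(svaf: float, purity: float, acn: float,
                thresholds: Mapping[str, float] | None = None) -> float:
    """Expected raw ``vaf`` that :func:`compute_svaf` maps back to ``svaf``.

    Inverse of the regime map given purity and adjusted CN; used by the
    synthetic cohort generator to turn a planted true SVAF into binomial
    read-count expectations. For amplified loci the regime guard
    (``base >= 0.60``) makes the forward map piecewise; the branch consistent
    with the target SVAF is selected.
    """
    cfg = thresholds or DEFAULTS
    if acn < cfg["loh_acn_max"]:
        return svaf * purity / ((2.0 - purity) * 0.5)
    if acn > cfg["amp_acn_min"]:
        # Amplified branch applies iff the implied base clears the guard,
        # i.e. svaf >= 0.5 * amp_base_min * acn / (acn - 0.5).
        if svaf >= 0.5 * cfg["amp_base_min"] * acn / (acn - 0.5):
            return svaf * purity * (acn - 0.5) / (0.5 * acn)
    return svaf * purity


# ---------------------------------------------------------------------------
# Segment lookup and table-level annotation
# ---------------------------------------------------------------------------

class _SegmentIndex:
    """Per-(sample, chrom) sorted segment arrays for O(log n) position lookup."""

    def __init__(self, segments: pd.DataFrame):
        self._idx: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for (sample, chrom), grp in segments.groupby(["sample_id", "chrom"], sort=False):
            g = grp.sort_values("start")
            self._idx[(sample, str(chrom))] = (
                g["start"].to_numpy(np.int64),
                g["end"].to_numpy(np.int64),
                g["acn"].to_numpy(float),
            )

    def acn_at(self, sample: str, chrom: str, pos: int) -> float:
        """Adjusted CN of the segment covering a 1-based position (nan if none)."""
        key = (sample, str(chrom))
        if key not in self._idx:
            return float("nan")
        starts, ends, acn = self._idx[key]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos > ends[i]:
            return float("nan")
        return float(acn[i])


def adjust_segments(segments: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Add the purity-adjusted ``acn`` column to a segment table."""
    purity = meta.set_index("sample_id")["purity"]
    out = segments.copy()
    p = out["sample_id"].map(purity)
    if p.isna().any():
        missing = out.loc[p.isna(), "sample_id"].unique()
        raise ValueError(f"samples missing purity: {list(missing)[:5]}")
    out["acn"] = 1.0 + (out["cnr"] - 1.0) / p
    return out


def delta_cn_at_breakpoint(index: _SegmentIndex, sample: str, chrom: str,
                           pos: int, flank: int | None = None) -> float:
    """Signed adjusted-CN difference across a breakpoint (right minus left).

    Reads the segments covering ``pos + flank`` and ``pos - flank``
    (default: 1 bp each side). Returns nan when a flank is uncovered, e.g. at
    a chromosome end.
    """
    flank = DEFAULTS["delta_cn_flank"] if flank is None else flank
    left = index.acn_at(sample, chrom, pos - flank)
    right = index.acn_at(sample, chrom, pos + flank)
    return right - left


def annotate_svaf(sv: pd.DataFrame, segments: pd.DataFrame, meta: pd.DataFrame,
                  thresholds: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Augment an SV table with ``vaf``, ``acn``, ``regime`` and ``svaf``.

    ``segments`` must already carry ``acn`` (see :func:`adjust_segments`).
    Read counts for the gate and the raw vaf are taken at the breakpoint
    chosen by :func:`select_breakpoint_acn`; a breakpoint falling outside all
    segments is treated as copy-neutral (acn 1).
    """
    index = _SegmentIndex(segments)
    purity = meta.set_index("sample_id")["purity"].to_dict()
    out = sv.copy()
    vafs, acns, regimes, svafs = [], [], [], []
    for row in out.itertuples(index=False):
        p = purity[row.sample_id]
        a1 = index.acn_at(row.sample_id, row.chrom1, row.pos1)
        a2 = index.acn_at(row.sample_id, row.chrom2, row.pos2)
        a1 = 1.0 if math.isnan(a1) else a1
        a2 = 1.0 if math.isnan(a2) else a2
        acn, which = select_breakpoint_acn(a1, a2)
        rref = row.rref2 if which == 1 else row.rref1
        svaf, regime = compute_svaf(row.rsv, rref, p, acn, thresholds)
        total = row.rsv + rref
        vafs.append(row.rsv / total if total > 0 else np.nan)
        acns.append(acn)
        regimes.append(regime)
        svafs.append(np.nan if svaf is None else svaf)
    out["vaf"] = vafs
    out["acn"] = acns
    out["regime"] = regimes
    out["svaf"] = svafs
    return out
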