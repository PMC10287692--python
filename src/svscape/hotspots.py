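"""Recurrent SV hotspots: windowed recurrence, four calling conditions, typing.

Genome-wide recurrence of tandem duplications and inversions is counted in
500 kb sliding windows overlapping by 50 kb (step 450 kb). A window becomes a
hotspot candidate when

1. SVs are detected in more than 5% of cases,
2. it is not a common fragile site and not driven by active transposons,
3. at least five cases carry an SV with SVAF > 0.4 in it, and
4. cases with SVs in the window show significantly higher adjusted copy
   number there than cases without (one-sided Mann-Whitney U, BH FDR < 0.05
   across candidate windows).

Overlapping passing windows merge into one hotspot, typed ``singular`` when a
core sub-interval is shared by at least 70% of the positive cases and the
median per-case SV count is at most 2, else ``multiple``.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEFAULTS
from .io_formats import AnnotationTrack

HOTSPOT_SV_TYPES = ("DUP", "INV")


@dataclasses.dataclass
class WindowCount:
    chrom: str
    start: int   # 1-based inclusive
    end: int
    cases_with_sv: set
    cases_high_svaf: set
    sv_types_present: set
    member_index: list  # sv table index labels with a breakpoint in the window


@dataclasses.dataclass
class Hotspot:
    chrom: str
    start: int
    end: int
    cases: set
    n_high_svaf: int
    q_value: float
    hotspot_class: str = ""


def window_recurrence(sv: pd.DataFrame, genome: Mapping[str, int],
                      thresholds: Mapping[str, float] | None = None,
                      ) -> list[WindowCount]:
    """Per-window DUP/INV recurrence counts.

    An SV is counted in every window containing either breakpoint. A
    chromosome shorter than the window yields a single whole-chromosome
    window. Requires the ``svaf`` column.
    """
    cfg = thresholds or DEFAULTS
    width = int(cfg["hotspot_window"])
    step = int(cfg["hotspot_step"])
    sub = sv[sv["sv_type"].isin(HOTSPOT_SV_TYPES)]
    windows: list[WindowCount] = []
    for chrom in sorted(genome):
        length = int(genome[chrom])
        starts = [1] if length <= width else \
            list(range(1, length - width + 2, step))
        if length > width and starts[-1] + width - 1 < length:
            starts.append(length - width + 1)
        for s in starts:
            e = min(s + width - 1, length)
            windows.append(WindowCount(chrom, s, e, set(), set(), set(), []))
    by_chrom: dict[str, list[WindowCount]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for idx, row in sub.iterrows():
        seen = set()
        for chrom, pos in ((str(row["chrom1"]), int(row["pos1"])),
                           (str(row["chrom2"]), int(row["pos2"]))):
            for w in by_chrom.get(chrom, []):
                if w.start <= pos <= w.end and id(w) not in seen:
                    seen.add(id(w))
                    w.cases_with_sv.add(str(row["sample_id"]))
                    w.sv_types_present.add(str(row["sv_type"]))
                    w.member_index.append(idx)
                    svaf = row.get("svaf", np.nan)
                    if not pd.isna(svaf) and svaf > cfg["hotspot_high_svaf"]:
                        w.cases_high_svaf.add(str(row["sample_id"]))
    return windows


def _mean_acn_in_window(segments: pd.DataFrame, chrom: str, start: int,
                        end: int) -> pd.Series:
    """Per-sample length-weighted mean adjusted CN over a window."""
    seg = segments[(segments["chrom"] == chrom) & (segments["start"] <= end)
                   & (segments["end"] >= start)]
    if len(seg) == 0:
        return pd.Series(dtype=float)
    ov = (np.minimum(seg["end"], end) - np.maximum(seg["start"], start) + 1)
    weighted = seg["acn"] * ov
    grp = pd.DataFrame({"sample_id": seg["sample_id"], "w": ov, "wx": weighted})
    agg = grp.groupby("sample_id").sum()
    return agg["wx"] / agg["w"]


def call_hotspots(windows: Sequence[WindowCount], sv: pd.DataFrame,
                  cfs: AnnotationTrack, line1: AnnotationTrack,
                  segments: pd.DataFrame, cohort_size: int,
                  thresholds: Mapping[str, float] | None = None,
                  ) -> list[Hotspot]:
    """Apply the four hotspot conditions and merge passing windows."""
    cfg = thresholds or DEFAULTS
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    # cohort universe: every profiled sample, including the SV-free ones
    all_samples = set(segments["sample_id"].astype(str)) \
        | set(sv["sample_id"].astype(str))

    def overlaps_track(track: AnnotationTrack, chrom: str, start: int,
                       end: int) -> bool:
        if chrom not in track.intervals:
            return False
        s0, e0 = start - 1, end  # to 0-based half-open
        starts, ends = track.intervals[chrom]
        i = int(np.searchsorted(starts, e0, side="left"))
        return bool(i > 0 and ends[i - 1] > s0) or bool(
            i < len(starts) and starts[i] < e0)

    def l1_driven(w: WindowCount) -> bool:
        # active-transposon rule: most SV-positive cases carry only
        # LINE-1-proximal translocations in the window
        cases = {}
        in_w = sv[((sv["chrom1"] == w.chrom) & (sv["pos1"].between(w.start, w.end)))
                  | ((sv["chrom2"] == w.chrom) & (sv["pos2"].between(w.start, w.end)))]
        for _, row in in_w.iterrows():
            near = (row["sv_type"] == "TRA" and (
                line1.distance(str(row["chrom1"]), int(row["pos1"]))
                < cfg["hotspot_l1_dist"]
                or line1.distance(str(row["chrom2"]), int(row["pos2"]))
                < cfg["hotspot_l1_dist"]))
            sample = str(row["sample_id"])
            cases.setdefault(sample, True)
            cases[sample] = cases[sample] and near
        if not cases:
            return False
        return sum(cases.values()) / len(cases) > cfg["hotspot_l1_case_frac"]

    candidates = []
    for w in windows:
        if len(w.cases_with_sv) <= cfg["hotspot_case_frac"] * cohort_size:
            continue
        if overlaps_track(cfs, w.chrom, w.start, w.end):
            continue
        if len(w.cases_high_svaf) < cfg["hotspot_min_high_cases"]:
            continue
        if l1_driven(w):
            continue
        candidates.append(w)

    if not candidates:
        return []
    pvals = []
    for w in candidates:
        means = _mean_acn_in_window(segments, w.chrom, w.start, w.end)
        pos = means.reindex([s for s in w.cases_with_sv]).dropna()
        neg = means.reindex([s for s in all_samples - w.cases_with_sv]).dropna()
        if len(pos) == 0 or len(neg) == 0:
            pvals.append(1.0)
            continue
        _, p = stats.mannwhitneyu(pos, neg, alternative="greater")
        pvals.append(float(p))
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    passing = [(w, q) for w, q in zip(candidates, qvals)
               if q < cfg["hotspot_fdr"]]
    passing.sort(key=lambda t: (t[0].chrom, t[0].start))
    hotspots: list[Hotspot] = []
    for w, q in passing:
        if (hotspots and hotspots[-1].chrom == w.chrom
                and w.start <= hotspots[-1].end + 1):
            h = hotspots[-1]
            h.end = max(h.end, w.end)
            h.cases |= w.cases_with_sv
            h.n_high_svaf = max(h.n_high_svaf, len(w.cases_high_svaf))
            h.q_value = min(h.q_value, float(q))
        else:
            hotspots.append(Hotspot(w.chrom, w.start, w.end,
                                    set(w.cases_with_sv),
                                    len(w.cases_high_svaf), float(q)))
    return hotspots


def classify_hotspot(hotspot: Hotspot, sv: pd.DataFrame,
                     thresholds: Mapping[str, float] | None = None) -> str:
    """Type a called hotspot as ``singular`` or ``multiple``.

    Singular: some sub-interval of the hotspot is shared by at least 70% of
    the positive cases (maximum overlap of per-case SV footprints) and the
    median per-case SV count inside the hotspot is at most 2.
    """
    cfg = thresholds or DEFAULTS
    sub = sv[sv["sv_type"].isin(HOTSPOT_SV_TYPES)
             & (sv["sample_id"].astype(str).isin(hotspot.cases))]
    footprints = {}
    counts = {}
    for _, row in sub.iterrows():
        bps = [int(p) for c, p in ((row["chrom1"], row["pos1"]),
                                   (row["chrom2"], row["pos2"]))
               if str(c) == hotspot.chrom and hotspot.start <= p <= hotspot.end]
        if not bps:
            continue
        sample = str(row["sample_id"])
        lo = min(min(bps), int(row["pos1"])) if str(row["chrom1"]) == hotspot.chrom \
            else min(bps)
        hi = max(max(bps), int(row["pos2"])) if str(row["chrom2"]) == hotspot.chrom \
            else max(bps)
        lo, hi = max(lo, hotspot.start), min(hi, hotspot.end)
        cur = footprints.get(sample)
        footprints[sample] = (min(lo, cur[0]), max(hi, cur[1])) if cur else (lo, hi)
        counts[sample] = counts.get(sample, 0) + 1
    if not footprints:
        return "multiple"
    # sweep over footprint endpoints for the maximum sharing fraction
    events = []
    for lo, hi in footprints.values():
        events.append((lo, 1))
        events.append((hi + 1, -1))
    events.sort()
    depth = best = 0
    for _, d in events:
        depth += d
        best = max(best, depth)
    share = best / len(hotspot.cases)
    median_count = float(np.median(list(counts.values()))) if counts else 0.0
    if share >= cfg["singular_share_frac"] and \
            median_count <= cfg["singular_max_median_sv"]:
        return "singular"
    return "multiple"


def hotspot_table(hotspots: Sequence[Hotspot]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": h.chrom, "start": h.start, "end": h.end,
        "n_cases": len(h.cases), "n_high_svaf": h.n_high_svaf,
        "q_value": h.q_value, "hotspot_class": h.hotspot_class,
    } for h in hotspots], columns=["chrom", "start", "end", "n_cases",
                                   "n_high_svaf", "q_value", "hotspot_class"])
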