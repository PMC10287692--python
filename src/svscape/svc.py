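"""SV clusters (SVCs): grouping, profiling and mechanism classification.

A sample's clustered regions (see :mod:`svscape.rs_features`) seed SV
clusters: every SV with a breakpoint in a region belongs to that region's
SVC, and an SV bridging two regions (a translocation, or an intra-chromosomal
junction spanning them) merges the regions into one SVC with multiple
footprints.

Each SVC is profiled (SV-type composition, mean adjusted CN over the
footprint, maximum |dCN| at member breakpoints, stepwise CN pattern, member
SVAFs) and assigned the first matching mechanism class in fixed precedence:

``CFS_LIKE``
    mostly deletions with a stepwise CN reduction, at least one deletion
    dropping the CN ratio by > 0.2 at a breakpoint.
``L1_TRANSPOSITION``
    mostly translocations whose clustered-side breakpoints concentrate in a
    < 500 bp window within 0.1 kb of a LINE-1 element.
``NAHRD``
    tandem-duplication rich, with mutually overlapping spacers (>= 90% of the
    shorter spacer), at least one nested duplication pair ordered by SVAF,
    over an amplified segment.
``BFBC``
    inversion rich with a majority of fold-back inversions, over an amplified
    segment.
``SELF_JOINING_AMPLICON``
    a top-30%-SVAF junction whose breakpoints demarcate the footprint and
    match an amplified segment's boundaries, enclosing most members.
``ASSEMBLED_AMPLICON``
    a top-30%-SVAF junction connecting boundaries of two or more amplified
    segments separated by > 2 Mb, with at least one lower-SVAF member
    connecting or inside the segments.

Anything else is ``UNCLASSIFIED``. An amplified segment is a maximal run of
copy-number segments with adjusted CN above 4.0 entered and exited through
boundary steps above 1.5.

SVs leaving a self-joining/assembled amplicon for a copy-neutral,
non-clustered locus as an ultra-large (> 2 Mb) or translocation junction are
flagged as candidate chromosomal reintegrations of extrachromosomal DNA.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .allele_frequency import _SegmentIndex, delta_cn_at_breakpoint
from .config import DEFAULTS
from .io_formats import AnnotationTrack
from .rs_features import RegionSet

SVC_LABELS = ("CFS_LIKE", "L1_TRANSPOSITION", "NAHRD", "BFBC",
              "SELF_JOINING_AMPLICON", "ASSEMBLED_AMPLICON", "UNCLASSIFIED")


@dataclasses.dataclass
class AmplifiedSegment:
    chrom: str
    start: int
    end: int
    boundary_delta: float
    mean_cn: float


@dataclasses.dataclass
class SVCluster:
    svc_id: str
    sample_id: str
    members: list          # sv table index labels
    footprints: list       # (chrom, start, end) 1-based intervals
    profile: dict = dataclasses.field(default_factory=dict)
    label: str = "UNCLASSIFIED"


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def build_svcs(sv: pd.DataFrame, regions: RegionSet) -> list[SVCluster]:
    """Group one sample's SVs into SV clusters.

    ``sv`` is that sample's SV table (index labels become member ids).
    Union-find over breakpoint-region incidence: an SV with breakpoints in
    two different regions merges them into a single SVC with both footprints.
    """
    reg = regions.regions
    if len(reg) == 0:
        return []
    parent = list(range(len(reg)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    hits: list[tuple[object, int, int]] = []  # (sv index, r1, r2)
    for idx, row in sv.iterrows():
        r1 = regions.region_id_at(str(row["chrom1"]), int(row["pos1"]))
        r2 = regions.region_id_at(str(row["chrom2"]), int(row["pos2"]))
        if r1 >= 0 and r2 >= 0 and r1 != r2:
            union(r1, r2)
        if r1 >= 0 or r2 >= 0:
            hits.append((idx, r1, r2))

    members: dict[int, list] = {}
    for idx, r1, r2 in hits:
        root = find(r1 if r1 >= 0 else r2)
        members.setdefault(root, []).append(idx)
    roots_regions: dict[int, list[int]] = {}
    for rid in range(len(reg)):
        roots_regions.setdefault(find(rid), []).append(rid)

    sample = str(sv["sample_id"].iloc[0]) if len(sv) else regions.sample_id
    out = []
    for n, (root, mem) in enumerate(sorted(members.items())):
        fps = [(str(reg.loc[r, "chrom"]), int(reg.loc[r, "start"]),
                int(reg.loc[r, "end"])) for r in roots_regions[root]]
        out.append(SVCluster(svc_id=f"{sample}.svc{n}", sample_id=sample,
                             members=mem, footprints=sorted(fps)))
    return out


# ---------------------------------------------------------------------------
# Amplified segments
# ---------------------------------------------------------------------------

def find_amplified_segments(segments: pd.DataFrame,
                            thresholds: Mapping[str, float] | None = None,
                            ) -> list[AmplifiedSegment]:
    """Amplified segments of one sample's adjusted copy-number profile.

    Maximal runs of consecutive segments with adjusted CN above
    ``amp_mean_cn`` whose entry and exit steps both exceed
    ``amp_boundary_delta`` (a missing neighbor, i.e. a chromosome end,
    counts as a satisfied boundary).
    """
    cfg = thresholds or DEFAULTS
    out: list[AmplifiedSegment] = []
    for chrom, grp in segments.groupby("chrom", sort=True):
        g = grp.sort_values("start").reset_index(drop=True)
        acn = g["acn"].to_numpy(float)
        high = acn > cfg["amp_mean_cn"]
        i = 0
        while i < len(g):
            if not high[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(g) and high[j + 1]:
                j += 1
            entry = acn[i] - acn[i - 1] if i > 0 else math.inf
            exit_ = acn[j] - acn[j + 1] if j + 1 < len(g) else math.inf
            if entry > cfg["amp_boundary_delta"] and exit_ > cfg["amp_boundary_delta"]:
                lengths = (g.loc[i:j, "end"] - g.loc[i:j, "start"] + 1).to_numpy(float)
                mean_cn = float(np.average(acn[i:j + 1], weights=lengths))
                if mean_cn > cfg["amp_mean_cn"]:
                    delta = min(x for x in (entry, exit_) if math.isfinite(x)) \
                        if math.isfinite(min(entry, exit_)) else max(entry, exit_)
                    out.append(AmplifiedSegment(
                        chrom=str(chrom), start=int(g.loc[i, "start"]),
                        end=int(g.loc[j, "end"]),
                        boundary_delta=float(delta), mean_cn=mean_cn))
            i = j + 1
    return out


def _overlaps(a: tuple[str, int, int], b: AmplifiedSegment) -> bool:
    return a[0] == b.chrom and a[1] <= b.end and b.start <= a[2]


# ---------------------------------------------------------------------------
# Fold-back inversions
# ---------------------------------------------------------------------------

def detect_foldback_inversions(sv: pd.DataFrame, seg_index: _SegmentIndex,
                               depth: Mapping[str, np.ndarray] | None = None,
                               thresholds: Mapping[str, float] | None = None,
                               ) -> set:
    """Flag fold-back inversions in one sample's SV table.

    An inversion is fold-back when (1) no opposite-orientation inversion has
    both breakpoints within the reciprocal-partner window, (2) the CN change
    at a breakpoint is significant (flanking read-depth comparison,
    BH-adjusted q < 0.01, when per-bin ``depth`` is supplied; otherwise a
    segment-based |dACN| > 0.5 fallback), and (3) its span is < 30 kb.
    Returns the set of flagged index labels.
    """
    cfg = thresholds or DEFAULTS
    inv = sv[sv["sv_type"] == "INV"]
    if len(inv) == 0:
        return set()
    w = cfg["foldback_reciprocal_window"]
    candidates = []
    for idx, row in inv.iterrows():
        span = int(row["pos2"]) - int(row["pos1"])
        if span >= cfg["foldback_max_span"]:
            continue
        partner = inv[(inv.index != idx)
                      & (inv["chrom1"] == row["chrom1"])
                      & (inv["orientation1"] != row["orientation1"])
                      & ((inv["pos1"] - row["pos1"]).abs() <= w)
                      & ((inv["pos2"] - row["pos2"]).abs() <= w)]
        if len(partner):
            continue
        candidates.append(idx)
    if not candidates:
        return set()

    if depth is not None:
        nb = int(cfg["foldback_depth_bins"])
        bs = int(cfg["foldback_depth_binsize"])
        pvals, keys = [], []
        for idx in candidates:
            row = sv.loc[idx]
            for pos in (int(row["pos1"]), int(row["pos2"])):
                arr = depth.get(str(row["chrom1"]))
                if arr is None:
                    continue
                b = pos // bs
                left = arr[max(0, b - nb):b]
                right = arr[b + 1:b + 1 + nb]
                if len(left) < 2 or len(right) < 2:
                    continue
                _, p = stats.mannwhitneyu(left, right, alternative="two-sided")
                pvals.append(p)
                keys.append(idx)
        flagged = set()
        if pvals:
            _, q, _, _ = multipletests(pvals, method="fdr_bh")
            for idx, qv in zip(keys, q):
                if qv < cfg["foldback_q_max"]:
                    flagged.add(idx)
        return flagged

    # segment-based fallback: |dACN| at >= 1 breakpoint
    flagged = set()
    for idx in candidates:
        row = sv.loc[idx]
        for pos in (int(row["pos1"]), int(row["pos2"])):
            d = delta_cn_at_breakpoint(seg_index, str(row["sample_id"]),
                                       str(row["chrom1"]), pos)
            if not math.isnan(d) and abs(d) > cfg["foldback_dcn_min"]:
                flagged.add(idx)
                break
    return flagged


# ---------------------------------------------------------------------------
# Profile
# ---------------------------------------------------------------------------

def compute_profile(svc: SVCluster, sv: pd.DataFrame, seg_index: _SegmentIndex,
                    segments: pd.DataFrame,
                    thresholds: Mapping[str, float] | None = None) -> dict:
    """SVC profile: type composition, CN summary and stepwise pattern."""
    cfg = thresholds or DEFAULTS
    mem = sv.loc[svc.members]
    comp = (mem["sv_type"].value_counts(normalize=True)
            .reindex(["DEL", "DUP", "INV", "TRA"], fill_value=0.0).to_dict())

    # footprint-weighted mean adjusted CN
    total_w = 0.0
    total = 0.0
    for chrom, start, end in svc.footprints:
        seg = segments[(segments["chrom"] == chrom)
                       & (segments["start"] <= end) & (segments["end"] >= start)]
        for _, s in seg.iterrows():
            w = min(end, int(s["end"])) - max(start, int(s["start"])) + 1
            total += w * float(s["acn"])
            total_w += w
    mean_cnr = total / total_w if total_w else float("nan")

    # ordered breakpoint CN steps per footprint chromosome
    deltas_by_chrom: dict[str, list[tuple[int, float]]] = {}
    sample = svc.sample_id
    fp_chroms = {c for c, _, _ in svc.footprints}
    for _, row in mem.iterrows():
        for chrom, pos in ((str(row["chrom1"]), int(row["pos1"])),
                           (str(row["chrom2"]), int(row["pos2"]))):
            if chrom in fp_chroms:
                d = delta_cn_at_breakpoint(seg_index, sample, chrom, pos)
                if not math.isnan(d):
                    deltas_by_chrom.setdefault(chrom, []).append((pos, d))
    max_delta = max((abs(d) for v in deltas_by_chrom.values() for _, d in v),
                    default=0.0)
    min_steps = int(cfg["stepwise_min_steps"])
    down = up = False
    for v in deltas_by_chrom.values():
        d = np.array([x for _, x in sorted(v)])
        neg = d < -cfg["cn_drop_min"]
        pos = d > cfg["cn_drop_min"]
        for run, flag in ((neg, "down"), (pos, "up")):
            best = count = 0
            for r in run:
                count = count + 1 if r else 0
                best = max(best, count)
            if best >= min_steps:
                if flag == "down":
                    down = True
                else:
                    up = True
    pattern = ("decreasing" if down and not up
               else "increasing" if up and not down else "none")
    return {
        "type_composition": comp,
        "mean_cnr": mean_cnr,
        "max_delta_cnr": float(max_delta),
        "stepwise_down": down,
        "stepwise_up": up,
        "stepwise_pattern": pattern,
        "n_members": len(mem),
    }


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _top_svaf_members(mem: pd.DataFrame, frac: float) -> set:
    svaf = mem["svaf"].fillna(-1.0)
    n_top = max(1, math.ceil(frac * len(mem)))
    return set(svaf.sort_values(ascending=False).index[:n_top])


def _near(a: int, b: int, tol: float) -> bool:
    return abs(a - b) <= tol


def classify_svc(svc: SVCluster, sv: pd.DataFrame, seg_index: _SegmentIndex,
                 amplified: Sequence[AmplifiedSegment],
                 line1: AnnotationTrack, foldback: set,
                 thresholds: Mapping[str, float] | None = None) -> str:
    """Mechanism class of one profiled SVC (first matching rule wins)."""
    cfg = thresholds or DEFAULTS
    mem = sv.loc[svc.members]
    prof = svc.profile
    comp = prof["type_composition"]
    on_amp = any(_overlaps(fp, seg) for fp in svc.footprints for seg in amplified)

    # --- CFS-like: recurrent deletions with stepwise CN reduction ---
    if comp["DEL"] > cfg["cfs_del_frac"] and prof["stepwise_down"]:
        for _, row in mem[mem["sv_type"] == "DEL"].iterrows():
            d1 = delta_cn_at_breakpoint(seg_index, svc.sample_id,
                                        str(row["chrom1"]), int(row["pos1"]))
            d2 = delta_cn_at_breakpoint(seg_index, svc.sample_id,
                                        str(row["chrom2"]), int(row["pos2"]))
            if ((not math.isnan(d1) and d1 <= -cfg["cn_drop_min"])
                    or (not math.isnan(d2) and d2 >= cfg["cn_drop_min"])):
                return "CFS_LIKE"

    # --- L1 transposition: concentrated translocation breakpoints near LINE-1 ---
    if comp["TRA"] > cfg["l1_tra_frac"]:
        tra = mem[mem["sv_type"] == "TRA"]
        groups: dict[tuple, list[tuple[object, int]]] = {}
        for idx, row in tra.iterrows():
            for chrom, pos in ((str(row["chrom1"]), int(row["pos1"])),
                               (str(row["chrom2"]), int(row["pos2"]))):
                for fp in svc.footprints:
                    if fp[0] == chrom and fp[1] <= pos <= fp[2]:
                        groups.setdefault(fp, []).append((idx, pos))
        for (chrom, _, _), entries in groups.items():
            ids = {i for i, _ in entries}
            pos = [p for _, p in entries]
            if (len(ids) > len(tra) / 2
                    and max(pos) - min(pos) < cfg["l1_concentration_window"]
                    and any(line1.distance(chrom, p) <= cfg["l1_svc_dist"]
                            for p in pos)):
                return "L1_TRANSPOSITION"

    # --- NAHRD: nested, spacer-sharing tandem duplications over an amplicon ---
    if comp["DUP"] > cfg["nahrd_dup_frac"] and on_amp:
        dups = mem[mem["sv_type"] == "DUP"]
        if len(dups) >= 2:
            rows = list(dups.iterrows())
            n_overlap = 0
            nested = False
            for i, (ia, a) in enumerate(rows):
                la = int(a["pos2"]) - int(a["pos1"])
                hit = False
                for j, (ib, b) in enumerate(rows):
                    if i == j or a["chrom1"] != b["chrom1"]:
                        continue
                    lb = int(b["pos2"]) - int(b["pos1"])
                    ov = (min(int(a["pos2"]), int(b["pos2"]))
                          - max(int(a["pos1"]), int(b["pos1"])))
                    if ov >= cfg["spacer_overlap_frac"] * min(la, lb):
                        hit = True
                    sa, sb = a["svaf"], b["svaf"]
                    if (int(a["pos1"]) < int(b["pos1"]) and int(b["pos2"]) < int(a["pos2"])
                            and not pd.isna(sa) and not pd.isna(sb) and sa > sb):
                        nested = True
                n_overlap += hit
            if n_overlap >= len(dups) / 2 and nested:
                return "NAHRD"

    # --- BFBC: fold-back inversion majority over an amplicon ---
    if comp["INV"] > cfg["bfbc_inv_frac"] and on_amp:
        invs = mem[mem["sv_type"] == "INV"]
        if len(invs) and sum(i in foldback for i in invs.index) >= len(invs) / 2:
            return "BFBC"

    top = _top_svaf_members(mem, cfg["top_svaf_frac"])
    tol = cfg["amplicon_boundary_tol"]

    # --- self-joining amplicon: one junction demarcating an amplified footprint ---
    for idx in top:
        row = mem.loc[idx]
        if row["chrom1"] != row["chrom2"]:
            continue
        chrom = str(row["chrom1"])
        p1, p2 = int(row["pos1"]), int(row["pos2"])
        fp_match = any(c == chrom and _near(p1, s, tol) and _near(p2, e, tol)
                       for c, s, e in svc.footprints)
        amp_match = any(seg.chrom == chrom and _near(p1, seg.start, tol)
                        and _near(p2, seg.end, tol) for seg in amplified)
        if not (fp_match and amp_match):
            continue
        between = 0
        for _, m in mem.iterrows():
            bps = [(str(m["chrom1"]), int(m["pos1"])),
                   (str(m["chrom2"]), int(m["pos2"]))]
            on_chrom = [p for c, p in bps if c == chrom]
            if on_chrom and all(p1 <= p <= p2 for p in on_chrom):
                between += 1
        if between > len(mem) / 2:
            return "SELF_JOINING_AMPLICON"

    # --- assembled amplicon: junction connecting distant amplified segments ---
    def _boundary_match(chrom: str, pos: int) -> AmplifiedSegment | None:
        for seg in amplified:
            if seg.chrom == chrom and (_near(pos, seg.start, tol)
                                       or _near(pos, seg.end, tol)):
                return seg
        return None

    def _inside(chrom: str, pos: int, seg: AmplifiedSegment) -> bool:
        return chrom == seg.chrom and seg.start - tol <= pos <= seg.end + tol

    for idx in top:
        row = mem.loc[idx]
        c1, p1 = str(row["chrom1"]), int(row["pos1"])
        c2, p2 = str(row["chrom2"]), int(row["pos2"])
        sa = _boundary_match(c1, p1)
        sb = _boundary_match(c2, p2)
        if sa is None or sb is None or sa is sb:
            continue
        separated = (sa.chrom != sb.chrom
                     or max(sa.start, sb.start) - min(sa.end, sb.end)
                     > cfg["assembled_min_gap"])
        if not separated:
            continue
        jun_svaf = row["svaf"] if not pd.isna(row["svaf"]) else 1.0
        for midx, m in mem.iterrows():
            if midx == idx:
                continue
            msvaf = m["svaf"] if not pd.isna(m["svaf"]) else 0.0
            if msvaf >= jun_svaf:
                continue
            b1 = (str(m["chrom1"]), int(m["pos1"]))
            b2 = (str(m["chrom2"]), int(m["pos2"]))
            connects = ((_inside(*b1, sa) and _inside(*b2, sb))
                        or (_inside(*b1, sb) and _inside(*b2, sa)))
            within_one = any(_inside(*b1, s) and _inside(*b2, s)
                             for s in (sa, sb))
            if connects or within_one:
                return "ASSEMBLED_AMPLICON"

    return "UNCLASSIFIED"


# ---------------------------------------------------------------------------
# Cohort orchestration + reintegration
# ---------------------------------------------------------------------------

def classify_cohort(sv: pd.DataFrame, segments: pd.DataFrame,
                    regions: Mapping[str, RegionSet], line1: AnnotationTrack,
                    depth: Mapping[str, Mapping[str, np.ndarray]] | None = None,
                    thresholds: Mapping[str, float] | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, list[SVCluster]]:
    """Build, profile and classify SVCs for a whole cohort.

    Returns (svc_table, sv_annotations, clusters). ``sv_annotations`` carries
    per-SV ``svc_id`` (empty for non-clustered SVs) and ``foldback`` columns
    aligned to ``sv.index``.
    """
    cfg = thresholds or DEFAULTS
    seg_index = _SegmentIndex(segments)
    svc_rows = []
    svc_id = pd.Series("", index=sv.index, dtype=object)
    fb_col = pd.Series(False, index=sv.index)
    clusters: list[SVCluster] = []
    for sample, grp in sv.groupby("sample_id", sort=True):
        sample = str(sample)
        rs = regions.get(sample)
        if rs is None or len(rs.regions) == 0:
            continue
        seg_s = segments[segments["sample_id"] == sample]
        amplified = find_amplified_segments(seg_s, cfg)
        foldback = detect_foldback_inversions(
            grp, seg_index, None if depth is None else depth.get(sample), cfg)
        for idx in foldback:
            fb_col.loc[idx] = True
        for cluster in build_svcs(grp, rs):
            cluster.profile = compute_profile(cluster, sv, seg_index, seg_s, cfg)
            cluster.label = classify_svc(cluster, sv, seg_index, amplified,
                                         line1, foldback, cfg)
            clusters.append(cluster)
            for m in cluster.members:
                svc_id.loc[m] = cluster.svc_id
            fp = ";".join(f"{c}:{s}-{e}" for c, s, e in cluster.footprints)
            svc_rows.append({
                "svc_id": cluster.svc_id, "sample_id": sample,
                "footprints": fp, "label": cluster.label,
                "n_members": cluster.profile["n_members"],
                "mean_cnr": cluster.profile["mean_cnr"],
                "max_delta_cnr": cluster.profile["max_delta_cnr"],
                "stepwise_pattern": cluster.profile["stepwise_pattern"],
                "frac_foldback": float(np.mean(
                    [m in foldback for m in cluster.members])),
            })
    svc_table = pd.DataFrame(svc_rows, columns=[
        "svc_id", "sample_id", "footprints", "label", "n_members", "mean_cnr",
        "max_delta_cnr", "stepwise_pattern", "frac_foldback"])
    annotations = pd.DataFrame({"svc_id": svc_id, "foldback": fb_col})
    return svc_table, annotations, clusters


def detect_reintegration(sv: pd.DataFrame, clusters: Sequence[SVCluster],
                         regions: Mapping[str, RegionSet],
                         segments: pd.DataFrame,
                         thresholds: Mapping[str, float] | None = None,
                         ) -> pd.Series:
    """Flag SVs that look like chromosomal reintegration of an amplicon.

    An SV is flagged when exactly one breakpoint lies in the footprint of a
    self-joining/assembled-amplicon SVC of its sample, the other breakpoint
    is outside every clustered region with |dACN| < 0.5 across it, and the SV
    spans > 2 Mb or is a translocation. Returns a boolean Series on
    ``sv.index``.
    """
    cfg = thresholds or DEFAULTS
    seg_index = _SegmentIndex(segments)
    amp_fps: dict[str, list[tuple[str, int, int]]] = {}
    for cluster in clusters:
        if cluster.label in ("SELF_JOINING_AMPLICON", "ASSEMBLED_AMPLICON"):
            amp_fps.setdefault(cluster.sample_id, []).extend(cluster.footprints)
    flags = pd.Series(False, index=sv.index)
    for idx, row in sv.iterrows():
        sample = str(row["sample_id"])
        fps = amp_fps.get(sample)
        if not fps:
            continue
        bps = [(str(row["chrom1"]), int(row["pos1"])),
               (str(row["chrom2"]), int(row["pos2"]))]
        in_amp = [any(c == fc and fs <= p <= fe for fc, fs, fe in fps)
                  for c, p in bps]
        if sum(in_amp) != 1:
            continue
        oc, op = bps[in_amp.index(False)]
        rs = regions.get(sample)
        if rs is not None and rs.contains(oc, op):
            continue
        d = delta_cn_at_breakpoint(seg_index, sample, oc, op)
        if math.isnan(d) or abs(d) >= cfg["reintegration_dcn_max"]:
            continue
        span = int(row["pos2"]) - int(row["pos1"]) \
            if row["chrom1"] == row["chrom2"] else None
        if row["sv_type"] == "TRA" or (span is not None
                                       and span > cfg["reintegration_min_span"]):
            flags.loc[idx] = True
    return flags
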