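"""Synthetic SV cohort generator with planted ground truth.

Emulates the data a tumor whole-genome SV study feeds into this pipeline —
per-sample somatic SV tables with read support, segmented copy-number
profiles consistent with the planted SVs, tumor purity, and annotation
tracks — on a miniature genome (three 50 Mb chromosomes by default) so full
runs finish in seconds to minutes. Every emitted entity is covered by a
truth table: true SVAFs and categories per SV, true exposures per sample,
mechanism class per planted SV cluster, and planted hotspot intervals.

The generative model per sample:

* purity ~ Uniform(0.3, 0.95);
* signature exposures ~ Dirichlet; SV categories ~ exposure-weighted mixture
  of planted category profiles; SV counts ~ negative binomial;
* coordinates respect the drawn category (size from the bin, clustered
  categories gathered around per-sample cluster seeds, chromatin-dependent
  placement inside/outside the active track, transpositions anchored at
  LINE-1 elements);
* deletions and duplications perturb the copy-number profile; archetype and
  hotspot loci override it with their planted levels; the emitted segments
  are the resulting piecewise-constant profile on the raw (purity-attenuated)
  scale;
* read counts: depth ~ Poisson, SV-supporting reads ~ Binomial(depth, vaf)
  where vaf is the true SVAF pushed backwards through the purity/LOH/
  amplification adjustment given the local adjusted copy number.

SVC archetypes are constructed to satisfy their class rules with margin
(e.g. a BFBC cluster is four same-orientation short inversions on an
adjusted-CN staircase; an assembled amplicon is two CN-8 segments 3 Mb apart
joined by a high-SVAF junction plus low-SVAF internal SVs). A configurable
fraction of self-joining/assembled archetypes also receives a planted
ecDNA-reintegration translocation into a copy-neutral, non-clustered locus.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .allele_frequency import select_breakpoint_acn
from .config import DEFAULTS
from .io_formats import AnnotationTrack, write_segments, write_sv_table, write_track
from .rs_features import CATEGORIES, size_bin

SVC_CLASSES = ("CFS_LIKE", "L1_TRANSPOSITION", "NAHRD", "BFBC",
               "SELF_JOINING_AMPLICON", "ASSEMBLED_AMPLICON")


@dataclasses.dataclass
class HotspotPlan:
    chrom: str
    start: int
    end: int
    n_cases: int
    sv_type: str = "DUP"
    svaf: float = 0.6
    acn: float = 5.0


@dataclasses.dataclass
class SimConfig:
    """Study conditions of a synthetic cohort (all values overridable)."""

    seed: int = 0
    n_samples: int = 60
    genome: dict = dataclasses.field(default_factory=lambda: {
        "chr1": 50_000_000, "chr2": 50_000_000, "chr3": 50_000_000})
    purity_range: tuple[float, float] = (0.3, 0.95)
    n_signatures: int = 6
    profiles: pd.DataFrame | None = None       # K x 80; default_profiles(K)
    exposure_alpha: float = 0.6                # Dirichlet concentration
    sv_count_mean: float = 80.0                # negative binomial mean
    sv_count_disp: float = 5.0                 # negative binomial size r
    svaf_beta: tuple[float, float] = (1.5, 3.5)  # background true-SVAF prior
    depth_mean: float = 80.0                   # Poisson breakpoint depth
    archetypes_per_class: int = 6              # planted SVCs per mechanism
    reintegration_frac: float = 0.5            # SJ/ASM archetypes with a TRA out
    hotspot_plan: list = dataclasses.field(default_factory=lambda: [
        HotspotPlan("chr1", 12_000_000, 12_025_000, 12),
        HotspotPlan("chr2", 30_000_000, 30_025_000, 12)])
    active_period: int = 1_000_000             # active-chromatin tiling period
    active_frac: float = 0.17                  # genomic share of active chromatin
    l1_per_chrom: int = 60
    l1_length: int = 6_000
    cluster_window: int = 150_000              # background cluster-seed spread


@dataclasses.dataclass
class Cohort:
    config: SimConfig
    sv: pd.DataFrame
    segments: pd.DataFrame
    meta: pd.DataFrame
    tracks: dict
    truth: dict
    genome: dict


# ---------------------------------------------------------------------------
# Planted signature profiles
# ---------------------------------------------------------------------------

def default_profiles(k: int = 6) -> pd.DataFrame:
    """Sparse, near-orthogonal planted signature profiles over the 80 categories.

    Caricatures of recurrent rearrangement processes: small deletions, small
    duplications, large active-chromatin duplications, large deletions,
    translocation/transposition, and clustered super-large SVs. Each profile
    puts 85% of its mass on its core categories and spreads the rest
    uniformly.
    """
    if not 1 <= k <= 6:
        raise ValueError("between 1 and 6 default profiles are available")
    cores = [
        lambda c: c.startswith(("DEL:<1kb", "DEL:1-10kb")) and ":nonclustered:" in c,
        lambda c: c.startswith(("DUP:<1kb", "DUP:1-10kb")) and ":nonclustered:" in c,
        lambda c: c.startswith(("DUP:10-100kb", "DUP:100kb-1Mb")) and c.endswith(":active"),
        lambda c: c.startswith(("DEL:10-100kb", "DEL:100kb-1Mb")) and ":nonclustered:" in c,
        lambda c: c.startswith(("TRA:", "TRANSPOSITION:")) and ":nonclustered:" in c,
        lambda c: (":1-10Mb:" in c or ":>10Mb:" in c) and ":clustered:" in c,
    ]
    rows = []
    for core in cores[:k]:
        mask = np.array([core(c) for c in CATEGORIES], dtype=float)
        p = 0.85 * mask / mask.sum() + 0.15 / len(CATEGORIES)
        rows.append(p / p.sum())
    return pd.DataFrame(rows, columns=list(CATEGORIES),
                        index=[f"P{i + 1}" for i in range(k)])


def uniform_background_profile() -> pd.DataFrame:
    """A single profile for uniformly placed, non-clustered background SVs.

    Type mix follows the proportions typical of tumor SV catalogs
    (deletions 45%, duplications 23%, inversions 17%, translocations 15%),
    spread evenly over size bins with chromatin mass at the genomic
    active:inactive share (17:83).
    """
    type_w = {"DEL": 0.45, "DUP": 0.23, "INV": 0.17,
              "TRA": 0.12, "TRANSPOSITION": 0.03}
    chrom_w = {"active": 0.17, "inactive": 0.83}
    w = np.zeros(len(CATEGORIES))
    for i, cat in enumerate(CATEGORIES):
        parts = cat.split(":")
        base, dist, chromatin = parts[0], parts[-2], parts[-1]
        if dist != "nonclustered":
            continue
        n_bins = 1 if base in ("TRA", "TRANSPOSITION") else 6
        w[i] = type_w[base] / n_bins * chrom_w[chromatin]
    return pd.DataFrame([w / w.sum()], columns=list(CATEGORIES), index=["BG"])


def simulate_catalog(profiles: pd.DataFrame, n_samples: int,
                     sv_per_sample: float, seed: int,
                     alpha: float = 0.6) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directly sample a catalog from planted profiles with Poisson noise.

    Returns (catalog, true exposure fractions); the fast path for signature
    recovery studies where genome placement is irrelevant.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    k = len(profiles)
    expo = rng.dirichlet(np.full(k, alpha), size=n_samples)
    mix = expo @ profiles.to_numpy()
    counts = rng.poisson(sv_per_sample * mix)
    idx = [f"S{i:03d}" for i in range(n_samples)]
    catalog = pd.DataFrame(counts, index=idx, columns=profiles.columns)
    exposures = pd.DataFrame(expo, index=idx, columns=profiles.index)
    return catalog, exposures


def simulate_subtype_exposures(n_samples: int = 90, n_components: int = 3,
                               n_signatures: int = 6, seed: int = 0,
                               concentration: float = 12.0,
                               ) -> tuple[pd.DataFrame, pd.Series]:
    """Exposures from well-separated Dirichlet components with truth labels."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows, labels = [], []
    for i in range(n_samples):
        g = i % n_components
        alpha = np.full(n_signatures, 0.15)
        alpha[g] = concentration
        rows.append(rng.dirichlet(alpha) * rng.integers(100, 400))
        labels.append(f"G{g + 1}")
    idx = [f"S{i:03d}" for i in range(n_samples)]
    expo = pd.DataFrame(rows, index=idx,
                        columns=[f"P{i + 1}" for i in range(n_signatures)])
    return expo, pd.Series(labels, index=idx, name="truth_subtype")


# ---------------------------------------------------------------------------
# Placement helpers
# ---------------------------------------------------------------------------

class _Allocator:
    """Reserves non-overlapping genomic blocks with a safety margin."""

    def __init__(self, genome: dict, margin: int = 500_000):
        self.genome = genome
        self.margin = margin
        self.used: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.used[chrom].append((start, end))

    def _free(self, chrom: str, start: int, end: int) -> bool:
        m = self.margin
        return all(e + m < start or end + m < s for s, e in self.used[chrom])

    def alloc(self, rng: np.random.Generator, size: int) -> tuple[str, int]:
        chroms = list(self.genome)
        lengths = np.array([self.genome[c] for c in chroms], dtype=float)
        for _ in range(1_000):
            chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
            hi = self.genome[chrom] - size - 1_000_000
            if hi <= 1_000_000:
                continue
            start = int(rng.integers(1_000_000, hi))
            if self._free(chrom, start, start + size):
                self.reserve(chrom, start, start + size)
                return chrom, start
        raise RuntimeError("could not place a block after 1,000 attempts")

    def point_ok(self, chrom: str, pos: int, margin: int = 250_000) -> bool:
        """Whether a single breakpoint keeps clear of all reserved blocks."""
        return all(pos < s - margin or pos > e + margin
                   for s, e in self.used[chrom])

    def free_position(self, rng: np.random.Generator,
                      exclude_chrom: str | None = None) -> tuple[str, int]:
        chroms = [c for c in self.genome if c != exclude_chrom] or list(self.genome)
        for _ in range(1_000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1_000_000, self.genome[chrom] - 1_000_000))
            if self._free(chrom, pos, pos):
                self.reserve(chrom, pos, pos)
                return chrom, pos
        raise RuntimeError("could not place a position after 1,000 attempts")


def _build_active_track(genome: dict, period: int, frac: float) -> AnnotationTrack:
    width = int(period * frac)
    rows = []
    for chrom, length in genome.items():
        for s in range(0, length - width, period):
            rows.append((chrom, s, s + width))
    return AnnotationTrack.from_intervals("chromatin_active", rows)


def _forward_expected_svaf(vaf: float, purity: float, acn: float) -> float:
    """Expected SVAF from a noiseless vaf (the read-gate-free forward map)."""
    base = vaf / purity
    if acn < DEFAULTS["loh_acn_max"]:
        return min(base * (2.0 - purity) * 0.5, 1.0)
    if acn > DEFAULTS["amp_acn_min"] and base >= DEFAULTS["amp_base_min"]:
        return min(base * acn / (acn - 0.5) * 0.5, 1.0)
    return min(base, 1.0)


def _invert_svaf(svaf: float, purity: float, acn: float) -> float:
    from .allele_frequency import invert_svaf
    return invert_svaf(svaf, purity, acn)


# ---------------------------------------------------------------------------
# Archetype constructions (offsets relative to the allocated block start)
# ---------------------------------------------------------------------------

_K = 1_000  # bp


def _arch_cfs(rng):
    # overlapping deletions; CN staircase descends 0.24 per step into the
    # valley (capped at depth 3 so the floor stays above the clamp level)
    spans = [(0, 200), (25, 225), (50, 250), (75, 175), (100, 150)]
    svs = [dict(sv_type="DEL", o1=(s * _K, "+"), o2=(e * _K, "-"),
                svaf=float(rng.uniform(0.3, 0.7)))
           for s, e in spans]
    overrides = [(0, 25 * _K, 0.76), (25 * _K, 50 * _K, 0.52),
                 (50 * _K, 200 * _K, 0.28), (200 * _K, 225 * _K, 0.52),
                 (225 * _K, 250 * _K, 0.76)]
    return svs, overrides, 250 * _K


def _arch_l1(rng):
    # LINE-1 element at +500 kb; four translocations out of it
    svs = []
    for i in range(4):
        svs.append(dict(sv_type="TRA", o1=(500 * _K + 20 + i * 90, "+"),
                        far=True, svaf=float(rng.uniform(0.2, 0.5))))
    return svs, [], 501 * _K


def _arch_nahrd(rng):
    spans = [(400, 800), (410, 790), (420, 780), (430, 770)]
    svafs = [0.85, 0.7, 0.55, 0.45]
    svs = [dict(sv_type="DUP", o1=(s * _K, "-"), o2=(e * _K, "+"), svaf=v)
           for (s, e), v in zip(spans, svafs)]
    overrides = [(400 * _K, 800 * _K, 6.0)]
    return svs, overrides, 850 * _K


def _arch_bfbc(rng):
    steps = [300, 370, 440, 510]
    levels = [4.5, 6.0, 7.5]
    overrides = [(steps[i] * _K, steps[i + 1] * _K, levels[i]) for i in range(3)]
    svs = []
    for i, s in enumerate(steps):
        # fold-back junction sits exactly at the copy-number step
        svs.append(dict(sv_type="INV", o1=(s * _K, "+"),
                        o2=(s * _K + 12 * _K, "+"),
                        svaf=float(rng.uniform(0.35, 0.8))))
    return svs, overrides, 560 * _K


def _arch_self_joining(rng):
    overrides = [(400 * _K, 700 * _K, 8.0)]
    svs = [
        dict(sv_type="DUP", o1=(400 * _K, "-"), o2=(700 * _K, "+"), svaf=0.9),
        dict(sv_type="DEL", o1=(450 * _K, "+"), o2=(480 * _K, "-"), svaf=0.12),
        dict(sv_type="INV", o1=(500 * _K, "+"), o2=(512 * _K, "+"), svaf=0.15),
        dict(sv_type="INV", o1=(550 * _K, "-"), o2=(610 * _K, "-"), svaf=0.1),
        dict(sv_type="DEL", o1=(640 * _K, "+"), o2=(660 * _K, "-"), svaf=0.14),
    ]
    return svs, overrides, 750 * _K


def _arch_assembled(rng):
    overrides = [(500 * _K, 800 * _K, 8.0), (3_800 * _K, 4_100 * _K, 8.0)]
    svs = [
        dict(sv_type="INV", o1=(800 * _K, "+"), o2=(3_800 * _K, "+"), svaf=0.92),
        dict(sv_type="INV", o1=(700 * _K, "-"), o2=(3_880 * _K, "-"), svaf=0.2),
        dict(sv_type="DEL", o1=(740 * _K, "+"), o2=(770 * _K, "-"), svaf=0.15),
        dict(sv_type="DEL", o1=(3_830 * _K, "+"), o2=(3_860 * _K, "-"), svaf=0.12),
    ]
    return svs, overrides, 4_200 * _K


_ARCHETYPE_BUILDERS = {
    "CFS_LIKE": _arch_cfs,
    "L1_TRANSPOSITION": _arch_l1,
    "NAHRD": _arch_nahrd,
    "BFBC": _arch_bfbc,
    "SELF_JOINING_AMPLICON": _arch_self_joining,
    "ASSEMBLED_AMPLICON": _arch_assembled,
}


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a full synthetic cohort (deterministic in ``config.seed``)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genome = dict(config.genome)
    profiles = (config.profiles if config.profiles is not None
                else default_profiles(config.n_signatures))
    k = len(profiles)
    prof = profiles.to_numpy()
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    purities = rng.uniform(*config.purity_range, size=config.n_samples)
    exposures = rng.dirichlet(np.full(k, config.exposure_alpha),
                              size=config.n_samples)

    # global fixed CFS intervals (one per chromosome, away from hotspots)
    cfs_rows = [(c, int(0.75 * length), int(0.75 * length) + 2_000_000)
                for c, length in genome.items()]
    global_reserved = _Allocator(genome, margin=1_000_000)
    for c, s, e in cfs_rows:
        global_reserved.reserve(c, s, e)
    for plan in config.hotspot_plan:
        global_reserved.reserve(plan.chrom, plan.start - 500_000,
                                plan.end + 500_000)

    l1_rows: list[tuple[str, int, int]] = []
    per_chrom_l1 = {c: [] for c in genome}
    for chrom, length in genome.items():
        for _ in range(config.l1_per_chrom):
            s = int(rng.integers(0, length - config.l1_length))
            l1_rows.append((chrom, s, s + config.l1_length))
            per_chrom_l1[chrom].append(s)

    # -------------------- plant archetypes --------------------
    arch_sv: dict[str, list[dict]] = {s: [] for s in sample_ids}
    overrides: dict[str, list[tuple[str, int, int, float]]] = {s: [] for s in sample_ids}
    allocators = {s: _Allocator(genome) for s in sample_ids}
    for s in sample_ids:
        for c, cs, ce in cfs_rows:
            allocators[s].reserve(c, cs, ce)
        for plan in config.hotspot_plan:
            allocators[s].reserve(plan.chrom, plan.start - 500_000,
                                  plan.end + 500_000)
    truth_svc_rows = []
    arch_queue = [(cls, i) for cls in SVC_CLASSES
                  for i in range(config.archetypes_per_class)]
    for n, (cls, _) in enumerate(arch_queue):
        sample = sample_ids[n % config.n_samples]
        alloc = allocators[sample]
        svs, ovr, block = _ARCHETYPE_BUILDERS[cls](rng)
        chrom, start = alloc.alloc(rng, block)
        if cls == "CFS_LIKE":
            cfs_rows.append((chrom, start, start + block))
        if cls == "L1_TRANSPOSITION":
            l1_rows.append((chrom, start + 500 * _K - 200, start + 500 * _K + 600))
        for sv in svs:
            rec = dict(sv_type=sv["sv_type"], svaf=sv["svaf"],
                       archetype=f"{cls}#{n}", effect=sv.get("effect", 0.0))
            p1, o1 = sv["o1"]
            rec.update(chrom1=chrom, pos1=start + p1, orientation1=o1)
            if sv.get("far"):
                c2, p2 = alloc.free_position(rng, exclude_chrom=chrom)
                rec.update(chrom2=c2, pos2=p2,
                           orientation2=rng.choice(["+", "-"]))
            else:
                p2, o2 = sv["o2"]
                rec.update(chrom2=chrom, pos2=start + p2, orientation2=o2)
            arch_sv[sample].append(rec)
        for os_, oe, val in ovr:
            overrides[sample].append((chrom, start + os_, start + oe, val))
        fp_end = start + block
        truth_svc_rows.append(dict(archetype=f"{cls}#{n}", sample_id=sample,
                                   svc_class=cls, chrom=chrom, start=start,
                                   end=fp_end))
        # planted ecDNA reintegration out of amplicon-type archetypes
        if (cls in ("SELF_JOINING_AMPLICON", "ASSEMBLED_AMPLICON")
                and rng.random() < config.reintegration_frac):
            c2, p2 = alloc.free_position(rng, exclude_chrom=chrom)
            anchor = 520 * _K if cls == "SELF_JOINING_AMPLICON" else 750 * _K
            arch_sv[sample].append(dict(
                sv_type="TRA", chrom1=chrom, pos1=start + anchor,
                orientation1="+", chrom2=c2, pos2=p2, orientation2="-",
                svaf=0.3, archetype=f"{cls}#{n}", effect=0.0,
                reintegration=True))

    # -------------------- tracks --------------------
    tracks = {
        "chromatin_active": _build_active_track(
            genome, config.active_period, config.active_frac),
        "line1": AnnotationTrack.from_intervals("line1", l1_rows),
        "cfs": AnnotationTrack.from_intervals("cfs", cfs_rows),
    }
    active = tracks["chromatin_active"]
    l1_track = tracks["line1"]
    l1_by_status: dict[bool, list[tuple[str, int]]] = {True: [], False: []}
    for chrom, s, e in ((c, s, e) for c, s, e in l1_rows):
        mid = (s + e) // 2 + 1
        l1_by_status[bool(active.contains(chrom, mid))].append((chrom, s))

    # -------------------- hotspot planting --------------------
    hotspot_truth = []
    hotspot_sv: dict[str, list[dict]] = {s: [] for s in sample_ids}
    for hn, plan in enumerate(config.hotspot_plan):
        cases = rng.choice(config.n_samples, size=min(plan.n_cases,
                                                      config.n_samples),
                           replace=False)
        for ci in cases:
            sample = sample_ids[int(ci)]
            j1 = int(rng.integers(-5_000, 5_000))
            j2 = int(rng.integers(-5_000, 5_000))
            hotspot_sv[sample].append(dict(
                sv_type=plan.sv_type, chrom1=plan.chrom,
                pos1=plan.start + j1, orientation1="-",
                chrom2=plan.chrom, pos2=plan.end + j2, orientation2="+",
                svaf=plan.svaf, hotspot=f"H{hn}", effect=0.0))
            overrides[sample].append((plan.chrom, plan.start - 20_000 + j1,
                                      plan.end + 20_000 + j2, plan.acn))
        hotspot_truth.append(dict(hotspot=f"H{hn}", chrom=plan.chrom,
                                  start=plan.start, end=plan.end,
                                  n_cases=int(len(cases)),
                                  sv_type=plan.sv_type))

    # -------------------- background SVs --------------------
    def sample_position(want_active: bool, chrom: str | None = None,
                        lo: int | None = None, hi: int | None = None) -> tuple[str, int]:
        chroms = list(genome)
        lens = np.array([genome[c] for c in chroms], dtype=float)
        for _ in range(300):
            c = chrom or chroms[rng.choice(len(chroms), p=lens / lens.sum())]
            a, b = lo or 1, hi or genome[c]
            pos = int(rng.integers(a, b + 1))
            if bool(active.contains(c, pos)) == want_active:
                return c, pos
        return c, pos  # chromatin constraint dropped after 300 tries

    bg_rows: dict[str, list[dict]] = {s: [] for s in sample_ids}
    bin_lo = {"<1kb": 50, "1-10kb": 1_000, "10-100kb": 10_000,
              "100kb-1Mb": 100_000, "1-10Mb": 1_000_000, ">10Mb": 10_000_000}
    bin_hi = {"<1kb": 1_000, "1-10kb": 10_000, "10-100kb": 100_000,
              "100kb-1Mb": 1_000_000, "1-10Mb": 10_000_000, ">10Mb": 40_000_000}
    for si, sample in enumerate(sample_ids):
        r = config.sv_count_disp
        n_sv = int(rng.negative_binomial(r, r / (r + config.sv_count_mean)))
        mix = exposures[si] @ prof
        cats = rng.choice(len(CATEGORIES), size=n_sv, p=mix / mix.sum())
        alloc = allocators[sample]
        seeds: dict[bool, list[tuple[str, int]]] = {True: [], False: []}
        l1_seed = None

        def new_seed(want_active: bool) -> tuple[str, int]:
            # reserve the seed neighborhood so other loci keep clear of it
            for _ in range(50):
                try:
                    chrom, start = alloc.alloc(rng, 2 * config.cluster_window)
                except RuntimeError:
                    return sample_position(want_active)
                center = start + config.cluster_window
                if bool(active.contains(chrom, center)) == want_active:
                    return chrom, center
            return chrom, center  # chromatin preference dropped

        def get_seed(want_active: bool) -> tuple[str, int]:
            pool = seeds[want_active]
            if not pool or (len(pool) < 3 and rng.random() < 0.15):
                pool.append(new_seed(want_active))
            return pool[int(rng.integers(len(pool)))]
        for cat_i in cats:
            cat = CATEGORIES[cat_i]
            base, bin_or_flag, dist, chromatin = (cat.split(":") + [""])[:4]
            if base in ("TRA", "TRANSPOSITION"):
                dist, chromatin = cat.split(":")[1:3]
            want_active = chromatin == "active"
            clustered = dist == "clustered"
            rec = dict(svaf=float(rng.beta(*config.svaf_beta)),
                       category=cat, effect=0.0)
            def far_end(own_chrom: str) -> tuple[str, int]:
                for _ in range(300):
                    c2, p2 = sample_position(want_active)
                    if c2 != own_chrom and alloc.point_ok(c2, p2):
                        return c2, p2
                return c2, p2

            if base == "TRANSPOSITION":
                pool = l1_by_status[want_active] or l1_by_status[not want_active]
                if clustered:
                    if l1_seed is None:
                        ok = [e for e in pool if alloc.point_ok(*e)] or pool
                        l1_seed = ok[int(rng.integers(len(ok)))]
                    c1, s0 = l1_seed
                else:
                    for _ in range(50):
                        c1, s0 = pool[int(rng.integers(len(pool)))]
                        if alloc.point_ok(c1, s0):
                            break
                p1 = s0 + 1 + int(rng.integers(0, config.l1_length))
                c2, p2 = far_end(c1)
                rec.update(sv_type="TRA", chrom1=c1, pos1=p1,
                           chrom2=c2, pos2=p2)
            elif base == "TRA":
                if clustered:
                    c1, center = get_seed(want_active)
                    p1 = int(np.clip(center + rng.integers(
                        -config.cluster_window, config.cluster_window),
                        1, genome[c1]))
                else:
                    for _ in range(300):
                        c1, p1 = sample_position(want_active)
                        if alloc.point_ok(c1, p1):
                            break
                c2, p2 = far_end(c1)
                rec.update(sv_type="TRA", chrom1=c1, pos1=p1,
                           chrom2=c2, pos2=p2)
            else:
                placed = False
                for _ in range(1_000):
                    size = int(np.exp(rng.uniform(np.log(bin_lo[bin_or_flag]),
                                                  np.log(bin_hi[bin_or_flag]))))
                    if clustered:
                        c1, center = get_seed(want_active)
                        p1 = center + int(rng.integers(-config.cluster_window,
                                                       config.cluster_window))
                    else:
                        center = None
                        c1, p1 = sample_position(want_active)
                    if p1 + size > genome[c1]:
                        p1 = p1 - size  # anchor becomes the right breakpoint
                    if not (1 <= p1 and p1 + size <= genome[c1]):
                        continue

                    def bp_ok(pos: int) -> bool:
                        near_own_seed = (center is not None and
                                         abs(pos - center) <= 2 * config.cluster_window)
                        return near_own_seed or alloc.point_ok(c1, pos)

                    if bp_ok(p1) and bp_ok(p1 + size):
                        placed = True
                        break
                if not placed:
                    raise RuntimeError(
                        f"could not place a {bin_or_flag} {base} after 1,000 attempts")
                if base in ("DEL", "DUP"):
                    rec["effect"] = (float(rng.uniform(0.4, 1.2)) if base == "DUP"
                                     else -float(rng.uniform(0.3, 0.8)))
                rec.update(sv_type=base, chrom1=c1, pos1=p1,
                           chrom2=c1, pos2=p1 + size)
            o1, o2 = {"DEL": ("+", "-"), "DUP": ("-", "+")}.get(
                rec["sv_type"], (rng.choice(["+", "-"]),) * 2)
            if rec["sv_type"] == "INV":
                o1 = o2 = rng.choice(["+", "-"])
            rec.update(orientation1=o1, orientation2=o2)
            bg_rows[sample].append(rec)

    # -------------------- copy-number profiles & segments --------------------
    seg_rows = []
    acn_eval: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for si, sample in enumerate(sample_ids):
        purity = float(purities[si])
        effects: dict[str, list[tuple[int, int, float]]] = {c: [] for c in genome}
        for rec in bg_rows[sample] + arch_sv[sample] + hotspot_sv[sample]:
            eff = rec.get("effect", 0.0)
            if eff and rec["chrom1"] == rec["chrom2"]:
                effects[rec["chrom1"]].append((rec["pos1"], rec["pos2"], eff))
        ovr = {c: [] for c in genome}
        for chrom, s, e, val in overrides[sample]:
            ovr[chrom].append((s, e, val))
        for chrom, length in genome.items():
            bounds = {1, length + 1}
            for s, e, _ in effects[chrom] + ovr[chrom]:
                bounds.add(max(1, s))
                bounds.add(min(length, e) + 1)
            cuts = np.array(sorted(bounds), dtype=np.int64)
            starts, ends, acns = [], [], []
            for a, b in zip(cuts[:-1], cuts[1:]):
                mid = (a + b - 1) // 2
                acn = 1.0 + sum(d for s, e, d in effects[chrom] if s <= mid <= e)
                for s, e, val in ovr[chrom]:
                    if s <= mid <= e:
                        acn = val
                acn = max(acn, 0.25)
                if acns and abs(acns[-1] - acn) < 1e-12:
                    ends[-1] = int(b - 1)
                else:
                    starts.append(int(a))
                    ends.append(int(b - 1))
                    acns.append(acn)
            sa = np.array(starts, dtype=np.int64)
            ea = np.array(ends, dtype=np.int64)
            aa = np.array(acns, dtype=float)
            acn_eval[(sample, chrom)] = (sa, ea, aa)
            cnr = 1.0 + (aa - 1.0) * purity
            for s, e, c_ in zip(sa, ea, cnr):
                seg_rows.append((sample, chrom, int(s), int(e), float(c_)))
    segments = pd.DataFrame(seg_rows, columns=["sample_id", "chrom", "start",
                                               "end", "cnr"])

    def acn_at(sample: str, chrom: str, pos: int) -> float:
        sa, ea, aa = acn_eval[(sample, chrom)]
        i = int(np.searchsorted(sa, pos, side="right")) - 1
        if i < 0 or pos > ea[i]:
            return 1.0
        return float(aa[i])

    # -------------------- read counts & final tables --------------------
    sv_rows = []
    truth_sv_rows = []
    for si, sample in enumerate(sample_ids):
        purity = float(purities[si])
        for ni, rec in enumerate(bg_rows[sample] + arch_sv[sample]
                                 + hotspot_sv[sample]):
            a1 = acn_at(sample, rec["chrom1"], rec["pos1"])
            a2 = acn_at(sample, rec["chrom2"], rec["pos2"])
            acn, which = select_breakpoint_acn(a1, a2)
            vaf = min(_invert_svaf(rec["svaf"], purity, acn), 0.97)
            true_svaf = _forward_expected_svaf(vaf, purity, acn)
            depth = max(int(rng.poisson(config.depth_mean)), 1)
            rsv = int(rng.binomial(depth, vaf))
            rref_chosen = depth - rsv
            depth_other = max(int(rng.poisson(config.depth_mean)), 1)
            rref_other = max(depth_other - rsv, 0)
            rref1 = rref_chosen if which == 0 else rref_other
            rref2 = rref_chosen if which == 1 else rref_other
            sv_id = f"{sample}.sv{ni}"
            sv_rows.append(dict(
                sv_id=sv_id, sample_id=sample, chrom1=rec["chrom1"],
                pos1=int(rec["pos1"]), chrom2=rec["chrom2"],
                pos2=int(rec["pos2"]), sv_type=rec["sv_type"],
                orientation1=rec["orientation1"],
                orientation2=rec["orientation2"],
                rsv=rsv, rref1=int(rref1), rref2=int(rref2)))
            if "category" in rec:
                category = rec["category"]
            else:
                clustered = "clustered" if "archetype" in rec else "nonclustered"
                is_active = bool(active.contains(rec["chrom1"], rec["pos1"])
                                 or active.contains(rec["chrom2"], rec["pos2"]))
                if rec["sv_type"] == "TRA":
                    near = (l1_track.distance(rec["chrom1"], rec["pos1"])
                            < DEFAULTS["l1_transposition_dist"]
                            or l1_track.distance(rec["chrom2"], rec["pos2"])
                            < DEFAULTS["l1_transposition_dist"])
                    base = "TRANSPOSITION" if near else "TRA"
                else:
                    base = (f"{rec['sv_type']}:"
                            f"{size_bin(rec['pos2'] - rec['pos1'])}")
                category = (f"{base}:{clustered}:"
                            f"{'active' if is_active else 'inactive'}")
            truth_sv_rows.append(dict(
                sv_id=sv_id, sample_id=sample, true_svaf=float(true_svaf),
                expected_vaf=float(vaf), acn=float(acn), category=category,
                archetype=rec.get("archetype", ""),
                hotspot=rec.get("hotspot", ""),
                reintegration=bool(rec.get("reintegration", False))))

    sv = pd.DataFrame(sv_rows).set_index("sv_id")
    truth_sv = pd.DataFrame(truth_sv_rows).set_index("sv_id")

    n_sv_per_sample = sv.groupby("sample_id").size()
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "purity": purities,
        "n_sv": [int(n_sv_per_sample.get(s, 0)) for s in sample_ids],
        "hypermutator": False,
    })
    dominant = [profiles.index[int(np.argmax(exposures[i]))]
                for i in range(config.n_samples)]
    meta["flag_feature"] = rng.random(config.n_samples) < np.where(
        np.array(dominant) == profiles.index[0], 0.7, 0.2)

    truth = {
        "sv": truth_sv.reset_index(),
        "exposures": pd.DataFrame(exposures, index=sample_ids,
                                  columns=profiles.index).reset_index(
                                      names="sample_id"),
        "svc": pd.DataFrame(truth_svc_rows),
        "hotspots": pd.DataFrame(hotspot_truth),
    }
    return Cohort(config=config, sv=sv.reset_index(), segments=segments,
                  meta=meta, tracks=tracks, truth=truth, genome=genome)


# ---------------------------------------------------------------------------
# Preset cohorts
# ---------------------------------------------------------------------------

def archetype_cohort_config(n_per_class: int = 40, seed: int = 0) -> SimConfig:
    """One archetype of every mechanism class per sample, sparse background.

    The sparse background keeps each sample's genome-average breakpoint
    density low so archetype loci are unambiguously clustered.
    """
    return SimConfig(seed=seed, n_samples=n_per_class,
                     archetypes_per_class=n_per_class,
                     sv_count_mean=10.0, sv_count_disp=20.0,
                     hotspot_plan=[], exposure_alpha=1.0)


def hotspot_cohort_config(seed: int = 0, n_samples: int = 100,
                          planted: bool = True) -> SimConfig:
    """Cohort for hotspot studies: uniform sparse background, optional plan.

    Background SVs are placed uniformly (no clustered categories) at a
    density (5 SVs per sample on the 150 Mb mini-genome) that keeps the
    expected number of chance high-SVAF co-occurrences per 500 kb window far
    below the calling conditions, so a cohort without planted hotspots is a
    true null for the caller.
    """
    plan = [
        HotspotPlan("chr1", 12_000_000, 12_025_000, 12),
        HotspotPlan("chr2", 30_000_000, 30_025_000, 12),
        HotspotPlan("chr3", 8_000_000, 8_025_000, 12),
    ] if planted else []
    return SimConfig(seed=seed, n_samples=n_samples, sv_count_mean=5.0,
                     sv_count_disp=10.0, archetypes_per_class=0,
                     profiles=uniform_background_profile(),
                     hotspot_plan=plan)


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the cohort in the formats the pipeline reads, plus truth/*.tsv."""
    out = Path(outdir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    write_sv_table(cohort.sv, out / "sv.tsv")
    write_segments(cohort.segments, out / "segments.tsv")
    cohort.meta.to_csv(out / "samples.tsv", sep="\t", index=False)
    for name, track in cohort.tracks.items():
        write_track(track, out / "tracks" / f"{name}.bed")
    emit_truth(cohort, out / "truth")
    genome = pd.DataFrame(sorted(cohort.genome.items()),
                          columns=["chrom", "length"])
    genome.to_csv(out / "genome.tsv", sep="\t", index=False)


def emit_truth(cohort: Cohort, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in cohort.truth.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
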