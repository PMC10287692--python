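"""Rearrangement-signature extraction and subtype assignment.

Extraction follows the Brunet-style restart protocol used throughout the
mutational-signature literature: for each candidate rank the samples x 80
catalog is factorized by Kullback-Leibler NMF from many random restarts, the
pooled restart signatures are clustered, and the mean silhouette of that
clustering measures the rank's stability. Profiles are L1-normalized (each
signature is a probability distribution over the 80 categories) and sample
exposures are refit against the consensus profiles by non-negative least
squares.

Subtypes are assigned by consensus hierarchical clustering of the normalized
exposures (cosine distance, Ward linkage on unsquared distances — the
"ward.D2" convention), resampling 80% of samples many times and clustering
the resulting consensus matrix.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment, nnls
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import silhouette_score

from .config import DEFAULTS


@dataclasses.dataclass
class SignatureSet:
    """Extracted signatures plus the per-rank diagnostics behind the choice."""

    profiles: pd.DataFrame          # K x categories, rows sum to 1
    rank: int
    diagnostics: pd.DataFrame       # rank, stability, rel_error


@dataclasses.dataclass
class SubtypeAssignment:
    assignments: pd.Series          # sample_id -> subtype label
    k: int
    consensus: pd.DataFrame         # samples x samples co-clustering fractions
    diagnostics: pd.DataFrame       # k, cdf_area, delta_area, delta_drop


def _l1_rows(m: np.ndarray) -> np.ndarray:
    s = m.sum(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return m / s


def _fit_nmf(v: np.ndarray, k: int, seed: int, tol: float, max_iter: int,
             ) -> tuple[np.ndarray, np.ndarray, float]:
    """One KL-NMF run; returns (W, H, relative Frobenius error)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = NMF(n_components=k, init="random", solver="mu",
                    beta_loss="kullback-leibler", tol=tol, max_iter=max_iter,
                    random_state=seed)
        w = model.fit_transform(v)
    h = model.components_
    err = float(np.linalg.norm(v - w @ h) / max(np.linalg.norm(v), 1e-12))
    return w, h, err


def _refit_exposures(v: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Per-sample NNLS of the catalog against fixed L1-normalized profiles."""
    k = h.shape[0]
    out = np.zeros((v.shape[0], k))
    for i in range(v.shape[0]):
        out[i], _ = nnls(h.T, v[i].astype(float))
    return out


def extract_signatures(catalog: pd.DataFrame,
                       rank_range: tuple[int, int] = (2, 8),
                       n_restarts: int | None = None,
                       seed: int = 0,
                       thresholds: Mapping[str, float] | None = None,
                       ) -> tuple[SignatureSet, pd.DataFrame]:
    """Extract signatures from a catalog already purged of <10-SV samples.

    Parameters
    ----------
    catalog
        Samples x categories count matrix (rows are samples).
    rank_range
        Inclusive (lo, hi) range of candidate ranks.
    n_restarts
        Random NMF restarts per rank (default 100).

    Returns
    -------
    (SignatureSet, exposures)
        ``exposures`` has absolute columns ``<sig>`` and normalized columns
        ``<sig>_frac`` per sample.

    Notes
    -----
    Rank selection: a rank is eligible when its restart stability (mean
    silhouette of the pooled restart signatures, cosine metric) is at least
    ``rank_stability_min`` and its reconstruction error does not exceed that
    of any smaller rank; the largest eligible rank wins (reconstruction error
    keeps falling past the true rank while stability collapses). If no rank
    is eligible the most stable rank is used.
    """
    cfg = thresholds or DEFAULTS
    n_restarts = int(cfg["nmf_restarts"]) if n_restarts is None else n_restarts
    lo, hi = rank_range
    v = catalog.to_numpy(dtype=float)
    if not (1 <= lo <= hi <= min(v.shape)):
        raise ValueError(f"rank_range {rank_range} exceeds matrix dimensions {v.shape}")
    # KL divergence is undefined on all-zero columns; lift by a tiny epsilon.
    v = v + 1e-9
    rng = np.random.SeedSequence(seed)
    seeds = rng.generate_state((hi - lo + 1) * n_restarts) % (2**31 - 1)

    diag_rows = []
    per_rank: dict[int, np.ndarray] = {}
    for ri, k in enumerate(range(lo, hi + 1)):
        pool = []
        best_err = np.inf
        for r in range(n_restarts):
            s = int(seeds[ri * n_restarts + r])
            _, h, err = _fit_nmf(v, k, s, cfg["nmf_tol"], int(cfg["nmf_max_iter"]))
            pool.append(_l1_rows(h))
            best_err = min(best_err, err)
        pooled = np.vstack(pool)
        if k == 1:
            stability = np.nan
            consensus = _l1_rows(pooled.mean(axis=0, keepdims=True))
        else:
            # cluster pooled restart signatures into k groups (cosine geometry)
            norms = np.linalg.norm(pooled, axis=1, keepdims=True)
            unit = pooled / np.clip(norms, 1e-12, None)
            from sklearn.cluster import KMeans
            km = KMeans(n_clusters=k, n_init=10, random_state=int(seeds[ri * n_restarts]))
            labels = km.fit_predict(unit)
            if len(set(labels)) < 2:
                stability = np.nan
            else:
                stability = float(silhouette_score(unit, labels, metric="cosine"))
            consensus = _l1_rows(np.vstack(
                [pooled[labels == c].mean(axis=0) for c in range(k)]))
        per_rank[k] = consensus
        diag_rows.append((k, stability, best_err))
    diagnostics = pd.DataFrame(diag_rows, columns=["rank", "stability", "rel_error"])

    # monotone-error eligibility, then the most stable rank (ties -> smaller):
    # restart stability peaks sharply at the true rank, whereas the
    # reconstruction error keeps creeping down past it
    err_floor = diagnostics["rel_error"].cummin()
    monotone = diagnostics["rel_error"] <= err_floor + 1e-12
    eligible = diagnostics[monotone & diagnostics["stability"].notna()]
    if len(eligible):
        rank = int(eligible.loc[eligible["stability"].idxmax(), "rank"])
    else:
        rank = lo

    profiles = pd.DataFrame(per_rank[rank], columns=catalog.columns,
                            index=[f"RS{i + 1}" for i in range(rank)])
    w = _refit_exposures(catalog.to_numpy(dtype=float), profiles.to_numpy())
    exposures = pd.DataFrame(w, index=catalog.index, columns=profiles.index)
    fracs = _l1_rows(w)
    for j, sig in enumerate(profiles.index):
        exposures[f"{sig}_frac"] = fracs[:, j]
    return SignatureSet(profiles, rank, diagnostics), exposures


def match_signatures(a: pd.DataFrame, b: pd.DataFrame,
                     ) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Optimal one-to-one pairing of two signature sets by cosine similarity.

    Hungarian assignment maximizing total cosine similarity between the rows
    of ``a`` and ``b`` (both over the same category columns). Returns the
    pairing and the matched similarities in ``a`` row order.
    """
    if list(a.columns) != list(b.columns):
        raise ValueError("signature sets are over different categories")
    av = a.to_numpy(float)
    bv = b.to_numpy(float)
    an = av / np.clip(np.linalg.norm(av, axis=1, keepdims=True), 1e-12, None)
    bn = bv / np.clip(np.linalg.norm(bv, axis=1, keepdims=True), 1e-12, None)
    sim = an @ bn.T
    rows, cols = linear_sum_assignment(-sim)
    pairing = [(str(a.index[i]), str(b.index[j])) for i, j in zip(rows, cols)]
    return pairing, sim[rows, cols]


# ---------------------------------------------------------------------------
# Consensus subtyping
# ---------------------------------------------------------------------------

def _cdf_area(values: np.ndarray) -> float:
    """Area under the empirical CDF of consensus values on [0, 1]."""
    grid = np.linspace(0.0, 1.0, 101)
    cdf = np.searchsorted(np.sort(values), grid, side="right") / max(len(values), 1)
    return float(np.trapezoid(cdf, grid))


def consensus_subtypes(exposures: pd.DataFrame,
                       k_range: tuple[int, int] = (2, 6),
                       resamplings: int | None = None,
                       subsample_fraction: float | None = None,
                       seed: int = 0,
                       thresholds: Mapping[str, float] | None = None,
                       ) -> SubtypeAssignment:
    """Assign samples to subtypes by consensus hierarchical clustering.

    Exposure rows are L1-normalized; each resampling draws a fraction of
    samples without replacement, clusters them (cosine distance, Ward
    linkage) and the co-clustering fractions are accumulated into a consensus
    matrix per k. The number of subtypes is the k with the sharpest drop in
    the relative change of the consensus-CDF area (the point where adding a
    cluster stops improving consensus); the final assignment clusters the
    chosen consensus matrix.
    """
    cfg = thresholds or DEFAULTS
    resamplings = int(cfg["consensus_resamplings"]) if resamplings is None else resamplings
    subsample_fraction = (cfg["consensus_subsample"]
                          if subsample_fraction is None else subsample_fraction)
    lo, hi = k_range
    n = len(exposures)
    if hi > n:
        raise ValueError(f"k_range {k_range} exceeds sample count {n}")
    sig_cols = [c for c in exposures.columns if not str(c).endswith("_frac")]
    x = _l1_rows(exposures[sig_cols].to_numpy(float))

    # degenerate cohort: no structure to cluster
    full_dist = pdist(x, metric="cosine")
    full_dist = np.clip(full_dist, 0.0, None)
    if len(full_dist) == 0 or full_dist.max() < 1e-12:
        labels = pd.Series(["S1"] * n, index=exposures.index, name="subtype")
        consensus = pd.DataFrame(np.ones((n, n)), index=exposures.index,
                                 columns=exposures.index)
        diag = pd.DataFrame({"k": [lo], "cdf_area": [np.nan],
                             "delta_area": [np.nan], "delta_drop": [np.nan]})
        return SubtypeAssignment(labels, lo, consensus, diag)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    m = max(2, int(round(subsample_fraction * n)))
    areas = {}
    consensus_by_k = {}
    for k in range(lo, hi + 1):
        together = np.zeros((n, n))
        copresent = np.zeros((n, n))
        for _ in range(resamplings):
            idx = rng.choice(n, size=m, replace=False)
            d = np.clip(pdist(x[idx], metric="cosine"), 0.0, None)
            z = linkage(d, method="ward")
            lab = fcluster(z, t=min(k, m), criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            copresent[np.ix_(idx, idx)] += 1
            together[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(copresent > 0, together / np.maximum(copresent, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        consensus_by_k[k] = cons
        areas[k] = _cdf_area(squareform(cons - np.eye(n), checks=False))

    ks = list(range(lo, hi + 1))
    delta = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            delta[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
    drop = {k: (delta[k] - delta[ks[i + 1]] if i + 1 < len(ks) else delta[k])
            for i, k in enumerate(ks)}
    chosen = min(ks, key=lambda k: (-drop[k], k))

    cons = consensus_by_k[chosen]
    d = np.clip(squareform(1.0 - cons, checks=False), 0.0, None)
    z = linkage(d, method="ward")
    lab = fcluster(z, t=chosen, criterion="maxclust")
    # stable label names ordered by cluster size
    order = {c: i for i, c in enumerate(
        pd.Series(lab).value_counts(sort=True).index)}
    labels = pd.Series([f"S{order[c] + 1}" for c in lab],
                       index=exposures.index, name="subtype")
    diag = pd.DataFrame({
        "k": ks,
        "cdf_area": [areas[k] for k in ks],
        "delta_area": [delta[k] for k in ks],
        "delta_drop": [drop[k] for k in ks],
    })
    consensus = pd.DataFrame(cons, index=exposures.index, columns=exposures.index)
    return SubtypeAssignment(labels, chosen, consensus, diag)
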