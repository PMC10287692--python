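"""Central registry of analysis thresholds.

Every tunable cut-off used anywhere in the pipeline lives here under a flat,
named key so that a run can be reproduced (the pipeline logs the full mapping)
and sensitivity analyses can override single values without touching code.
Defaults are the published values of the underlying method where one exists;
keys that operationalize a qualitative rule are documented in docs/methods.md.
"""

from __future__ import annotations

from typing import Any, Mapping

#: Default thresholds, in base-pair / ratio / fraction units as noted.
DEFAULTS: dict[str, Any] = {
    # --- allele frequency ---
    "min_breakpoint_reads": 10,     # reads (rsv+rref) required to report an SVAF
    "loh_acn_max": 0.75,            # adjusted CN below which a breakpoint is LOH
    "amp_acn_min": 1.25,            # adjusted CN above which amplification is considered
    "amp_base_min": 0.60,           # vaf/purity ratio gating the amplification correction
    "delta_cn_flank": 1,            # bp past a segment boundary when reading flank CN
    # --- clustered-region detection ---
    "cluster_density_factor": 10.0,  # clustered = gaps <= (genome mean gap) / factor
    "min_cluster_size": 3,           # breakpoints required to emit a cluster region
    # --- SV categories ---
    "size_bin_edges": (1_000, 10_000, 100_000, 1_000_000, 10_000_000),
    "l1_transposition_dist": 1_000,  # bp: TRA breakpoint within this of LINE-1 => transposition
    # --- signature extraction ---
    "nmf_restarts": 100,
    "nmf_tol": 1e-6,
    "nmf_max_iter": 5_000,
    "min_sv_per_sample": 10,         # samples below this are excluded from extraction
    "rank_stability_min": 0.80,      # silhouette floor for an eligible NMF rank
    # --- consensus subtyping ---
    "consensus_resamplings": 1_000,
    "consensus_subsample": 0.80,
    # --- SVC profile / classification ---
    "cfs_del_frac": 0.5,
    "cn_drop_min": 0.2,              # CN-ratio drop at a deletion breakpoint (CFS-like)
    "stepwise_min_steps": 2,         # successive same-sign steps > cn_drop_min => stepwise
    "l1_tra_frac": 0.5,
    "l1_concentration_window": 500,  # bp: translocation breakpoints concentrated within
    "l1_svc_dist": 100,              # bp: distance to nearest LINE-1 for L1-type SVCs
    "nahrd_dup_frac": 0.4,
    "spacer_overlap_frac": 0.9,      # fraction of spacer length counting as overlap
    "bfbc_inv_frac": 0.4,
    "foldback_max_span": 30_000,     # bp between the two ends of a fold-back inversion
    "foldback_reciprocal_window": 5_000,   # bp window for a reciprocal inversion partner
    "foldback_q_max": 0.01,          # BH-adjusted q for the breakpoint depth change
    "foldback_depth_bins": 10,       # flanking bins per side for the depth test
    "foldback_depth_binsize": 5_000,
    "foldback_dcn_min": 0.5,         # segment-based fallback: |dACN| at a breakpoint
    "amp_boundary_delta": 1.5,       # CN-ratio change defining an amplified-segment boundary
    "amp_mean_cn": 4.0,              # mean adjusted CN defining an amplified segment
    "top_svaf_frac": 0.3,            # "high-SVAF" = within the top 30% of the SVC
    "amplicon_boundary_tol": 50_000,  # bp tolerance matching breakpoints to amp boundaries
    "assembled_min_gap": 2_000_000,  # bp separating independent amplified segments
    "reintegration_dcn_max": 0.5,
    "reintegration_min_span": 2_000_000,
    # --- hotspots ---
    "hotspot_window": 500_000,
    "hotspot_step": 450_000,         # 500 kb windows with 50 kb overlap
    "hotspot_case_frac": 0.05,       # condition 1: detected in > 5% of cases
    "hotspot_high_svaf": 0.4,        # condition 3 SVAF cut-off
    "hotspot_min_high_cases": 5,     # condition 3 case count
    "hotspot_fdr": 0.05,             # condition 4 BH FDR on the CN comparison
    "hotspot_l1_dist": 100,          # bp: LINE-1 proximity for the active-transposon rule
    "hotspot_l1_case_frac": 0.5,     # windows driven by L1-only cases above this are dropped
    "singular_share_frac": 0.70,     # cases sharing the core interval for singular typing
    "singular_max_median_sv": 2,     # "one or few SVs" per case
    # --- association testing ---
    "assoc_alpha": 0.05,
}


def resolve(overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Return the full threshold mapping with ``overrides`` applied.

    Unknown keys raise ``KeyError`` so that typos in config files surface
    immediately instead of silently falling back to a default.
    """
    cfg = dict(DEFAULTS)
    if overrides:
        for key, value in overrides.items():
            if key not in cfg:
                raise KeyError(f"unknown threshold key: {key!r}")
            cfg[key] = value
    return cfg
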