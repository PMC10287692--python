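"""End-to-end pipeline orchestration.

``run_pipeline`` wires the stages together as a pure function of
(inputs, configuration, seed): SVAF annotation -> feature extraction and
catalog -> signature extraction and subtyping -> SVC classification and
reintegration flagging -> hotspot calling -> association testing. Stage
outputs are written as TSV tables plus a JSON record of every threshold
used.

The configuration is a flat mapping (typically loaded from YAML)::

    inputs:            # either a cohort directory ...
      dir: cohort/
    synthetic:         # ... or a synthetic cohort generated on the fly
      seed: 1
      preset: standard | archetype | hotspot | null
    stages: [svaf, features, signatures, svc, hotspots, assoc]
    out: results/
    seed: 1
    thresholds: {hotspot_fdr: 0.05, ...}
    signatures:
      rank_range: [2, 8]
      n_restarts: 100
      k_range: [2, 6]
      resamplings: 1000
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import association_stats, hotspots, rs_features, signatures, svc
from .allele_frequency import adjust_segments, annotate_svaf
from .config import resolve
from .io_formats import (read_sample_meta, read_segments, read_sv_table,
                         read_track)
from .synthetic_data import (Cohort, SimConfig, archetype_cohort_config,
                             hotspot_cohort_config, simulate_cohort)

STAGES = ("svaf", "features", "signatures", "svc", "hotspots", "assoc")

_PRESETS = {
    "standard": lambda seed: SimConfig(seed=seed),
    "archetype": lambda seed: archetype_cohort_config(seed=seed),
    "hotspot": lambda seed: hotspot_cohort_config(seed=seed),
    "null": lambda seed: hotspot_cohort_config(seed=seed, planted=False),
}


@dataclasses.dataclass
class PipelineResult:
    sv: pd.DataFrame | None = None
    segments: pd.DataFrame | None = None
    meta: pd.DataFrame | None = None
    tracks: dict | None = None
    genome: dict | None = None
    regions: dict | None = None
    catalog: pd.DataFrame | None = None
    excluded_samples: list | None = None
    signature_set: signatures.SignatureSet | None = None
    exposures: pd.DataFrame | None = None
    subtypes: signatures.SubtypeAssignment | None = None
    svc_table: pd.DataFrame | None = None
    clusters: list | None = None
    sv_annotations: pd.DataFrame | None = None
    reintegration: pd.Series | None = None
    hotspot_list: list | None = None
    associations: pd.DataFrame | None = None
    thresholds: dict | None = None
    truth: dict | None = None


def _load_inputs(config: Mapping[str, Any]) -> tuple:
    if "synthetic" in config:
        syn = config["synthetic"]
        if "seed" not in syn:
            raise KeyError("config missing key: synthetic.seed")
        preset = syn.get("preset", "standard")
        if preset not in _PRESETS:
            raise KeyError(f"unknown synthetic preset {preset!r}")
        sim = _PRESETS[preset](int(syn["seed"]))
        overrides = {k: v for k, v in syn.items() if k not in ("seed", "preset")}
        if overrides:
            sim = dataclasses.replace(sim, **overrides)
        cohort: Cohort = simulate_cohort(sim)
        return (cohort.sv.set_index("sv_id"), cohort.segments, cohort.meta,
                cohort.tracks, cohort.genome, cohort.truth)
    if "inputs" not in config:
        raise KeyError("config missing key: inputs (or synthetic)")
    inputs = config["inputs"]
    if "dir" in inputs:
        d = Path(inputs["dir"])
        paths = {"sv": d / "sv.tsv", "segments": d / "segments.tsv",
                 "samples": d / "samples.tsv", "genome": d / "genome.tsv",
                 "chromatin_active": d / "tracks" / "chromatin_active.bed",
                 "line1": d / "tracks" / "line1.bed",
                 "cfs": d / "tracks" / "cfs.bed"}
    else:
        paths = {k: Path(v) for k, v in inputs.items()}
    missing = [k for k, p in paths.items() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing pipeline inputs: {missing}")
    sv = read_sv_table(paths["sv"])
    if "sv_id" in sv.columns:
        sv = sv.set_index("sv_id")
    else:
        sv.index = pd.Index([f"sv{i}" for i in range(len(sv))], name="sv_id")
    segments = read_segments(paths["segments"])
    meta = read_sample_meta(paths["samples"])
    tracks = {name: read_track(paths[name], name)
              for name in ("chromatin_active", "line1", "cfs")}
    genome_df = pd.read_csv(paths["genome"], sep="\t")
    genome = dict(zip(genome_df["chrom"].astype(str), genome_df["length"]))
    return sv, segments, meta, tracks, genome, None


def run_pipeline(config: Mapping[str, Any]) -> PipelineResult:
    """Run the requested stages; later stages require earlier ones."""
    stages = list(config.get("stages", STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise KeyError(f"unknown stages: {unknown}")
    thresholds = resolve(config.get("thresholds"))
    seed = int(config.get("seed", 0))
    sig_cfg = dict(config.get("signatures", {}))

    sv, segments, meta, tracks, genome, truth = _load_inputs(config)
    res = PipelineResult(sv=sv, segments=segments, meta=meta, tracks=tracks,
                         genome=genome, thresholds=dict(thresholds),
                         truth=truth)

    if "svaf" in stages:
        res.segments = adjust_segments(segments, meta)
        res.sv = annotate_svaf(sv, res.segments, meta, thresholds)

    if "features" in stages:
        res.regions = rs_features.detect_clustered_regions_cohort(
            res.sv, thresholds)
        res.sv = rs_features.classify_sv_table(
            res.sv, res.regions, tracks["chromatin_active"], tracks["line1"],
            thresholds)
        res.catalog, res.excluded_samples = rs_features.build_catalog(
            res.sv, thresholds["min_sv_per_sample"])

    if "signatures" in stages:
        kept = res.catalog.drop(index=res.excluded_samples)
        rank_range = tuple(sig_cfg.get("rank_range", (2, 8)))
        sig_set, exposures = signatures.extract_signatures(
            kept, rank_range=rank_range,
            n_restarts=sig_cfg.get("n_restarts"),
            seed=seed, thresholds=thresholds)
        res.signature_set = sig_set
        res.exposures = exposures
        k_range = tuple(sig_cfg.get("k_range", (2, 6)))
        res.subtypes = signatures.consensus_subtypes(
            exposures, k_range=k_range,
            resamplings=sig_cfg.get("resamplings"),
            seed=seed + 1, thresholds=thresholds)

    if "svc" in stages:
        res.svc_table, res.sv_annotations, res.clusters = svc.classify_cohort(
            res.sv, res.segments, res.regions, tracks["line1"],
            thresholds=thresholds)
        res.reintegration = svc.detect_reintegration(
            res.sv, res.clusters, res.regions, res.segments, thresholds)
        res.sv = res.sv.join(res.sv_annotations)
        res.sv["reintegration"] = res.reintegration

    if "hotspots" in stages:
        windows = hotspots.window_recurrence(res.sv, genome, thresholds)
        called = hotspots.call_hotspots(
            windows, res.sv, tracks["cfs"], tracks["line1"], res.segments,
            cohort_size=len(meta), thresholds=thresholds)
        for h in called:
            h.hotspot_class = hotspots.classify_hotspot(h, res.sv, thresholds)
        res.hotspot_list = called

    if "assoc" in stages and res.subtypes is not None:
        assignments = res.subtypes.assignments
        feats = meta.set_index("sample_id")
        kinds = {"n_sv": "continuous"}
        if "flag_feature" in feats.columns:
            kinds["flag_feature"] = "categorical"
        excl = {"n_sv": list(feats.index[feats.get(
            "hypermutator", pd.Series(False, index=feats.index)).astype(bool)])}
        results = association_stats.test_features(
            assignments, feats, kinds, exclusions=excl)
        res.associations = association_stats.summarize(
            results, thresholds["assoc_alpha"])

    if "out" in config:
        _write_outputs(res, Path(config["out"]))
    return res


def _write_outputs(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "thresholds.json", "w") as fh:
        json.dump(res.thresholds, fh, indent=2, sort_keys=True)
    if res.sv is not None:
        res.sv.to_csv(outdir / "sv_annotated.tsv", sep="\t")
    if res.segments is not None:
        res.segments.to_csv(outdir / "segments_adjusted.tsv", sep="\t",
                            index=False)
    if res.catalog is not None:
        res.catalog.to_csv(outdir / "catalog.tsv", sep="\t")
        pd.Series(res.excluded_samples, name="sample_id").to_csv(
            outdir / "excluded_samples.tsv", sep="\t", index=False)
    if res.regions is not None:
        pd.concat([r.regions.assign(sample_id=s)
                   for s, r in res.regions.items() if len(r.regions)]
                  or [pd.DataFrame()]).to_csv(
            outdir / "cluster_regions.tsv", sep="\t", index=False)
    if res.signature_set is not None:
        res.signature_set.profiles.to_csv(outdir / "signatures.tsv", sep="\t")
        res.signature_set.diagnostics.to_csv(
            outdir / "signature_diagnostics.tsv", sep="\t", index=False)
        res.exposures.to_csv(outdir / "exposures.tsv", sep="\t")
    if res.subtypes is not None:
        res.subtypes.assignments.to_frame().to_csv(
            outdir / "subtypes.tsv", sep="\t")
        res.subtypes.consensus.to_csv(outdir / "consensus_matrix.tsv", sep="\t")
    if res.svc_table is not None:
        res.svc_table.to_csv(outdir / "svc.tsv", sep="\t", index=False)
    if res.hotspot_list is not None:
        hotspots.hotspot_table(res.hotspot_list).to_csv(
            outdir / "hotspots.tsv", sep="\t", index=False)
    if res.associations is not None:
        res.associations.to_csv(outdir / "associations.tsv", sep="\t",
                                index=False)
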