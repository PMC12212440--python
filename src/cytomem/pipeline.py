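"""End-to-end workflows tying simulation, testing and classification together.

A :class:`RunConfig` (YAML on disk) either points at an existing counts TSV
+ sample sheet or embeds a simulation block. :func:`run_pipeline` executes
the appropriate workflow (peak memory or gene memory), writes all artifact
tables, and records a JSON manifest with every threshold, seed and
open-question mode in force — so a run is fully reproducible from its
manifest. Identical config + seed yields byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .genes import classify_genes
from .io import (
    read_counts,
    read_design,
    write_bed,
    write_counts,
    write_design,
    write_json,
    write_table,
)
from .matrix import CountMatrix, SampleDesign
from .peaks import classify_peaks
from .sim import SimConfig, simulate, truth_to_frame

__all__ = ["RunConfig", "RunConfigError", "run_pipeline", "load_config"]

log = logging.getLogger("cytomem")


class RunConfigError(ValueError):
    pass


_THRESHOLD_FIELDS = (
    "l2fc_cutoff",
    "fdr_cutoff",
    "fold_cutoff_media",
    "fold_cutoff_rux",
    "ratio_cutoff",
    "basal_l2fc_cutoff",
    "isg_fold_cutoff",
    "prior_cpm",
)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    workflow: str = "peaks"  # "peaks" | "genes"
    counts: str | None = None
    design: str | None = None
    simulate: dict | None = None
    seed: int = 0
    out_dir: str = "cytomem_out"
    # thresholds (defaults are the published cutoffs)
    l2fc_cutoff: float = 2.0
    fdr_cutoff: float = 0.01
    fold_cutoff_media: float = 5.0
    fold_cutoff_rux: float = 4.0
    ratio_cutoff: float = 2.0
    basal_l2fc_cutoff: float = 0.5
    isg_fold_cutoff: float = 5.0
    prior_cpm: float = 0.5
    persistence_reference: str = "unstimulated"
    inducible_mode: str = "either_arm"
    isg_reference: str = "vehicle_8h"
    criteria: str = "media"
    abundance_filter: bool = True
    # clustering block
    cluster_k: int = 3
    cluster_seed: int = 17
    cluster_restarts: int = 50
    cluster_columns: str = "replicates"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.workflow not in ("peaks", "genes"):
            raise RunConfigError("workflow must be 'peaks' or 'genes'")
        if (self.counts is None) != (self.design is None):
            raise RunConfigError("counts and design must be given together")
        if self.counts is None and self.simulate is None:
            raise RunConfigError("either counts/design paths or a simulate block is required")
        for name in _THRESHOLD_FIELDS:
            if getattr(self, name) <= 0:
                raise RunConfigError(f"threshold {name} must be positive")
        for name in ("counts", "design"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise RunConfigError(f"{name} path does not exist: {p}")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise RunConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _sim_config(cfg: RunConfig) -> SimConfig:
    block = dict(cfg.simulate or {})
    kind = block.pop("kind", "peaks" if cfg.workflow == "peaks" else "genes")
    block.setdefault("seed", cfg.seed)
    if "timepoints_h" in block:
        block["timepoints_h"] = tuple(block["timepoints_h"])
    base = SimConfig.peaks_default() if kind == "peaks" else SimConfig.genes_default()
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(block) - known
    if unknown:
        raise RunConfigError(f"unknown simulate keys: {sorted(unknown)}")
    return dataclasses.replace(base, **block)


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns the manifest dict (also written to disk).

    Stage order: simulate-or-load -> abundance filter -> differential
    contrasts -> classification -> clustering -> summaries. Any stage
    failure propagates after the manifest records the stages completed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    manifest: dict = {
        "version": __version__,
        "workflow": config.workflow,
        "seed": config.seed,
        "thresholds": {name: getattr(config, name) for name in _THRESHOLD_FIELDS},
        "modes": {
            "persistence_reference": config.persistence_reference,
            "inducible_mode": config.inducible_mode,
            "isg_reference": config.isg_reference,
            "criteria": config.criteria,
            "abundance_filter": config.abundance_filter,
            "cluster_columns": config.cluster_columns,
            "zscore_ddof": 1,
            "normalization": "cpm",
            "dispersion_prior_df": 20.0,
            "replicates_paired": False,
        },
        "clustering": {
            "k": config.cluster_k,
            "seed": config.cluster_seed,
            "restarts": config.cluster_restarts,
        },
        "stages": [],
        "artifacts": {},
    }

    def stage(name: str):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)

        def done():
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            manifest["stages"].append(name)

        return done

    done = stage("load")
    if config.simulate is not None:
        sim_cfg = _sim_config(config)
        matrix, design, truth = simulate(sim_cfg)
        write_counts(matrix, out / "counts.tsv")
        write_design(design, out / "samples.csv")
        write_table(truth_to_frame(truth), out / "truth.tsv")
        manifest["simulate"] = sim_cfg.to_dict()
        manifest["artifacts"]["counts"] = "counts.tsv"
        manifest["artifacts"]["design"] = "samples.csv"
        manifest["artifacts"]["truth"] = "truth.tsv"
    else:
        design = read_design(config.design)
        lib = design.library_sizes_for(design.sample_ids)
        matrix = read_counts(config.counts, library_sizes=lib)
        matrix = CountMatrix(
            counts=matrix.counts[:, matrix.sample_index(design.sample_ids)],
            feature_ids=matrix.feature_ids,
            sample_ids=design.sample_ids,
            coords=matrix.coords,
            library_sizes=lib,
        )
    done()

    if config.workflow == "peaks":
        done = stage("classify_peaks")
        result = classify_peaks(
            matrix,
            design,
            l2fc_cutoff=config.l2fc_cutoff,
            fdr_cutoff=config.fdr_cutoff,
            prior=config.prior_cpm,
            persistence_reference=config.persistence_reference,
            apply_abundance_filter=config.abundance_filter,
            cluster_k=config.cluster_k,
            cluster_seed=config.cluster_seed,
            cluster_restarts=config.cluster_restarts,
            cluster_columns=config.cluster_columns,
        )
        done()

        done = stage("write_artifacts")
        write_table(result.calls, out / "peak_calls.tsv")
        manifest["artifacts"]["calls"] = "peak_calls.tsv"
        for name, ctr in result.contrasts.items():
            fname = f"contrast_{name}_vs_{ctr.condition_a}.tsv"
            write_table(ctr.table, out / fname)
            manifest["artifacts"][f"contrast_{name}"] = fname
        if matrix.coords is not None:
            coords = matrix.coords.copy()
            coords["feature_id"] = matrix.feature_ids
            # carry the acute IFNγ l2fc into BED scores
            ifng = result.contrasts["ifng_8h"].table.set_index("feature_id")["l2fc"]
            for stim, col in (("ifng", "induced_ifng"), ("lps", "induced_lps")):
                ids = set(result.calls.loc[result.calls[col], "feature_id"])
                sub = coords[coords["feature_id"].isin(ids)].copy()
                sub["l2fc"] = sub["feature_id"].map(ifng).fillna(0.0)
                write_bed(sub, out / f"induced_{stim}.bed")
                manifest["artifacts"][f"induced_{stim}_bed"] = f"induced_{stim}.bed"
            label_by_id = result.calls.set_index("feature_id")["cluster_label"]
            for treatment in ("media", "anti_ifng_ab", "ruxolitinib"):
                col = f"persistent_{treatment}"
                if col not in result.calls.columns:
                    continue
                ids = set(result.calls.loc[result.calls[col], "feature_id"])
                sub = coords[coords["feature_id"].isin(ids)].copy()
                sub["l2fc"] = sub["feature_id"].map(ifng).fillna(0.0)
                sub["feature_id"] = sub["feature_id"].map(label_by_id).fillna("n/a") + "|" + sub["feature_id"]
                write_bed(sub, out / f"persistent_{treatment}.bed")
                manifest["artifacts"][f"persistent_{treatment}_bed"] = f"persistent_{treatment}.bed"
        write_json(result.summary, out / "summary.json")
        manifest["artifacts"]["summary"] = "summary.json"
        manifest["summary"] = result.summary
        manifest["modes"].update(result.metadata)
        done()
    else:
        done = stage("classify_genes")
        result = classify_genes(
            matrix,
            design,
            criteria=config.criteria,
            fold_cutoff_media=config.fold_cutoff_media,
            fold_cutoff_rux=config.fold_cutoff_rux,
            ratio_cutoff=config.ratio_cutoff,
            basal_l2fc_cutoff=config.basal_l2fc_cutoff,
            isg_fold_cutoff=config.isg_fold_cutoff,
            prior=config.prior_cpm,
            inducible_mode=config.inducible_mode,
            isg_reference=config.isg_reference,
        )
        done()
        done = stage("write_artifacts")
        write_table(result.calls, out / "gene_calls.tsv")
        write_json(result.summary, out / "summary.json")
        manifest["artifacts"]["calls"] = "gene_calls.tsv"
        manifest["artifacts"]["summary"] = "summary.json"
        manifest["summary"] = result.summary
        manifest["modes"].update(result.metadata)
        done()

    write_json(manifest, out / "manifest.json")
    return manifest
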