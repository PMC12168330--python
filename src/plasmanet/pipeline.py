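"""End-to-end pipeline orchestration.

Stages run in a fixed order — simulate (or load) -> QC -> network ->
differential abundance -> enrichment -> panel -> traits — sharing one
configuration object and one master seed that is deterministically split
into per-stage substreams, so any stage can be re-run in isolation and
reproduce its part of a full run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from plasmanet import io
from plasmanet.simulate import study_cohort_config, generate_cohort
from plasmanet.qc import (
    apply_lod_mask, filter_proteins, remove_outlier_samples, bootstrap_covariate_adjust,
)
from plasmanet.network import NetworkParams, build_network
from plasmanet.diffabund import anova_tukey, eigenprotein_group_tests, module_da_summary
from plasmanet.enrichment import module_overrepresentation
from plasmanet.panel import rfecv_select
from plasmanet.traits import module_trait_correlations, protein_trait_differential_correlation

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed"]

_STAGES = ("simulate", "qc", "network", "da", "enrichment", "panel", "traits")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters with their standard defaults."""

    stages: tuple[str, ...] = _STAGES
    seed: int = 0
    # inputs (unused when the simulate stage is on)
    matrix_path: str | None = None
    qc_path: str | None = None
    meta_path: str | None = None
    traits_path: str | None = None
    # qc
    missing_threshold: float = 0.5
    z_cutoff: float = 3.0
    n_boot: int = 1000
    # network
    power: float = 7.5
    deep_split: int = 4
    min_module_size: int = 10
    merge_cut_height: float = 0.07
    # da / enrichment / panel
    da_alpha: float = 0.05
    contrast: tuple[str, str] = ("RHI", "CTL")
    k_folds: int = 5
    panel_n_boot: int = 1000
    cognition_trait: str = "global_cognition_z"
    cognition_group: str = "RHI"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("stages", "contrast"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["contrast"] = list(self.contrast)
        return d


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_checksums: dict = field(default_factory=dict)
    accounting: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    failed_stage: str | None = None

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute the enabled stages in order, writing TSV/JSON outputs.

    A stage failure aborts the run with a stage-named error; outputs of the
    completed stages are retained and the manifest records the failure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    state: dict = {}
    try:
        for stage in _STAGES:
            if stage not in config.stages:
                continue
            _run_stage(stage, config, state, out, manifest)
    except Exception as exc:
        manifest.failed_stage = getattr(exc, "_stage", "unknown")
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.write(out / "manifest.json")
        (out / "FAILED").write_text(f"{manifest.failed_stage}: {exc}\n")
        raise
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    return manifest


def _stage_error(stage, exc):
    exc._stage = stage
    return exc


def _run_stage(stage, cfg, state, out, manifest):  # noqa: C901 — dispatcher
    try:
        if stage == "simulate":
            sim_cfg = study_cohort_config(seed=stage_seed(cfg.seed, "simulate"))
            matrix, meta, qc, traits, gt = generate_cohort(sim_cfg)
            state.update(matrix=matrix, meta=meta, qc=qc, traits=traits, truth=gt)
            io.write_matrix(matrix, out / "matrix.tsv")
            io.write_table(meta, out / "metadata.tsv")
            io.write_table(qc, out / "assay_qc.tsv")
            io.write_table(traits, out / "traits.tsv")
            (out / "ground_truth.json").write_text(json.dumps({
                "module_of": gt.module_of.to_dict(),
                "outliers": gt.outlier_flag[gt.outlier_flag].index.tolist(),
            }, indent=2))
            manifest.accounting["simulate"] = {"samples": len(matrix), "proteins": matrix.shape[1]}
        elif stage == "qc":
            if "matrix" not in state:
                state["matrix"] = io.read_matrix(cfg.matrix_path)
                state["qc"] = io.read_table(cfg.qc_path)
                state["meta"] = io.read_table(cfg.meta_path)
                if cfg.traits_path:
                    state["traits"] = io.read_table(cfg.traits_path)
                for key, p in (("matrix", cfg.matrix_path), ("qc", cfg.qc_path), ("meta", cfg.meta_path)):
                    manifest.input_checksums[key] = _checksum(p)
                missing = set(state["matrix"].index) ^ set(state["meta"].index)
                if missing:
                    raise ValueError(f"matrix/metadata sample mismatch: {sorted(missing)[:5]}")
            m = apply_lod_mask(state["matrix"], state["qc"])
            m, prot_report = filter_proteins(m, state["qc"], cfg.missing_threshold)
            m, samp_report = remove_outlier_samples(m, cfg.z_cutoff)
            meta = state["meta"].loc[m.index]
            adjusted, coefs = bootstrap_covariate_adjust(
                m, meta, n_boot=cfg.n_boot, seed=stage_seed(cfg.seed, "qc"))
            state["clean"] = adjusted
            state["meta_clean"] = meta
            io.write_matrix(adjusted, out / "matrix_adjusted.tsv")
            io.write_table(coefs, out / "covariate_coefficients.tsv")
            report = {**prot_report.to_dict(), **{k: v for k, v in samp_report.to_dict().items()
                                                 if "sample" in k}}
            (out / "qc_report.json").write_text(json.dumps(report, indent=2))
            manifest.accounting["qc"] = report
        elif stage == "network":
            params = NetworkParams(power=cfg.power, deep_split=cfg.deep_split,
                                   min_module_size=cfg.min_module_size,
                                   merge_cut_height=cfg.merge_cut_height)
            model = build_network(state["clean"], params)
            state["model"] = model
            assign = pd.DataFrame({"module": model.module_labels})
            if not model.kme.empty:
                own = [model.kme.at[p, f"M{m}"] if m > 0 else np.nan
                       for p, m in model.module_labels.items()]
                assign["own_kme"] = own
            io.write_table(assign, out / "module_assignment.tsv")
            io.write_table(model.eigenproteins, out / "eigenproteins.tsv")
            manifest.accounting["network"] = {
                "n_modules": model.n_modules,
                "n_assigned": int((model.module_labels > 0).sum()),
                "n_unassigned": int((model.module_labels == 0).sum()),
            }
        elif stage == "da":
            groups = state["meta_clean"]["group"]
            diff = anova_tukey(state["clean"], groups,
                               module_labels=state.get("model") and state["model"].module_labels)
            state["da"] = diff
            io.write_table(diff, out / "differential_abundance.tsv")
            if "model" in state and state["model"].n_modules:
                me_tests = eigenprotein_group_tests(state["model"].eigenproteins, groups)
                io.write_table(me_tests, out / "eigenprotein_tests.tsv")
                summ = module_da_summary(diff, state["model"].module_labels, cfg.contrast, cfg.da_alpha)
                io.write_table(summ, out / "module_da_summary.tsv")
            a, b = cfg.contrast
            pcol = f"tukey_p_{a}_vs_{b}" if f"tukey_p_{a}_vs_{b}" in diff.columns else f"tukey_p_{b}_vs_{a}"
            manifest.accounting["da"] = {
                "n_tested": int(diff["tested"].sum()),
                "n_da_contrast": int((diff[pcol] < cfg.da_alpha).sum()),
            }
        elif stage == "enrichment":
            if "traits" not in state or cfg.cognition_trait not in state["traits"].columns:
                manifest.accounting["enrichment"] = {"skipped": "no cognition trait available"}
                return
            model = state.get("model")
            if model is None or not model.n_modules:
                manifest.accounting["enrichment"] = {"skipped": "no network modules"}
                return
            groups = state["meta_clean"]["group"]
            sub_idx = state["clean"].index[groups == cfg.cognition_group]
            trait = state["traits"][cfg.cognition_trait]
            volcano, summary = protein_trait_differential_correlation(
                state["clean"], trait, sub_idx, model.module_labels, cfg.da_alpha)
            over = module_overrepresentation(volcano, model.module_labels, "negative", cfg.da_alpha)
            io.write_table(volcano, out / "cognition_correlations.tsv")
            io.write_table(over, out / "module_overrepresentation.tsv")
            state["cognition_volcano"] = volcano
            manifest.accounting["enrichment"] = {
                "n_hits": int(((volcano["p"] < cfg.da_alpha) & (volcano["rho"] < 0)).sum()),
                "n_modules_tested": len(over),
            }
        elif stage == "panel":
            a, b = cfg.contrast
            diff = state["da"]
            pcol = f"tukey_p_{a}_vs_{b}" if f"tukey_p_{a}_vs_{b}" in diff.columns else f"tukey_p_{b}_vs_{a}"
            candidates = diff.index[diff[pcol] < cfg.da_alpha]
            groups = state["meta_clean"]["group"]
            keep = groups.isin([a, b])
            if len(candidates) < 2:
                manifest.accounting["panel"] = {"skipped": "fewer than 2 candidate proteins"}
                return
            X = state["clean"].loc[keep, candidates]
            X = X.fillna(X.median())
            y = (groups[keep] == a).astype(int)
            result = rfecv_select(X, y.to_numpy(), k=cfg.k_folds,
                                  seed=stage_seed(cfg.seed, "panel"), n_boot=cfg.panel_n_boot)
            io.write_table(result.cv_curve, out / "panel_cv_curve.tsv")
            io.write_table(result.per_protein_auc, out / "panel_protein_auc.tsv")
            (out / "panel_result.json").write_text(json.dumps({
                "selected": result.selected,
                "cv_accuracy": result.cv_accuracy,
                "panel_auc": result.panel_auc,
                "panel_auc_ci": list(result.panel_auc_ci),
                "C": result.C,
            }, indent=2))
            manifest.accounting["panel"] = {
                "n_candidates": int(len(candidates)),
                "n_selected": len(result.selected),
                "cv_accuracy": result.cv_accuracy,
                "panel_auc": result.panel_auc,
            }
        elif stage == "traits":
            model = state.get("model")
            if model is None or not model.n_modules or "traits" not in state:
                manifest.accounting["traits"] = {"skipped": "no modules or traits"}
                return
            traits = state["traits"].reindex(state["clean"].index)
            numeric = traits.select_dtypes(include=[np.number])
            table = module_trait_correlations(model.eigenproteins, numeric,
                                              groups=state["meta_clean"]["group"])
            io.write_table(table, out / "module_trait_correlations.tsv", index=False)
            manifest.accounting["traits"] = {"n_cells": len(table)}
    except Exception as exc:
        raise _stage_error(stage, exc)
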