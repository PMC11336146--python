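"""End-to-end pipeline runner driven by a YAML run-config.

Stages (each toggleable): preprocess -> screen/fixed signature -> score ->
cutoff scan -> KM figure -> per-dataset replication -> paired multivariate.
Every output table is written as TSV, every figure as SVG/PNG, and a
manifest records a content hash per file so that re-runs with the same
config and seed are verifiably identical at the table level (figures are
exempt: renderer metadata varies).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time as _time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import dataset_results_frame, paired_results_frame
from .cutoff import scan_profile
from .io import (
    ClinicalTable,
    ExpressionMatrix,
    clinical_summary,
    read_clinical,
    read_expression,
    read_gene_list,
    read_platform_probes,
    read_probe_map,
    write_clinical,
    write_expression,
)
from .model import SenescenceSignatureModel
from .preprocess import (
    QCThresholds,
    collapse_to_genes,
    qc_flag,
    read_qc_metrics,
    restrict_probes,
    scale_normalize,
)

logger = logging.getLogger("senosig.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _log(stage: str, **kv) -> None:
    pairs = " ".join(f"{k}={v}" for k, v in kv.items())
    logger.info("stage=%s %s", stage, pairs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns the manifest dict.

    ``config`` keys (all optional unless noted): ``expression`` (path,
    required), ``clinical`` (path, required), ``orientation``,
    ``gene_list``, ``platform_probes``, ``probe_map``, ``qc_metrics``,
    ``qc`` (threshold block), ``normalize`` (bool, default true),
    ``target_mean``, ``scan`` (q_low/q_high/min_group/test), ``screen``
    (standardize/median_split), ``per_dataset`` (min_n/min_events/enabled),
    ``multivariate`` (enabled/covariates), ``figures`` (format svg|png).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = _time.time()
    stage = "load"
    try:
        expr = read_expression(
            _require(config, "expression"), config.get("orientation", "samples_by_genes")
        )
        clin = read_clinical(_require(config, "clinical"))
        _log(stage, samples=expr.n_samples, genes=expr.n_genes, clinical=len(clin))

        stage = "preprocess"
        if config.get("qc_metrics"):
            metrics = read_qc_metrics(config["qc_metrics"])
            thresholds = QCThresholds(**config.get("qc", {}))
            flags = qc_flag(metrics, thresholds)
            _write_table(flags, out / "qc_flags.tsv")
            failed = set(flags.loc[flags["status"] == "fail", "sample_id"])
            # failing arrays are excluded; unevaluable ones are kept, logged
            keep = [s for s in expr.sample_ids if s not in failed]
            _log(stage, qc_fail=len(failed),
                 qc_unevaluable=int((flags["status"] == "unevaluable").sum()))
            expr = ExpressionMatrix(expr.data.loc[keep])
        if config.get("platform_probes"):
            probes = read_platform_probes(config["platform_probes"])
            expr, dropped = restrict_probes(expr, probes)
            _log(stage, probes_dropped=dropped)
        if config.get("probe_map"):
            expr = collapse_to_genes(expr, read_probe_map(config["probe_map"]))
            _log(stage, genes_after_collapse=expr.n_genes)
        if config.get("normalize", True):
            expr = scale_normalize(expr, float(config.get("target_mean", 1000.0)))
            _log(stage, normalized_mean=float(config.get("target_mean", 1000.0)))

        stage = "fit"
        scan_cfg = config.get("scan", {})
        screen_cfg = config.get("screen", {})
        gene_list = config.get("gene_list")
        fixed = read_gene_list(gene_list) if gene_list else None
        if fixed is not None and all(e.fixed_weight is None for e in fixed):
            keep = [e.gene_id for e in fixed if e.gene_id in set(expr.gene_ids)]
            expr = ExpressionMatrix(expr.data[keep])
            fixed = None
        model = SenescenceSignatureModel(
            expr,
            clin,
            fixed_signature=fixed,
            standardize_screen=screen_cfg.get("standardize", True),
            median_split_screen=screen_cfg.get("median_split", False),
            scan_test=scan_cfg.get("test", "cox"),
            q_low=scan_cfg.get("q_low", 0.25),
            q_high=scan_cfg.get("q_high", 0.75),
            min_group=scan_cfg.get("min_group"),
        )
        results = model.fit()
        weights_df = results.weights.data
        _log(stage, genes=len(weights_df),
             weight_zero=int((weights_df["weight"] == 0).sum()),
             selected_cutoff=f"{results.scan.selected_cutoff:.6g}",
             hr=f"{results.hr:.4g}", p=f"{results.p:.3g}")
        results.weights.to_tsv(out / "gene_weights.tsv")
        _write_table(results.scores.rename("score").reset_index(), out / "scores.tsv")
        _write_table(results.scan.table, out / "cutoff_scan.tsv")
        _write_table(results.scan_profile(), out / "scan_profile.tsv")
        _write_table(clinical_summary(clin), out / "clinical_summary.tsv")
        cox_df = pd.DataFrame([{
            "term": results.cox.term, "hr": results.cox.hr,
            "ci_low": results.cox.ci_low, "ci_high": results.cox.ci_high,
            "p": results.cox.p, "n": results.cox.n, "events": results.cox.events,
        }])
        _write_table(cox_df, out / "signature_cox.tsv")

        stage = "figures"
        fmt = config.get("figures", {}).get("format", "svg")
        results.plot_km(out / f"km.{fmt}")
        results.plot_scan(out / f"scan_profile.{fmt}")

        stage = "per_dataset"
        pd_cfg = config.get("per_dataset", {})
        panels_written = False
        if pd_cfg.get("enabled", True) and clin.data["dataset_id"].nunique() > 1:
            ds_results, excluded = results.per_dataset(
                min_n=pd_cfg.get("min_n", 30),
                min_events=pd_cfg.get("min_events", 10),
                use_global_cutoff=pd_cfg.get("use_global_cutoff", False),
            )
            _write_table(dataset_results_frame(ds_results), out / "per_dataset.tsv")
            _write_table(
                pd.DataFrame(excluded, columns=["dataset_id", "reason"]),
                out / "per_dataset_excluded.tsv",
            )
            _log(stage, retained=len(ds_results), excluded=len(excluded),
                 direction_consistent=sum(r.direction_consistent for r in ds_results))
            from .plotting import render_km_grid
            from .survival import SurvivalData, km_estimate

            panels = []
            for r in ds_results:
                sub = clin.data[clin.data["dataset_id"] == r.dataset_id]
                scores = results.scores.loc[sub.index]
                high = scores.to_numpy() > r.selected_cutoff
                surv_t, surv_e = sub["time"].to_numpy(), sub["event"].to_numpy()
                curves = {
                    "low": km_estimate(SurvivalData(surv_t[~high], surv_e[~high]), ci=False),
                    "high": km_estimate(SurvivalData(surv_t[high], surv_e[high]), ci=False),
                }
                panels.append(
                    (r.dataset_id, curves,
                     f"HR = {r.cox.hr:.2f}\np = {r.cox.format_p()}")
                )
            render_km_grid(panels, out / f"per_dataset_km.{fmt}")
            panels_written = True

        stage = "multivariate"
        mv_cfg = config.get("multivariate", {})
        if mv_cfg.get("enabled", True) and clin.covariates_present():
            paired, skipped = results.paired_multivariate_all(
                covariates=mv_cfg.get("covariates")
            )
            if paired:
                _write_table(paired_results_frame(paired), out / "paired_cox.tsv")
            _write_table(
                pd.DataFrame(skipped, columns=["covariate", "reason"]),
                out / "paired_cox_skipped.tsv",
            )
            _log(stage, fitted=len(paired), skipped=len(skipped))
    except Exception as exc:  # noqa: BLE001 - re-raise with the stage named
        raise PipelineError(stage, exc) from exc

    stage = "manifest"
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    manifest = {
        "version": __version__,
        "elapsed_s": round(_time.time() - t0, 2),
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.suffix in (".tsv", ".yaml")
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    _log("done", files=len(manifest["files"]), elapsed_s=manifest["elapsed_s"])
    return manifest


def _require(config: dict, key: str):
    value = config.get(key)
    if not value:
        raise ValueError(f"run config missing required key {key!r}")
    path = Path(value)
    if not path.exists():
        raise FileNotFoundError(f"{key}: no such file {path}")
    return path
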