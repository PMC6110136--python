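"""End-to-end benchmark analysis producing a paper-style report bundle.

`run_benchmark` reads one benchmark table and writes, under an output
directory: pooled and per-TKI metric tables with bootstrap CIs, a
threshold-sweep table, ROC points and AUCs (including the naive and
consensus models), optional Bayesian posterior summaries, and a JSON run
log with every seed and setting used. Energies and proportions are rounded
to 2 decimals in the report tables; full-precision companions are kept
alongside.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .bayes import IntrinsicErrorModel, SamplerSettings
from .bootstrap import BootstrapSpec, bootstrap_ci
from .constants import ThermoConstants
from .evaluate import (
    accuracy,
    build_truth_table,
    mue,
    quantitative_records,
    rmse,
    sensitivity,
    specificity,
    threshold_sweep,
)
from .records import PredictionRecord, method_names, read_benchmark_table
from .roc import add_method, consensus, fit_scale, naive_predictions, roc_curve
from .transform import cutoff_from_fold


@dataclass
class RunConfig:
    """Settings for a full benchmark run."""

    input_path: str | Path
    output_dir: str | Path
    methods: Sequence[str] | None = None
    folds: Sequence[float] = (10.0, 20.0, 100.0)
    temperature: float = 298.15
    sigma_exp: float = 0.57
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    run_bayes: bool = False
    bayes_settings: SamplerSettings = field(default_factory=SamplerSettings)
    roc_step: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 1 for f in self.folds):
            raise ValueError("folds must all exceed 1")


def _metric_row(
    records: list[PredictionRecord], method: str, threshold, spec: BootstrapSpec
) -> dict[str, object]:
    """One Table-2-style row: N_quant, MUE, RMSE, N_class, acc/spec/sens + CIs."""
    quant = quantitative_records(records, method)
    row: dict[str, object] = {
        "method": method,
        "n_quant": len(quant),
        "n_class": len(records),
    }
    stats = {
        "mue": lambda rs: mue(rs, method),
        "rmse": lambda rs: rmse(rs, method),
        "accuracy": lambda rs: accuracy(build_truth_table(rs, method, threshold)),
        "specificity": lambda rs: specificity(
            build_truth_table(rs, method, threshold)
        ),
        "sensitivity": lambda rs: sensitivity(
            build_truth_table(rs, method, threshold)
        ),
    }
    for name, stat in stats.items():
        try:
            est = bootstrap_ci(stat, records, spec, name=name)
        except ValueError:
            row[name] = row[f"{name}_low"] = row[f"{name}_high"] = None
            continue
        row[name] = est.value
        row[f"{name}_low"] = est.ci_low
        row[f"{name}_high"] = est.ci_high
    return row


def run_benchmark(config: RunConfig) -> dict[str, Path]:
    """Execute every analysis stage; returns the paths written."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    constants = ThermoConstants(T=config.temperature)
    threshold = cutoff_from_fold(config.folds[0], constants)
    records = read_benchmark_table(config.input_path)
    methods = list(config.methods) if config.methods else method_names(records)
    if not methods:
        raise ValueError("no prediction methods found in the input table")
    spec = BootstrapSpec(
        config.bootstrap.n_boot, config.bootstrap.alpha, config.seed
    )
    written: dict[str, Path] = {}

    # --- pooled and per-TKI metric tables -------------------------------
    rows = []
    for method in methods:
        row = _metric_row(records, method, threshold, spec)
        row["tki"] = "all"
        rows.append(row)
        for tki in sorted({r.tki for r in records}):
            sub = [r for r in records if r.tki == tki]
            row = _metric_row(sub, method, threshold, spec)
            row["tki"] = tki
            rows.append(row)
    metrics = pd.DataFrame(rows)
    metrics_path = outdir / "metrics.csv"
    metrics.round(2).to_csv(metrics_path, index=False)
    metrics.to_csv(outdir / "metrics_full.csv", index=False)
    written["metrics"] = metrics_path

    # --- threshold sweep ------------------------------------------------
    sweep_rows = []
    for method in methods:
        sweep = threshold_sweep(records, method, config.folds, constants)
        for fold, (table, mets) in sweep.items():
            sweep_rows.append(
                {
                    "method": method,
                    "fold": fold,
                    "cutoff": round(cutoff_from_fold(fold, constants).cutoff, 2),
                    "tp": table.tp, "fn": table.fn,
                    "fp": table.fp, "tn": table.tn,
                    **{
                        k: (round(v, 2) if v is not None else None)
                        for k, v in mets.items()
                    },
                }
            )
    sweep_path = outdir / "threshold_sweep.csv"
    pd.DataFrame(sweep_rows).to_csv(sweep_path, index=False)
    written["threshold_sweep"] = sweep_path

    # --- ROC incl. naive and consensus ----------------------------------
    roc_records = add_method(records, "naive", naive_predictions(records))
    roc_methods = methods + ["naive"]
    scale_info = {}
    if len(methods) >= 2:
        roc_records = add_method(
            roc_records, "consensus", consensus(records, methods[0], methods[1])
        )
        roc_methods.append("consensus")
        for m in methods[:2]:
            fitted = fit_scale(records, m)
            scale_info[m] = {"slope": fitted.slope, "rmse": fitted.rmse}
    auc_rows = []
    for method in roc_methods:
        curve = roc_curve(roc_records, method, threshold, config.roc_step)
        pd.DataFrame(curve.points, columns=["fpr", "tpr"]).to_csv(
            outdir / f"roc_{method}.csv", index=False
        )
        auc_rows.append({"method": method, "auc": round(curve.auc, 2)})
    auc_path = outdir / "roc_auc.csv"
    pd.DataFrame(auc_rows).to_csv(auc_path, index=False)
    written["roc_auc"] = auc_path

    # --- Bayesian intrinsic error (optional) ----------------------------
    if config.run_bayes:
        bayes_rows = []
        for method in methods:
            model = IntrinsicErrorModel.from_records(
                records, method, config.sigma_exp
            )
            results = model.fit(config.bayes_settings, seed=config.seed)
            summary = results.summary()
            summary.insert(0, "method", method)
            bayes_rows.append(summary)
            results.draws.to_csv(outdir / f"bayes_draws_{method}.csv", index=False)
            pm = results.posterior_metrics(threshold, seed=config.seed)
            pm.round(2).to_csv(outdir / f"bayes_predictive_{method}.csv")
        bayes_path = outdir / "bayes_summary.csv"
        pd.concat(bayes_rows).to_csv(bayes_path)
        written["bayes_summary"] = bayes_path

    # --- machine-readable run log ---------------------------------------
    log = {
        "fepbench_version": __version__,
        "python": platform.python_version(),
        "input": str(config.input_path),
        "methods": methods,
        "folds": list(config.folds),
        "temperature_K": config.temperature,
        "sigma_exp": config.sigma_exp,
        "n_boot": spec.n_boot,
        "alpha": spec.alpha,
        "seed": config.seed,
        "roc_step": config.roc_step,
        "scale_fits": scale_info,
        "run_bayes": config.run_bayes,
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    written["run_log"] = log_path
    return written
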