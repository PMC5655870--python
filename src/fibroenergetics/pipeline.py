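"""End-to-end orchestration: simulate -> features -> stats -> classify.

A run is described by a :class:`RunConfig` (serializable to YAML); its
outputs land in one directory together with a verbatim copy of the
config, a structured log, and a ``summary.json`` of headline numbers.
Fixed seed implies byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import pandas as pd
import yaml

from . import classify, features as features_mod, stats, synthesize
from .core import (
    FEATURES,
    Cohort,
    assemble_feature_matrix,
    read_cohort,
    write_cohort,
)
from .synthesize import SPEARMAN_PAIRS

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for exit diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    input_dir: str | None = None      # read an existing cohort instead of simulating
    seed: int = 0
    # synthetic overrides
    group_sizes: dict[str, int] | None = None
    technical_cv: float | None = None
    outlier_rate: float | None = None
    use_tmrm_mtg_subset: bool = False
    # stats options
    n_boot: int = 10_000
    fdr: float = 0.05
    bh_family: str = "joint"
    # classifier options
    k_folds: int = 10
    tasks: tuple[str, ...] = ("control-vs-disease", "sals-vs-pls")
    stages: tuple[str, ...] = ("simulate", "features", "stats", "classify")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("tasks", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _log(handle, entries: list[str], stage: str, event: str, **fields) -> None:
    line = json.dumps({"stage": stage, "event": event, **fields})
    entries.append(line)
    handle.write(line + "\n")
    handle.flush()


def _build_synthetic_config(cfg: RunConfig) -> synthesize.SyntheticConfig:
    base = synthesize.default_config(seed=cfg.seed,
                                     use_tmrm_mtg_subset=cfg.use_tmrm_mtg_subset)
    groups = dict(base.groups)
    if cfg.group_sizes:
        for name, n in cfg.group_sizes.items():
            groups[name] = replace(groups[name], n_lines=int(n))
    kwargs = {}
    if cfg.technical_cv is not None:
        kwargs["technical_cv"] = cfg.technical_cv
    if cfg.outlier_rate is not None:
        kwargs["outlier_rate"] = cfg.outlier_rate
    noise = replace(base.noise, **kwargs) if kwargs else base.noise
    return replace(base, groups=groups, noise=noise)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Raises :class:`PipelineError` with stage context on any failure.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)

    summary: dict = {"seed": cfg.seed}
    entries: list[str] = []
    log_fh = open(out / "run_log.jsonl", "w")
    t0 = time.time()
    cohort: Cohort | None = None
    profiles = None
    current_stage = "setup"
    try:
        if "simulate" in cfg.stages:
            current_stage = "simulate"
            syn_cfg = _build_synthetic_config(cfg)
            cohort, truth = synthesize.generate_cohort(syn_cfg)
            cohort_dir = out / "cohort"
            write_cohort(cohort, cohort_dir)
            truth.to_csv(cohort_dir / "truth_profiles.csv", index=False)
            _log(log_fh, entries, "simulate", "done",
                 n_lines=int(len(cohort.lines)),
                 n_flux_rows=int(len(cohort.flux)),
                 n_fluor_rows=int(len(cohort.fluorescence)),
                 n_atp_rows=int(len(cohort.atp)))
            summary["n_lines"] = int(len(cohort.lines))

        if "features" in cfg.stages:
            current_stage = "features"
            if cohort is None:
                src = cfg.input_dir or (out / "cohort")
                cohort = read_cohort(src)
            profiles, qc_report = features_mod.build_profiles(cohort)
            profiles.to_csv(out / "profiles.csv", index=False)
            qc_report.to_csv(out / "qc_report.csv", index=False)
            _log(log_fh, entries, "features", "done",
                 n_profiles=int(profiles[list(FEATURES)].notna().all(axis=1).sum()),
                 n_qc_records=int(len(qc_report)))

        if "stats" in cfg.stages or "classify" in cfg.stages:
            current_stage = "stats" if "stats" in cfg.stages else "classify"
            if profiles is None:
                profiles = pd.read_csv(out / "profiles.csv", dtype={"line_id": str})
            if cohort is None:
                cohort = read_cohort(cfg.input_dir or (out / "cohort"))
            complete = profiles.dropna(subset=list(FEATURES))
            X, y = assemble_feature_matrix(complete, lines=cohort.lines if cohort
                                           is not None else None)

        if "stats" in cfg.stages:
            scan, nonparametric = stats.normality_scan(X)
            scan.to_csv(out / "normality_scan.csv", index=False)
            report, _ = stats.group_comparison_table(
                X, y, n_boot=cfg.n_boot, seed=cfg.seed)
            report.to_csv(out / "stats_report.csv", index=False)
            prof_groups = X.copy()
            prof_groups["group"] = y
            corr = stats.spearman_bh(prof_groups, SPEARMAN_PAIRS,
                                     fdr=cfg.fdr, family=cfg.bh_family)
            corr.to_csv(out / "correlations.csv", index=False)
            _log(log_fh, entries, "stats", "done",
                 nonparametric=bool(nonparametric),
                 n_comparisons=int(len(report)),
                 n_correlations=int(len(corr)))
            summary["nonparametric"] = bool(nonparametric)

        if "classify" in cfg.stages:
            current_stage = "classify"
            for task in cfg.tasks:
                mask, y_bin = classify.make_task(y.to_numpy(), task)
                Xt = X.to_numpy()[mask]
                search = classify.cross_validate_grid(Xt, y_bin, k=cfg.k_folds,
                                                      seed=cfg.seed)
                report = classify.evaluate_best(Xt, y_bin, search.best_point,
                                                k=cfg.k_folds, seed=cfg.seed,
                                                task=task)
                stem = task.replace("-", "_")
                search.accuracy_table.to_csv(out / f"grid_{stem}.csv", index=False)
                pd.DataFrame({"fpr": report.fpr_grid, "tpr": report.mean_tpr}
                             ).to_csv(out / f"roc_mean_{stem}.csv", index=False)
                pd.concat([
                    pd.DataFrame({"fold": i, "fpr": fpr, "tpr": tpr})
                    for i, (fpr, tpr) in enumerate(report.fold_curves)
                ]).to_csv(out / f"roc_folds_{stem}.csv", index=False)
                with open(out / f"cv_report_{stem}.json", "w") as fh:
                    json.dump({**report.summary(),
                               "fold_accuracies": report.fold_accuracies,
                               "fold_aucs": report.fold_aucs,
                               "pooled_confusion": report.pooled_confusion,
                               "panel": report.panel.to_dict(orient="records"),
                               "warnings": report.warnings}, fh, indent=2)
                _log(log_fh, entries, "classify", "done", task=task,
                     best_kernel=search.best_point.kernel,
                     mean_accuracy=search.best_mean_accuracy,
                     auc_mean_curve=report.auc_mean_curve)
                summary[task] = report.summary()

        summary["elapsed_s"] = round(time.time() - t0, 2)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(current_stage, str(exc)) from exc
    finally:
        log_fh.close()
    return out
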