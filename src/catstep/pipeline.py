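"""Pipeline orchestration: simulate -> measure -> fit -> statistics -> report.

``run_pipeline`` drives a whole analysis from one config: it either simulates
a cohort or loads one from CSV, then (for training/transfer experiments)
aggregates ratings, builds the group summary table, runs the correlation /
regression / agreement suite, and fits and compares the step-model variants;
for the control-task experiment it produces per-condition summaries and the
ANOVA / Tukey / effect-size suite.  Every statistic in the report is produced
by calling the module-level operations on the same intermediate data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import (
    CohortConfig,
    Dataset,
    EXP4_CONDITIONS,
    ConfigError,
    read_dataset,
    simulate_cohort,
    write_dataset,
)
from .stepmodel import GridSpec, compare_variants, fit_inputs_from_dataset
from .stats import (
    EXCLUDED,
    agreement,
    aggregate_ratings,
    anova_tukey,
    group_summary,
    ols_standardized,
    participant_metrics,
    spearman,
)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One run's full configuration.

    Exactly one of ``cohort`` (simulate) or ``input_dir`` (load CSVs) must be
    given.  ``variants`` are the step-model variants to compare; ``alpha`` the
    post-hoc significance level; ``p_method`` the Spearman p-value method.
    """

    experiment: str
    cohort: CohortConfig | None = None
    input_dir: str | None = None
    grid: GridSpec = field(default_factory=GridSpec)
    variants: tuple[str, ...] = ("GATED_FR", "UNGATED", "CA_ONLY")
    alpha: float = 0.05
    p_method: str = "t_approx"
    out_dir: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.input_dir is None):
            raise ConfigError(
                "exactly one of cohort (simulate) or input_dir (load) must be set"
            )

    def canonical_json(self) -> str:
        def default(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if isinstance(obj, (set, frozenset, tuple)):
                return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
            raise TypeError(f"not JSON-serializable: {obj!r}")

        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # where outputs land is not provenance
        return json.dumps(payload, sort_keys=True, default=default)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


@dataclass
class RunReport:
    """Everything one pipeline run computed, JSON-serializable."""

    experiment: str
    provenance: dict
    group_summary: pd.DataFrame | None = None
    correlations: dict | None = None
    regressions: dict | None = None
    agreement: dict | None = None
    model_comparison: dict | None = None
    participant_fits: dict | None = None
    condition_summary: pd.DataFrame | None = None
    task_rt_anova: dict | None = None
    feature_rt_anova: dict | None = None

    def to_dict(self) -> dict:
        out = {"experiment": self.experiment, "provenance": self.provenance}
        if self.group_summary is not None:
            out["group_summary"] = json.loads(
                self.group_summary.to_json(orient="columns")
            )
        for name in (
            "correlations",
            "regressions",
            "agreement",
            "model_comparison",
            "participant_fits",
            "task_rt_anova",
            "feature_rt_anova",
        ):
            value = getattr(self, name)
            if value is not None:
                out[name] = value
        if self.condition_summary is not None:
            out["condition_summary"] = json.loads(
                self.condition_summary.to_json(orient="index")
            )
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _corr_dict(result) -> dict:
    return {
        "rho": result.rho,
        "df": result.df,
        "p_value": result.p_value,
        "method": result.method,
        "formatted": result.summary(),
    }


def _reg_dict(result) -> dict:
    return {
        "beta": result.beta,
        "t": result.t,
        "df": result.df,
        "p_value": result.p_value,
        "r_squared": result.r_squared,
        "adj_r_squared": result.adj_r_squared,
        "formatted": result.summary(),
    }


def _anova_dict(result) -> dict:
    return {
        "F": result.f,
        "df1": result.df1,
        "df2": result.df2,
        "p_value": result.p_value,
        "eta_squared": result.eta_squared,
        "formatted": result.summary(),
        "tukey": [dataclasses.asdict(p) for p in result.pairs],
    }


#: metric columns correlated with the dims-used rating in Exp1-3-style runs
METRIC_COLUMNS = (
    "mean_transfer_rt",
    "dim_accuracy_pct",
    "dims_100",
    "mean_training_rt",
    "training_blocks",
)


def aggregate_all_ratings(dataset: Dataset) -> dict:
    """participant_id -> mean rating in [1,5] or EXCLUDED."""
    out = {}
    for _, row in dataset.ratings.iterrows():
        out[row["participant_id"]] = aggregate_ratings(row["rater1"], row["rater2"])
    return out


def analyze_exp13(
    dataset: Dataset,
    grid: GridSpec | None = None,
    variants=("GATED_FR", "UNGATED", "CA_ONLY"),
    p_method: str = "t_approx",
    perm_seed: int | None = None,
) -> dict:
    """Full analysis of a training/transfer cohort (summary table,
    correlations and regressions of behavior against dims-used, agreement,
    step-model comparison)."""
    dims_used = aggregate_all_ratings(dataset)
    table = group_summary(dataset, dims_used)
    metrics = participant_metrics(dataset)
    included = [
        p for p, v in dims_used.items() if v != EXCLUDED and p in metrics.index
    ]
    ratings_vec = np.array([float(dims_used[p]) for p in included])

    from .stats import UndefinedStatisticError

    correlations = {}
    regressions = {}
    for col in METRIC_COLUMNS:
        values = metrics.loc[included, col].to_numpy(dtype=float)
        mask = ~np.isnan(values)
        kwargs = {"p_method": p_method}
        if p_method == "permutation":
            kwargs["seed"] = perm_seed
        try:
            correlations[f"dims_used_vs_{col}"] = _corr_dict(
                spearman(ratings_vec[mask], values[mask], **kwargs)
            )
            regressions[f"dims_used_vs_{col}"] = _reg_dict(
                ols_standardized(values[mask], ratings_vec[mask])
            )
        except UndefinedStatisticError as exc:
            # e.g. every participant needed the same number of training blocks
            correlations[f"dims_used_vs_{col}"] = {"undefined": str(exc)}
            regressions[f"dims_used_vs_{col}"] = {"undefined": str(exc)}

    agree = agreement(
        dataset.ratings["rater1"].tolist(), dataset.ratings["rater2"].tolist()
    )
    agreement_dict = {
        "kappa": agree.kappa,
        "percent_identical": agree.percent_identical,
        "mean_abs_diff": agree.mean_abs_diff,
        "n_excluded": int(sum(1 for v in dims_used.values() if v == EXCLUDED)),
    }

    fit_inputs = fit_inputs_from_dataset(dataset)
    comparison = compare_variants(fit_inputs, variants=variants, grid=grid or GridSpec())

    return {
        "group_summary": table,
        "correlations": correlations,
        "regressions": regressions,
        "agreement": agreement_dict,
        "model_comparison": comparison.to_dict(),
        "participant_fits": comparison.per_participant,
    }


def analyze_exp4(dataset: Dataset, alpha: float = 0.05) -> dict:
    """Per-condition summaries plus the RT ANOVA suites for a control-task
    cohort (all five conditions expected)."""
    trials = dataset.trials
    summary_rows = {}
    task_rt_groups: list[np.ndarray] = []
    task_labels: list[str] = []
    feature_rt_groups: list[np.ndarray] = []
    feature_labels: list[str] = []
    for condition in EXP4_CONDITIONS:
        cond = trials[trials["condition"] == condition]
        if len(cond) == 0:
            continue
        per_pid = cond.groupby("participant_id")

        def phase_mean(sub, column):
            return float(sub[column].mean()) if len(sub) else np.nan

        feat_last, task_train_acc, task_test_acc, task_test_rt, feat_last_rt = (
            [], [], [], [], [],
        )
        for _pid, g in per_pid:
            ft = g[g["phase"] == "feature_training"]
            last_block = ft[ft["block"] == ft["block"].max()] if len(ft) else ft
            feat_last.append(phase_mean(last_block, "correct") * 100.0)
            feat_last_rt.append(phase_mean(last_block, "rt_seconds"))
            task_train_acc.append(
                phase_mean(g[g["phase"] == "task_training"], "correct") * 100.0
            )
            tt = g[g["phase"] == "task_test"]
            task_test_acc.append(phase_mean(tt, "correct") * 100.0)
            task_test_rt.append(phase_mean(tt, "rt_seconds"))
        summary_rows[condition] = {
            "n": int(per_pid.ngroups),
            "feature_training_last_block_acc_pct": float(np.nanmean(feat_last)),
            "feature_training_last_block_rt": float(np.nanmean(feat_last_rt)),
            "task_training_acc_pct": float(np.nanmean(task_train_acc)),
            "task_test_acc_pct": float(np.nanmean(task_test_acc)),
            "task_test_rt": float(np.nanmean(task_test_rt)),
        }
        task_rt_groups.append(np.asarray(task_test_rt))
        task_labels.append(condition)
        if condition in ("ODD_EVEN_T", "ODD_EVEN_A", "FR"):
            feature_rt_groups.append(np.asarray(feat_last_rt))
            feature_labels.append(condition)

    out: dict = {
        "condition_summary": pd.DataFrame(summary_rows).T,
    }
    if len(task_rt_groups) >= 2:
        out["task_rt_anova"] = _anova_dict(
            anova_tukey(task_rt_groups, alpha=alpha, labels=task_labels)
        )
    if len(feature_rt_groups) >= 2:
        out["feature_rt_anova"] = _anova_dict(
            anova_tukey(feature_rt_groups, alpha=alpha, labels=feature_labels)
        )
    return out


def run_pipeline(config: PipelineConfig, write: bool = True) -> RunReport:
    """Run the configured pipeline end to end; optionally write the dataset,
    the summary table and the JSON report under ``config.out_dir``."""
    out_dir = Path(config.out_dir) if (config.out_dir and write) else None
    written: list[Path] = []
    try:
        stage = "acquire-data"
        if config.cohort is not None:
            dataset = simulate_cohort(config.cohort)
        else:
            dataset = read_dataset(config.input_dir)

        provenance = {
            "config_hash": config.config_hash(),
            "seed": config.cohort.seed if config.cohort is not None else config.seed,
            "version": __version__,
        }
        report = RunReport(experiment=config.experiment, provenance=provenance)

        if config.experiment == "EXP4":
            stage = "exp4-analysis"
            results = analyze_exp4(dataset, alpha=config.alpha)
            report.condition_summary = results["condition_summary"]
            report.task_rt_anova = results.get("task_rt_anova")
            report.feature_rt_anova = results.get("feature_rt_anova")
        else:
            stage = "exp1-3-analysis"
            results = analyze_exp13(
                dataset,
                grid=config.grid,
                variants=config.variants,
                p_method=config.p_method,
                perm_seed=config.seed,
            )
            report.group_summary = results["group_summary"]
            report.correlations = results["correlations"]
            report.regressions = results["regressions"]
            report.agreement = results["agreement"]
            report.model_comparison = results["model_comparison"]
            report.participant_fits = results["participant_fits"]

        if out_dir is not None:
            stage = "write-outputs"
            out_dir.mkdir(parents=True, exist_ok=True)
            write_dataset(dataset, out_dir)
            written += [out_dir / f for f in ("trials.csv", "ratings.csv", "participants.csv")]
            report_path = out_dir / "report.json"
            report_path.write_text(report.to_json() + "\n")
            written.append(report_path)
            if report.group_summary is not None:
                p = out_dir / "group_summary.csv"
                report.group_summary.to_csv(p, lineterminator="\n")
                written.append(p)
            if report.condition_summary is not None:
                p = out_dir / "condition_summary.csv"
                report.condition_summary.to_csv(p, lineterminator="\n")
                written.append(p)
        return report
    except Exception as exc:
        for path in written:  # remove partial outputs
            try:
                path.unlink(missing_ok=True)
            except OSError:
                pass
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, str(exc)) from exc
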