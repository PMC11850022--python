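"""Descriptive and inferential statistics for the behavioral pipeline.

Covers rating aggregation and exclusion, dimensions-used binning, Spearman
rank correlation (t approximation or permutation p), standardized simple
regression, inter-rater agreement (unweighted Cohen's kappa, percent
identical, mean absolute difference), the one-way ANOVA / Tukey HSD /
Cohen's d suite, and the per-group summary table.

The statistics are computed from their closed forms (with scipy supplying
ranks and reference distributions) so they can be cross-checked against
independent library implementations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import INCOMPREHENSIBLE, Dataset, parse_feature_token


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given input (e.g. a
    constant vector in a correlation) instead of silently returning NaN."""


class InsufficientDataError(ValueError):
    """Raised when a procedure's minimal sample-size requirement is not met."""


EXCLUDED = "EXCLUDED"
BINS = ("LOW", "MID", "HIGH")


def aggregate_ratings(rater1, rater2):
    """Mean of the two raters' 1-5 judgements, or ``EXCLUDED`` if either
    marked the description incomprehensible."""
    if rater1 == INCOMPREHENSIBLE or rater2 == INCOMPREHENSIBLE:
        return EXCLUDED
    return (float(rater1) + float(rater2)) / 2.0


def bin_dims_used(x: float) -> str:
    """Group label for a dimensions-used value: x<2, 2<=x<4, 4<=x<=5."""
    if not 1.0 <= x <= 5.0:
        raise UndefinedStatisticError(f"dims-used must be in [1, 5], got {x}")
    if x < 2.0:
        return "LOW"
    if x < 4.0:
        return "MID"
    return "HIGH"


# ---------------------------------------------------------------------------
# correlation and regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    df: int
    p_value: float
    method: str

    def summary(self) -> str:
        return f"r({self.df}) = {self.rho:.2f}, p = {self.p_value:.4g}"


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt(float(x @ x) * float(y @ y))
    if denom == 0.0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    return float(x @ y) / denom


def _t_approx_p(rho: float, n: int) -> float:
    df = n - 2
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt(df / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df))


def spearman(
    xs,
    ys,
    p_method: str = "t_approx",
    n_perm: int = 9999,
    seed: int | None = None,
) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    ``p_method`` is ``"t_approx"`` (two-sided t approximation on n-2 df) or
    ``"permutation"`` (two-sided permutation of one variable, add-one rule;
    requires ``seed``).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need n >= 3, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _pearson(rx, ry)
    if p_method == "t_approx":
        p = _t_approx_p(rho, n)
        method = "t_approx"
    elif p_method == "permutation":
        if seed is None:
            raise ValueError("permutation p-values require a seed")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            try:
                r = _pearson(rx, rng.permutation(ry))
            except UndefinedStatisticError:  # pragma: no cover
                r = 0.0
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        method = f"permutation(n_perm={n_perm}, seed={seed})"
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return CorrelationResult(rho=rho, df=n - 2, p_value=p, method=method)


@dataclass(frozen=True)
class RegressionResult:
    beta: float
    t: float
    df: int
    p_value: float
    r_squared: float
    adj_r_squared: float

    def summary(self) -> str:
        return (
            f"beta = {self.beta:.2f}, t({self.df}) = {self.t:.2f}, "
            f"p = {self.p_value:.4g}, R2 = {self.r_squared:.2f}"
        )


def ols_standardized(x, y) -> RegressionResult:
    """Simple linear regression on z-scored variables.

    With one predictor the standardized slope equals the Pearson correlation,
    R^2 = beta^2, and t = beta * sqrt((n-2) / (1 - R^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need n >= 3, got {n}")
    beta = _pearson(x, y)
    r2 = beta * beta
    df = n - 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if r2 >= 1.0:
        t = math.inf if beta > 0 else -math.inf
        p = 0.0
    else:
        t = beta * math.sqrt(df / (1.0 - r2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return RegressionResult(
        beta=beta, t=t, df=df, p_value=p, r_squared=r2, adj_r_squared=adj
    )


# ---------------------------------------------------------------------------
# inter-rater agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    percent_identical: float
    mean_abs_diff: float | None  # None when no pair is fully numeric


def agreement(rater1, rater2) -> AgreementResult:
    """Unweighted Cohen's kappa over the observed categories (integer ratings
    and the incomprehensible token are distinct nominal categories), percent
    identical ratings, and the mean absolute difference over numeric pairs."""
    r1 = [str(v) for v in rater1]
    r2 = [str(v) for v in rater2]
    if len(r1) != len(r2) or len(r1) == 0:
        raise ValueError("rating lists must be equal-length and non-empty")
    n = len(r1)
    cats = sorted(set(r1) | set(r2))
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for a, b in zip(r1, r2):
        table[idx[a], idx[b]] += 1
    p_o = float(np.trace(table)) / n
    marg1 = table.sum(axis=1) / n
    marg2 = table.sum(axis=0) / n
    p_e = float(marg1 @ marg2)
    if p_e >= 1.0 - 1e-12:
        raise UndefinedStatisticError(
            "kappa undefined: both raters constant and identical"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    def _as_number(v):
        try:
            return float(v)
        except ValueError:
            return None

    numeric = [
        (x, y)
        for a, b in zip(r1, r2)
        if (x := _as_number(a)) is not None and (y := _as_number(b)) is not None
    ]
    mad = (
        float(np.mean([abs(a - b) for a, b in numeric])) if numeric else None
    )
    return AgreementResult(
        kappa=kappa, percent_identical=100.0 * p_o, mean_abs_diff=mad
    )


# ---------------------------------------------------------------------------
# one-way ANOVA + Tukey HSD + Cohen's d
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TukeyPair:
    group1: str
    group2: str
    mean_diff: float  # mean(group2) - mean(group1)
    p_adj: float
    reject: bool
    cohen_d: float


@dataclass(frozen=True)
class AnovaTukeyResult:
    f: float
    df1: int
    df2: int
    p_value: float
    eta_squared: float
    pairs: tuple[TukeyPair, ...]

    def summary(self) -> str:
        return (
            f"F({self.df1}, {self.df2}) = {self.f:.2f}, "
            f"p = {self.p_value:.4g}, eta2 = {self.eta_squared:.2f}"
        )


def anova_tukey(groups, alpha: float = 0.05, labels=None) -> AnovaTukeyResult:
    """One-way between-subjects ANOVA with Tukey(-Kramer) HSD post-hocs.

    ``groups`` is a sequence of k >= 2 samples (each of size >= 2).  The
    adjusted p-values come from the studentized-range distribution on
    ``N - k`` error df; Cohen's d uses the pairwise pooled SD.
    """
    samples = [np.asarray(grp, dtype=float) for grp in groups]
    k = len(samples)
    if k < 2:
        raise InsufficientDataError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise InsufficientDataError("every group needs at least 2 observations")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    ns = np.array([len(s) for s in samples])
    n_total = int(ns.sum())
    grand = float(np.concatenate(samples).mean())
    means = np.array([s.mean() for s in samples])
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((s - s.mean()) ** 2).sum() for s in samples))
    ss_total = ss_between + ss_within
    if ss_total == 0.0:
        raise UndefinedStatisticError("zero total variance: F undefined")
    df1 = k - 1
    df2 = n_total - k
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0.0:
        f = math.inf
        p = 0.0
    else:
        f = ms_between / ms_within
        p = float(sps.f.sf(f, df1, df2))
    eta_sq = ss_between / ss_total

    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[j] - means[i])
            se = math.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0.0:
                p_adj = 0.0 if diff != 0 else 1.0
            else:
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, k, df2))
            s_pool = math.sqrt(
                (
                    (ns[i] - 1) * samples[i].var(ddof=1)
                    + (ns[j] - 1) * samples[j].var(ddof=1)
                )
                / (ns[i] + ns[j] - 2)
            )
            d = diff / s_pool if s_pool > 0 else math.inf * np.sign(diff)
            pairs.append(
                TukeyPair(
                    group1=str(labels[i]),
                    group2=str(labels[j]),
                    mean_diff=diff,
                    p_adj=p_adj,
                    reject=bool(p_adj < alpha),
                    cohen_d=float(d),
                )
            )
    return AnovaTukeyResult(
        f=f, df1=df1, df2=df2, p_value=p, eta_squared=eta_sq, pairs=tuple(pairs)
    )


# ---------------------------------------------------------------------------
# per-participant metrics and the group summary table
# ---------------------------------------------------------------------------


def participant_metrics(dataset: Dataset) -> pd.DataFrame:
    """Per-participant behavioral metrics for a training/transfer cohort.

    Columns: mean_transfer_rt, dim_accuracy_pct (overall all-features %),
    dims_100 (count of dimensions with perfect all-features accuracy),
    mean_training_rt (classification trials), training_blocks.
    Participants missing a phase get NaN for that column, with a warning.
    """
    rows = []
    for pid, group in dataset.trials.groupby("participant_id", sort=True):
        row: dict = {"participant_id": pid}
        transfer = group[group["phase"] == "transfer"]
        af = group[group["phase"] == "all_features"]
        cls = group[group["phase"] == "training_cls"]
        if len(transfer):
            row["mean_transfer_rt"] = float(transfer["rt_seconds"].mean())
        else:
            warnings.warn(f"participant {pid} has no transfer trials")
            row["mean_transfer_rt"] = np.nan
        if len(af):
            row["dim_accuracy_pct"] = 100.0 * float(af["correct"].mean())
            per_dim_correct: dict[int, list[int]] = {}
            for token, correct in zip(af["stimulus"], af["correct"]):
                d, _v = parse_feature_token(str(token))
                per_dim_correct.setdefault(d, []).append(int(correct))
            row["dims_100"] = sum(
                1 for v in per_dim_correct.values() if all(v)
            )
        else:
            warnings.warn(f"participant {pid} has no all-features trials")
            row["dim_accuracy_pct"] = np.nan
            row["dims_100"] = np.nan
        if len(cls):
            row["mean_training_rt"] = float(cls["rt_seconds"].mean())
            row["training_blocks"] = int(cls["block"].max())
        else:
            warnings.warn(f"participant {pid} has no classification training trials")
            row["mean_training_rt"] = np.nan
            row["training_blocks"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")


SUMMARY_ROWS = (
    "n_participants",
    "mean_transfer_rt",
    "dim_accuracy_pct",
    "dims_100",
    "mean_training_rt",
    "training_blocks",
)


def group_summary(dataset: Dataset, dims_used: dict) -> pd.DataFrame:
    """Summary table binned by dimensions used (LOW / MID / HIGH / ID).

    ``dims_used`` maps participant_id to an aggregated rating in [1, 5] or
    ``EXCLUDED``.  Rows follow ``SUMMARY_ROWS``; the ID column summarizes the
    excluded participants.
    """
    metrics = participant_metrics(dataset)
    assignments: dict[str, str] = {}
    for pid in metrics.index:
        if pid not in dims_used:
            raise ValueError(f"no aggregated rating for participant {pid}")
        value = dims_used[pid]
        assignments[pid] = "ID" if value == EXCLUDED else bin_dims_used(float(value))
    columns = {}
    for label in (*BINS, "ID"):
        members = metrics.loc[[p for p, b in assignments.items() if b == label]]
        col = {"n_participants": float(len(members))}
        for metric in SUMMARY_ROWS[1:]:
            col[metric] = (
                float(members[metric].mean(skipna=True)) if len(members) else np.nan
            )
        columns[label] = col
    table = pd.DataFrame(columns).reindex(list(SUMMARY_ROWS))
    return table
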