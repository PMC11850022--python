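"""Bayesian step-function model of dimension use in transfer categorization.

The model predicts, trial by trial, the probability that a participant
categorizes a transfer stimulus as category A.  Its core assumption is a step
gate: a stimulus dimension is used for categorization if and only if it was
learned with accuracy at or above a latent threshold ``theta`` (accuracy being
the fraction correct on that dimension's single-feature probes in the
all-features test).  Used dimensions vote for the category their believed
feature-category mapping assigns to the presented feature value; the response
is the majority vote, softened by a lapse rate ``g`` that mixes in chance.

Inference is exact on a small (theta, g) grid with a uniform prior, giving a
deterministic posterior and a closed-form model evidence per participant.
Three variants embody different theoretical positions:

* ``GATED_FR`` -- every dimension with accuracy >= theta is used (a partially
  diagnostic dimension participates only once it is learned accurately),
* ``UNGATED`` -- all dimensions are used regardless of learned accuracy,
* ``CA_ONLY`` -- only the perfectly diagnostic dimension is used.

Model comparison sums per-participant log evidence and reports log Bayes
factors between variants.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .simulate import parse_feature_token
from .structures import FeatureVector, N_DIMS


class MissingDataError(ValueError):
    """A dimension has no all-features trials to measure accuracy from."""


class InsufficientDataError(ValueError):
    """Raised when a fit is requested with no usable trials."""


class InvalidVariantError(ValueError):
    """Raised when a variant is mis-specified (e.g. CA_ONLY without ca_index)."""


class ModelVariant(str, Enum):
    GATED_FR = "GATED_FR"
    UNGATED = "UNGATED"
    CA_ONLY = "CA_ONLY"


@dataclass(frozen=True)
class DimensionKnowledge:
    """Per-dimension learned accuracy and believed mapping, measured from the
    all-features test (accuracy = fraction correct; mapping = modal response
    direction, ambiguous on an exact split)."""

    accuracy: tuple[float, ...]
    mapping: tuple[str, ...]  # "correct" | "reversed" | "ambiguous"
    n_trials: tuple[int, ...]

    @property
    def n_dims(self) -> int:
        return len(self.accuracy)

    @property
    def fully_learned(self) -> tuple[bool, ...]:
        return tuple(a == 1.0 for a in self.accuracy)


def dimension_accuracy(all_features_trials: pd.DataFrame) -> DimensionKnowledge:
    """Measure per-dimension accuracy and modal mapping for one participant.

    ``all_features_trials`` holds that participant's all-features (or
    feature-training) test trials with ``stimulus`` tokens like ``d3v1`` and a
    0/1 ``correct`` column.
    """
    n_correct = np.zeros(N_DIMS, dtype=int)
    n_total = np.zeros(N_DIMS, dtype=int)
    for token, correct in zip(
        all_features_trials["stimulus"], all_features_trials["correct"]
    ):
        d, _v = parse_feature_token(str(token))
        if not 1 <= d <= N_DIMS:
            raise MissingDataError(f"feature token {token!r} outside 1..{N_DIMS}")
        n_total[d - 1] += 1
        n_correct[d - 1] += int(correct)
    missing = [d + 1 for d in range(N_DIMS) if n_total[d] == 0]
    if missing:
        raise MissingDataError(f"no all-features trials for dimension(s) {missing}")
    accuracy = tuple(float(c) / t for c, t in zip(n_correct, n_total))
    mapping = []
    for c, t in zip(n_correct, n_total):
        wrong = t - c
        if c > wrong:
            mapping.append("correct")
        elif c < wrong:
            mapping.append("reversed")
        else:
            mapping.append("ambiguous")
    return DimensionKnowledge(
        accuracy=accuracy, mapping=tuple(mapping), n_trials=tuple(int(t) for t in n_total)
    )


@dataclass(frozen=True)
class StepModelParams:
    theta: float
    g: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0 and 0.0 <= self.g <= 1.0):
            raise ValueError("theta and g must lie in [0, 1]")


def used_dimensions(
    knowledge: DimensionKnowledge,
    theta: float,
    variant: ModelVariant | str,
    ca_index: int | None = None,
) -> frozenset[int]:
    """The set of dimensions a variant deems eligible at threshold ``theta``.

    Equality at the step counts as used (``a_d >= theta``).
    """
    variant = ModelVariant(variant)
    if variant is ModelVariant.UNGATED:
        return frozenset(range(1, knowledge.n_dims + 1))
    if variant is ModelVariant.CA_ONLY:
        if ca_index is None:
            raise InvalidVariantError("CA_ONLY requires ca_index")
        return frozenset({ca_index})
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0,1], got {theta}")
    return frozenset(
        d
        for d in range(1, knowledge.n_dims + 1)
        if knowledge.accuracy[d - 1] >= theta - 1e-12
    )


def _core_prob_a(
    vec: FeatureVector, used: frozenset[int], knowledge: DimensionKnowledge
) -> float:
    """Majority-vote probability of responding A before the lapse mixture:
    1 if A-votes win, 0 if B-votes win, 0.5 on a tie or empty used set."""
    score = 0
    for d in used:
        m = knowledge.mapping[d - 1]
        if m == "ambiguous":
            continue
        bit = vec.values[d - 1]
        vote_a = (bit == 1) == (m == "correct")
        score += 1 if vote_a else -1
    if score > 0:
        return 1.0
    if score < 0:
        return 0.0
    return 0.5


def predict_response_prob(
    vec: FeatureVector,
    used: frozenset[int],
    knowledge: DimensionKnowledge,
    g: float,
) -> float:
    """P(respond A) = g/2 + (1 - g) * majority-vote core."""
    if not 0.0 <= g <= 1.0:
        raise ValueError(f"g must be in [0,1], got {g}")
    return g * 0.5 + (1.0 - g) * _core_prob_a(vec, used, knowledge)


NEG_INF = float("-inf")


def _extract_transfer(transfer_trials) -> tuple[list[FeatureVector], np.ndarray, np.ndarray]:
    """Collapse transfer trials to unique stimuli with A/B response counts."""
    if isinstance(transfer_trials, pd.DataFrame):
        pairs = list(zip(transfer_trials["stimulus"], transfer_trials["response"]))
    else:
        pairs = [(str(s), r) for s, r in transfer_trials]
    counts: dict[str, list[int]] = {}
    for stim, resp in pairs:
        if resp not in ("A", "B"):
            raise InsufficientDataError(f"non-binary response {resp!r}")
        c = counts.setdefault(str(stim), [0, 0])
        c[0 if resp == "A" else 1] += 1
    stims = [FeatureVector.from_string(s) for s in counts]
    n_a = np.array([counts[str(s)][0] for s in stims], dtype=float)
    n_b = np.array([counts[str(s)][1] for s in stims], dtype=float)
    return stims, n_a, n_b


def log_likelihood(
    transfer_trials,
    knowledge: DimensionKnowledge,
    params: StepModelParams,
    variant: ModelVariant | str = ModelVariant.GATED_FR,
    ca_index: int | None = None,
) -> float:
    """Bernoulli log likelihood of the observed A/B responses.

    Returns ``-inf`` (a sentinel, never an exception) when any observed
    response has predicted probability exactly zero.
    """
    stims, n_a, n_b = _extract_transfer(transfer_trials)
    used = used_dimensions(knowledge, params.theta, variant, ca_index)
    total = 0.0
    for vec, a, b in zip(stims, n_a, n_b):
        p = predict_response_prob(vec, used, knowledge, params.g)
        if a > 0:
            if p == 0.0:
                return NEG_INF
            total += a * math.log(p)
        if b > 0:
            if p == 1.0:
                return NEG_INF
            total += b * math.log(1.0 - p)
    return total


def default_theta_grid(n_probe_trials: int = 6) -> tuple[float, ...]:
    """Thresholds aligned to attainable accuracies (k / n_probe_trials)."""
    return tuple(k / n_probe_trials for k in range(n_probe_trials + 1))


@dataclass(frozen=True)
class GridSpec:
    """Finite grids for (theta, g) with a uniform prior over grid points."""

    theta: tuple[float, ...] = field(default_factory=default_theta_grid)
    g: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.linspace(0.0, 0.5, 21))
    )

    def __post_init__(self) -> None:
        if not self.theta or not self.g:
            raise ValueError("grids must be non-empty")
        if any(not 0 <= t <= 1 for t in self.theta) or any(
            not 0 <= g <= 1 for g in self.g
        ):
            raise ValueError("grid values must lie in [0, 1]")


@dataclass
class PosteriorSummary:
    """Grid posterior over (theta, g) for one participant under one variant."""

    variant: ModelVariant
    theta_grid: tuple[float, ...]
    g_grid: tuple[float, ...]
    weights: np.ndarray  # shape (n_theta, n_g), sums to 1
    log_evidence: float
    theta_mean: float
    theta_ci: tuple[float, float]
    g_mean: float
    g_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.value,
            "log_evidence": self.log_evidence,
            "theta_mean": self.theta_mean,
            "theta_ci": list(self.theta_ci),
            "g_mean": self.g_mean,
            "g_ci": list(self.g_ci),
        }


def _weighted_interval(
    values: np.ndarray, weights: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Central credible interval on a discrete grid (cumulative-weight rule)."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    lo = v[np.searchsorted(cum, lo_q, side="left")]
    hi = v[min(np.searchsorted(cum, hi_q, side="left"), len(v) - 1)]
    return float(lo), float(hi)


def _loglik_matrix(
    transfer_trials,
    knowledge: DimensionKnowledge,
    variant: ModelVariant,
    grid: GridSpec,
    ca_index: int | None,
) -> np.ndarray:
    """Log likelihood on the full (theta, g) grid, vectorized over g."""
    stims, n_a, n_b = _extract_transfer(transfer_trials)
    g = np.asarray(grid.g)  # (G,)
    ll = np.empty((len(grid.theta), len(g)))
    core_cache: dict[frozenset[int], np.ndarray] = {}
    for ti, theta in enumerate(grid.theta):
        used = used_dimensions(knowledge, theta, variant, ca_index)
        core = core_cache.get(used)
        if core is None:
            core = np.array(
                [_core_prob_a(vec, used, knowledge) for vec in stims]
            )
            core_cache[used] = core
        p = g[None, :] * 0.5 + (1.0 - g[None, :]) * core[:, None]  # (S, G)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_p = np.log(p)
            log_q = np.log(1.0 - p)
            # 0 * log(0) counts as 0: that response was never observed
            term_a = np.where(n_a[:, None] > 0, n_a[:, None] * log_p, 0.0)
            term_b = np.where(n_b[:, None] > 0, n_b[:, None] * log_q, 0.0)
        ll[ti] = (term_a + term_b).sum(axis=0)
    return ll


def fit_participant(
    transfer_trials,
    knowledge: DimensionKnowledge,
    variant: ModelVariant | str = ModelVariant.GATED_FR,
    grid: GridSpec | None = None,
    ca_index: int | None = None,
) -> PosteriorSummary:
    """Exact grid posterior and evidence for one participant.

    Evidence is the log of the prior-weighted mean likelihood over the grid
    (uniform prior), so variants that waste prior mass on poorly fitting
    regions pay an automatic Occam penalty.
    """
    variant = ModelVariant(variant)
    grid = grid or GridSpec()
    stims, n_a, n_b = _extract_transfer(transfer_trials)
    if len(stims) == 0:
        raise InsufficientDataError("no transfer trials to fit")
    ll = _loglik_matrix(transfer_trials, knowledge, variant, grid, ca_index)
    flat = ll.ravel()
    log_z = float(logsumexp(flat))  # may be -inf only if all points are -inf
    log_evidence = log_z - math.log(flat.size)
    if np.isneginf(log_z):
        weights = np.full(ll.shape, 1.0 / ll.size)
    else:
        weights = np.exp(ll - log_z)
    theta = np.asarray(grid.theta)
    g = np.asarray(grid.g)
    w_theta = weights.sum(axis=1)
    w_g = weights.sum(axis=0)
    return PosteriorSummary(
        variant=variant,
        theta_grid=tuple(grid.theta),
        g_grid=tuple(grid.g),
        weights=weights,
        log_evidence=log_evidence,
        theta_mean=float(np.dot(w_theta, theta)),
        theta_ci=_weighted_interval(theta, w_theta),
        g_mean=float(np.dot(w_g, g)),
        g_ci=_weighted_interval(g, w_g),
    )


@dataclass
class ParticipantFitInput:
    """One participant's inputs to model fitting/comparison."""

    participant_id: str
    transfer_trials: pd.DataFrame
    knowledge: DimensionKnowledge
    ca_index: int | None = None


@dataclass
class ModelComparison:
    """Summed log evidence per variant, pairwise log Bayes factors, winner."""

    totals: dict[str, float]
    bayes_factors: dict[str, float]
    winner: str
    tied: tuple[str, ...]
    per_participant: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "variant_totals": self.totals,
            "bayes_factors": self.bayes_factors,
            "winner": self.winner,
            "tied": list(self.tied),
        }


def compare_variants(
    participants: list[ParticipantFitInput],
    variants=(ModelVariant.GATED_FR, ModelVariant.UNGATED, ModelVariant.CA_ONLY),
    grid: GridSpec | None = None,
) -> ModelComparison:
    """Compare variants by total log evidence across participants."""
    if not variants:
        raise InvalidVariantError("no variants supplied")
    if not participants:
        raise InsufficientDataError("no participants supplied")
    variants = tuple(ModelVariant(v) for v in variants)
    grid = grid or GridSpec()
    totals = {v.value: 0.0 for v in variants}
    per_participant: dict[str, dict[str, float]] = {}
    for p in participants:
        row = {}
        for v in variants:
            summary = fit_participant(
                p.transfer_trials, p.knowledge, v, grid, ca_index=p.ca_index
            )
            row[v.value] = summary.log_evidence
            totals[v.value] += summary.log_evidence
        per_participant[p.participant_id] = row
    best = max(totals.values())
    winners = tuple(v for v, t in totals.items() if t == best)
    bayes_factors = {}
    for v1, v2 in itertools.combinations(totals, 2):
        bayes_factors[f"{v1}_vs_{v2}"] = totals[v1] - totals[v2]
    return ModelComparison(
        totals=totals,
        bayes_factors=bayes_factors,
        winner=winners[0],
        tied=winners if len(winners) > 1 else (),
        per_participant=per_participant,
    )


def fit_inputs_from_dataset(dataset) -> list[ParticipantFitInput]:
    """Extract per-participant transfer trials + measured knowledge from a
    simulated or loaded cohort dataset."""
    inputs = []
    ca_by_pid = {}
    if len(dataset.participants):
        for _, row in dataset.participants.iterrows():
            ca = row.get("ca_index", "")
            ca_by_pid[row["participant_id"]] = int(ca) if str(ca).strip() else None
    trials = dataset.trials
    for pid, group in trials.groupby("participant_id", sort=True):
        transfer = group[group["phase"] == "transfer"]
        af = group[group["phase"] == "all_features"]
        if len(transfer) == 0 or len(af) == 0:
            continue
        knowledge = dimension_accuracy(af)
        inputs.append(
            ParticipantFitInput(
                participant_id=str(pid),
                transfer_trials=transfer,
                knowledge=knowledge,
                ca_index=ca_by_pid.get(pid),
            )
        )
    return inputs
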