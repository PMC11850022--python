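"""Trial-level synthetic behavioral data for category-learning cohorts.

The generator emulates the structure of a supervised category-learning study:

* a training phase repeated to a 90%-twice learning criterion (with an
  observation-learning sub-block in some experiment variants),
* three transfer blocks of 10 stimuli whose criterial cue conflicts with the
  family-resemblance majority,
* three all-features-test blocks probing each of the 10 feature values,
* five control-task conditions (letter counting vs. association recall,
  multidimensional vs. unidimensional), and
* two independent raters judging how many dimensions each participant used.

Each simulated participant has a latent *believed mapping* per dimension
(correct / reversed / ambiguous), a *strategy set* of dimensions actually used
for categorization, and a response-time process model under one of two
theoretical modes:

* ``COMBINATION`` -- feature information is gathered and combined, so mean RT
  grows linearly with the number of dimensions used:
  ``rt_base + |U| * (t_fix + t_recall * needs_recall)``.
* ``DIFFERENTIATION`` -- the stimulus is first processed holistically, and
  *analytic* (not-fully-holistic) strategies pay a differentiation cost:
  ``rt_base + t_fix + t_recall * needs_recall + t_diff * 1[|U| < n_dims]``.

RTs are drawn multiplicatively lognormal around the process mean.  Everything
is deterministic given the seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structures import (
    DEFAULT_UNI_DIM,
    N_DIMS,
    FeatureVector,
    StimulusDesign,
    TaskKind,
    TaskSpec,
    build_design,
    correct_response,
    response_alphabet,
)

INCOMPREHENSIBLE = "ID"

TRIAL_COLUMNS = [
    "participant_id",
    "experiment",
    "condition",
    "phase",
    "block",
    "trial_index",
    "stimulus",
    "response",
    "correct",
    "rt_seconds",
]
RATING_COLUMNS = ["participant_id", "rater1", "rater2"]
PARTICIPANT_COLUMNS = [
    "participant_id",
    "experiment",
    "condition",
    "theory_mode",
    "ca_index",
    "true_dims_used",
    "converged",
    "n_training_blocks",
]


class ConfigError(ValueError):
    """Raised for invalid cohort or participant configuration."""


class ParseError(ValueError):
    """Raised when a dataset file violates the declared schema."""


def feature_token(dim: int, value: int) -> str:
    """Stimulus token for a single-feature trial, e.g. ``d3v1``."""
    return f"d{dim}v{value}"


def parse_feature_token(token: str) -> tuple[int, int]:
    if (
        len(token) >= 4
        and token[0] == "d"
        and "v" in token[1:]
    ):
        d_part, v_part = token[1:].split("v", 1)
        if d_part.isdigit() and v_part in ("0", "1"):
            return int(d_part), int(v_part)
    raise ParseError(f"not a feature token: {token!r}")


# ---------------------------------------------------------------------------
# participant-level parameters
# ---------------------------------------------------------------------------

_MAPPINGS = ("correct", "reversed", "ambiguous")


@dataclass
class ParticipantParams:
    """Generative parameters of one simulated participant.

    ``learn_prob[d-1]`` is the probability that dimension ``d``'s
    feature-to-category mapping is acquired correctly; otherwise it is reversed
    with probability ``rho_rev`` and ambiguous with the remainder.
    ``recall_fidelity[d-1]`` is the reliability of retrieving the mapping on an
    isolated feature probe: a correct mapping answers a probe correctly with
    that probability, a reversed one with its complement, an ambiguous one at
    chance.  ``strategy_dims`` fixes the used-dimension set explicitly; if it
    is ``None`` and ``gate_theta`` is set, the set is derived from the realized
    all-features accuracies via the step gate ``a_d >= gate_theta``; if both
    are ``None`` every dimension is used.
    """

    participant_id: str
    seed: int | np.random.SeedSequence
    theory_mode: str = "COMBINATION"
    strategy_dims: frozenset[int] | None = None
    gate_theta: float | None = None
    learn_prob: tuple[float, ...] = (0.8,) * N_DIMS
    rho_rev: float = 0.25
    recall_fidelity: tuple[float, ...] = (0.9,) * N_DIMS
    rt_base: float = 0.75
    t_fix: float = 0.3
    t_recall: float = 0.4
    t_diff: float = 1.0
    rt_sigma: float = 0.3
    lapse: float = 0.05
    max_training_blocks: int = 25
    n_dims: int = N_DIMS

    def __post_init__(self) -> None:
        problems = []
        if self.theory_mode not in ("COMBINATION", "DIFFERENTIATION"):
            problems.append(f"theory_mode={self.theory_mode!r}")
        if self.strategy_dims is not None:
            dims = frozenset(self.strategy_dims)
            self.strategy_dims = dims
            if not dims or not dims <= set(range(1, self.n_dims + 1)):
                problems.append(f"strategy_dims={sorted(dims)}")
        if len(self.learn_prob) != self.n_dims or not all(
            0.0 <= p <= 1.0 for p in self.learn_prob
        ):
            problems.append("learn_prob")
        if len(self.recall_fidelity) != self.n_dims or not all(
            0.0 <= q <= 1.0 for q in self.recall_fidelity
        ):
            problems.append("recall_fidelity")
        if not 0.0 <= self.rho_rev <= 1.0:
            problems.append("rho_rev")
        for name in ("rt_base", "rt_sigma"):
            if getattr(self, name) <= 0:
                problems.append(name)
        for name in ("t_fix", "t_recall", "t_diff"):
            if getattr(self, name) < 0:
                problems.append(name)
        if not 0.0 <= self.lapse <= 1.0:
            problems.append("lapse")
        if self.gate_theta is not None and not 0.0 <= self.gate_theta <= 1.0:
            problems.append("gate_theta")
        if self.max_training_blocks < 1:
            problems.append("max_training_blocks")
        if problems:
            raise ConfigError(f"invalid ParticipantParams fields: {', '.join(problems)}")


@dataclass
class ParticipantResult:
    """Trials plus the latent state realized for one participant."""

    params: ParticipantParams
    trials: list[dict]
    converged: bool
    n_training_blocks: int
    mapping: tuple[str, ...]
    probe_accuracy: tuple[float, ...]  # latent per-dimension probe reliability
    measured_accuracy: tuple[float, ...] | None  # a_d from the all-features test
    used_dims: frozenset[int]


def _rng_for(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _realize_knowledge(
    rng: np.random.Generator, params: ParticipantParams
) -> tuple[tuple[str, ...], tuple[float, ...]]:
    """Draw the believed mapping and probe reliability once per dimension."""
    mapping = []
    probe_q = []
    for d in range(params.n_dims):
        u = rng.random()
        if u < params.learn_prob[d]:
            m = "correct"
        elif rng.random() < params.rho_rev:
            m = "reversed"
        else:
            m = "ambiguous"
        mapping.append(m)
        fid = params.recall_fidelity[d]
        q = {"correct": fid, "reversed": 1.0 - fid, "ambiguous": 0.5}[m]
        probe_q.append(q)
    return tuple(mapping), tuple(probe_q)


def mean_rt(
    params: ParticipantParams, n_used: int, needs_recall: bool, single_feature: bool = False
) -> float:
    """Closed-form mean RT of the process model (before lognormal noise)."""
    recall = params.t_recall if needs_recall else 0.0
    if single_feature:
        return params.rt_base + params.t_fix + recall
    if params.theory_mode == "COMBINATION":
        return params.rt_base + n_used * (params.t_fix + recall)
    return (
        params.rt_base
        + params.t_fix
        + recall
        + params.t_diff * (1.0 if n_used < params.n_dims else 0.0)
    )


def _vote(vec: FeatureVector, used: frozenset[int], mapping: tuple[str, ...]) -> int:
    """Majority vote over used dimensions: +1 per A vote, -1 per B vote."""
    score = 0
    for d in used:
        m = mapping[d - 1]
        if m == "ambiguous":
            continue
        bit = vec.values[d - 1]
        vote_a = (bit == 1) == (m == "correct")
        score += 1 if vote_a else -1
    return score


def _categorize_block(
    rng: np.random.Generator,
    items: list[tuple[FeatureVector, str]],
    used: frozenset[int],
    mapping: tuple[str, ...],
    params: ParticipantParams,
    needs_recall: bool,
) -> list[tuple[FeatureVector, str, str, bool, float]]:
    """One block of whole-stimulus categorization: shuffled order, vote rule,
    lapse, lognormal RTs.  Returns (vec, truth, response, correct, rt) rows."""
    n = len(items)
    order = rng.permutation(n)
    u_lapse = rng.random(n)
    u_choice = rng.integers(0, 2, n)
    u_tie = rng.integers(0, 2, n)
    noise = rng.normal(0.0, params.rt_sigma, n)
    mu = mean_rt(params, len(used), needs_recall)
    rows = []
    for i in range(n):
        vec, truth = items[order[i]]
        if u_lapse[i] < params.lapse:
            resp = "A" if u_choice[i] == 0 else "B"
        else:
            score = _vote(vec, used, mapping)
            if score > 0:
                resp = "A"
            elif score < 0:
                resp = "B"
            else:
                resp = "A" if u_tie[i] == 0 else "B"
        rt = mu * math.exp(noise[i])
        rows.append((vec, truth, resp, resp == truth, rt))
    return rows


def _all_features_blocks(
    rng: np.random.Generator,
    params: ParticipantParams,
    probe_q: tuple[float, ...],
    n_blocks: int = 3,
) -> tuple[list[tuple[int, str, str, str, bool, float]], tuple[float, ...]]:
    """Simulate the all-features test: ``n_blocks`` shuffled passes over the
    10 feature values.  Returns rows (block, token, truth, response, correct,
    rt) and the measured per-dimension accuracy a_d."""
    features = [(d, v) for d in range(1, params.n_dims + 1) for v in (0, 1)]
    n = len(features)
    n_correct = [0] * params.n_dims
    n_trials = [0] * params.n_dims
    mu = mean_rt(params, 1, True, single_feature=True)
    rows = []
    for block in range(1, n_blocks + 1):
        order = rng.permutation(n)
        u_right = rng.random(n)
        noise = rng.normal(0.0, params.rt_sigma, n)
        for i in range(n):
            d, v = features[order[i]]
            truth = "A" if v == 1 else "B"
            right = bool(u_right[i] < probe_q[d - 1])
            resp = truth if right else ("B" if truth == "A" else "A")
            rt = mu * math.exp(noise[i])
            rows.append((block, feature_token(d, v), truth, resp, right, rt))
            n_trials[d - 1] += 1
            n_correct[d - 1] += right
    a = tuple(c / t for c, t in zip(n_correct, n_trials))
    return rows, a


def simulate_participant(
    params: ParticipantParams,
    design: StimulusDesign,
    experiment: str,
) -> ParticipantResult:
    """Simulate one participant through training, transfer and all-features.

    ``experiment`` is one of ``EXP1``/``EXP2`` (observation + classification
    training sub-blocks) or ``EXP3`` (classification only).  Training repeats
    until two classification blocks reach >=90% accuracy or
    ``max_training_blocks`` is hit (then the result carries
    ``converged=False`` rather than being dropped).
    """
    if experiment not in ("EXP1", "EXP2", "EXP3"):
        raise ConfigError(f"unknown experiment tag {experiment!r}")
    if design.experiment != "EXP1_3":
        raise ConfigError("simulate_participant needs a training/transfer design")
    rng = _rng_for(params.seed)
    mapping, probe_q = _realize_knowledge(rng, params)

    # The all-features probes are simulated up front because, under gated
    # strategy assignment, the used-dimension set depends on the measured a_d.
    af_rows, a_measured = _all_features_blocks(rng, params, probe_q)
    if params.strategy_dims is not None:
        used = frozenset(params.strategy_dims)
    elif params.gate_theta is not None:
        used = frozenset(
            d for d in range(1, params.n_dims + 1)
            if a_measured[d - 1] >= params.gate_theta - 1e-12
        )
    else:
        used = frozenset(range(1, params.n_dims + 1))

    trials: list[dict] = []
    pid = params.participant_id

    def emit(phase, block, idx, stimulus, response, correct, rt):
        trials.append(
            {
                "participant_id": pid,
                "experiment": experiment,
                "condition": "",
                "phase": phase,
                "block": block,
                "trial_index": idx,
                "stimulus": stimulus,
                "response": response,
                "correct": int(correct),
                "rt_seconds": rt,
            }
        )

    # -- training to criterion ------------------------------------------------
    items = list(design.training_items)
    with_observation = experiment in ("EXP1", "EXP2")
    blocks_at_criterion = 0
    block = 0
    while blocks_at_criterion < 2 and block < params.max_training_blocks:
        block += 1
        if with_observation:
            # observation sub-block: the label is shown; the keypress echoes it
            order = rng.permutation(len(items))
            noise = rng.normal(0.0, params.rt_sigma, len(items))
            for i in range(len(items)):
                vec, truth = items[order[i]]
                rt = params.rt_base * math.exp(noise[i])
                emit("training_obs", block, i + 1, str(vec), truth, True, rt)
        rows = _categorize_block(rng, items, used, mapping, params, needs_recall=True)
        n_right = 0
        for i, (vec, truth, resp, right, rt) in enumerate(rows):
            emit("training_cls", block, i + 1, str(vec), resp, right, rt)
            n_right += right
        if n_right / len(items) >= 0.9:
            blocks_at_criterion += 1
    converged = blocks_at_criterion >= 2

    # -- transfer -------------------------------------------------------------
    transfer = list(design.transfer_items)
    for t_block in range(1, 4):
        rows = _categorize_block(
            rng, transfer, used, mapping, params, needs_recall=True
        )
        for i, (vec, truth, resp, right, rt) in enumerate(rows):
            emit("transfer", t_block, i + 1, str(vec), resp, right, rt)

    # -- all-features test (simulated earlier, emitted in phase order) --------
    counters: dict[int, int] = {}
    for block_no, token, _truth, resp, right, rt in af_rows:
        counters[block_no] = counters.get(block_no, 0) + 1
        emit("all_features", block_no, counters[block_no], token, resp, right, rt)

    return ParticipantResult(
        params=params,
        trials=trials,
        converged=converged,
        n_training_blocks=block,
        mapping=mapping,
        probe_accuracy=probe_q,
        measured_accuracy=a_measured,
        used_dims=used,
    )


# ---------------------------------------------------------------------------
# control-task conditions (Exp4-style)
# ---------------------------------------------------------------------------

EXP4_CONDITIONS = ("ODD_EVEN_T", "ODD_EVEN_A", "FR", "UNI_T", "UNI_A")


def simulate_exp4_participant(
    params: ParticipantParams, condition: str
) -> ParticipantResult:
    """Simulate one participant in a control-task condition.

    Phases: 3 feature-training blocks (10 feature-test trials each in the
    multidimensional conditions, 2 in the unidimensional ones), one
    task-training block and one task-test block of 20 stimuli each.  The
    letter conditions read the answer off the stimulus (no association
    recall); the category conditions answer through the believed mapping.
    """
    if condition not in EXP4_CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}")
    task = TaskSpec(TaskKind(condition))
    design = build_design("EXP4")
    rng = _rng_for(params.seed)
    mapping, probe_q = _realize_knowledge(rng, params)
    letter_task = condition in ("ODD_EVEN_T", "UNI_T")
    multidim = condition in ("ODD_EVEN_T", "ODD_EVEN_A", "FR")
    used = (
        frozenset(range(1, params.n_dims + 1))
        if multidim
        else frozenset({task.uni_dim_index})
    )
    params = replace(params, strategy_dims=used)
    alphabet = response_alphabet(task)

    trials: list[dict] = []
    pid = params.participant_id

    def emit(phase, block, idx, stimulus, response, correct, rt):
        trials.append(
            {
                "participant_id": pid,
                "experiment": "EXP4",
                "condition": condition,
                "phase": phase,
                "block": block,
                "trial_index": idx,
                "stimulus": stimulus,
                "response": response,
                "correct": int(correct),
                "rt_seconds": rt,
            }
        )

    # -- feature training: 3 blocks of feature-test trials --------------------
    if multidim:
        features = [(d, v) for d in range(1, params.n_dims + 1) for v in (0, 1)]
    else:
        features = [(task.uni_dim_index, v) for v in (0, 1)]
    mu_feat = mean_rt(params, 1, task.needs_recall, single_feature=True)
    feat_alpha = ("T", "L") if letter_task else ("A", "B")
    for block in range(1, 4):
        order = rng.permutation(len(features))
        u_right = rng.random(len(features))
        noise = rng.normal(0.0, params.rt_sigma, len(features))
        for i in range(len(features)):
            d, v = features[order[i]]
            truth = feat_alpha[0] if v == 1 else feat_alpha[1]
            p_right = (1.0 - params.lapse) if letter_task else probe_q[d - 1]
            right = bool(u_right[i] < p_right)
            resp = truth if right else (feat_alpha[1] if truth == feat_alpha[0] else feat_alpha[0])
            rt = mu_feat * math.exp(noise[i])
            emit("feature_training", block, i + 1, feature_token(d, v), resp, right, rt)

    # -- task training and task test ------------------------------------------
    mu_task = mean_rt(params, len(used), task.needs_recall)
    for phase in ("task_training", "task_test"):
        order = rng.permutation(20)
        u_lapse = rng.random(20)
        u_choice = rng.integers(0, 2, 20)
        u_bits = rng.integers(0, 2, (20, params.n_dims))
        noise = rng.normal(0.0, params.rt_sigma, 20)
        for i in range(20):
            vec = design.exp4_items[order[i]]
            truth = correct_response(task, vec, design)
            if u_lapse[i] < params.lapse:
                resp = alphabet[u_choice[i]]
            else:
                if letter_task:
                    believed = vec.values
                else:
                    believed = tuple(
                        vec.values[d]
                        if mapping[d] == "correct"
                        else 1 - vec.values[d]
                        if mapping[d] == "reversed"
                        else int(u_bits[i, d])
                        for d in range(params.n_dims)
                    )
                resp = correct_response(task, FeatureVector(believed), design)
            rt = mu_task * math.exp(noise[i])
            emit(phase, 1, i + 1, str(vec), resp, resp == truth, rt)

    return ParticipantResult(
        params=params,
        trials=trials,
        converged=True,
        n_training_blocks=0,
        mapping=mapping,
        probe_accuracy=probe_q,
        measured_accuracy=None,
        used_dims=used,
    )


# ---------------------------------------------------------------------------
# raters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RaterModel:
    """Two independent noisy raters of a 1-5 dimensions-used judgement.

    Each rater independently returns the true value perturbed by +/-1 with
    probability ``p_error`` (split evenly, clipped to 1..5) or the
    incomprehensible token with probability ``p_incomprehensible``.
    """

    p_error: float = 0.2
    p_incomprehensible: float = 0.07

    def __post_init__(self) -> None:
        if not (
            0.0 <= self.p_error <= 1.0
            and 0.0 <= self.p_incomprehensible <= 1.0
            and self.p_error + self.p_incomprehensible <= 1.0
        ):
            raise ConfigError("rater probabilities must be in [0,1] and sum <= 1")


def simulate_ratings(
    true_dims_used: int, rater_model: RaterModel, rng: np.random.Generator
):
    """Draw the two raters' judgements for one participant."""
    if not 1 <= true_dims_used <= 5:
        raise ConfigError(f"true_dims_used must be in 1..5, got {true_dims_used}")
    out = []
    for _ in range(2):
        u = rng.random()
        if u < rater_model.p_incomprehensible:
            out.append(INCOMPREHENSIBLE)
            continue
        if u < rater_model.p_incomprehensible + rater_model.p_error:
            delta = 1 if rng.random() < 0.5 else -1
            out.append(int(np.clip(true_dims_used + delta, 1, 5)))
        else:
            out.append(true_dims_used)
    return tuple(out)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class LearningConfig:
    """Per-dimension learning parameters, split by strategy membership.

    Dimensions a participant actively uses are assumed well learned; the
    others are learned with mixed success (some reversed, some never
    acquired), mirroring the spread of all-features accuracies seen in this
    kind of study.
    """

    p_correct_strategy: float = 0.97
    p_correct_other: float = 0.55
    rho_rev: float = 0.25
    fidelity_strategy: tuple[float, float] = (0.9, 1.0)
    fidelity_other: tuple[float, float] = (0.7, 1.0)


@dataclass
class CohortConfig:
    """Everything needed to simulate a cohort deterministically.

    ``strategy_mode`` selects how the used-dimension set arises:
    ``"explicit"`` draws its size from ``strategy_mix`` (the set is the CA
    dimension plus random FR dimensions), ``"gated"`` derives it from realized
    all-features accuracy via the step gate at ``gate_theta``, and ``"all"``
    uses every dimension.  For ``experiment="EXP4"``, ``n_participants`` is
    per condition; ``condition=None`` simulates all five conditions.
    """

    n_participants: int
    experiment: str  # EXP1 | EXP2 | EXP3 | EXP4
    seed: int
    condition: str | None = None
    theory_mode: str = "COMBINATION"
    strategy_mode: str = "explicit"
    strategy_mix: dict[int, float] = field(
        default_factory=lambda: {1: 0.45, 2: 0.2, 3: 0.15, 4: 0.1, 5: 0.1}
    )
    gate_theta: float = 0.9
    learning: LearningConfig = field(default_factory=LearningConfig)
    # per-participant uniform ranges for the RT process parameters (seconds)
    rt_base_range: tuple[float, float] = (0.5, 1.0)
    t_fix_range: tuple[float, float] = (0.25, 0.35)
    t_recall_range: tuple[float, float] = (0.35, 0.45)
    t_diff_range: tuple[float, float] = (0.8, 1.2)
    rt_sigma: float = 0.3
    lapse_range: tuple[float, float] = (0.0, 0.1)
    rater: RaterModel = field(default_factory=RaterModel)
    max_training_blocks: int = 25

    def __post_init__(self) -> None:
        problems = []
        if self.n_participants < 1:
            problems.append("n_participants")
        if self.experiment not in ("EXP1", "EXP2", "EXP3", "EXP4"):
            problems.append("experiment")
        if self.condition is not None and self.condition not in EXP4_CONDITIONS:
            problems.append("condition")
        if self.theory_mode not in ("COMBINATION", "DIFFERENTIATION"):
            problems.append("theory_mode")
        if self.strategy_mode not in ("explicit", "gated", "all"):
            problems.append("strategy_mode")
        if self.strategy_mode == "explicit":
            if not self.strategy_mix or any(
                k not in range(1, N_DIMS + 1) or p < 0
                for k, p in self.strategy_mix.items()
            ):
                problems.append("strategy_mix")
            elif not math.isclose(sum(self.strategy_mix.values()), 1.0, abs_tol=1e-9):
                problems.append("strategy_mix (probabilities must sum to 1)")
        for name in (
            "rt_base_range",
            "t_fix_range",
            "t_recall_range",
            "t_diff_range",
            "lapse_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                problems.append(name)
        if self.rt_sigma <= 0:
            problems.append("rt_sigma")
        if problems:
            raise ConfigError(f"invalid CohortConfig fields: {', '.join(problems)}")


#: strategy mix used under DIFFERENTIATION defaults: the differentiation
#: literature predicts overall-similarity (all-dimension) strategies are modal.
DIFFERENTIATION_MIX = {1: 0.25, 2: 0.1, 3: 0.1, 4: 0.1, 5: 0.45}


def default_cohort_config(
    experiment: str,
    n_participants: int | None = None,
    seed: int = 0,
    theory_mode: str = "COMBINATION",
    condition: str | None = None,
    strategy_mode: str = "explicit",
    gate_theta: float = 0.9,
    **overrides,
) -> CohortConfig:
    """Study-condition defaults per experiment variant.

    EXP1/EXP3 use the base learning configuration; EXP2 (color cues covary
    with the FR features) elevates the learning probability of non-strategy
    dimensions; EXP4 uses well-learned features and the control-task RT scale.
    """
    if n_participants is None:
        n_participants = {"EXP1": 45, "EXP2": 45, "EXP3": 50, "EXP4": 50}[experiment]
    kwargs: dict = dict(
        n_participants=n_participants,
        experiment=experiment,
        seed=seed,
        condition=condition,
        theory_mode=theory_mode,
        strategy_mode=strategy_mode,
        gate_theta=gate_theta,
    )
    if strategy_mode == "gated":
        # no designated strategy set: uniform learning whose realized
        # accuracies span the threshold region (a step location is only
        # identifiable when accuracies fall on both sides of it), so the
        # gate itself decides which dimensions are used
        kwargs["learning"] = LearningConfig(
            p_correct_strategy=0.8,
            p_correct_other=0.8,
            fidelity_strategy=(0.75, 0.98),
            fidelity_other=(0.75, 0.98),
        )
    elif strategy_mode == "all":
        # use-all-dimensions behavior presumes a directional believed mapping
        # on every dimension (correct or reversed, never absent): rho_rev=1
        kwargs["learning"] = LearningConfig(
            p_correct_strategy=0.85,
            p_correct_other=0.85,
            rho_rev=1.0,
            fidelity_strategy=(0.85, 1.0),
            fidelity_other=(0.85, 1.0),
        )
    elif experiment == "EXP2":
        kwargs["learning"] = LearningConfig(p_correct_other=0.7)
    if theory_mode == "DIFFERENTIATION" and strategy_mode == "explicit":
        kwargs["strategy_mix"] = dict(DIFFERENTIATION_MIX)
    if experiment == "EXP4":
        kwargs.update(
            rt_base_range=(0.4, 0.6),
            t_fix_range=(0.4, 0.5),
            t_recall_range=(0.25, 0.35),
            lapse_range=(0.0, 0.04),
            learning=LearningConfig(
                p_correct_strategy=0.95,
                p_correct_other=0.95,
                fidelity_strategy=(0.92, 1.0),
                fidelity_other=(0.92, 1.0),
            ),
        )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@dataclass
class Dataset:
    """A simulated (or loaded) cohort: tidy trials, ratings and metadata."""

    trials: pd.DataFrame
    ratings: pd.DataFrame
    participants: pd.DataFrame

    def participant_trials(self, participant_id: str) -> pd.DataFrame:
        return self.trials[self.trials["participant_id"] == participant_id]


def _draw_participant_params(
    cfg: CohortConfig,
    rng: np.random.Generator,
    pid: str,
    ca_index: int,
    seed: np.random.SeedSequence,
) -> ParticipantParams:
    strategy_dims: frozenset[int] | None = None
    gate_theta: float | None = None
    if cfg.strategy_mode == "explicit":
        sizes = sorted(cfg.strategy_mix)
        probs = np.array([cfg.strategy_mix[k] for k in sizes], dtype=float)
        probs = probs / probs.sum()
        k = int(rng.choice(sizes, p=probs))
        fr_dims = [d for d in range(1, N_DIMS + 1) if d != ca_index]
        extra = rng.choice(fr_dims, size=k - 1, replace=False) if k > 1 else []
        strategy_dims = frozenset({ca_index, *map(int, extra)})
    elif cfg.strategy_mode == "gated":
        gate_theta = cfg.gate_theta

    lc = cfg.learning
    learn_prob = []
    fidelity = []
    for d in range(1, N_DIMS + 1):
        in_strategy = strategy_dims is not None and d in strategy_dims
        if in_strategy:
            learn_prob.append(lc.p_correct_strategy)
            fidelity.append(float(rng.uniform(*lc.fidelity_strategy)))
        else:
            learn_prob.append(lc.p_correct_other)
            fidelity.append(float(rng.uniform(*lc.fidelity_other)))

    return ParticipantParams(
        participant_id=pid,
        seed=seed,
        theory_mode=cfg.theory_mode,
        strategy_dims=strategy_dims,
        gate_theta=gate_theta,
        learn_prob=tuple(learn_prob),
        rho_rev=lc.rho_rev,
        recall_fidelity=tuple(fidelity),
        rt_base=float(rng.uniform(*cfg.rt_base_range)),
        t_fix=float(rng.uniform(*cfg.t_fix_range)),
        t_recall=float(rng.uniform(*cfg.t_recall_range)),
        t_diff=float(rng.uniform(*cfg.t_diff_range)),
        rt_sigma=cfg.rt_sigma,
        lapse=float(rng.uniform(*cfg.lapse_range)),
        max_training_blocks=cfg.max_training_blocks,
    )


def simulate_cohort(config: CohortConfig) -> Dataset:
    """Simulate a full cohort with per-participant seeds derived from the
    master seed.  For EXP1-3, the stimulus set (CA dimension) cycles across
    participants; for EXP4, ``n_participants`` are simulated per condition."""
    root = np.random.SeedSequence(config.seed)
    all_trials: list[dict] = []
    rating_rows = []
    participant_rows = []

    if config.experiment == "EXP4":
        conditions = (
            EXP4_CONDITIONS if config.condition is None else (config.condition,)
        )
        children = root.spawn(len(conditions) * config.n_participants)
        idx = 0
        for condition in conditions:
            for i in range(config.n_participants):
                child = children[idx]
                idx += 1
                param_rng = _rng_for(child)
                trial_seed, rating_seed = child.spawn(2)
                pid = f"P{idx:03d}"
                params = _draw_participant_params(config, param_rng, pid, DEFAULT_UNI_DIM, trial_seed)
                result = simulate_exp4_participant(params, condition)
                all_trials.extend(result.trials)
                true_k = max(1, min(5, len(result.used_dims)))
                r1, r2 = simulate_ratings(true_k, config.rater, _rng_for(rating_seed))
                rating_rows.append((pid, r1, r2))
                participant_rows.append(
                    (pid, "EXP4", condition, config.theory_mode, "",
                     len(result.used_dims), result.converged, result.n_training_blocks)
                )
    else:
        designs = {ca: build_design("EXP1_3", ca) for ca in range(1, N_DIMS + 1)}
        children = root.spawn(config.n_participants)
        for i in range(config.n_participants):
            child = children[i]
            param_rng = _rng_for(child)
            trial_seed, rating_seed = child.spawn(2)
            pid = f"P{i + 1:03d}"
            ca_index = (i % N_DIMS) + 1
            params = _draw_participant_params(config, param_rng, pid, ca_index, trial_seed)
            result = simulate_participant(params, designs[ca_index], config.experiment)
            all_trials.extend(result.trials)
            true_k = max(1, min(5, len(result.used_dims)))
            r1, r2 = simulate_ratings(true_k, config.rater, _rng_for(rating_seed))
            rating_rows.append((pid, r1, r2))
            participant_rows.append(
                (pid, config.experiment, "", config.theory_mode, ca_index,
                 len(result.used_dims), result.converged, result.n_training_blocks)
            )

    trials = pd.DataFrame(all_trials, columns=TRIAL_COLUMNS)
    ratings = pd.DataFrame(rating_rows, columns=RATING_COLUMNS)
    participants = pd.DataFrame(participant_rows, columns=PARTICIPANT_COLUMNS)
    return Dataset(trials=trials, ratings=ratings, participants=participants)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------


def write_dataset(dataset: Dataset, directory) -> None:
    """Write trials.csv / ratings.csv / participants.csv (RTs at 6 decimals)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trials = dataset.trials.copy()
    trials["rt_seconds"] = trials["rt_seconds"].map(lambda x: f"{x:.6f}")
    trials.to_csv(directory / "trials.csv", index=False, lineterminator="\n")
    dataset.ratings.to_csv(directory / "ratings.csv", index=False, lineterminator="\n")
    dataset.participants.to_csv(
        directory / "participants.csv", index=False, lineterminator="\n"
    )


def read_dataset(directory) -> Dataset:
    """Read a dataset directory, validating the tidy schema."""
    from pathlib import Path

    directory = Path(directory)
    trials_path = directory / "trials.csv"
    ratings_path = directory / "ratings.csv"
    if not trials_path.exists():
        raise ParseError(f"missing file: {trials_path}")
    if not ratings_path.exists():
        raise ParseError(f"missing file: {ratings_path}")
    trials = pd.read_csv(
        trials_path,
        dtype={
            "participant_id": str, "experiment": str, "condition": str,
            "phase": str, "stimulus": str, "response": str,
        },
        keep_default_na=False,
    )
    for col in TRIAL_COLUMNS:
        if col not in trials.columns:
            raise ParseError(f"trials.csv missing required column {col!r}")
    if len(trials):
        trials["block"] = trials["block"].astype(int)
        trials["trial_index"] = trials["trial_index"].astype(int)
        trials["correct"] = trials["correct"].astype(int)
        rts = pd.to_numeric(trials["rt_seconds"], errors="coerce")
        bad = rts.isna() | (rts <= 0)
        if bad.any():
            row = int(trials.index[bad][0])
            raise ParseError(f"trials.csv row {row}: invalid rt_seconds")
        trials["rt_seconds"] = rts
    ratings = pd.read_csv(ratings_path, dtype=str, keep_default_na=False)
    for col in RATING_COLUMNS:
        if col not in ratings.columns:
            raise ParseError(f"ratings.csv missing required column {col!r}")
    for col in ("rater1", "rater2"):
        for row, val in ratings[col].items():
            if val != INCOMPREHENSIBLE and val not in {"1", "2", "3", "4", "5"}:
                raise ParseError(f"ratings.csv row {int(row)}, column {col}: {val!r}")
    parts_path = directory / "participants.csv"
    if parts_path.exists():
        participants = pd.read_csv(parts_path, keep_default_na=False)
    else:
        participants = pd.DataFrame(columns=PARTICIPANT_COLUMNS)
    return Dataset(trials=trials, ratings=ratings, participants=participants)
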