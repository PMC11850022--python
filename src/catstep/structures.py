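"""Stimulus spaces, category assignments and correctness rules.

Stimuli are fish-like objects with five binary dimensions (mouth, top fin,
bottom fin, body, tail).  Each dimension takes one of two feature values; the
value coded ``1`` is the one typical of (more common in) category A.  One
dimension -- the criterion attribute (CA) -- is perfectly diagnostic of
category membership during training, the remaining four family-resemblance
(FR) dimensions are only partially diagnostic.  Transfer stimuli are training
stimuli with the CA feature flipped, pitting the single criterial cue against
the FR majority.

A separate 20-item stimulus set supports five control tasks (family
resemblance, odd/even counting and unidimensional tasks over either letters
embedded in the features or learned feature-category associations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class InvalidDesignError(ValueError):
    """Raised when a stimulus design is requested with inconsistent arguments."""


class InvalidIndexError(ValueError):
    """Raised when a dimension index falls outside ``1..n_dims``."""


class UnsupportedDesignError(ValueError):
    """Raised when a task rule is applied to a design it is not defined for."""


class InvalidTaskError(ValueError):
    """Raised when a task and a design (or stimulus) do not match."""


N_DIMS = 5
#: dimension order: mouth, top fin, bottom fin, body, tail (1-based indices)
DIMENSION_NAMES = ("mouth", "top_fin", "bottom_fin", "body", "tail")
#: the unidimensional tasks probe the top fin (median visual salience)
DEFAULT_UNI_DIM = 2


@dataclass(frozen=True)
class FeatureVector:
    """Ordered binary encoding of one stimulus.

    ``values[d-1] == 1`` means dimension ``d`` shows the feature value typical
    of category A (or, in the letter tasks, the feature containing a T).
    """

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("FeatureVector must have at least one dimension")
        if any(v not in (0, 1) for v in self.values):
            raise ValueError(f"feature values must be 0 or 1, got {self.values}")

    @property
    def n_dims(self) -> int:
        return len(self.values)

    @classmethod
    def from_string(cls, bits: str) -> "FeatureVector":
        """Parse a bitstring such as ``"11011"`` (dimension 1 leftmost)."""
        if not bits or any(c not in "01" for c in bits):
            raise ValueError(f"not a bitstring: {bits!r}")
        return cls(tuple(int(c) for c in bits))

    def __str__(self) -> str:
        return "".join(str(v) for v in self.values)

    def __getitem__(self, dim: int) -> int:
        """Feature value on 1-based dimension ``dim``."""
        if not 1 <= dim <= self.n_dims:
            raise InvalidIndexError(f"dimension {dim} outside 1..{self.n_dims}")
        return self.values[dim - 1]


class TaskKind(str, Enum):
    TRANSFER_CA = "TRANSFER_CA"
    FR = "FR"
    ODD_EVEN_A = "ODD_EVEN_A"
    ODD_EVEN_T = "ODD_EVEN_T"
    UNI_A = "UNI_A"
    UNI_T = "UNI_T"


#: tasks whose correct response depends on feature-category associations
#: learned during the experiment (as opposed to letters readable off the screen)
_RECALL_TASKS = frozenset(
    {TaskKind.TRANSFER_CA, TaskKind.FR, TaskKind.ODD_EVEN_A, TaskKind.UNI_A}
)


@dataclass(frozen=True)
class TaskSpec:
    """A task rule plus the extra indices it needs."""

    kind: TaskKind
    uni_dim_index: int | None = None

    def __post_init__(self) -> None:
        kind = TaskKind(self.kind)
        object.__setattr__(self, "kind", kind)
        is_uni = kind in (TaskKind.UNI_A, TaskKind.UNI_T)
        if is_uni and self.uni_dim_index is None:
            object.__setattr__(self, "uni_dim_index", DEFAULT_UNI_DIM)
        if not is_uni and self.uni_dim_index is not None:
            raise InvalidTaskError(f"uni_dim_index given for non-UNI task {kind}")

    @property
    def needs_recall(self) -> bool:
        return self.kind in _RECALL_TASKS


# The 20-item logical structure used by the five control tasks, row-major.
# Rows 1/3 carry the category-A family resemblance, rows 2/4 category B's.
EXP4_TABLE = (
    "11111", "10111", "11011", "11101", "11110",
    "00000", "01000", "00100", "00010", "00001",
    "01111", "00111", "01011", "01101", "01110",
    "10000", "11000", "10100", "10010", "10001",
)


@dataclass(frozen=True)
class StimulusDesign:
    """A full stimulus set: training items, transfer items or the 20-item set."""

    experiment: str  # "EXP1_3" or "EXP4"
    n_dims: int
    ca_index: int | None
    training_items: tuple[tuple[FeatureVector, str], ...] = ()
    transfer_items: tuple[tuple[FeatureVector, str], ...] = ()
    exp4_items: tuple[FeatureVector, ...] = ()

    def to_frame(self):
        """Serialize to a tidy table (item_id, phase_set, vector, category)."""
        import pandas as pd

        rows = []
        for i, (vec, cat) in enumerate(self.training_items):
            rows.append((f"train_{i:02d}", "training", str(vec), cat))
        for i, (vec, cat) in enumerate(self.transfer_items):
            rows.append((f"transfer_{i:02d}", "transfer", str(vec), cat))
        for i, vec in enumerate(self.exp4_items):
            rows.append((f"exp4_{i:02d}", "exp4", str(vec), fr_label(vec)))
        return pd.DataFrame(rows, columns=["item_id", "phase_set", "vector", "category"])


def flip_ca(vec: FeatureVector, ca_index: int) -> FeatureVector:
    """Invert the feature value on the CA dimension (an involution)."""
    if not 1 <= ca_index <= vec.n_dims:
        raise InvalidIndexError(f"ca_index {ca_index} outside 1..{vec.n_dims}")
    vals = list(vec.values)
    vals[ca_index - 1] = 1 - vals[ca_index - 1]
    return FeatureVector(tuple(vals))


def fr_label(vec: FeatureVector) -> str:
    """Family-resemblance category: A iff three or more A-typical features."""
    if vec.n_dims != N_DIMS:
        raise UnsupportedDesignError(
            f"the majority rule is defined for {N_DIMS} dimensions, got {vec.n_dims}"
        )
    return "A" if sum(vec.values) >= 3 else "B"


def parity_label(vec: FeatureVector) -> str:
    """ODD iff the number of 1-coded features is odd."""
    return "ODD" if sum(vec.values) % 2 == 1 else "EVEN"


def build_design(experiment: str, ca_index: int | None = None) -> StimulusDesign:
    """Construct a stimulus design.

    ``EXP1_3`` builds the training/transfer family-resemblance structure with
    the perfectly diagnostic dimension at ``ca_index``: category A consists of
    the all-ones prototype plus the four vectors with exactly one FR dimension
    flipped (CA fixed at 1); category B items are the bitwise complements; each
    transfer item is a training item with the CA bit flipped, labelled with the
    category its CA value implies.  ``EXP4`` builds the 20-item control set.
    """
    if experiment == "EXP1_3":
        if ca_index is None or not 1 <= ca_index <= N_DIMS:
            raise InvalidDesignError(f"ca_index must be in 1..{N_DIMS}, got {ca_index}")
        fr_dims = [d for d in range(1, N_DIMS + 1) if d != ca_index]
        a_items = [FeatureVector((1,) * N_DIMS)]
        for d in fr_dims:
            vals = [1] * N_DIMS
            vals[d - 1] = 0
            a_items.append(FeatureVector(tuple(vals)))
        b_items = [FeatureVector(tuple(1 - v for v in vec.values)) for vec in a_items]
        training = tuple([(v, "A") for v in a_items] + [(v, "B") for v in b_items])
        transfer = []
        for vec, _cat in training:
            flipped = flip_ca(vec, ca_index)
            implied = "A" if flipped[ca_index] == 1 else "B"
            transfer.append((flipped, implied))
        return StimulusDesign(
            experiment="EXP1_3",
            n_dims=N_DIMS,
            ca_index=ca_index,
            training_items=training,
            transfer_items=tuple(transfer),
        )
    if experiment == "EXP4":
        if ca_index is not None:
            raise InvalidDesignError("the EXP4 design has no CA dimension")
        items = tuple(FeatureVector.from_string(s) for s in EXP4_TABLE)
        return StimulusDesign(
            experiment="EXP4", n_dims=N_DIMS, ca_index=None, exp4_items=items
        )
    raise InvalidDesignError(f"unknown experiment {experiment!r}")


def correct_response(
    task: TaskSpec, vec: FeatureVector, design: StimulusDesign | None = None
) -> str:
    """The correct response label for ``vec`` under ``task``.

    Training/transfer categorization follows the CA bit; FR the >=3 majority;
    the odd/even tasks the parity of the 1-count; the unidimensional tasks the
    bit on the probed dimension (category label or letter identity).
    """
    kind = task.kind
    if kind is TaskKind.TRANSFER_CA:
        if design is None or design.ca_index is None:
            raise InvalidTaskError("TRANSFER_CA requires a design with a CA dimension")
        return "A" if vec[design.ca_index] == 1 else "B"
    if kind is TaskKind.FR:
        return fr_label(vec)
    if kind in (TaskKind.ODD_EVEN_A, TaskKind.ODD_EVEN_T):
        return parity_label(vec)
    if kind is TaskKind.UNI_A:
        return "A" if vec[task.uni_dim_index] == 1 else "B"
    if kind is TaskKind.UNI_T:
        return "T" if vec[task.uni_dim_index] == 1 else "L"
    raise InvalidTaskError(f"unknown task kind {kind}")  # pragma: no cover


def response_alphabet(task: TaskSpec) -> tuple[str, str]:
    """The two possible responses for a task."""
    if task.kind in (TaskKind.ODD_EVEN_A, TaskKind.ODD_EVEN_T):
        return ("ODD", "EVEN")
    if task.kind is TaskKind.UNI_T:
        return ("T", "L")
    return ("A", "B")
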