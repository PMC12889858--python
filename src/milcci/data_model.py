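"""Core domain types for label-conditioned multi-trial decompositions.

A dataset is a collection of trials, each an ``N x T(m)`` channels-by-time
matrix carrying a *label*: one option per metadata category (e.g. task
difficulty, choice).  The model expresses each trial as a product of a
per-trial *loading matrix* -- assembled from label-selected component
variants -- and a per-trial *trace matrix* of temporal activations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CategorySpec",
    "TrialObservations",
    "ComponentTensor",
    "TraceMatrix",
    "LoadingMatrix",
    "ModelConfig",
    "InvalidLabelError",
    "assign_trace_rows",
    "total_components",
    "construct_loading",
    "reconstruct_trial",
    "residual_for_category",
    "validate_dataset",
]


class InvalidLabelError(ValueError):
    """A trial label references an option unknown to its category."""


@dataclass
class CategorySpec:
    """One metadata category: its ordered options and component budget.

    Parameters
    ----------
    name : str
        Category identifier (e.g. ``"difficulty"``).
    options : sequence
        Ordered option identifiers; an option's position defines the slice
        index of its component variant (first option -> slice 0).
    p : int
        Number of components allotted to this category.
    ordinal_values : sequence of float, optional
        Numeric positions of the options on an ordinal axis.  Present iff
        the category is ordinal.
    trace_rows : range, optional
        Contiguous global trace-row indices owned by this category.
        Normally assigned by :func:`assign_trace_rows`.
    """

    name: str
    options: Sequence
    p: int
    ordinal_values: Sequence[float] | None = None
    trace_rows: range | None = None

    def __post_init__(self) -> None:
        self.options = list(self.options)
        if len(self.options) < 1:
            raise ValueError(f"category {self.name!r} needs at least one option")
        if len(set(self.options)) != len(self.options):
            raise ValueError(f"category {self.name!r} has duplicate options")
        if self.p < 1:
            raise ValueError(f"category {self.name!r} needs p >= 1, got {self.p}")
        if self.ordinal_values is not None:
            self.ordinal_values = [float(v) for v in self.ordinal_values]
            if len(self.ordinal_values) != len(self.options):
                raise ValueError(
                    f"category {self.name!r}: ordinal_values length "
                    f"{len(self.ordinal_values)} != {len(self.options)} options"
                )

    @property
    def n_options(self) -> int:
        return len(self.options)

    @property
    def is_ordinal(self) -> bool:
        return self.ordinal_values is not None

    def option_index(self, option) -> int:
        """Map an option identifier to its variant slice index (0-based)."""
        try:
            return self.options.index(option)
        except ValueError:
            raise InvalidLabelError(
                f"option {option!r} is not an option of category {self.name!r} "
                f"(options: {self.options})"
            ) from None


def assign_trace_rows(specs: Sequence[CategorySpec]) -> list[CategorySpec]:
    """Assign contiguous trace-row blocks in declaration order.

    Category ``k`` owns rows ``[offset, offset + p(k))`` where ``offset`` is
    the cumulative budget of earlier categories; the blocks partition
    ``0..P-1`` with ``P = sum(p)``.
    """
    out = []
    offset = 0
    for spec in specs:
        out.append(dataclasses.replace(spec, trace_rows=range(offset, offset + spec.p)))
        offset += spec.p
    return out


def total_components(specs: Sequence[CategorySpec]) -> int:
    """``P``, the summed component budget over categories."""
    return int(sum(s.p for s in specs))


@dataclass
class TrialObservations:
    """One trial: an ``N x T`` real matrix plus its label tuple."""

    trial_id: int
    values: np.ndarray
    label: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"trial {self.trial_id}: values must be 2-D")
        if self.values.shape[1] < 2:
            raise ValueError(f"trial {self.trial_id}: needs at least 2 time steps")
        self.label = tuple(self.label)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


@dataclass
class ComponentTensor:
    """Per-category stack of label-option component variants.

    ``values[n, j, i]`` is channel ``n``'s membership in component ``j``
    under the category's ``i``-th option.
    """

    category: CategorySpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.values.shape[0], self.category.p, self.category.n_options)
        if self.values.shape != expected:
            raise ValueError(
                f"component tensor for {self.category.name!r}: shape "
                f"{self.values.shape} != (N, p, n_options) = {expected}"
            )

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def slice_for_option(self, option) -> np.ndarray:
        """The ``N x p`` variant selected by a label option."""
        return self.values[:, :, self.category.option_index(option)]


@dataclass
class TraceMatrix:
    """Per-trial temporal activations, one row per global component."""

    trial_id: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trace values must be 2-D (P x T)")


@dataclass
class LoadingMatrix:
    """Per-trial ``N x P`` loading with per-column provenance.

    ``provenance[c]`` records ``(category name, component index, slice
    index)`` for column ``c``.
    """

    values: np.ndarray
    provenance: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class ModelConfig:
    """Hyperparameters and run controls for model fitting.

    gamma1 weights component sparsity (L1), gamma2 the graph-coupled
    attraction between same-category variants, gamma3 temporal smoothness of
    traces (squared first differences), gamma4 the within-trial trace
    decorrelation penalty.
    """

    gamma1: float = 0.1
    gamma2: float = 0.1
    gamma3: float = 0.1
    gamma4: float = 0.01
    nonneg: bool = False
    norm_constant: float = 1.0
    max_outer_iters: int = 50
    tol: float = 1e-4
    seed: int = 0
    mask_missing: bool = False
    n_inner_trace: int = 5
    check_descent: bool = False

    def __post_init__(self) -> None:
        for name in ("gamma1", "gamma2", "gamma3", "gamma4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.norm_constant <= 0:
            raise ValueError("norm_constant must be positive")
        if self.max_outer_iters < 1:
            raise ValueError("max_outer_iters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def construct_loading(
    tensors: Sequence[ComponentTensor],
    label: tuple,
    category_order: Sequence[str] | None = None,
) -> LoadingMatrix:
    """Assemble a trial's loading matrix from its label.

    Selects, for each category in order, the variant slice indexed by the
    trial's option for that category, and concatenates the slices
    horizontally.  Pure lookup: equal labels yield identical loadings.
    """
    if category_order is not None:
        by_name = {t.category.name: t for t in tensors}
        tensors = [by_name[name] for name in category_order]
    if len(label) != len(tensors):
        raise InvalidLabelError(
            f"label has {len(label)} entries for {len(tensors)} categories"
        )
    n_set = {t.n_channels for t in tensors}
    if len(n_set) > 1:
        raise ValueError(f"component tensors disagree on N: {sorted(n_set)}")
    blocks = []
    provenance = []
    for tensor, option in zip(tensors, label):
        idx = tensor.category.option_index(option)
        blocks.append(tensor.values[:, :, idx])
        provenance.extend(
            (tensor.category.name, j, idx) for j in range(tensor.category.p)
        )
    return LoadingMatrix(values=np.concatenate(blocks, axis=1), provenance=provenance)


def reconstruct_trial(loading: LoadingMatrix, trace: TraceMatrix) -> np.ndarray:
    """Noiseless model prediction ``loading @ trace`` for one trial."""
    if loading.values.shape[1] != trace.values.shape[0]:
        raise ValueError(
            f"loading has {loading.values.shape[1]} columns but trace has "
            f"{trace.values.shape[0]} rows"
        )
    return loading.values @ trace.values


def residual_for_category(
    trial: TrialObservations,
    tensors: Sequence[ComponentTensor],
    trace: TraceMatrix,
    k: CategorySpec,
) -> np.ndarray:
    """Residual of a trial after removing every category except ``k``.

    Returns ``Y - sum_{k' != k} A_slice(k') Phi_G(k')``; this is the signal
    that category ``k``'s variant update must explain.  Missing cells (NaN)
    propagate unchanged so downstream fidelity terms can exclude them.
    """
    if trace is None:
        raise RuntimeError(f"no trace available for trial {trial.trial_id}")
    residual = trial.values.copy()
    for tensor, option in zip(tensors, trial.label):
        if tensor.category.name == k.name:
            continue
        rows = tensor.category.trace_rows
        if rows is None:
            raise RuntimeError(
                f"category {tensor.category.name!r} has no trace_rows; "
                "call assign_trace_rows first"
            )
        residual -= tensor.slice_for_option(option) @ trace.values[rows.start : rows.stop]
    return residual


def validate_dataset(
    trials: Sequence[TrialObservations],
    specs: Sequence[CategorySpec],
    allow_nan: bool = False,
) -> None:
    """Check shared N, label validity and finiteness across a dataset."""
    if not trials:
        raise ValueError("dataset is empty")
    n = trials[0].n_channels
    for trial in trials:
        if trial.n_channels != n:
            raise ValueError(
                f"trial {trial.trial_id} has {trial.n_channels} channels, "
                f"expected {n} (channel identities are fixed across trials)"
            )
        if len(trial.label) != len(specs):
            raise InvalidLabelError(
                f"trial {trial.trial_id}: label {trial.label} has "
                f"{len(trial.label)} entries for {len(specs)} categories"
            )
        for spec, option in zip(specs, trial.label):
            spec.option_index(option)
        finite = np.isfinite(trial.values)
        if not finite.all():
            if not allow_nan or np.isinf(trial.values[~finite]).any():
                raise ValueError(
                    f"trial {trial.trial_id} contains non-finite values "
                    "(enable mask_missing to treat NaN as missing)"
                )
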