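"""Alternating optimization for label-conditioned sparse decomposition.

The fit alternates two convex-ish blocks until the total objective
stabilizes:

* **Component variants** -- for every (category, option) pair, the variant
  slice is the minimizer of a least-squares fidelity over all trials
  carrying that option, plus an L1 sparsity penalty (``gamma1``) and a
  graph-weighted quadratic attraction toward the category's other variants
  (``gamma2``).  The problem separates across channels and is solved by
  cyclic coordinate descent with soft-thresholding (one-sided when the
  non-negativity constraint is on).

* **Traces** -- per trial, the temporal activations minimize fidelity plus
  a squared-first-difference smoothness penalty (``gamma3``) and a
  normalized cross-trace decorrelation penalty (``gamma4``).  The
  decorrelation term is non-convex; it is handled by iterated quadratic
  surrogates that freeze the trace norms and Gram signs from the previous
  inner iterate, each surrogate being solved exactly through a banded
  linear system.

After every component sweep each non-zero component column is rescaled to
a fixed absolute sum, with the matching trace rows counter-scaled so
reconstructions are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded

from .data_model import (
    CategorySpec,
    ComponentTensor,
    LoadingMatrix,
    ModelConfig,
    TraceMatrix,
    TrialObservations,
    assign_trace_rows,
    construct_loading,
    residual_for_category,
    total_components,
    validate_dataset,
)
from .label_graphs import LabelGraph, build_label_graph

__all__ = [
    "FitResult",
    "initialize",
    "update_component_variant",
    "update_all_components",
    "update_trace",
    "normalize_components",
    "fit",
    "component_subproblem_objective",
    "trace_objective",
    "total_objective",
]

_ZERO_DIAG_EPS = 1e-14
_CD_TOL = 1e-13
_CD_MAX_ITER = 20000


@dataclass
class FitResult:
    """Outcome of the alternating fit."""

    tensors: list[ComponentTensor]
    traces: list[TraceMatrix]
    objective_history: list[float]
    converged: bool
    n_iters: int
    specs: list[CategorySpec] = field(default_factory=list)


# ---------------------------------------------------------------------------
# initialization


def initialize(
    trials: Sequence[TrialObservations],
    specs: Sequence[CategorySpec],
    config: ModelConfig,
) -> tuple[list[ComponentTensor], list[TraceMatrix]]:
    """Spectral initialization of component tensors and traces.

    The leading eigenvectors of the channel covariance accumulated over all
    trials seed the components: category ``k`` takes the block of ``p(k)``
    eigenvectors following those claimed by earlier categories, so
    categories start from orthogonal subspaces rather than duplicating the
    top modes.  Slices within a category start identical; the label-graph
    coupling differentiates them during fitting.  Traces are then the
    (ridge-stabilized) least-squares solution against the initial loadings.
    Fully deterministic: eigendecomposition plus a fixed sign convention.
    """
    validate_dataset(trials, specs, allow_nan=config.mask_missing)
    specs = assign_trace_rows(specs)
    n = trials[0].n_channels
    p_total = total_components(specs)

    gram = np.zeros((n, n))
    for trial in trials:
        y = trial.values
        if config.mask_missing:
            y = np.nan_to_num(y, nan=0.0)
        gram += y @ y.T
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    eigvecs = eigvecs[:, order]

    if p_total > n:
        warnings.warn(
            f"P={p_total} exceeds N={n}; trailing components initialized to zero"
        )
        eigvecs = np.concatenate(
            [eigvecs, np.zeros((n, p_total - n))], axis=1
        )

    # sign convention: dominant entry of each eigenvector positive
    for j in range(eigvecs.shape[1]):
        col = eigvecs[:, j]
        if col.any():
            peak = np.argmax(np.abs(col))
            if col[peak] < 0:
                eigvecs[:, j] = -col

    tensors = []
    for spec in specs:
        block = eigvecs[:, spec.trace_rows.start : spec.trace_rows.stop]
        if config.nonneg:
            block = np.abs(block)
        values = np.repeat(block[:, :, None], spec.n_options, axis=2)
        tensors.append(ComponentTensor(category=spec, values=values))

    traces = [
        _least_squares_trace(trial, construct_loading(tensors, trial.label), config)
        for trial in trials
    ]
    tensors, traces = normalize_components(tensors, traces, trials, config)
    return tensors, traces


def _least_squares_trace(
    trial: TrialObservations, loading: LoadingMatrix, config: ModelConfig
) -> TraceMatrix:
    a = loading.values
    ata = a.T @ a + 1e-8 * np.eye(a.shape[1])
    y = trial.values
    if config.mask_missing and np.isnan(y).any():
        phi = np.empty((a.shape[1], y.shape[1]))
        for t in range(y.shape[1]):
            obs = ~np.isnan(y[:, t])
            asub = a[obs]
            phi[:, t] = np.linalg.solve(
                asub.T @ asub + 1e-8 * np.eye(a.shape[1]), asub.T @ y[obs, t]
            )
    else:
        phi = np.linalg.solve(ata, a.T @ y)
    return TraceMatrix(trial_id=trial.trial_id, values=phi)


# ---------------------------------------------------------------------------
# component updates (graph-fused LASSO)


def component_subproblem_objective(
    slice_values: np.ndarray,
    gram: np.ndarray,
    linear: np.ndarray,
    gamma1: float,
    const: float = 0.0,
) -> float:
    """Quadratic-form value of one variant subproblem (constants optional).

    ``tr(A G A^T) - 2 tr(A linear^T) + gamma1 ||A||_1 + const``; with
    ``const`` set to the data/attraction constants this equals the full
    subproblem objective, without it differences are still exact.
    """
    a = slice_values
    return float(
        np.einsum("nj,jk,nk->", a, gram, a)
        - 2.0 * np.sum(a * linear)
        + gamma1 * np.abs(a).sum()
        + const
    )


def _coordinate_descent(
    a0: np.ndarray,
    gram: np.ndarray,
    linear: np.ndarray,
    gamma1: float,
    nonneg: bool,
) -> np.ndarray:
    """Cyclic coordinate descent for the row-separable fused LASSO.

    Each channel row solves ``min_a a G a^T - 2 a c^T + gamma1 ||a||_1``
    (optionally over the nonnegative orthant).  Coordinates are visited in
    fixed ascending order for bit-reproducibility.  Columns whose curvature
    is (numerically) zero are left at their incumbent value.
    """
    a = a0.copy()
    p = gram.shape[0]
    diag = np.diag(gram).copy()
    dead = diag <= _ZERO_DIAG_EPS
    scale = max(np.abs(a).max(initial=0.0), np.abs(linear).max(initial=0.0), 1.0)
    thresh = gamma1 / 2.0
    for _ in range(_CD_MAX_ITER):
        max_delta = 0.0
        for j in range(p):
            if dead[j]:
                continue
            r = linear[:, j] - a @ gram[:, j] + a[:, j] * diag[j]
            if nonneg:
                new = np.maximum(0.0, r - thresh) / diag[j]
            else:
                new = np.sign(r) * np.maximum(0.0, np.abs(r) - thresh) / diag[j]
            delta = np.abs(new - a[:, j]).max(initial=0.0)
            if delta > max_delta:
                max_delta = delta
            a[:, j] = new
        if max_delta <= _CD_TOL * scale:
            break
    return a


def _masked_coordinate_descent(
    a0: np.ndarray,
    grams: np.ndarray,
    linear: np.ndarray,
    gamma1: float,
    nonneg: bool,
) -> np.ndarray:
    """Coordinate descent with a per-channel Gram (missing-data path)."""
    a = a0.copy()
    n, p = a.shape
    diag = np.einsum("njj->nj", grams).copy()
    dead = diag <= _ZERO_DIAG_EPS
    scale = max(np.abs(a).max(initial=0.0), np.abs(linear).max(initial=0.0), 1.0)
    thresh = gamma1 / 2.0
    safe_diag = np.where(dead, 1.0, diag)
    for _ in range(_CD_MAX_ITER):
        max_delta = 0.0
        for j in range(p):
            r = linear[:, j] - np.einsum("nk,nk->n", a, grams[:, :, j]) + a[:, j] * diag[:, j]
            if nonneg:
                new = np.maximum(0.0, r - thresh) / safe_diag[:, j]
            else:
                new = np.sign(r) * np.maximum(0.0, np.abs(r) - thresh) / safe_diag[:, j]
            new = np.where(dead[:, j], a[:, j], new)
            delta = np.abs(new - a[:, j]).max(initial=0.0)
            if delta > max_delta:
                max_delta = delta
            a[:, j] = new
        if max_delta <= _CD_TOL * scale:
            break
    return a


def _variant_problem_terms(
    spec: CategorySpec,
    option_index: int,
    residuals: Sequence[np.ndarray],
    trace_blocks: Sequence[np.ndarray],
    tensor_values: np.ndarray,
    graph: LabelGraph,
    config: ModelConfig,
):
    """Accumulate the Gram and linear terms of one variant subproblem."""
    n = tensor_values.shape[0]
    p = spec.p
    masked = config.mask_missing and any(np.isnan(r).any() for r in residuals)

    lam = graph.weights[:, option_index]
    lam_total = float(lam.sum() - lam[option_index])
    attraction = np.zeros((n, p))
    for i_other in range(spec.n_options):
        if i_other == option_index or lam[i_other] == 0.0:
            continue
        attraction += lam[i_other] * tensor_values[:, :, i_other]

    if masked:
        grams = np.zeros((n, p, p))
        linear = np.zeros((n, p))
        for resid, phi in zip(residuals, trace_blocks):
            miss = np.isnan(resid)
            r0 = np.where(miss, 0.0, resid)
            linear += r0 @ phi.T
            base = phi @ phi.T
            grams += base[None, :, :]
            for nn in np.nonzero(miss.any(axis=1))[0]:
                phim = phi[:, miss[nn]]
                grams[nn] -= phim @ phim.T
        grams += config.gamma2 * lam_total * np.eye(p)[None, :, :]
        linear += config.gamma2 * attraction
        return grams, linear, masked
    gram = np.zeros((p, p))
    linear = np.zeros((n, p))
    for resid, phi in zip(residuals, trace_blocks):
        gram += phi @ phi.T
        linear += resid @ phi.T
    gram += config.gamma2 * lam_total * np.eye(p)
    linear += config.gamma2 * attraction
    return gram, linear, masked


def update_component_variant(
    spec: CategorySpec,
    option_index: int,
    residuals: Sequence[np.ndarray],
    trace_blocks: Sequence[np.ndarray],
    tensor_values: np.ndarray,
    graph: LabelGraph,
    config: ModelConfig,
) -> np.ndarray:
    """Solve one (category, option) variant subproblem.

    ``residuals`` and ``trace_blocks`` hold, for every trial carrying this
    option, the other-category residual and the category's trace rows.  An
    empty list is allowed (no trial carries the option): the fidelity term
    vanishes and the solution is the soft-thresholded graph-weighted
    average of the sibling variants.  Returns the new ``N x p`` slice; the
    incumbent is returned unchanged (with a warning) when the subproblem
    carries no curvature at all.
    """
    incumbent = tensor_values[:, :, option_index]
    gram, linear, masked = _variant_problem_terms(
        spec, option_index, residuals, trace_blocks, tensor_values, graph, config
    )
    if not residuals:
        warnings.warn(
            f"category {spec.name!r} option index {option_index}: no trials "
            "carry this option; variant driven by graph attraction only"
        )
    if masked:
        diag = np.einsum("njj->nj", gram)
        if np.all(diag <= _ZERO_DIAG_EPS):
            warnings.warn(
                f"category {spec.name!r} option {option_index}: all trace rows "
                "zero and no graph attraction; keeping incumbent variant"
            )
            return incumbent.copy()
        return _masked_coordinate_descent(
            incumbent, gram, linear, config.gamma1, config.nonneg
        )
    if np.all(np.diag(gram) <= _ZERO_DIAG_EPS):
        warnings.warn(
            f"category {spec.name!r} option {option_index}: all trace rows "
            "zero and no graph attraction; keeping incumbent variant"
        )
        return incumbent.copy()
    solution = _coordinate_descent(incumbent, gram, linear, config.gamma1, config.nonneg)
    if config.check_descent:
        before = component_subproblem_objective(incumbent, gram, linear, config.gamma1)
        after = component_subproblem_objective(solution, gram, linear, config.gamma1)
        if after > before + 1e-8 * max(1.0, abs(before)):
            raise AssertionError(
                f"component subproblem objective increased: {before} -> {after}"
            )
    return solution


def update_all_components(
    trials: Sequence[TrialObservations],
    tensors: list[ComponentTensor],
    traces: Sequence[TraceMatrix],
    graphs: Sequence[LabelGraph],
    config: ModelConfig,
) -> list[ComponentTensor]:
    """Gauss-Seidel sweep over every (category, option) variant.

    Residuals are recomputed before each variant update so neighbor
    attraction and cross-category explanations always use the most recent
    values.  Tensors are updated in place and returned.
    """
    trials_by_option: dict[tuple[str, int], list[int]] = {}
    for m, trial in enumerate(trials):
        for spec, option in zip((t.category for t in tensors), trial.label):
            key = (spec.name, spec.option_index(option))
            trials_by_option.setdefault(key, []).append(m)

    for tensor, graph in zip(tensors, graphs):
        spec = tensor.category
        rows = spec.trace_rows
        for i in range(spec.n_options):
            members = trials_by_option.get((spec.name, i), [])
            residuals = [
                residual_for_category(trials[m], tensors, traces[m], spec)
                for m in members
            ]
            blocks = [traces[m].values[rows.start : rows.stop] for m in members]
            new_slice = update_component_variant(
                spec, i, residuals, blocks, tensor.values, graph, config
            )
            tensor.values[:, :, i] = new_slice
    return tensors


# ---------------------------------------------------------------------------
# trace updates


def trace_objective(
    y: np.ndarray,
    loading: np.ndarray,
    phi: np.ndarray,
    gamma3: float,
    gamma4: float,
) -> float:
    """Per-trial trace objective: fidelity, smoothness, decorrelation.

    The decorrelation term sums ``|<phi_j, phi_j'>| / (||phi_j|| ||phi_j'||)``
    over distinct component pairs; rows with zero norm contribute nothing.
    Missing observations (NaN in ``y``) are excluded from fidelity.
    """
    resid = y - loading @ phi
    if np.isnan(resid).any():
        fidelity = float(np.nansum(resid**2))
    else:
        fidelity = float(np.sum(resid**2))
    smooth = float(gamma3 * np.sum(np.diff(phi, axis=1) ** 2))
    decor = 0.0
    if gamma4 > 0 and phi.shape[0] > 1:
        norms = np.linalg.norm(phi, axis=1)
        inv = np.where(norms > 0, 1.0 / np.where(norms > 0, norms, 1.0), 0.0)
        c = phi @ phi.T
        normalized = np.abs(c) * np.outer(inv, inv)
        decor = float(gamma4 * (normalized.sum() - np.trace(normalized)))
    return fidelity + smooth + decor


def _banded_system(
    ata: np.ndarray,
    w: np.ndarray | None,
    gamma3: float,
    gamma4: float,
    t_len: int,
    per_column_ata: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble the block-tridiagonal system in banded (LAPACK) storage."""
    p = ata.shape[-1]
    k = p * t_len
    ab = np.zeros((2 * p + 1, k))
    block = ata + (gamma4 * w if w is not None else 0.0)
    # diagonal blocks, entry (a, b): band row p + a - b, columns b::p
    for a in range(p):
        for b in range(p):
            if per_column_ata is not None:
                vals = per_column_ata[:, a, b].copy()
                if w is not None:
                    vals += gamma4 * w[a, b]
            else:
                vals = np.full(t_len, block[a, b])
            if a == b:
                smooth_diag = np.full(t_len, 2.0 * gamma3)
                smooth_diag[0] = gamma3
                smooth_diag[-1] = gamma3
                if t_len == 1:
                    smooth_diag[:] = 0.0
                vals = vals + smooth_diag
            ab[p + a - b, b::p] = vals
    if t_len > 1 and gamma3 > 0:
        ab[0, p:] = -gamma3  # super-diagonal blocks (-gamma3 I at offset p)
        ab[2 * p, : k - p] = -gamma3
    return ab


def update_trace(
    trial: TrialObservations,
    loading: LoadingMatrix,
    config: ModelConfig,
    init: TraceMatrix | None = None,
) -> TraceMatrix:
    """Update one trial's traces by iterated quadratic surrogates.

    With ``gamma4 = 0`` the problem is an exact quadratic solved in one
    banded linear solve.  Otherwise the decorrelation term is linearized by
    freezing row norms and Gram signs from the previous inner iterate; each
    frozen quadratic is solved exactly and a candidate is kept only if it
    does not increase its own surrogate, so the surrogate value is
    non-increasing across inner iterations.  As a final safeguard the true
    objective is compared against the incumbent and the better iterate is
    returned.
    """
    a = loading.values
    y = trial.values
    n, p = a.shape
    t_len = y.shape[1]
    masked = config.mask_missing and np.isnan(y).any()

    per_column_ata = None
    if masked:
        y0 = np.where(np.isnan(y), 0.0, y)
        aty = a.T @ y0
        per_column_ata = np.empty((t_len, p, p))
        base = a.T @ a
        miss_any = np.isnan(y).any(axis=0)
        per_column_ata[:] = base
        for t in np.nonzero(miss_any)[0]:
            obs = ~np.isnan(y[:, t])
            asub = a[obs]
            per_column_ata[t] = asub.T @ asub
        ata = base
    else:
        ata = a.T @ a
        aty = a.T @ y

    diag_ref = np.diag(ata)
    if np.any(diag_ref <= _ZERO_DIAG_EPS) and config.gamma3 == 0:
        warnings.warn(
            f"trial {trial.trial_id}: zero loading columns with gamma3=0; "
            "adding 1e-8 ridge jitter"
        )
        ata = ata + 1e-8 * np.eye(p)
        if per_column_ata is not None:
            per_column_ata = per_column_ata + 1e-8 * np.eye(p)[None]

    if init is not None:
        phi = init.values.copy()
    else:
        phi = np.zeros((p, t_len))

    rhs = aty.flatten(order="F")
    n_inner = config.n_inner_trace if (config.gamma4 > 0 and p > 1) else 1
    incumbent_true = trace_objective(y, a, phi, config.gamma3, config.gamma4)
    start_phi = phi.copy()

    for _ in range(n_inner):
        if config.gamma4 > 0 and p > 1:
            norms = np.linalg.norm(phi, axis=1)
            inv = np.where(norms > 0, 1.0 / np.where(norms > 0, norms, 1.0), 0.0)
            gram = phi @ phi.T
            w = np.sign(gram) * np.outer(inv, inv)
            np.fill_diagonal(w, 0.0)
        else:
            w = None
        ab = _banded_system(ata, w, config.gamma3, config.gamma4, t_len, per_column_ata)
        try:
            sol = solve_banded((p, p), ab, rhs)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"trial {trial.trial_id}: singular trace system; adding ridge"
            )
            ab[p, :] += 1e-8
            sol = solve_banded((p, p), ab, rhs)
        if not np.all(np.isfinite(sol)):
            warnings.warn(
                f"trial {trial.trial_id}: singular trace system; adding ridge"
            )
            ab[p, :] += 1e-8
            sol = solve_banded((p, p), ab, rhs)
        candidate = sol.reshape((p, t_len), order="F")
        if w is not None:
            # keep the candidate only if its own frozen surrogate decreased
            surr_old = _frozen_surrogate(y, a, phi, w, config)
            surr_new = _frozen_surrogate(y, a, candidate, w, config)
            if surr_new > surr_old + 1e-10 * max(1.0, abs(surr_old)):
                break
        prev = phi
        phi = candidate
        if np.abs(phi - prev).max(initial=0.0) <= 1e-12:
            break

    final_true = trace_objective(y, a, phi, config.gamma3, config.gamma4)
    if final_true > incumbent_true + 1e-10 * max(1.0, abs(incumbent_true)) and init is not None:
        phi = start_phi
        final_true = incumbent_true
    if config.check_descent and init is not None:
        if final_true > incumbent_true + 1e-8 * max(1.0, abs(incumbent_true)):
            raise AssertionError(
                f"trace objective increased: {incumbent_true} -> {final_true}"
            )
    return TraceMatrix(trial_id=trial.trial_id, values=phi)


def _frozen_surrogate(y, a, phi, w, config) -> float:
    resid = y - a @ phi
    if np.isnan(resid).any():
        fidelity = float(np.nansum(resid**2))
    else:
        fidelity = float(np.sum(resid**2))
    smooth = float(config.gamma3 * np.sum(np.diff(phi, axis=1) ** 2))
    decor = float(config.gamma4 * np.einsum("jt,jk,kt->", phi, w, phi))
    return fidelity + smooth + decor


# ---------------------------------------------------------------------------
# normalization


def normalize_components(
    tensors: list[ComponentTensor],
    traces: list[TraceMatrix],
    trials: Sequence[TrialObservations],
    config: ModelConfig,
) -> tuple[list[ComponentTensor], list[TraceMatrix]]:
    """Rescale component columns to a fixed absolute sum.

    Every non-zero column of every variant slice is rescaled so its entries'
    absolute values sum to ``norm_constant``; the matching trace row of each
    trial that selects that slice is multiplied by the inverse factor, so
    all reconstructions are preserved to floating point.  All-zero columns
    are left untouched.
    """
    option_of = [
        {
            tensor.category.name: tensor.category.option_index(opt)
            for tensor, opt in zip(tensors, trial.label)
        }
        for trial in trials
    ]
    for tensor in tensors:
        spec = tensor.category
        rows = spec.trace_rows
        sums = np.abs(tensor.values).sum(axis=0)  # p x n_options
        factors = np.where(sums > 0, config.norm_constant / np.where(sums > 0, sums, 1.0), 1.0)
        tensor.values *= factors[None, :, :]
        inverse = 1.0 / factors  # multiply trace rows by sums / norm_constant
        for m, trace in enumerate(traces):
            i = option_of[m][spec.name]
            trace.values[rows.start : rows.stop] *= inverse[:, i][:, None]
    return tensors, traces


# ---------------------------------------------------------------------------
# total objective and outer loop


def total_objective(
    trials: Sequence[TrialObservations],
    tensors: Sequence[ComponentTensor],
    traces: Sequence[TraceMatrix],
    graphs: Sequence[LabelGraph],
    config: ModelConfig,
) -> float:
    """Global objective: fidelity plus every penalty term.

    The variant-coupling penalty sums over unordered option pairs, so each
    per-variant subproblem is exactly the global objective restricted to
    that slice (holding the rest fixed).
    """
    obj = 0.0
    for trial, trace in zip(trials, traces):
        loading = construct_loading(tensors, trial.label)
        obj += trace_objective(
            trial.values, loading.values, trace.values, config.gamma3, config.gamma4
        )
    for tensor, graph in zip(tensors, graphs):
        obj += config.gamma1 * np.abs(tensor.values).sum()
        k = tensor.category.n_options
        for i in range(k):
            for i2 in range(i + 1, k):
                lam = graph.weights[i, i2]
                if lam > 0:
                    diff = tensor.values[:, :, i] - tensor.values[:, :, i2]
                    obj += config.gamma2 * lam * float(np.sum(diff**2))
    return float(obj)


def fit(
    trials: Sequence[TrialObservations],
    specs: Sequence[CategorySpec],
    config: ModelConfig | None = None,
    graphs: Sequence[LabelGraph] | None = None,
    graph_bandwidth: float = 0.5,
    verbose: bool = False,
    init_tensors: Sequence[ComponentTensor] | None = None,
    init_traces: Sequence[TraceMatrix] | None = None,
) -> FitResult:
    """Run the full three-stage fit.

    Stage 1 precomputes label similarity graphs (unless supplied), stage 2
    initializes components and traces spectrally, stage 3 alternates
    component sweeps, normalization and per-trial trace updates until the
    relative change of the total objective drops below ``config.tol`` or
    ``config.max_outer_iters`` is reached.
    """
    if config is None:
        config = ModelConfig()
    validate_dataset(trials, specs, allow_nan=config.mask_missing)
    specs = assign_trace_rows(specs)
    if graphs is None:
        graphs = [build_label_graph(spec, graph_bandwidth) for spec in specs]
    else:
        graphs = [LabelGraph(category=s, weights=g.weights) for s, g in zip(specs, graphs)]

    if init_tensors is not None and init_traces is not None:
        tensors = [
            ComponentTensor(category=spec, values=t.values.copy())
            for spec, t in zip(specs, init_tensors)
        ]
        traces = [TraceMatrix(trial_id=t.trial_id, values=t.values.copy()) for t in init_traces]
        tensors, traces = normalize_components(tensors, traces, trials, config)
    else:
        tensors, traces = initialize(trials, specs, config)
        # re-bind categories so tensors carry the trace_rows assignment
        tensors = [
            ComponentTensor(category=spec, values=t.values)
            for spec, t in zip(specs, tensors)
        ]

    history: list[float] = []
    converged = False
    prev = None
    n_iters = 0
    for it in range(config.max_outer_iters):
        tensors = update_all_components(trials, tensors, traces, graphs, config)
        tensors, traces = normalize_components(tensors, traces, trials, config)
        new_traces = []
        for trial, trace in zip(trials, traces):
            loading = construct_loading(tensors, trial.label)
            new_traces.append(update_trace(trial, loading, config, init=trace))
        traces = new_traces
        obj = total_objective(trials, tensors, traces, graphs, config)
        history.append(obj)
        n_iters = it + 1
        if verbose:
            print(f"iter {n_iters}: objective {obj:.6g}")
        if prev is not None:
            rel = abs(prev - obj) / max(abs(prev), 1e-12)
            if rel < config.tol:
                converged = True
                break
        prev = obj
    return FitResult(
        tensors=tensors,
        traces=traces,
        objective_history=history,
        converged=converged,
        n_iters=n_iters,
        specs=list(specs),
    )
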