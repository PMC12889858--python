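"""Recovery metrics and the permutation-null significance test.

Factorizations are identifiable only up to component permutation, so all
comparisons against ground truth first solve an optimal assignment between
estimated and true components (cost: one minus the absolute Pearson
correlation of variant-averaged compositions).  Significance of the label
structure is assessed by refitting or rescoring under shuffled trial-label
assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .data_model import (
    CategorySpec,
    ComponentTensor,
    ModelConfig,
    TraceMatrix,
    TrialObservations,
    construct_loading,
)
from .optimization import FitResult, _least_squares_trace, fit as _fit, update_trace

__all__ = ["MatchResult", "match_components", "recovery_metrics", "permutation_null_test"]


@dataclass
class MatchResult:
    """Optimal estimated-to-true component correspondence and its quality."""

    permutation: np.ndarray  # permutation[i] = true index matched to estimated i
    component_correlations: np.ndarray
    trace_correlations: np.ndarray | None
    mean_component_corr: float
    mean_trace_corr: float | None
    cost: float


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(pearsonr(x, y)[0])


def _flatten(tensors: list[ComponentTensor]) -> np.ndarray:
    """N x P matrix of variant-averaged component compositions."""
    cols = []
    for tensor in tensors:
        cols.append(tensor.values.mean(axis=2))
    return np.concatenate(cols, axis=1)


def _per_variant_cost(tensors_a, tensors_b) -> np.ndarray | None:
    """Pairwise cost averaged over variant slices; None if shapes differ."""
    shapes_a = [t.values.shape[2] for t in tensors_a]
    shapes_b = [t.values.shape[2] for t in tensors_b]
    if shapes_a != shapes_b:
        return None
    cols_a = []  # list over global components of (N, n_slices)
    cols_b = []
    for ta, tb in zip(tensors_a, tensors_b):
        for j in range(ta.category.p):
            cols_a.append(ta.values[:, j, :])
            cols_b.append(tb.values[:, j, :])
    p = len(cols_a)
    cost = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            if cols_a[i].shape[1] != cols_b[j].shape[1]:
                ca = cols_a[i].mean(axis=1)
                cb = cols_b[j].mean(axis=1)
                cost[i, j] = 1.0 - abs(_safe_corr(ca, cb))
            else:
                corrs = [
                    abs(_safe_corr(cols_a[i][:, s], cols_b[j][:, s]))
                    for s in range(cols_a[i].shape[1])
                ]
                cost[i, j] = 1.0 - float(np.mean(corrs))
    return cost


def match_components(
    estimated: list[ComponentTensor],
    true: list[ComponentTensor],
    estimated_traces: list[TraceMatrix] | None = None,
    true_traces: list[TraceMatrix] | None = None,
    per_variant: bool = False,
) -> MatchResult:
    """Align estimated components with ground truth by optimal assignment.

    Components are flattened by averaging their variants over label
    options; the assignment minimizes ``sum(1 - |pearson|)`` over all
    estimated-true pairings (``per_variant=True`` instead averages the cost
    over matching variant slices where the category layouts agree).  Signed
    correlations under the optimal assignment are reported; zero-variance
    components get correlation 0 with a warning.  If traces are supplied,
    per-component trace correlations (mean over trials of the per-trial
    Pearson correlation between matched trace rows) are reported too.
    """
    e_flat = _flatten(estimated)
    t_flat = _flatten(true)
    if e_flat.shape != t_flat.shape:
        raise ValueError(
            f"estimated and true components disagree in shape: "
            f"{e_flat.shape} vs {t_flat.shape}"
        )
    p = e_flat.shape[1]
    for name, flat in (("estimated", e_flat), ("true", t_flat)):
        if np.any(flat.std(axis=0) == 0):
            warnings.warn(f"{name} components include a constant column; its correlations are 0")

    cost = None
    if per_variant:
        cost = _per_variant_cost(estimated, true)
    if cost is None:
        cost = np.empty((p, p))
        for i in range(p):
            for j in range(p):
                cost[i, j] = 1.0 - abs(_safe_corr(e_flat[:, i], t_flat[:, j]))
    rows, cols = linear_sum_assignment(cost)
    permutation = np.empty(p, dtype=int)
    permutation[rows] = cols

    comp_corrs = np.array(
        [_safe_corr(e_flat[:, i], t_flat[:, permutation[i]]) for i in range(p)]
    )

    trace_corrs = None
    mean_trace = None
    if estimated_traces is not None and true_traces is not None:
        per_comp = []
        for i in range(p):
            j = permutation[i]
            vals = [
                _safe_corr(et.values[i], tt.values[j])
                for et, tt in zip(estimated_traces, true_traces)
            ]
            per_comp.append(float(np.mean(vals)))
        trace_corrs = np.array(per_comp)
        mean_trace = float(np.mean(np.abs(trace_corrs)))

    return MatchResult(
        permutation=permutation,
        component_correlations=comp_corrs,
        trace_correlations=trace_corrs,
        mean_component_corr=float(np.mean(np.abs(comp_corrs))),
        mean_trace_corr=mean_trace,
        cost=float(cost[rows, cols].sum()),
    )


def recovery_metrics(
    fit_result: FitResult,
    truth,
    trials: list[TrialObservations],
    per_variant: bool = False,
) -> dict:
    """Full recovery report against a known ground truth.

    Returns matched component and trace correlation distributions, the
    per-trial reconstruction R^2 of the fitted model, and summary means.
    """
    match = match_components(
        fit_result.tensors,
        truth.tensors,
        estimated_traces=fit_result.traces,
        true_traces=truth.traces,
        per_variant=per_variant,
    )
    r2s = []
    for trial, trace in zip(trials, fit_result.traces):
        loading = construct_loading(fit_result.tensors, trial.label)
        recon = loading.values @ trace.values
        ss_res = float(np.nansum((trial.values - recon) ** 2))
        ss_tot = float(np.nansum((trial.values - np.nanmean(trial.values)) ** 2))
        r2s.append(1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    return {
        "permutation": match.permutation.tolist(),
        "component_correlations": match.component_correlations.tolist(),
        "trace_correlations": (
            match.trace_correlations.tolist()
            if match.trace_correlations is not None
            else None
        ),
        "mean_component_corr": match.mean_component_corr,
        "mean_trace_corr": match.mean_trace_corr,
        "r2_per_trial": r2s,
        "mean_r2": float(np.mean(r2s)),
    }


def _reconstruction_score(
    trials: list[TrialObservations],
    tensors: list[ComponentTensor],
    labels: list[tuple],
    config: ModelConfig,
) -> float:
    """Total reconstruction R^2 with traces refit under the given labels."""
    ss_res = 0.0
    ss_tot = 0.0
    for trial, label in zip(trials, labels):
        loading = construct_loading(tensors, label)
        shadow = TrialObservations(
            trial_id=trial.trial_id, values=trial.values, label=label
        )
        trace = _least_squares_trace(shadow, loading, config)
        trace = update_trace(shadow, loading, config, init=trace)
        recon = loading.values @ trace.values
        ss_res += float(np.nansum((trial.values - recon) ** 2))
        ss_tot += float(np.nansum((trial.values - np.nanmean(trial.values)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def permutation_null_test(
    trials: list[TrialObservations],
    specs: list[CategorySpec],
    config: ModelConfig | None = None,
    n_perms: int = 99,
    mode: str = "rescore",
    seed: int = 0,
    holdout_fraction: float = 0.5,
    fit_result: FitResult | None = None,
) -> dict:
    """Test whether labels carry structure beyond chance.

    The trial-to-label assignment is shuffled uniformly ``n_perms`` times
    and the score is the total reconstruction R^2; the add-one p-value
    ``(1 + #{null >= real}) / (1 + n_perms)`` never reaches zero.

    In ``"rescore"`` mode the trials are split at random: components are
    fitted once on a training subset (real labels) and held fixed, and the
    held-out subset is scored -- traces refit per trial -- under its real
    labels versus label assignments permuted within the held-out set.
    Scoring out of sample is what makes the mode calibrated: components
    fitted and rescored on the same trials absorb noise aligned with the
    real labeling and would beat almost every permutation even when labels
    carry no information.  A ``fit_result`` passed in must therefore come
    from a fit on the training subset alone (the subset is reproducible
    from ``seed``); with the default ``None`` the function fits it.

    In ``"refit"`` mode the whole model is refit from scratch on every
    permuted dataset, so the null scores inherit the same in-sample
    flexibility as the real score.
    """
    if n_perms < 19:
        raise ValueError("n_perms must be at least 19")
    if mode not in ("rescore", "refit"):
        raise ValueError(f"unknown mode {mode!r}")
    if not (0.0 < holdout_fraction < 1.0):
        raise ValueError("holdout_fraction must lie in (0, 1)")
    if config is None:
        config = ModelConfig()
    rng = np.random.default_rng(seed)

    if mode == "rescore":
        idx = rng.permutation(len(trials))
        n_train = max(1, int(round((1.0 - holdout_fraction) * len(trials))))
        n_train = min(n_train, len(trials) - 1)
        train = [trials[i] for i in idx[:n_train]]
        test = [trials[i] for i in idx[n_train:]]
        if fit_result is None:
            fit_result = _fit(train, specs, config)
        tensors = [
            ComponentTensor(category=spec, values=t.values)
            for spec, t in zip(fit_result.specs or specs, fit_result.tensors)
        ]
        labels = [t.label for t in test]
        real_score = _reconstruction_score(test, tensors, labels, config)
        null_scores = []
        for _ in range(n_perms):
            perm = rng.permutation(len(test))
            permuted = [labels[j] for j in perm]
            null_scores.append(
                _reconstruction_score(test, tensors, permuted, config)
            )
    else:
        if fit_result is None:
            fit_result = _fit(trials, specs, config)
        specs = fit_result.specs or specs
        labels = [t.label for t in trials]
        real_score = _reconstruction_score(trials, fit_result.tensors, labels, config)
        null_scores = []
        for _ in range(n_perms):
            perm = rng.permutation(len(trials))
            permuted = [labels[j] for j in perm]
            shadow = [
                TrialObservations(trial_id=t.trial_id, values=t.values, label=lab)
                for t, lab in zip(trials, permuted)
            ]
            perm_fit = _fit(shadow, specs, config)
            null_scores.append(
                _reconstruction_score(shadow, perm_fit.tensors, permuted, config)
            )

    null_scores = np.array(null_scores)
    p = (1.0 + float(np.sum(null_scores >= real_score))) / (1.0 + n_perms)
    return {
        "p_value": p,
        "real_score": real_score,
        "null_scores": null_scores.tolist(),
        "mode": mode,
        "n_perms": n_perms,
    }
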