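"""Synthetic labeled multi-trial datasets with known ground truth.

The generator emulates the structure the model assumes: sparse nonnegative
component variants that differ subtly across label options (interpolating
monotonically along ordinal categories), Gaussian-process temporal traces
whose kernel parameters are tied to the trial's label option for each
component, and additive i.i.d. Gaussian observation noise.  Everything is
driven by a single integer seed, so datasets are bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import (
    CategorySpec,
    ComponentTensor,
    TraceMatrix,
    TrialObservations,
    assign_trace_rows,
    construct_loading,
)

__all__ = ["SyntheticConfig", "GroundTruth", "sample_gp_trace", "generate_components", "generate_dataset", "make_specs"]

#: category declarations: (name, n_options, ordinal?, p)
DEFAULT_CATEGORIES = (("difficulty", 5, True, 2), ("choice", 2, False, 2))


@dataclass
class SyntheticConfig:
    """Generator settings.

    Defaults follow the validation protocol this package targets: P = 4
    sparse components split over an ordinal 5-option "difficulty" category
    and a categorical 2-option "choice" category, M = 250 trials of T = 500
    time points, with N = 100 channels.
    """

    n_channels: int = 100
    n_trials: int = 250
    n_times: int = 500
    categories: Sequence[tuple] = DEFAULT_CATEGORIES
    sparsity: float = 0.15
    variant_jitter: float = 0.2
    gp_lengthscale_range: tuple[float, float] = (10.0, 60.0)
    gp_amplitude_range: tuple[float, float] = (0.5, 1.5)
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.sparsity <= 1.0):
            raise ValueError("sparsity must lie in (0, 1]")
        if self.variant_jitter < 0:
            raise ValueError("variant_jitter must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        for rng_ in (self.gp_lengthscale_range, self.gp_amplitude_range):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid positive range {rng_}")
        for cat in self.categories:
            if cat[1] < 1 or cat[3] < 1:
                raise ValueError(f"invalid category declaration {cat}")


@dataclass
class GroundTruth:
    """True components, traces and labels underlying a synthetic dataset."""

    tensors: list[ComponentTensor]
    traces: list[TraceMatrix]
    labels: list[tuple]
    specs: list[CategorySpec] = field(default_factory=list)


def make_specs(config: SyntheticConfig) -> list[CategorySpec]:
    """Category specs implied by the generator configuration."""
    specs = []
    for name, n_options, ordinal, p in config.categories:
        options = [f"{name}_{i}" for i in range(n_options)]
        specs.append(
            CategorySpec(
                name=name,
                options=options,
                p=p,
                ordinal_values=list(range(n_options)) if ordinal else None,
            )
        )
    return assign_trace_rows(specs)


def sample_gp_trace(
    n_times: int,
    lengthscale: float,
    amplitude: float,
    rng: np.random.Generator,
    chol: np.ndarray | None = None,
) -> np.ndarray:
    """Draw one zero-mean Gaussian-process trace.

    Squared-exponential kernel ``amplitude^2 * exp(-(t - t')^2 /
    (2 lengthscale^2))`` with 1e-6 diagonal jitter.  A pre-computed unit
    Cholesky factor (``amplitude`` = 1) may be passed to amortize repeated
    draws with the same lengthscale.
    """
    if lengthscale <= 0 or amplitude < 0:
        raise ValueError("lengthscale must be positive and amplitude nonnegative")
    if chol is None:
        chol = _unit_cholesky(n_times, lengthscale)
    return amplitude * (chol @ rng.standard_normal(n_times))


def _unit_cholesky(n_times: int, lengthscale: float) -> np.ndarray:
    t = np.arange(n_times, dtype=float)
    d2 = (t[:, None] - t[None, :]) ** 2
    cov = np.exp(-d2 / (2.0 * lengthscale**2))
    cov[np.diag_indices_from(cov)] += 1e-6
    return np.linalg.cholesky(cov)


def generate_components(
    config: SyntheticConfig, rng: np.random.Generator
) -> list[ComponentTensor]:
    """Draw sparse nonnegative component variants per category.

    Each component starts from a base support of ``ceil(sparsity * N)``
    channels with uniform(0.5, 1) magnitudes.  A perturbation direction
    touching at most 20% of the support (half added channels, half removed)
    is drawn once per (component, option); its magnitude scales linearly
    with ``variant_jitter``, so jitter 0 leaves all slices identical.  For
    ordinal categories the perturbation of a single drawn direction is
    interpolated monotonically along the option order.  Columns are
    L1-normalized.
    """
    n = config.n_channels
    support_size = math.ceil(config.sparsity * n)
    n_touch = max(1, int(round(0.1 * support_size)))  # added + removed <= 20%
    specs = make_specs(config)
    tensors = []
    for spec in specs:
        values = np.zeros((n, spec.p, spec.n_options))
        for j in range(spec.p):
            support = rng.choice(n, size=support_size, replace=False)
            base = np.zeros(n)
            base[support] = rng.uniform(0.5, 1.0, size=support_size)
            if spec.is_ordinal:
                deltas = [_perturbation(base, support, n_touch, rng)]
            else:
                deltas = [
                    _perturbation(base, support, n_touch, rng)
                    for _ in range(spec.n_options)
                ]
            for i in range(spec.n_options):
                if spec.is_ordinal:
                    frac = i / max(spec.n_options - 1, 1)
                    delta = frac * deltas[0]
                else:
                    delta = deltas[i]
                col = np.maximum(0.0, base + config.variant_jitter * delta)
                total = np.abs(col).sum()
                if total > 0:
                    col = col / total
                values[:, j, i] = col
        tensors.append(ComponentTensor(category=spec, values=values))
    return tensors


def _perturbation(
    base: np.ndarray, support: np.ndarray, n_touch: int, rng: np.random.Generator
) -> np.ndarray:
    """Unit-jitter perturbation: recruit new channels, shed existing ones."""
    n = base.shape[0]
    outside = np.setdiff1d(np.arange(n), support)
    delta = np.zeros(n)
    add = rng.choice(outside, size=min(n_touch, outside.size), replace=False)
    drop = rng.choice(support, size=min(n_touch, support.size), replace=False)
    delta[add] = rng.uniform(0.5, 1.0, size=add.size)
    delta[drop] = -base[drop]
    return delta


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[TrialObservations], GroundTruth]:
    """Generate a full labeled dataset plus its ground truth.

    Labels are assigned uniformly over the product of option spaces.  Each
    global component's GP kernel parameters (lengthscale, amplitude) are
    drawn once per label option of its own category; every trial then draws
    a fresh GP sample under those parameters, so same-label trials share
    components and trace statistics but never the trace itself.
    """
    rng = np.random.default_rng(config.seed)
    specs = make_specs(config)
    tensors = generate_components(config, rng)

    # per (global row, option-of-owning-category) kernel parameters
    ls_lo, ls_hi = config.gp_lengthscale_range
    amp_lo, amp_hi = config.gp_amplitude_range
    kernel_params: list[np.ndarray] = []  # per category: (p, n_options, 2)
    for spec in specs:
        params = np.empty((spec.p, spec.n_options, 2))
        params[:, :, 0] = rng.uniform(ls_lo, ls_hi, size=(spec.p, spec.n_options))
        params[:, :, 1] = rng.uniform(amp_lo, amp_hi, size=(spec.p, spec.n_options))
        kernel_params.append(params)

    chol_cache: dict[float, np.ndarray] = {}

    def chol_for(lengthscale: float) -> np.ndarray:
        if lengthscale not in chol_cache:
            chol_cache[lengthscale] = _unit_cholesky(config.n_times, lengthscale)
        return chol_cache[lengthscale]

    labels = [
        tuple(spec.options[rng.integers(spec.n_options)] for spec in specs)
        for _ in range(config.n_trials)
    ]

    p_total = sum(spec.p for spec in specs)
    trials = []
    truth_traces = []
    for m in range(config.n_trials):
        phi = np.empty((p_total, config.n_times))
        for ci, (spec, params) in enumerate(zip(specs, kernel_params)):
            i = spec.option_index(labels[m][ci])
            for j, row in enumerate(spec.trace_rows):
                lengthscale, amplitude = params[j, i]
                phi[row] = sample_gp_trace(
                    config.n_times, lengthscale, amplitude, rng, chol=chol_for(lengthscale)
                )
        loading = construct_loading(tensors, labels[m])
        clean = loading.values @ phi
        noise = (
            config.noise_sigma * rng.standard_normal(clean.shape)
            if config.noise_sigma > 0
            else 0.0
        )
        trials.append(
            TrialObservations(trial_id=m, values=clean + noise, label=labels[m])
        )
        truth_traces.append(TraceMatrix(trial_id=m, values=phi))

    truth = GroundTruth(tensors=tensors, traces=truth_traces, labels=labels, specs=specs)
    return trials, truth
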