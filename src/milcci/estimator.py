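"""Scikit-learn style estimator wrapping the alternating fit.

``MILCCI`` follows the sklearn decomposition idiom: hyperparameters in the
constructor, ``fit`` on a list of trials, fitted state in
trailing-underscore attributes, ``transform`` to obtain traces for new
trials under the fitted components.  It composes with ``sklearn.clone``
and ``get_params``/``set_params`` based model selection.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .data_model import (
    CategorySpec,
    ModelConfig,
    TraceMatrix,
    TrialObservations,
    construct_loading,
)
from .label_graphs import LabelGraph
from .optimization import _least_squares_trace, fit as _fit, update_trace

__all__ = ["MILCCI"]


class MILCCI(BaseEstimator):
    """Label-conditioned sparse component identification.

    Decomposes multi-trial time series ``Y(m) ~ A_L(m) Phi(m)`` where the
    loading ``A_L(m)`` concatenates, per metadata category, the sparse
    component variant selected by the trial's label, and ``Phi(m)`` are
    flexible per-trial temporal traces.

    Parameters
    ----------
    categories : sequence of CategorySpec
        Metadata categories (options, ordinal values, component budgets).
    gamma1, gamma2, gamma3, gamma4 : float
        Penalty weights: component sparsity, graph-coupled variant
        similarity, temporal smoothness, within-trial trace decorrelation.
    nonneg : bool
        Constrain component memberships to be nonnegative.
    norm_constant : float
        Fixed absolute sum of each component column after normalization.
    max_outer_iters, tol : int, float
        Outer-loop budget and relative objective-change stopping rule.
    graph_bandwidth : float
        Gaussian bandwidth of ordinal label similarity graphs.
    label_graph_weights : dict, optional
        Per-category override of the similarity matrix
        (``{category name: (K, K) array}``).

    Attributes
    ----------
    tensors_ : list of ComponentTensor
        Fitted per-category variant stacks (``N x p(k) x |k|``).
    traces_ : list of TraceMatrix
        Fitted per-trial traces (``P x T(m)``).
    objective_history_ : list of float
        Total objective after each outer iteration.
    converged_ : bool
    n_iter_ : int
    specs_ : list of CategorySpec
        Categories with assigned trace-row blocks.
    """

    def __init__(
        self,
        categories: Sequence[CategorySpec] = (),
        gamma1: float = 0.1,
        gamma2: float = 0.1,
        gamma3: float = 0.1,
        gamma4: float = 0.01,
        nonneg: bool = False,
        norm_constant: float = 1.0,
        max_outer_iters: int = 50,
        tol: float = 1e-4,
        seed: int = 0,
        mask_missing: bool = False,
        n_inner_trace: int = 5,
        graph_bandwidth: float = 0.5,
        label_graph_weights: dict | None = None,
        verbose: bool = False,
    ):
        self.categories = categories
        self.gamma1 = gamma1
        self.gamma2 = gamma2
        self.gamma3 = gamma3
        self.gamma4 = gamma4
        self.nonneg = nonneg
        self.norm_constant = norm_constant
        self.max_outer_iters = max_outer_iters
        self.tol = tol
        self.seed = seed
        self.mask_missing = mask_missing
        self.n_inner_trace = n_inner_trace
        self.graph_bandwidth = graph_bandwidth
        self.label_graph_weights = label_graph_weights
        self.verbose = verbose

    # -- helpers -----------------------------------------------------------

    def _config(self) -> ModelConfig:
        return ModelConfig(
            gamma1=self.gamma1,
            gamma2=self.gamma2,
            gamma3=self.gamma3,
            gamma4=self.gamma4,
            nonneg=self.nonneg,
            norm_constant=self.norm_constant,
            max_outer_iters=self.max_outer_iters,
            tol=self.tol,
            seed=self.seed,
            mask_missing=self.mask_missing,
            n_inner_trace=self.n_inner_trace,
        )

    @staticmethod
    def _as_trials(X, y=None) -> list[TrialObservations]:
        if y is not None:
            return [
                TrialObservations(trial_id=m, values=np.asarray(x), label=tuple(lab))
                for m, (x, lab) in enumerate(zip(X, y))
            ]
        trials = list(X)
        if not all(isinstance(t, TrialObservations) for t in trials):
            raise TypeError(
                "X must be a list of TrialObservations, or pass labels via y"
            )
        return trials

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None):
        """Fit components and traces.

        ``X`` is either a list of :class:`TrialObservations`, or a list of
        ``N x T(m)`` arrays with ``y`` a matching sequence of label tuples.
        """
        trials = self._as_trials(X, y)
        if not self.categories:
            raise ValueError("categories must be provided")
        graphs = None
        if self.label_graph_weights is not None:
            graphs = [
                LabelGraph(
                    category=spec,
                    weights=np.asarray(self.label_graph_weights[spec.name]),
                )
                if spec.name in self.label_graph_weights
                else None
                for spec in self.categories
            ]
            if any(g is None for g in graphs):
                from .label_graphs import build_label_graph

                graphs = [
                    g
                    if g is not None
                    else build_label_graph(spec, self.graph_bandwidth)
                    for g, spec in zip(graphs, self.categories)
                ]
        result = _fit(
            trials,
            list(self.categories),
            self._config(),
            graphs=graphs,
            graph_bandwidth=self.graph_bandwidth,
            verbose=self.verbose,
        )
        self.tensors_ = result.tensors
        self.traces_ = result.traces
        self.objective_history_ = result.objective_history
        self.converged_ = result.converged
        self.n_iter_ = result.n_iters
        self.specs_ = result.specs
        self.n_channels_ = trials[0].n_channels
        self.n_components_ = sum(s.p for s in result.specs)
        return self

    def transform(self, X, y=None) -> list[TraceMatrix]:
        """Traces for (possibly new) trials under the fitted components."""
        self._check_fitted()
        trials = self._as_trials(X, y)
        config = self._config()
        out = []
        for trial in trials:
            loading = construct_loading(self.tensors_, trial.label)
            trace = _least_squares_trace(trial, loading, config)
            out.append(update_trace(trial, loading, config, init=trace))
        return out

    def fit_transform(self, X, y=None) -> list[TraceMatrix]:
        return self.fit(X, y).traces_

    def reconstruct(self, X, y=None, traces: list[TraceMatrix] | None = None) -> list[np.ndarray]:
        """Model predictions ``A_L(m) Phi(m)`` for the given trials."""
        self._check_fitted()
        trials = self._as_trials(X, y)
        if traces is None:
            traces = self.transform(trials)
        return [
            construct_loading(self.tensors_, t.label).values @ tr.values
            for t, tr in zip(trials, traces)
        ]

    def score(self, X, y=None) -> float:
        """Total reconstruction R^2 over the given trials."""
        trials = self._as_trials(X, y)
        recons = self.reconstruct(trials)
        ss_res = sum(float(np.nansum((t.values - r) ** 2)) for t, r in zip(trials, recons))
        ss_tot = sum(
            float(np.nansum((t.values - np.nanmean(t.values)) ** 2)) for t in trials
        )
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    def _check_fitted(self):
        if not hasattr(self, "tensors_"):
            raise RuntimeError("this MILCCI instance is not fitted yet")
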