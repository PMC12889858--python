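"""Label similarity graphs coupling same-category component variants.

Each category gets a symmetric, zero-diagonal, nonnegative weight matrix
over its options.  During fitting the weights scale a quadratic attraction
between variant slices, so similar label options (e.g. adjacent difficulty
levels) are pulled toward similar component compositions while dissimilar
ones are left freer to diverge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import CategorySpec

__all__ = ["LabelGraph", "build_label_graph"]

DEFAULT_BANDWIDTH = 0.5


@dataclass
class LabelGraph:
    """Nonnegative symmetric option-to-option similarity weights."""

    category: CategorySpec
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        k = self.category.n_options
        if w.shape != (k, k):
            raise ValueError(
                f"weights for {self.category.name!r} must be {k}x{k}, got {w.shape}"
            )
        if not np.allclose(w, w.T):
            raise ValueError("label graph weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("label graph diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("label graph weights must be nonnegative")
        self.weights = w


def build_label_graph(spec: CategorySpec, bandwidth: float = DEFAULT_BANDWIDTH) -> LabelGraph:
    """Build the similarity graph for one category.

    Categorical categories get uniform coupling (all off-diagonal weights
    1).  Ordinal categories get a Gaussian kernel on their ordinal values
    rescaled to [0, 1]:

        w(i, j) = exp(-(v_i - v_j)^2 / (2 * bandwidth^2)),

    which decays monotonically with option distance and converges to the
    categorical graph as ``bandwidth -> inf``.  The diagonal is zero.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    k = spec.n_options
    if spec.is_ordinal:
        v = np.asarray(spec.ordinal_values, dtype=float)
        span = v.max() - v.min()
        if span > 0:
            v = (v - v.min()) / span
        else:
            v = np.zeros_like(v)
        d2 = (v[:, None] - v[None, :]) ** 2
        weights = np.exp(-d2 / (2.0 * bandwidth**2))
    else:
        weights = np.ones((k, k))
    np.fill_diagonal(weights, 0.0)
    return LabelGraph(category=spec, weights=weights)
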