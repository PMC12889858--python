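import numpy as np
import pytest

from milcci.data_model import (
    CategorySpec,
    ModelConfig,
    TrialObservations,
    assign_trace_rows,
)
from milcci.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_cat_specs():
    """Two categories, p=2 each: ordinal 3-option plus categorical binary."""
    return assign_trace_rows(
        [
            CategorySpec(
                name="difficulty",
                options=["easy", "medium", "hard"],
                p=2,
                ordinal_values=[0.0, 1.0, 2.0],
            ),
            CategorySpec(name="choice", options=["left", "right"], p=2),
        ]
    )


@pytest.fixture
def small_dataset():
    """Small synthetic dataset with ground truth (N=20, M=12, T=40)."""
    cfg = SyntheticConfig(
        n_channels=20, n_trials=12, n_times=40, seed=7, noise_sigma=0.05
    )
    return generate_dataset(cfg)


@pytest.fixture
def default_config():
    return ModelConfig()


def random_trials(rng, specs, n_trials, n_channels, n_times):
    """Unstructured Gaussian trials with uniform random labels."""
    trials = []
    for m in range(n_trials):
        label = tuple(s.options[rng.integers(s.n_options)] for s in specs)
        trials.append(
            TrialObservations(
                trial_id=m,
                values=rng.standard_normal((n_channels, n_times)),
                label=label,
            )
        )
    return trials
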