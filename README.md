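# milcci

Label-conditioned sparse component identification for multi-trial time
series.

Many experiments collect repeated time-series measurements ("trials") —
neural population recordings, election returns, page-view counts — where
every trial carries metadata spanning several categories (task
difficulty and choice; party and office; language and platform).  A
central question is how those labels are encoded in the data: which
groups of channels act together, how their composition shifts *subtly*
when a label changes, and how their activation evolves within each
trial.  Classical factorizations either force one set of components on
all trials (hiding label effects) or fit each trial separately (losing
cross-trial structure).

`milcci` models each trial `Y(m) ∈ R^{N×T(m)}` as

    Y(m) = A_L(m) Φ(m) + ε,

where the loading matrix `A_L(m)` is assembled from the trial's label:
each category `k` contributes `p(k)` sparse components stored as a
tensor `A(k) ∈ R^{N×p(k)×|k|}` of per-option *variants*, and the trial's
label selects one slice per category.  Trials with equal labels share
loadings exactly; the traces `Φ(m) ∈ R^{P×T(m)}` vary freely per trial.
Fitting alternates

* a graph-fused LASSO for each variant — least-squares fidelity over all
  trials carrying that option, an L1 sparsity penalty (`γ1`), and a
  quadratic attraction toward the category's other variants weighted by
  a label-similarity graph `λ(k)` (`γ2`), with optional nonnegativity;
* a penalized trace update per trial — fidelity, squared-first-difference
  temporal smoothness (`γ3`), and a normalized cross-trace decorrelation
  penalty (`γ4`) handled by exact banded solves of iterated quadratic
  surrogates;

with component columns rescaled to a fixed absolute sum after every
sweep (traces counter-scaled, reconstructions preserved).  See
`docs/methods.md` for the full model, solver, and design notes.

The package also ships a seeded synthetic-data generator with known
ground truth (sparse label-conditioned variants, Gaussian-process
traces, Gaussian noise), recovery metrics based on optimal component
assignment, a holdout permutation test for label significance, an HDF5 /
NPZ dataset container with CSV label tables, and spike-train-to-rate
preprocessing.

## Worked example

```python
from milcci import MILCCI, SyntheticConfig, generate_dataset
from milcci.evaluation import recovery_metrics
from milcci.optimization import FitResult

cfg = SyntheticConfig(n_channels=50, n_trials=80, n_times=200, seed=1)
trials, truth = generate_dataset(cfg)

model = MILCCI(categories=truth.specs, nonneg=True, max_outer_iters=30)
model.fit(trials)
print(f"converged: {model.converged_} after {model.n_iter_} iterations")
print(f"reconstruction R^2: {model.score(trials):.3f}")

result = FitResult(model.tensors_, model.traces_, model.objective_history_,
                   model.converged_, model.n_iter_, model.specs_)
report = recovery_metrics(result, truth, trials)
print(f"mean matched component correlation: {report['mean_component_corr']:.3f}")
print(f"mean matched trace correlation:     {report['mean_trace_corr']:.3f}")
```

Output:

```
converged: True after 27 iterations
reconstruction R^2: 0.502
mean matched component correlation: 0.943
mean matched trace correlation:     0.879
```

The dataset has four ground-truth components (two varying with an
ordinal 5-level "difficulty" category, two with a binary "choice"
category) at noise level 0.1.  An R² around 0.5 is the signal fraction
of this data — the rest is observation noise — while the correlations
say the recovered component memberships and their per-trial time courses
match the generating ones closely after optimal assignment.

The same pipeline is available from the shell:

```sh
milcci --seed 1 simulate --config sim.yaml --out data.h5
milcci fit --data data.h5 --config model.yaml --out fit.h5
milcci evaluate --fit fit.h5 --truth data.h5 --report report.json
milcci preprocess-spikes --spikes spikes.npz --out rates.npz --t-start 0 --t-end 60
```

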