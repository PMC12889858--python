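import numpy as np
import pytest

from oracles import dense_trace_solve, prox_gradient_variant, variant_objective

from milcci.data_model import (
    CategorySpec,
    ComponentTensor,
    ModelConfig,
    TraceMatrix,
    TrialObservations,
    assign_trace_rows,
    construct_loading,
)
from milcci.label_graphs import build_label_graph
from milcci.optimization import (
    component_subproblem_objective,
    fit,
    initialize,
    normalize_components,
    total_objective,
    trace_objective,
    update_all_components,
    update_component_variant,
    update_trace,
)
from milcci.synthetic import SyntheticConfig, generate_dataset


def _single_cat(p=2, options=("a", "b")):
    return assign_trace_rows(
        [CategorySpec(name="c", options=list(options), p=p)]
    )[0]


class TestInitialize:
    def test_same_seed_gives_identical_initialization(self, small_dataset):
        trials, truth = small_dataset
        config = ModelConfig(seed=3)
        t1, p1 = initialize(trials, truth.specs, config)
        t2, p2 = initialize(trials, truth.specs, config)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.values, b.values)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_nonneg_flag_gives_nonnegative_components(self, small_dataset):
        trials, truth = small_dataset
        tensors, _ = initialize(trials, truth.specs, ModelConfig(nonneg=True))
        for tensor in tensors:
            assert np.all(tensor.values >= 0)

    def test_rank_one_noiseless_data_is_reconstructed(self, rng):
        """Spectral init is exact on rank-1 data with a single component."""
        spec = _single_cat(p=1, options=("only",))
        a = rng.standard_normal(12)
        trials = [
            TrialObservations(
                trial_id=m,
                values=np.outer(a, rng.standard_normal(30)),
                label=("only",),
            )
            for m in range(4)
        ]
        tensors, traces = initialize(trials, [spec], ModelConfig())
        err = 0.0
        norm = 0.0
        for trial, trace in zip(trials, traces):
            recon = construct_loading(tensors, trial.label).values @ trace.values
            err += np.sum((trial.values - recon) ** 2)
            norm += np.sum(trial.values**2)
        assert np.sqrt(err / norm) < 1e-6


class TestComponentUpdate:
    def test_unpenalized_orthonormal_traces_give_closed_form(self, rng):
        spec = _single_cat(p=3, options=("a",))
        phi = np.linalg.qr(rng.standard_normal((20, 3)))[0].T  # orthonormal rows
        resid = rng.standard_normal((5, 20))
        graph = build_label_graph(spec)
        config = ModelConfig(gamma1=0.0, gamma2=0.0)
        tensor_values = np.zeros((5, 3, 1))
        new = update_component_variant(
            spec, 0, [resid], [phi], tensor_values, graph, config
        )
        assert np.abs(new - resid @ phi.T).max() < 1e-8

    def test_gamma1_above_null_threshold_zeroes_the_slice(self, rng):
        spec = _single_cat(p=2, options=("a",))
        phi = rng.standard_normal((2, 15))
        resid = rng.standard_normal((4, 15))
        threshold = 2.0 * np.abs(resid @ phi.T).max()
        graph = build_label_graph(spec)
        config = ModelConfig(gamma1=threshold * 1.01, gamma2=0.0)
        new = update_component_variant(
            spec, 0, [resid], [phi], np.zeros((4, 2, 1)), graph, config
        )
        assert not new.any()

    @pytest.mark.parametrize("nonneg", [False, True])
    def test_solution_matches_proximal_gradient_oracle(self, rng, nonneg):
        """Graph-fused LASSO vs. an independent FISTA run on the raw objective."""
        spec = _single_cat(p=2, options=("a", "b", "c"))
        graph = build_label_graph(spec)
        config = ModelConfig(gamma1=0.1, gamma2=0.3, nonneg=nonneg)
        tensor_values = rng.standard_normal((3, 2, 3))
        if nonneg:
            tensor_values = np.abs(tensor_values)
        residuals = [rng.standard_normal((3, 6)) for _ in range(2)]
        blocks = [rng.standard_normal((2, 6)) for _ in range(2)]
        new = update_component_variant(
            spec, 0, residuals, blocks, tensor_values, graph, config
        )
        lam = [graph.weights[i, 0] for i in (1, 2)]
        neighbors = [tensor_values[:, :, i] for i in (1, 2)]
        oracle = prox_gradient_variant(
            residuals, blocks, 0.1, 0.3, lam, neighbors, (3, 2), nonneg=nonneg
        )
        assert np.abs(new - oracle).max() < 1e-6

    def test_sparsity_is_weakly_monotone_in_gamma1(self, rng):
        spec = _single_cat(p=2, options=("a",))
        phi = rng.standard_normal((2, 30))
        resid = rng.standard_normal((6, 30))
        graph = build_label_graph(spec)
        counts = []
        for g1 in (0.0, 1.0, 5.0, 20.0, 200.0):
            config = ModelConfig(gamma1=g1, gamma2=0.0)
            new = update_component_variant(
                spec, 0, [resid], [phi], np.zeros((6, 2, 1)), graph, config
            )
            counts.append(int(np.sum(np.abs(new) > 1e-12)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_option_falls_back_to_graph_attraction(self, rng):
        spec = _single_cat(p=2, options=("a", "b"))
        graph = build_label_graph(spec)
        config = ModelConfig(gamma1=0.0, gamma2=1.0)
        tensor_values = rng.standard_normal((4, 2, 2))
        with pytest.warns(UserWarning, match="no trials"):
            new = update_component_variant(
                spec, 0, [], [], tensor_values, graph, config
            )
        np.testing.assert_allclose(new, tensor_values[:, :, 1], atol=1e-10)

    def test_all_zero_traces_keep_incumbent_with_warning(self, rng):
        spec = _single_cat(p=2, options=("a",))
        graph = build_label_graph(spec)
        config = ModelConfig(gamma2=0.0)
        incumbent = rng.standard_normal((4, 2, 1))
        with pytest.warns(UserWarning, match="zero"):
            new = update_component_variant(
                spec,
                0,
                [rng.standard_normal((4, 10))],
                [np.zeros((2, 10))],
                incumbent,
                graph,
                config,
            )
        np.testing.assert_array_equal(new, incumbent[:, :, 0])


class TestSweep:
    def test_sweep_descends_every_subproblem(self, small_dataset):
        trials, truth = small_dataset
        config = ModelConfig(nonneg=True, check_descent=True, max_outer_iters=4)
        result = fit(trials, truth.specs, config)  # raises if any update ascends
        assert result.n_iters >= 1

    def test_strong_coupling_fuses_variants(self, rng, small_dataset):
        trials, truth = small_dataset
        config = ModelConfig(gamma2=1e6, nonneg=True, max_outer_iters=5)
        result = fit(trials, truth.specs, config)
        for tensor in result.tensors:
            ref = tensor.values[:, :, 0]
            for i in range(1, tensor.values.shape[2]):
                rel = np.linalg.norm(tensor.values[:, :, i] - ref) / max(
                    np.linalg.norm(ref), 1e-12
                )
                assert rel < 1e-3

    def test_coupling_strength_weakly_shrinks_variant_distances(self):
        # every label option must carry trials for the trend to be clean
        cfg = SyntheticConfig(
            n_channels=20,
            n_trials=30,
            n_times=40,
            seed=5,
            noise_sigma=0.05,
            categories=(("difficulty", 3, True, 2), ("choice", 2, False, 2)),
        )
        trials, truth = generate_dataset(cfg)
        distances = []
        for g2 in (0.0, 0.5, 50.0):
            config = ModelConfig(gamma2=g2, nonneg=True, max_outer_iters=8)
            result = fit(trials, truth.specs, config)
            dist = []
            for tensor in result.tensors:
                k = tensor.values.shape[2]
                for i in range(k):
                    for j in range(i + 1, k):
                        dist.append(
                            np.linalg.norm(tensor.values[:, :, i] - tensor.values[:, :, j])
                        )
            distances.append(np.mean(dist))
        assert distances[0] + 1e-9 >= distances[1] >= distances[2] - 1e-9


class TestTraceUpdate:
    def test_orthonormal_unpenalized_projection(self, rng):
        spec = _single_cat(p=4, options=("a",))
        q = np.linalg.qr(rng.standard_normal((10, 4)))[0]
        tensor = ComponentTensor(category=spec, values=q[:, :, None])
        trial = TrialObservations(
            trial_id=0, values=rng.standard_normal((10, 25)), label=("a",)
        )
        config = ModelConfig(gamma3=0.0, gamma4=0.0)
        trace = update_trace(trial, construct_loading([tensor], ("a",)), config)
        assert np.abs(trace.values - q.T @ trial.values).max() < 1e-8

    @pytest.mark.parametrize("gamma3", [0.0, 0.3, 7.0])
    def test_matches_dense_normal_equation_oracle(self, rng, gamma3):
        loading_values = rng.standard_normal((6, 3))
        spec = _single_cat(p=3, options=("a",))
        tensor = ComponentTensor(category=spec, values=loading_values[:, :, None])
        trial = TrialObservations(
            trial_id=0, values=rng.standard_normal((6, 12)), label=("a",)
        )
        config = ModelConfig(gamma3=gamma3, gamma4=0.0)
        trace = update_trace(trial, construct_loading([tensor], ("a",)), config)
        oracle = dense_trace_solve(trial.values, loading_values, gamma3)
        assert np.abs(trace.values - oracle).max() < 1e-6

    def test_huge_smoothness_flattens_rows(self, rng):
        loading_values = rng.standard_normal((6, 2))
        spec = _single_cat(p=2, options=("a",))
        tensor = ComponentTensor(category=spec, values=loading_values[:, :, None])
        trial = TrialObservations(
            trial_id=0, values=rng.standard_normal((6, 12)) + 2.0, label=("a",)
        )
        config = ModelConfig(gamma3=1e6, gamma4=0.0)
        trace = update_trace(trial, construct_loading([tensor], ("a",)), config)
        for row in trace.values:
            assert np.ptp(row) < 1e-3 * max(np.abs(row).max(), 1e-12)

    def test_decorrelation_never_increases_true_objective(self, rng):
        loading_values = rng.standard_normal((8, 3))
        spec = _single_cat(p=3, options=("a",))
        tensor = ComponentTensor(category=spec, values=loading_values[:, :, None])
        trial = TrialObservations(
            trial_id=0, values=rng.standard_normal((8, 20)), label=("a",)
        )
        config = ModelConfig(gamma3=0.2, gamma4=0.5, check_descent=True)
        init = TraceMatrix(trial_id=0, values=rng.standard_normal((3, 20)))
        before = trace_objective(
            trial.values, loading_values, init.values, 0.2, 0.5
        )
        trace = update_trace(
            trial, construct_loading([tensor], ("a",)), config, init=init
        )
        after = trace_objective(
            trial.values, loading_values, trace.values, 0.2, 0.5
        )
        assert after <= before + 1e-8 * max(1.0, abs(before))

    def test_zero_loading_with_no_smoothness_warns_and_solves(self, rng):
        spec = _single_cat(p=2, options=("a",))
        values = np.zeros((5, 2, 1))
        values[:, 0, 0] = rng.standard_normal(5)  # second column dead
        tensor = ComponentTensor(category=spec, values=values)
        trial = TrialObservations(
            trial_id=0, values=rng.standard_normal((5, 10)), label=("a",)
        )
        config = ModelConfig(gamma3=0.0, gamma4=0.0)
        with pytest.warns(UserWarning, match="ridge"):
            trace = update_trace(trial, construct_loading([tensor], ("a",)), config)
        assert np.all(np.isfinite(trace.values))


class TestNormalization:
    def test_reconstructions_preserved(self, small_dataset):
        trials, truth = small_dataset
        config = ModelConfig(nonneg=True, max_outer_iters=2)
        result = fit(trials, truth.specs, config)
        before = [
            construct_loading(result.tensors, t.label).values @ tr.values
            for t, tr in zip(trials, result.traces)
        ]
        normalize_components(result.tensors, result.traces, trials, config)
        after = [
            construct_loading(result.tensors, t.label).values @ tr.values
            for t, tr in zip(trials, result.traces)
        ]
        for a, b in zip(before, after):
            assert np.abs(a - b).max() < 1e-10

    def test_columns_sum_to_norm_constant(self, small_dataset):
        trials, truth = small_dataset
        config = ModelConfig(nonneg=True, max_outer_iters=2, norm_constant=2.5)
        result = fit(trials, truth.specs, config)
        for tensor in result.tensors:
            sums = np.abs(tensor.values).sum(axis=0)
            nonzero = sums > 0
            np.testing.assert_allclose(sums[nonzero], 2.5, rtol=1e-10)

    def test_normalization_is_scale_invariant(self, rng, two_cat_specs):
        config = ModelConfig()
        tensors = [
            ComponentTensor(category=s, values=np.abs(rng.standard_normal((6, s.p, s.n_options))))
            for s in two_cat_specs
        ]
        scaled = [
            ComponentTensor(category=s, values=3.7 * t.values.copy())
            for s, t in zip(two_cat_specs, tensors)
        ]
        trials = [
            TrialObservations(trial_id=0, values=np.zeros((6, 5)), label=("easy", "left"))
        ]
        traces_a = [TraceMatrix(trial_id=0, values=np.ones((4, 5)))]
        traces_b = [TraceMatrix(trial_id=0, values=np.ones((4, 5)))]
        normalize_components(tensors, traces_a, trials, config)
        normalize_components(scaled, traces_b, trials, config)
        for a, b in zip(tensors, scaled):
            np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestFit:
    def test_truth_is_a_near_fixed_point_on_noiseless_data(self):
        """With negligible penalties, one iteration from the truth stays put."""
        cfg = SyntheticConfig(
            n_channels=20,
            n_trials=30,
            n_times=40,
            seed=11,
            noise_sigma=0.0,
            categories=(("difficulty", 3, True, 2), ("choice", 2, False, 2)),
        )
        trials, truth = generate_dataset(cfg)
        config = ModelConfig(
            gamma1=1e-8, gamma2=1e-8, gamma3=1e-8, gamma4=0.0,
            nonneg=True, max_outer_iters=1,
        )
        result = fit(
            trials,
            truth.specs,
            config,
            init_tensors=truth.tensors,
            init_traces=truth.traces,
        )
        norm_y = sum(np.sum(t.values**2) for t in trials)
        assert result.objective_history[-1] / norm_y < 1e-6
        for fitted, true in zip(result.tensors, truth.tensors):
            assert np.abs(fitted.values - true.values).max() < 1e-3

    def test_single_trial_factorization_descends(self, rng):
        spec = _single_cat(p=2, options=("a",))
        trials = [
            TrialObservations(
                trial_id=0, values=rng.standard_normal((8, 30)), label=("a",)
            )
        ]
        config = ModelConfig(gamma2=0.0, max_outer_iters=10)
        result = fit(trials, [spec], config)
        hist = np.array(result.objective_history)
        assert np.all(np.diff(hist) <= 1e-8 * np.maximum(1.0, np.abs(hist[:-1])))

    def test_equal_label_trials_share_loadings_after_fit(self, small_dataset):
        trials, truth = small_dataset
        result = fit(trials, truth.specs, ModelConfig(nonneg=True, max_outer_iters=3))
        by_label = {}
        for trial in trials:
            loading = construct_loading(result.tensors, trial.label)
            if trial.label in by_label:
                assert np.array_equal(by_label[trial.label], loading.values)
            else:
                by_label[trial.label] = loading.values

    def test_fit_is_deterministic(self, small_dataset):
        trials, truth = small_dataset
        config = ModelConfig(nonneg=True, max_outer_iters=3)
        r1 = fit(trials, truth.specs, config)
        r2 = fit(trials, truth.specs, config)
        assert r1.objective_history == r2.objective_history
        for a, b in zip(r1.tensors, r2.tensors):
            np.testing.assert_array_equal(a.values, b.values)

    def test_nan_input_rejected_without_masking(self, small_dataset):
        trials, truth = small_dataset
        bad = [
            TrialObservations(
                trial_id=t.trial_id, values=t.values.copy(), label=t.label
            )
            for t in trials
        ]
        bad[0].values[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit(bad, truth.specs, ModelConfig())

    def test_masked_fit_handles_missing_cells(self, small_dataset):
        trials, truth = small_dataset
        masked = []
        rng = np.random.default_rng(0)
        for t in trials:
            values = t.values.copy()
            holes = rng.random(values.shape) < 0.05
            values[holes] = np.nan
            masked.append(
                TrialObservations(trial_id=t.trial_id, values=values, label=t.label)
            )
        config = ModelConfig(nonneg=True, mask_missing=True, max_outer_iters=3)
        result = fit(masked, truth.specs, config)
        assert np.all(np.isfinite(result.objective_history))
        for tensor in result.tensors:
            assert np.all(np.isfinite(tensor.values))


def test_total_objective_matches_sum_of_parts(rng, small_dataset):
    """Subproblem quadratic-form differences agree with global differences."""
    trials, truth = small_dataset
    specs = truth.specs
    config = ModelConfig(nonneg=True, max_outer_iters=2)
    result = fit(trials, specs, config)
    graphs = [build_label_graph(s) for s in specs]
    base = total_objective(trials, result.tensors, result.traces, graphs, config)
    # perturb one variant slice and verify the global delta equals the
    # restricted subproblem delta computed from its Gram/linear terms
    tensor = result.tensors[0]
    spec = tensor.category
    members = [m for m, t in enumerate(trials) if t.label[0] == spec.options[0]]
    from milcci.data_model import residual_for_category

    residuals = [
        residual_for_category(trials[m], result.tensors, result.traces[m], spec)
        for m in members
    ]
    blocks = [
        result.traces[m].values[spec.trace_rows.start : spec.trace_rows.stop]
        for m in members
    ]
    from milcci.optimization import _variant_problem_terms

    gram, linear, _ = _variant_problem_terms(
        spec, 0, residuals, blocks, tensor.values, graphs[0], config
    )
    old = tensor.values[:, :, 0].copy()
    new = old + 0.01
    delta_sub = component_subproblem_objective(
        new, gram, linear, config.gamma1
    ) - component_subproblem_objective(old, gram, linear, config.gamma1)
    tensor.values[:, :, 0] = new
    perturbed = total_objective(trials, result.tensors, result.traces, graphs, config)
    tensor.values[:, :, 0] = old
    assert perturbed - base == pytest.approx(delta_sub, rel=1e-6, abs=1e-8)
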