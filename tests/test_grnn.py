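import numpy as np
import pytest

from deltanci.dataio import (
    Dataset,
    MoleculeRecord,
    NormalizationMap,
    SchemaError,
    TARGET_KEY,
    save_model,
)
from deltanci.grnn import (
    CVConfig,
    GRNNModel,
    PipelineConfig,
    apply_correction,
    cv_rmse,
    grnn_fit,
    grnn_predict,
    kfold_partition,
    optimize_sigma,
    sigma_grid_values,
    train_pipeline,
)


def _identity_map(names):
    """Normalization that is the identity on [-1, 1] variables."""
    ranges = {n: (-1.0, 1.0) for n in names}
    ranges[TARGET_KEY] = (-1.0, 1.0)
    return NormalizationMap(ranges)


def _model(patterns, targets, sigma, names=None):
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    names = names or ["dft_nci"] + [
        f"v{j}" for j in range(1, patterns.shape[1])
    ]
    return GRNNModel(
        descriptor_names=names,
        patterns=patterns,
        targets=np.asarray(targets, dtype=float),
        sigma=sigma,
        normalization=_identity_map(names),
    )


def _kernel_oracle(patterns, targets, query, sigma):
    """Direct two-loop evaluation of the kernel-regression formula."""
    num = den = 0.0
    for Xi, yi in zip(patterns, targets):
        w = np.exp(-np.sum((query - Xi) ** 2) / (2 * sigma**2))
        num += yi * w
        den += w
    return num / den


def _dataset(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = ["dft_nci"] + [f"v{j}" for j in range(1, X.shape[1])]
    recs = [
        MoleculeRecord(
            id=f"r{i}",
            descriptors=dict(zip(names, map(float, X[i]))),
            reference_nci=float(y[i]),
        )
        for i in range(X.shape[0])
    ]
    return Dataset(recs, names)


class TestGRNNPredict:
    def test_single_pattern_returns_its_target(self):
        m = _model([[0.3, -0.2]], [5.0], sigma=0.7)
        assert grnn_predict(m, np.array([[0.9, 0.9]]))[0] == pytest.approx(5.0)

    def test_equidistant_patterns_average(self):
        m = _model([[-1.0], [1.0]], [2.0, 4.0], sigma=0.5)
        assert grnn_predict(m, np.array([[0.0]]))[0] == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_two_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.uniform(-1, 1, (5, 3))
        t = rng.normal(size=5)
        q = rng.uniform(-1, 1, 3)
        m = _model(P, t, sigma=0.2)
        assert grnn_predict(m, q[None, :])[0] == pytest.approx(
            _kernel_oracle(P, t, q, 0.2), abs=1e-12
        )

    @pytest.mark.parametrize("sigma", [0.05, 0.3, 2.0])
    def test_prediction_is_convex_combination_of_targets(self, sigma):
        rng = np.random.default_rng(10)
        m = _model(rng.uniform(-1, 1, (20, 4)), rng.normal(size=20), sigma)
        preds = grnn_predict(m, rng.uniform(-3, 3, (50, 4)))
        assert np.all(preds >= m.targets.min() - 1e-12)
        assert np.all(preds <= m.targets.max() + 1e-12)

    def test_pattern_permutation_invariance(self):
        rng = np.random.default_rng(4)
        P, t = rng.uniform(-1, 1, (8, 2)), rng.normal(size=8)
        q = rng.uniform(-1, 1, (3, 2))
        perm = rng.permutation(8)
        a = grnn_predict(_model(P, t, 0.3), q)
        b = grnn_predict(_model(P[perm], t[perm], 0.3), q)
        assert a == pytest.approx(b, abs=1e-12)

    def test_distant_query_degrades_to_nearest_pattern(self):
        # 1000 normalized units away: naive weights underflow, the shifted
        # exponent contract must still return the nearest pattern's target
        m = _model([[0.0], [0.5]], [1.0, 2.0], sigma=0.1)
        val = grnn_predict(m, np.array([[1000.0]]))[0]
        assert np.isfinite(val)
        assert val == pytest.approx(2.0)

    def test_missing_descriptor_is_schema_error(self):
        m = _model([[0.0, 0.0]], [1.0], sigma=0.5)
        with pytest.raises(SchemaError):
            grnn_predict(m, {"dft_nci": 0.1})


class TestGRNNFit:
    def test_one_pattern_neuron_per_training_sample(self, bench):
        data, _ = bench
        train = data.subset(data.ids[:7])
        m = grnn_fit(train, ["dft_nci", "nve"], sigma=0.2)
        assert m.patterns.shape == (7, 2)

    def test_small_sigma_interpolates_training_targets(self, bench):
        data, _ = bench
        train = data.subset(data.ids[:30])
        m = grnn_fit(train, ["dft_nci", "nve"], sigma=1e-4)
        preds = grnn_predict(m, train)
        assert preds == pytest.approx(m.targets, abs=1e-9)

    def test_large_sigma_returns_training_mean(self, bench):
        data, _ = bench
        train = data.subset(data.ids[:30])
        m = grnn_fit(train, ["dft_nci", "nve"], sigma=1e6)
        preds = grnn_predict(m, train)
        assert preds == pytest.approx(
            np.full(30, m.targets.mean()), abs=1e-9
        )

    def test_nonpositive_sigma_rejected(self, bench):
        data, _ = bench
        with pytest.raises(ValueError):
            grnn_fit(data.subset(data.ids[:5]), ["dft_nci"], sigma=0.0)


class TestKFold:
    def test_even_fold_sizes(self):
        ids = [f"r{i}" for i in range(10)]
        folds = kfold_partition(ids, CVConfig(k=5, seed=0))
        assert [len(f) for f in folds] == [2] * 5
        assert sorted(sum(folds, [])) == sorted(ids)

    def test_benchmark_training_set_fold_sizes(self):
        folds = kfold_partition(
            [f"r{i}" for i in range(91)], CVConfig(k=10, seed=0)
        )
        assert sorted(len(f) for f in folds) == [9] * 9 + [10]

    def test_seed_determinism(self):
        ids = [f"r{i}" for i in range(20)]
        a = kfold_partition(ids, CVConfig(k=4, seed=5))
        b = kfold_partition(ids, CVConfig(k=4, seed=5))
        c = kfold_partition(ids, CVConfig(k=4, seed=6))
        assert a == b
        assert a != c

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_partition(["a", "b"], CVConfig(k=3, seed=0))


class TestCrossValidation:
    def test_leave_one_out_matches_hand_rolled_loop(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(-4, -1, (6, 1))
        y = (2 * X[:, 0] + 1).astype(float)
        ds = _dataset(X, y)
        cv = CVConfig(k=6, seed=0)
        val, oof = cv_rmse(ds, ["dft_nci"], 0.3, cv, return_oof=True)
        # hand-rolled leave-one-out with per-fold normalization refit
        expected = np.empty(6)
        for i in range(6):
            rest = ds.subset([f"r{j}" for j in range(6) if j != i])
            m = grnn_fit(rest, ["dft_nci"], 0.3)
            expected[i] = grnn_predict(
                m, ds.subset([f"r{i}"]), denormalize=True
            )[0]
        assert oof == pytest.approx(expected, abs=1e-12)
        assert val == pytest.approx(
            np.sqrt(np.mean((expected - y) ** 2)), abs=1e-12
        )

    def test_noiseless_smooth_function_is_recovered(self):
        # dense 1-D sampling of an exactly smooth response: held-out error
        # falls below a 1e-3 kcal/mol noise floor
        x = np.linspace(-1.0, 1.0, 401)
        y = 0.5 * np.sin(1.5 * x)
        ds = _dataset(x[:, None], y)
        val = cv_rmse(ds, ["dft_nci"], 0.01, CVConfig(k=10, seed=0))
        assert val < 1e-3

    def test_pure_noise_at_max_sigma_approaches_sample_sd(self):
        rng = np.random.default_rng(42)
        ds = _dataset(rng.uniform(-1, 1, (100, 2)), rng.normal(0, 1.0, 100))
        val = cv_rmse(ds, ["dft_nci", "v1"], 2.0, CVConfig(k=10, seed=0))
        sd = float(np.std(ds.y))
        assert abs(val - sd) / sd < 0.25


class TestOptimizeSigma:
    def test_default_grid_has_twenty_candidates(self):
        assert sigma_grid_values((0.1, 2.0, 0.1)).size == 20

    def test_single_point_grid(self, bench):
        data, _ = bench
        train = data.subset(data.ids[:30])
        s = optimize_sigma(
            train, ["dft_nci"], (0.5, 0.5, 0.1), CVConfig(k=5, seed=0)
        )
        assert s.sigma == 0.5
        assert len(s.table) == 1

    def test_argmin_matches_independent_table(self, bench):
        data, _ = bench
        train = data.subset(data.ids[:40])
        cv = CVConfig(k=5, seed=3)
        grid = (0.1, 1.0, 0.1)
        s = optimize_sigma(train, ["dft_nci", "nve"], grid, cv)
        table = {
            sig: cv_rmse(train, ["dft_nci", "nve"], sig, cv)
            for sig in sigma_grid_values(grid)
        }
        assert s.sigma == min(table, key=lambda k: (table[k], -k))
        for sig, r in s.table:
            assert r == pytest.approx(table[sig], abs=1e-12)

    def test_invalid_grid(self, bench):
        data, _ = bench
        with pytest.raises(ValueError):
            optimize_sigma(
                data.subset(data.ids[:20]),
                ["dft_nci"],
                (0.0, 1.0, 0.1),
                CVConfig(k=5, seed=0),
            )


class TestTrainPipeline:
    def test_minimal_run_completes(self, bench):
        data, _ = bench
        tiny = data.subset(data.ids[:3])
        result = train_pipeline(
            tiny,
            PipelineConfig(
                n_train=2, k=2, seed=0, sigma_grid=(0.2, 0.4, 0.2),
                top_k=3, max_subset=2, pls_components=1,
            ),
        )
        assert result.model.n_patterns == 2

    def test_rerun_is_bit_identical(self, tmp_path, bench):
        data, _ = bench
        cfg = PipelineConfig(seed=7)
        a = train_pipeline(data, cfg)
        b = train_pipeline(data, cfg)
        save_model(a.model, tmp_path / "a.json")
        save_model(b.model, tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (
            tmp_path / "b.json"
        ).read_bytes()

    def test_unlabelled_data_rejected(self, bench):
        data, _ = bench
        for r in data.records[:1]:
            r_unlab = MoleculeRecord(
                id="u0", descriptors=dict(r.descriptors), reference_nci=None
            )
        bad = Dataset(
            [r_unlab] + data.records[1:], data.descriptor_names
        )
        with pytest.raises(ValueError):
            train_pipeline(bad)

    def test_validation_metrics_on_default_benchmark(self, pipeline_runs):
        # the simulated analogue of the benchmark regime: all three
        # validation parameters exceed 0.9 and no over-fit flag fires
        run = next(r for r in pipeline_runs if r["seed"] == 7)
        rep = run["results"].report
        assert rep.r2 > 0.9
        assert rep.q2 > 0.9
        assert rep.q2cv > 0.9
        assert not rep.overfit_flag


class TestApplyCorrection:
    def test_identity_holds_exactly(self, bench):
        data, _ = bench
        train = data.subset(data.ids[:50])
        m = grnn_fit(train, ["dft_nci", "nve"], sigma=0.3)
        for row in apply_correction(m, data.subset(data.ids[50:80])):
            assert row.corrected_nci == row.dft_nci + row.correction

    def test_training_point_reproduced_at_tiny_sigma(self, bench):
        data, _ = bench
        train = data.subset(data.ids[:50])
        m = grnn_fit(train, ["dft_nci", "nve"], sigma=1e-4)
        row = apply_correction(m, data.subset([data.ids[0]]))[0]
        assert row.corrected_nci == pytest.approx(
            data.records[0].reference_nci, abs=1e-6
        )

    def test_batch_matches_denormalized_oracle(self, bench):
        data, _ = bench
        train = data.subset(data.ids[:60])
        subset = ["dft_nci", "nve", "dipole"]
        m = grnn_fit(train, subset, sigma=0.25)
        queries = data.subset(data.ids[60:90])
        rows = apply_correction(m, queries)
        Q = m.normalization.transform_matrix(
            np.column_stack([queries.column(n) for n in subset]), subset
        )
        for row, q in zip(rows, Q):
            expected = m.normalization.invert_target(
                _kernel_oracle(m.patterns, m.targets, q, 0.25)
            )
            assert row.corrected_nci == pytest.approx(
                float(expected), abs=1e-9
            )
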