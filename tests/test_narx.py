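import numpy as np
import pytest

from emonarx.narx import (LagSpec, NarxDivergenceError, NarxModel,
                          build_regressors, fit_narx, pearson_r)
from emonarx.simulate import (TrueNarxProcess, generate_intensity_from_narx,
                              synthesize_feature_series)


def naive_regressors(y, u, spec):
    """Triple-loop oracle for the regressor construction."""
    T = len(y)
    L = max(spec.n_y, max(k + nu for k, nu in zip(spec.n_k, spec.n_u)))
    rows, targets = [], []
    for t in range(L, T):
        row = [y[t - i] for i in range(1, spec.n_y + 1)]
        for name, nu, nk in zip(spec.features, spec.n_u, spec.n_k):
            lin = [u[name][t - lag] for lag in range(nk, nk + nu + 1)]
            row.extend(lin)
            row.extend(v * v for v in lin)
        rows.append(row)
        targets.append(y[t])
    return np.array(rows), np.array(targets)


def random_spec(rng, names):
    m = int(rng.integers(1, 4))
    feats = tuple(rng.choice(names, size=m, replace=False))
    return LagSpec(int(rng.integers(1, 12)), feats,
                   tuple(int(v) for v in rng.integers(1, 12, m)),
                   tuple(int(v) for v in rng.integers(1, 12, m)))


class TestLagSpec:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            LagSpec(12, ("u1",), (1,), (1,))
        with pytest.raises(ValueError):
            LagSpec(1, ("u1",), (1,), (0,))

    def test_max_three_features(self):
        with pytest.raises(ValueError):
            LagSpec(1, ("a", "b", "c", "d"), (1,) * 4, (1,) * 4)

    def test_vector_round_trip(self):
        spec = LagSpec(3, ("a", "b"), (2, 5), (4, 1))
        assert spec.as_vector() == (3, 2, 4, 5, 1)
        assert LagSpec.from_vector(spec.as_vector(), spec.features) == spec

    def test_lookback_and_param_count(self):
        spec = LagSpec(9, ("a", "b"), (2, 1), (4, 8))
        assert spec.max_lookback == 9
        assert spec.n_params == 5


class TestBuildRegressors:
    def test_small_example_shape_and_columns(self):
        """n_y=1, one feature with n_u=1, n_k=1, T=10: 8 rows and columns
        [y(t-1), u(t-1), u(t-2), u(t-1)^2, u(t-2)^2]."""
        rng = np.random.default_rng(0)
        y = rng.normal(size=10)
        u = {"a": rng.normal(size=10)}
        spec = LagSpec(1, ("a",), (1,), (1,))
        Z, tgt = build_regressors(y, u, spec)
        assert Z.shape == (8, 5)
        assert spec.column_names() == [
            "y(t-1)", "a(t-1)", "a(t-2)", "a(t-1)^2", "a(t-2)^2"]
        t = 5
        expected = [y[t - 1], u["a"][t - 1], u["a"][t - 2],
                    u["a"][t - 1] ** 2, u["a"][t - 2] ** 2]
        assert np.allclose(Z[t - 2], expected)
        assert tgt[t - 2] == y[t]

    def test_matches_naive_loop_on_random_specs(self):
        rng = np.random.default_rng(42)
        names = np.array(["a", "b", "c", "d"])
        for _ in range(15):
            spec = random_spec(rng, names)
            T = int(rng.integers(spec.max_lookback + 5, 80))
            y = rng.normal(size=T)
            u = {n: rng.normal(size=T) for n in names}
            Z, tgt = build_regressors(y, u, spec)
            Zo, to = naive_regressors(y, u, spec)
            assert np.array_equal(Z, Zo)
            assert np.array_equal(tgt, to)
            assert Z.shape[0] == T - spec.max_lookback

    def test_zero_feature_gives_zero_quadratic_columns(self):
        y = np.random.default_rng(1).normal(size=30)
        spec = LagSpec(2, ("a",), (2,), (1,))
        Z, _ = build_regressors(y, {"a": np.zeros(30)}, spec)
        assert np.all(Z[:, spec.n_y:] == 0.0)

    def test_too_short_series_rejected(self):
        spec = LagSpec(5, ("a",), (5,), (5,))
        with pytest.raises(ValueError):
            build_regressors(np.zeros(10), {"a": np.zeros(10)}, spec)

    def test_masked_feature_name_rejected(self):
        spec = LagSpec(1, ("missing",), (1,), (1,))
        with pytest.raises(KeyError):
            build_regressors(np.zeros(20), {"a": np.zeros(20)}, spec)


class TestFit:
    def test_linear_process_recovered_exactly(self, linear_narx_trials):
        spec, proc, trials = linear_narx_trials
        model = NarxModel.from_feature_sets(trials[:6], spec, n_units=8)
        res = model.fit(seed=0)
        assert res.resid_var < 1e-6
        # the wavelet network stays out of the way on linear data
        assert len(res.units) == 0 or np.all(np.abs(res.units.amps) < 1e-6)

    def test_constant_target(self):
        rng = np.random.default_rng(3)
        u = {"a": rng.normal(size=60)}
        y = np.full(60, 0.4)
        spec = LagSpec(1, ("a",), (1,), (1,))
        res = fit_narx([build_regressors(y, u, spec)], spec, n_units=0)
        assert res.y0 == pytest.approx(0.4)
        pred = res.predict(y, u)
        assert np.allclose(pred, 0.4, atol=1e-9)

    def test_quadratic_map_needs_quadratic_columns(self):
        """y(t) = u(t-1)^2: the full regressor set fits far better than a
        linear-only ablation."""
        rng = np.random.default_rng(7)
        u = {"a": rng.normal(size=300)}
        y = np.zeros(300)
        y[1:] = u["a"][:-1] ** 2
        spec = LagSpec(1, ("a",), (1,), (1,))
        Z, tgt = build_regressors(y, u, spec)
        res = fit_narx([(Z, tgt)], spec, n_units=0)
        lin_cols = Z[:, :1 + 2]  # y-lag + linear input lags only
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(tgt)), lin_cols]), tgt, rcond=None)
        mse_lin = np.mean((tgt - np.column_stack(
            [np.ones(len(tgt)), lin_cols]) @ beta) ** 2)
        assert res.resid_var < 0.01 * mse_lin

    def test_non_finite_rejected(self):
        spec = LagSpec(1, ("a",), (1,), (1,))
        Z = np.ones((10, 5))
        Z[3, 2] = np.nan
        with pytest.raises(ValueError):
            fit_narx([(Z, np.ones(10))], spec)

    def test_prediction_formula_as_stored(self, linear_narx_trials):
        """Prediction equals y0 + (z - zbar)' P l + W + S computed from the
        stored pieces."""
        spec, _, trials = linear_narx_trials
        res = NarxModel.from_feature_sets(trials[:3], spec, n_units=4).fit(0)
        fs = trials[3]
        Z, _ = build_regressors(fs.intensity, fs.features, spec)
        manual = (res.y0 + (Z - res.zbar) @ res.projection
                  @ res.linear_weights
                  + res.units.evaluate((Z - res.zbar) @ res.projection))
        assert np.allclose(manual, res.predict_regressors(Z), atol=1e-10)


class TestSimulate:
    def test_parameter_recovery_free_run(self, linear_narx_trials):
        spec, proc, trials = linear_narx_trials
        res = NarxModel.from_feature_sets(trials[:6], spec, n_units=8).fit(0)
        held = trials[6]
        pred = res.simulate(held.intensity, held.features, mode="free-run")
        r = pearson_r(pred, held.intensity[spec.max_lookback:])
        assert r >= 0.99

    def test_zero_weight_model_predicts_offset(self):
        spec = LagSpec(1, ("a",), (1,), (1,))
        y = np.full(50, 0.25)
        u = {"a": np.random.default_rng(0).normal(size=50)}
        res = fit_narx([build_regressors(y, u, spec)], spec, n_units=0)
        sim = res.simulate(y, u, mode="free-run")
        assert np.allclose(sim, 0.25, atol=1e-8)

    def test_one_step_reproduces_training_residuals(self, linear_narx_trials):
        spec, _, trials = linear_narx_trials
        res = NarxModel.from_feature_sets(trials[:1], spec, n_units=0).fit(0)
        fs = trials[0]
        pred = res.simulate(fs.intensity, fs.features, mode="one-step")
        resid = fs.intensity[spec.max_lookback:] - pred
        assert np.mean(resid ** 2) == pytest.approx(res.resid_var, rel=1e-6)

    def test_divergence_guard(self):
        spec = LagSpec(1, ("a",), (1,), (1,))
        rng = np.random.default_rng(2)
        # explosive AR coefficient by construction: y(t) = 2 y(t-1)
        T = 200
        y = np.zeros(T)
        y[0] = 0.01
        for t in range(1, T):
            y[t] = min(2.0 * y[t - 1] + 1e-4, 1e9)
        u = {"a": rng.normal(size=T)}
        res = fit_narx([build_regressors(y[:60], {"a": u["a"][:60]}, spec)],
                       spec, n_units=0)
        with pytest.raises(NarxDivergenceError):
            res.simulate(y, u, mode="free-run", divergence_bound=10.0)

    def test_unknown_mode_rejected(self, linear_narx_trials):
        spec, _, trials = linear_narx_trials
        res = NarxModel.from_feature_sets(trials[:2], spec, n_units=0).fit(0)
        with pytest.raises(ValueError):
            res.simulate(trials[2].intensity, trials[2].features,
                         mode="two-step")


class TestSerialization:
    def test_round_trip_bit_identical(self, tmp_path, linear_narx_trials):
        spec, _, trials = linear_narx_trials
        res = NarxModel.from_feature_sets(trials[:5], spec, n_units=6).fit(3)
        path = tmp_path / "model.npz"
        res.save(path)
        from emonarx.narx import NarxResults
        back = NarxResults.load(path)
        fs = trials[5]
        a = res.simulate(fs.intensity, fs.features)
        b = back.simulate(fs.intensity, fs.features)
        assert np.array_equal(a, b)
        assert back.spec == res.spec

    def test_summary_mentions_structure(self, linear_narx_trials):
        spec, _, trials = linear_narx_trials
        res = NarxModel.from_feature_sets(trials[:2], spec, n_units=0).fit(0)
        text = res.summary()
        assert "n_y" in text and "gsr_filtered" in text


class TestDelayDiscrimination:
    def test_true_spec_beats_wrong_delays_across_replicates(self):
        """LOOCV free-run correlation of the generating lag structure
        exceeds that of a structure whose windows miss the true lags, in
        every one of 10 seeded replicates."""
        from emonarx.evaluate import narx_loocv_correlations
        from emonarx.experiments import make_narx_subject
        spec = LagSpec(2, ("hr_filtered", "rsp_rate"), (2, 1), (2, 1))
        proc = TrueNarxProcess(
            spec, a=(0.55, -0.15), b=((0.30, 0.18, 0.10), (0.25, 0.12)),
            q=((0.06, 0.04, 0.02), (0.05, 0.03)), noise_sd=0.45)
        wrong = LagSpec(2, spec.features, (2, 1), (6, 5))  # misses all lags
        wins = 0
        for seed in range(10):
            trials = make_narx_subject(
                proc, ("hr_filtered", "rsp_rate"), seed=seed,
                smoothness_s=1.0)
            r_true = narx_loocv_correlations(trials, spec, "free-run",
                                             n_units=0).mean()
            r_wrong = narx_loocv_correlations(trials, wrong, "free-run",
                                              n_units=0).mean()
            wins += r_true > r_wrong + 0.01
        assert wins == 10


class TestPearson:
    def test_identity_and_sign(self):
        a = np.array([1.0, 2.0, 4.0, 3.0])
        assert pearson_r(a, a) == pytest.approx(1.0)
        assert pearson_r(a, -a) == pytest.approx(-1.0)

    def test_zero_variance_convention(self):
        a = np.array([1.0, 2.0, 3.0])
        assert pearson_r(a, np.full(3, 7.0)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.zeros(3), np.zeros(4))
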