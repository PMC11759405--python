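import itertools
import warnings

import numpy as np
import pytest
from scipy import stats

from emonarx.evaluate import (EvalConfig, apriori_frequent_sets,
                              compare_models, loocv_evaluate,
                              lr_loocv_correlations, meaningful_features,
                              narx_loocv_correlations, rank_features,
                              summary_stats)
from emonarx.narx import LagSpec, build_regressors, fit_narx, pearson_r
from emonarx.search import GaConfig


class TestSummaryStats:
    def test_single_value(self):
        assert summary_stats([0.42]) == (0.42, 0.0)

    def test_symmetric_triple(self):
        med, mad = summary_stats([0.3, 0.5, 0.7])
        assert med == 0.5 and mad == pytest.approx(0.2)

    def test_unscaled_mad(self):
        vals = [1.0, 2.0, 3.0, 4.0, 100.0]
        med, mad = summary_stats(vals)
        assert med == 3.0
        assert mad == np.median(np.abs(np.array(vals) - 3.0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summary_stats([])


class TestWilcoxon:
    def test_all_zero_differences(self):
        x = {f"s{i}": 0.5 for i in range(10)}
        stat, p = compare_models(x, dict(x))
        assert p == 1.0

    def test_uniform_shift_minimal_p_n21(self):
        """All 21 differences positive: the exact two-sided p is
        2 / 2^21."""
        x = {f"s{i:02d}": 0.6 + 0.001 * i for i in range(21)}
        y = {k: v - 0.1 for k, v in x.items()}
        _, p = compare_models(x, y)
        assert p == pytest.approx(2 / 2 ** 21, rel=1e-9)

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for rep in range(20):
            n = int(rng.integers(8, 25))
            a = rng.normal(size=n)
            b = a + rng.normal(scale=0.5, size=n)
            x = {f"s{i}": float(a[i]) for i in range(n)}
            y = {f"s{i}": float(b[i]) for i in range(n)}
            stat, p = compare_models(x, y)
            ref = stats.wilcoxon(a, b, zero_method="wilcox",
                                 alternative="two-sided", method="exact")
            assert stat == pytest.approx(float(ref.statistic))
            assert p == pytest.approx(float(ref.pvalue))

    def test_low_power_warning(self):
        with pytest.warns(UserWarning):
            compare_models({"a": 1.0, "b": 2.0}, {"a": 0.5, "b": 1.0})


class TestRankFeatures:
    def test_counts_once_per_subject(self):
        sets = {"s1": ["A", "B", "A"], "s2": ["A"], "s3": ["B", "C"]}
        counts = rank_features(sets)
        assert counts["A"] == 2 and counts["B"] == 2 and counts["C"] == 1

    def test_empty_sets_zero_counts(self):
        assert rank_features({"s1": [], "s2": []}) == {}


class TestApriori:
    @staticmethod
    def brute_force(transactions, min_support, max_k):
        sets = [frozenset(t) for t in transactions]
        items = sorted(set().union(*sets)) if sets else []
        out = {}
        for k in range(1, max_k + 1):
            level = {}
            for combo in itertools.combinations(items, k):
                sup = sum(1 for s in sets if set(combo) <= s)
                if sup >= min_support:
                    level[frozenset(combo)] = sup
            if level:
                out[k] = level
        return out

    def test_shared_pair_is_frequent(self):
        transactions = [{"A", "B"}] * 7 + [{"A", "B", "C"}] * 2
        res = apriori_frequent_sets(transactions, min_support=6, max_k=3)
        assert res.frequent(1)[frozenset({"A"})] == 9
        assert res.frequent(2)[frozenset({"A", "B"})] == 9
        assert frozenset({"A", "C"}) not in res.frequent(2)

    def test_equals_exhaustive_oracle_on_random_transactions(self):
        rng = np.random.default_rng(17)
        items = list("ABCDEFGH")
        for rep in range(30):
            n_tx = int(rng.integers(5, 25))
            transactions = [
                set(rng.choice(items, size=rng.integers(0, 5), replace=False))
                for _ in range(n_tx)]
            min_sup = int(rng.integers(2, 7))
            mine = apriori_frequent_sets(transactions, min_sup, max_k=3)
            oracle = self.brute_force(transactions, min_sup, 3)
            got = {k: dict(v) for k, v in mine.itemsets.items() if v}
            assert got == oracle

    def test_apriori_property_holds(self):
        rng = np.random.default_rng(23)
        items = list("ABCDEF")
        transactions = [
            set(rng.choice(items, size=rng.integers(1, 5), replace=False))
            for _ in range(15)]
        res = apriori_frequent_sets(transactions, min_support=3, max_k=3)
        for k in (2, 3):
            for itemset in res.frequent(k):
                for sub in itertools.combinations(itemset, k - 1):
                    assert frozenset(sub) in res.frequent(k - 1)


class TestMeaningfulFeatures:
    def test_threshold_cap_and_exclusion(self):
        sets = {f"s{i}": {"A", "B"} for i in range(6)}
        sets.update({f"t{i}": {"C", "D", "E"} for i in range(7)})
        feats = meaningful_features(sets, masked_anywhere={"C"},
                                    min_support=6, max_features=3)
        assert "C" not in feats
        assert len(feats) <= 3
        assert set(feats) <= {"A", "B", "D", "E"}


class TestLoocv:
    def test_mean_equals_fold_mean_and_symmetry(self, linear_narx_trials):
        spec, _, trials = linear_narx_trials
        # 7 identical trials -> identical fold correlations
        same = [trials[0]] * 7
        rs = narx_loocv_correlations(same, spec, mode="free-run", n_units=0)
        assert np.allclose(rs, rs[0])

    def test_fast_path_matches_reference_fit(self, linear_narx_trials):
        spec, _, trials = linear_narx_trials
        fast = narx_loocv_correlations(trials, spec, mode="one-step",
                                       n_units=0)
        slow = np.empty(len(trials))
        data = [build_regressors(t.intensity, t.features, spec)
                for t in trials]
        for f in range(len(trials)):
            res = fit_narx([d for i, d in enumerate(data) if i != f], spec,
                           n_units=0)
            slow[f] = pearson_r(res.predict_regressors(data[f][0]),
                                data[f][1])
        assert np.allclose(fast, slow, atol=1e-9)

    def test_selection_finds_generating_feature(self, linear_narx_trials):
        spec, _, trials = linear_narx_trials
        config = EvalConfig(
            bounds=(1, 4), n_units=0, seed=0,
            ga=GaConfig(population=12, max_generations=8, stall_window=4))
        cv = loocv_evaluate(trials, "narx", config=config)
        assert cv.features[0] == "gsr_filtered"
        assert cv.mean_r == pytest.approx(float(cv.fold_r.mean()))
        assert cv.fold_r.shape[0] == 7
        assert cv.mean_r > 0.95  # noiseless generator

    def test_lr_pipeline_runs_and_scores(self, linear_narx_trials):
        _, _, trials = linear_narx_trials
        cv = loocv_evaluate(trials, "lr", config=EvalConfig())
        assert cv.model_kind == "lr"
        assert cv.spec is None
        assert cv.fold_r.shape[0] == 7
        assert cv.features  # selected at least one feature

    def test_unknown_model_kind_rejected(self, linear_narx_trials):
        _, _, trials = linear_narx_trials
        with pytest.raises(ValueError):
            loocv_evaluate(trials, "svm")


@pytest.fixture(scope="module")
def population():
    from emonarx.experiments import homogeneous_population
    return homogeneous_population(n_subjects=21, seed=0)


class TestIntersubject:
    def test_lr_split_counts_and_determinism(self, population):
        from emonarx.evaluate import intersubject_evaluate
        feats = ("hr_filtered", "rsp_rate")
        res = intersubject_evaluate(population, feats, model_kind="lr",
                                    repeats=2, seed=3)
        for r in res:
            assert len(r.train_subjects) == 14
            assert len(r.test_subjects) == 7
            assert not set(r.train_subjects) & set(r.test_subjects)
            assert r.n_train_trials == 98
            assert r.n_test_trials == 49
        res2 = intersubject_evaluate(population, feats, model_kind="lr",
                                     repeats=2, seed=3)
        assert [r.mean_r for r in res] == [r.mean_r for r in res2]
        assert [r.train_subjects for r in res] == \
            [r.train_subjects for r in res2]

    def test_narx_transfers_on_homogeneous_population(self, population):
        """All subjects share one generating process, so a model fitted on
        one subset predicts another; leakage-free mode is the honest
        estimate and still scores high."""
        from emonarx.evaluate import intersubject_evaluate
        cfg = EvalConfig(bounds=(1, 4), n_units=0, seed=0,
                         ga=GaConfig(population=10, max_generations=6,
                                     stall_window=3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = intersubject_evaluate(population,
                                        ("hr_filtered", "rsp_rate"),
                                        model_kind="narx", repeats=2,
                                        seed=1, config=cfg,
                                        objective="holdout")
        assert all(r.objective == "holdout" for r in res)
        assert all(r.mean_r > 0.5 for r in res)

    def test_literal_mode_warns_about_leakage(self, population):
        from emonarx.evaluate import intersubject_evaluate
        cfg = EvalConfig(bounds=(1, 2), n_units=0, seed=0,
                         ga=GaConfig(population=8, max_generations=2,
                                     stall_window=2))
        with pytest.warns(UserWarning, match="leakage"):
            intersubject_evaluate(population, ("hr_filtered",),
                                  model_kind="narx", repeats=1, seed=0,
                                  config=cfg, objective="literal")

    def test_small_population_proportional_split(self, population):
        from emonarx.evaluate import intersubject_evaluate
        few = {k: population[k] for k in list(population)[:9]}
        with pytest.warns(UserWarning, match="proportional"):
            res = intersubject_evaluate(few, ("hr_filtered",),
                                        model_kind="lr", repeats=1, seed=0)
        assert len(res[0].train_subjects) == 6
        assert len(res[0].test_subjects) == 3
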