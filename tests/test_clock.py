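"""Mixed-effect clock: EM fits, tuning, CV, importance, comparisons."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import ElasticNet

from tcellclock import clock
from tests.conftest import make_linear_problem


class TestFitMixedML:
    def test_noiseless_interpolation_limit(self):
        X, y, groups, beta = make_linear_problem(200, 5, seed=0, noise=0.0)
        model = clock.fit_mixed_ml(
            X, y, groups, clock.ElasticNetSpec(lam=1e-8, l1_ratio=0.5)
        )
        assert np.allclose(model.fixed_predict(X), y, atol=1e-3)
        assert np.allclose(model.learner.coef_, beta, atol=1e-2)

    def test_single_group_equals_plain_elastic_net(self):
        X, y, groups, _ = make_linear_problem(300, 10, seed=1)
        spec = clock.ElasticNetSpec(lam=0.05, l1_ratio=0.5)
        model = clock.fit_mixed_ml(X, y, groups, spec)
        plain = ElasticNet(alpha=0.05, l1_ratio=0.5, max_iter=5000).fit(X, y)
        assert np.allclose(model.learner.coef_, plain.coef_, atol=1e-6)
        assert model.learner.intercept_ == pytest.approx(
            plain.intercept_, abs=1e-6
        )
        assert model.sigma_b2 == 0.0

    def test_two_group_offsets_recovered(self):
        X, y, groups, _ = make_linear_problem(
            600, 5, seed=2, n_groups=2, noise=0.5, offsets=[4.0, -4.0]
        )
        model = clock.fit_mixed_ml(
            X, y, groups, clock.ElasticNetSpec(lam=0.01, l1_ratio=0.5)
        )
        se = np.sqrt(model.sigma_e2 / 300)
        assert model.random_intercepts["g0"] == pytest.approx(
            4.0, abs=2 * se + 0.5
        )
        assert model.random_intercepts["g1"] == pytest.approx(
            -4.0, abs=2 * se + 0.5
        )
        assert model.converged

    def test_random_intercepts_mean_centered(self):
        X, y, groups, _ = make_linear_problem(
            300, 4, seed=3, n_groups=3, noise=0.5, offsets=[6.0, 1.0, -2.0]
        )
        model = clock.fit_mixed_ml(
            X, y, groups, clock.ElasticNetSpec(lam=0.01)
        )
        assert np.mean(list(model.random_intercepts.values())) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_forest_constant_response(self):
        X, _, groups, _ = make_linear_problem(120, 3, seed=4)
        y = np.full(120, 37.0)
        model = clock.fit_mixed_ml(
            X, y, groups, clock.ForestSpec(n_trees=20, min_node=10, seed=0)
        )
        assert np.allclose(model.fixed_predict(X), 37.0)

    def test_forest_config_honored(self):
        X, y, groups, _ = make_linear_problem(150, 3, seed=5)
        model = clock.fit_mixed_ml(
            X, y, groups, clock.ForestSpec(n_trees=25, min_node=40, seed=1)
        )
        assert model.kind == "MERF"
        assert model.learner.n_estimators == 25
        assert model.learner.min_samples_split == 40
        assert model.learner.bootstrap is True

    def test_merf_recovers_group_offsets(self):
        X, y, groups, _ = make_linear_problem(
            600, 3, seed=6, n_groups=2, noise=0.5, offsets=[5.0, -5.0]
        )
        model = clock.fit_mixed_ml(
            X, y, groups, clock.ForestSpec(n_trees=50, min_node=50, seed=2)
        )
        b = model.random_intercepts
        assert b["g0"] > 2.0 and b["g1"] < -2.0


class TestTuneMeen:
    def test_pure_noise_selects_heavy_penalty(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 20))
        y = rng.normal(size=300)
        lam_star, curve = clock.tune_meen(X, y, n_folds=5, n_lambda=50, seed=0)
        lams = curve["lam"].to_numpy()
        # minimum-MSE lambda sits in the top (most penalized) decade
        assert lam_star >= lams[0] * 10 ** (-1.0)

    def test_strong_signal_selects_interior_lambda(self):
        # many weak-ish predictors: unpenalized fits overfit, so an
        # interior penalty minimizes the CV error
        rng = np.random.default_rng(7)
        X = rng.normal(size=(300, 100))
        y = X @ (rng.normal(size=100) * 0.5) + rng.normal(0, 2.0, 300)
        lam_star, curve = clock.tune_meen(X, y, n_folds=5, n_lambda=50, seed=1)
        lams = curve["lam"].to_numpy()
        assert lams[-1] < lam_star < lams[0]
        assert curve["mean_mse"].min() < 0.25 * y.var()


class TestPredictCellAge:
    def _intercept_model(self, value=40.0, n_feat=4):
        est = ElasticNet(alpha=1.0)
        est.coef_ = np.zeros(n_feat)
        est.intercept_ = value
        est.n_features_in_ = n_feat
        return clock.ClockModel(
            kind="MEEN", learner=est,
            feature_names=[f"g{i}" for i in range(n_feat)],
            random_intercepts={"d1": 3.0}, fixed_offset=0.0,
            sigma_b2=1.0, sigma_e2=1.0, tuning={}, converged=True, n_iter=1,
        )

    def test_intercept_only_and_group_bookkeeping(self):
        model = self._intercept_model()
        X = pd.DataFrame(np.zeros((3, 4)), columns=model.feature_names)
        out = clock.predict_cell_age(model, X)
        assert (out["predicted_age"] == 40.0).all()
        assert not out["used_random_effect"].any()
        out2 = clock.predict_cell_age(model, X, groups=["d1", "d1", "new"])
        assert list(out2["predicted_age"]) == [43.0, 43.0, 40.0]
        assert list(out2["used_random_effect"]) == [True, True, False]

    def test_missing_feature_imputation_and_error(self):
        model = self._intercept_model(n_feat=4)
        X = pd.DataFrame(np.ones((2, 3)),
                         columns=["g0", "g1", "g2"])  # g3 missing
        out = clock.predict_cell_age(model, X)
        assert (out["predicted_age"] == 40.0).all()
        with pytest.raises(ValueError, match="missing"):
            clock.predict_cell_age(
                model, pd.DataFrame(np.ones((2, 1)), columns=["g0"])
            )


class TestCrossValidation:
    def test_fold_partition_and_negative_control(self):
        X, y, groups, _ = make_linear_problem(400, 10, seed=8, noise=0.5)
        preds, rmse, r = clock.cross_validate_clock(
            X, y, groups, clock.ElasticNetSpec(lam=0.05), n_folds=5, seed=0
        )
        assert (preds["fold_id"] >= 0).all()
        assert preds["fold_id"].nunique() == 5
        assert r > 0.8
        # shuffled response destroys the correlation
        rng = np.random.default_rng(1)
        _, _, r0 = clock.cross_validate_clock(
            X, rng.permutation(y), groups, clock.ElasticNetSpec(lam=0.05),
            n_folds=5, seed=0,
        )
        assert abs(r0) < 0.2

    def test_donor_holdout_mode_uses_fixed_part_only(self):
        X, y, groups, _ = make_linear_problem(
            300, 5, seed=9, n_groups=3, noise=0.5, offsets=[3.0, 0.0, -3.0]
        )
        preds, _, _ = clock.cross_validate_clock(
            X, y, groups, clock.ElasticNetSpec(lam=0.05), n_folds=3,
            seed=0, fold_mode="donor",
        )
        assert not preds["used_random_effect"].any()


class TestPermutationImportance:
    def test_informative_feature_ranks_first(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 5))
        y = 3.0 * X[:, 2] + rng.normal(0, 0.3, 400)
        model = clock.fit_mixed_ml(
            X, y, np.full(400, "g"), clock.ElasticNetSpec(lam=0.01),
            feature_names=["a", "b", "signal", "c", "d"],
        )
        imp = clock.permutation_importance(model, X, y, n_repeats=5, seed=0)
        assert imp["feature"].iloc[0] == "signal"
        # zero-coefficient features have ~zero importance
        rest = imp[imp["feature"] != "signal"]["importance"]
        assert (rest.abs() < 0.05 * imp["importance"].iloc[0]).all()

    def test_repeats_tighten_the_estimate(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        y = X[:, 0] + rng.normal(0, 0.5, 200)
        model = clock.fit_mixed_ml(
            X, y, np.full(200, "g"), clock.ElasticNetSpec(lam=0.01)
        )
        few = clock.permutation_importance(model, X, y, n_repeats=3, seed=0)
        many = clock.permutation_importance(model, X, y, n_repeats=30, seed=0)
        assert (
            many.set_index("feature")["importance_se"]["f0"]
            < few.set_index("feature")["importance_se"]["f0"]
        )


class TestCompareGroups:
    def test_identity_shift_and_antisymmetry(self):
        rng = np.random.default_rng(4)
        a = rng.normal(50, 5, 100)
        d0, p0 = clock.compare_groups(a, a)
        assert d0 == 0.0 and p0 == 1.0
        d, p = clock.compare_groups(a, a + 10.0, elapsed_years=1.0)
        assert d == pytest.approx(9.0, abs=1e-9)
        assert p < 1e-6
        dab, _ = clock.compare_groups(a, a + 10.0)
        dba, _ = clock.compare_groups(a + 10.0, a)
        assert dab == pytest.approx(-dba)

    def test_singleton_group_reports_na_p(self):
        d, p = clock.compare_groups([40.0], [50.0, 52.0])
        assert d == pytest.approx(11.0)
        assert np.isnan(p)
        with pytest.raises(ValueError):
            clock.compare_groups([], [1.0])


class TestSerialization:
    def test_meen_round_trip(self, tmp_path):
        X, y, groups, _ = make_linear_problem(
            200, 6, seed=10, n_groups=2, noise=0.5, offsets=[2.0, -2.0]
        )
        model = clock.fit_mixed_ml(
            X, y, groups, clock.ElasticNetSpec(lam=0.02)
        )
        path = tmp_path / "model.json"
        clock.save_model(model, path)
        back = clock.load_model(path)
        Xdf = pd.DataFrame(X, columns=model.feature_names)
        a = clock.predict_cell_age(model, Xdf, groups=groups)
        b = clock.predict_cell_age(back, Xdf, groups=groups)
        assert np.allclose(a["predicted_age"], b["predicted_age"])


def test_sex_is_one_hot_male(small_study):
    _, norm = small_study
    X, feats, _, _ = clock.make_features(norm)
    j = feats.index("sex")
    male = (norm.obs["sex"] == "M").to_numpy()
    assert np.array_equal(X[:, j] == 1.0, male)
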