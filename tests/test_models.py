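"""Filter-model fitting, AICc, elimination, diagnostics and prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import darkneighbors as dn
from darkneighbors.distances import NN, biotic_design_tables, env_predictor_tables
from darkneighbors.models import (
    ModelSpec,
    backward_eliminate,
    build_design,
    compute_aicc,
    diagnose,
    fit_biotic_model,
    fit_env_model,
    interaction_pairs,
    predict_biotic,
    predict_env,
    standardize_predictors,
)

from conftest import make_pool


def irls_logistic(X, y, tol=1e-12, max_iter=200):
    """Independent iteratively-reweighted least-squares oracle."""
    X = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = p * (1 - p)
        z = X @ beta + (y - p) / W
        beta_new = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta


class TestStandardize:
    def test_three_point_column(self):
        Z, const, flags = standardize_predictors(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(Z["x"], [-1.0, 0.0, 1.0])
        assert const.loc["x", "sd"] == pytest.approx(1.0)  # sample sd
        assert not flags

    def test_idempotent_on_standardized_column(self, rng):
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std(ddof=1)
        Z, _, _ = standardize_predictors(pd.DataFrame({"x": x}))
        np.testing.assert_allclose(Z["x"], x, atol=1e-12)

    def test_constant_column_flagged_and_zeroed(self):
        Z, _, flags = standardize_predictors(pd.DataFrame({"x": [2.0, 2.0, 2.0]}))
        assert Z["x"].eq(0.0).all()
        assert flags == ["constant predictor: x"]


class TestAicc:
    def test_closed_form_example(self):
        assert compute_aicc(-10.0, 3, 20) == pytest.approx(27.5)

    def test_reduces_to_aic_for_large_n(self):
        ll, k = -123.4, 5
        aic = -2 * ll + 2 * k
        assert compute_aicc(ll, k, 10**9) == pytest.approx(aic, abs=1e-6)

    def test_matches_independent_formula_on_random_cases(self, rng):
        for _ in range(1000):
            ll = rng.uniform(-500, 0)
            k = int(rng.integers(1, 15))
            n = int(rng.integers(k + 2, 400))
            expected = -2 * ll + 2 * k + (2 * k * (k + 1)) / (n - k - 1)
            assert compute_aicc(ll, k, n) == pytest.approx(expected, rel=1e-12)

    def test_undefined_when_n_too_small(self):
        with pytest.warns(UserWarning):
            assert compute_aicc(-5.0, 4, 5) == float("inf")


class TestEnvModel:
    def _fixture(self, rng, n=150, signal=True):
        x = rng.uniform(0, 1, n)
        eta = 2.0 - 6.0 * x if signal else np.zeros(n)
        y = pd.Series((rng.uniform(size=n) < expit(eta)).astype(int),
                      index=[f"sp{i}" for i in range(n)])
        X = pd.DataFrame({"d": x}, index=y.index)
        return X, y

    def test_matches_irls_oracle(self, rng):
        X, y = self._fixture(rng)
        m = fit_env_model(X, y, ModelSpec("environmental", 1.0, "none"))
        Z, _, _ = standardize_predictors(X)
        oracle = irls_logistic(Z.to_numpy(), y.to_numpy().astype(float))
        np.testing.assert_allclose(
            [m.params["intercept"], m.params["d"]], oracle, atol=1e-5
        )

    def test_permuted_labels_show_no_signal(self, rng):
        X, y = self._fixture(rng, n=300)
        yp = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        m = fit_env_model(X, yp, ModelSpec("environmental", 1.0, "none"))
        assert abs(m.params["d"] / m.bse["d"]) < 3.5

    def test_clustered_pool_gives_negative_distance_coefficient(self, rng):
        traits = pd.DataFrame(
            {"t1": rng.uniform(size=250), "t2": rng.uniform(size=250)},
            index=[f"sp{i}" for i in range(250)],
        )
        d2 = ((traits - 0.5) ** 2).sum(axis=1)
        members = traits.index[rng.uniform(size=250) < np.exp(-d2 / (2 * 0.15**2))]
        pool = make_pool(traits.index, members)
        designs, resp = env_predictor_tables(pool, traits, [0.5], basis="multivariate")
        m = fit_env_model(designs[0.5], resp, ModelSpec("environmental", 0.5, "none"))
        assert m.params["multivariate"] < 0
        assert m.pvalues["multivariate"] < 0.05

    def test_intercept_only_recovers_pool_fraction(self, rng):
        y = pd.Series(rng.permutation([1] * 30 + [0] * 70),
                      index=[f"sp{i}" for i in range(100)])
        X = pd.DataFrame(index=y.index)
        m = fit_env_model(X, y, ModelSpec("environmental", 1.0, "none"))
        assert expit(m.params["intercept"]) == pytest.approx(0.3, abs=1e-6)

    def test_nested_fit_never_below_intercept_only_loglik(self, rng):
        X, y = self._fixture(rng)
        full = fit_env_model(X, y, ModelSpec("environmental", 1.0, "none"))
        null = fit_env_model(pd.DataFrame(index=y.index), y,
                             ModelSpec("environmental", 1.0, "none"))
        assert full.llf >= null.llf - 1e-9


class TestBioticModel:
    def _frame(self, rng, n_plots=6, n_species=30, re_sd=0.0, beta=-2.0):
        rows = []
        b = rng.normal(0, re_sd, n_plots)
        for p in range(n_plots):
            for s in range(n_species):
                x = rng.normal()
                eta = -0.5 + beta * x + b[p]
                rows.append((f"p{p}", f"sp{s}",
                             int(rng.uniform() < expit(eta)), x))
        return pd.DataFrame(rows, columns=["plot_id", "species_id", "present", "dist"])

    def _identical_plots(self, rng, n_plots=10, n_species=40):
        """The same species outcomes replicated across plots: no plot effect."""
        x = rng.normal(size=n_species)
        y = (rng.uniform(size=n_species) < expit(-0.5 - 2.0 * x)).astype(int)
        rows = [
            (f"p{p}", f"sp{s}", int(y[s]), x[s])
            for p in range(n_plots)
            for s in range(n_species)
        ]
        return pd.DataFrame(rows, columns=["plot_id", "species_id", "present", "dist"])

    def test_identical_plot_structure_matches_plain_logistic(self, rng):
        frame = self._identical_plots(rng)
        m = fit_biotic_model(frame, ModelSpec("biotic", 1.0, "none", ("dist",)))
        assert "zero RE variance" in m.degenerate
        import statsmodels.api as sm

        Z, _, _ = standardize_predictors(frame[["dist"]])
        logit = sm.Logit(frame["present"].to_numpy(),
                         sm.add_constant(Z.to_numpy())).fit(disp=0)
        np.testing.assert_allclose(
            [m.params["intercept"], m.params["dist"]], logit.params, atol=1e-4
        )

    def test_detects_plot_heterogeneity(self, rng):
        frame = self._frame(rng, n_plots=25, n_species=40, re_sd=1.0)
        m = fit_biotic_model(frame, ModelSpec("biotic", 1.0, "none", ("dist",)))
        assert m.re_sd > 0.4
        assert m.params["dist"] < 0

    def test_wpe_simulation_gives_negative_coefficient(self):
        cfg = dn.SimulationConfig(biotic_mode=(dn.WPE, "neutral"))
        a = dn.simulate_assembly(cfg, 71)
        frames, _ = biotic_design_tables(a.pool, a.community, a.traits.values, [1.0])
        m = fit_biotic_model(frames[1.0], ModelSpec("biotic", 1.0, "none", ("trait_1",)))
        assert m.params["trait_1"] < 0

    def test_limiting_similarity_gives_positive_nn_coefficient(self):
        cfg = dn.SimulationConfig(biotic_mode=(dn.LS, "neutral"))
        a = dn.simulate_assembly(cfg, 72)
        frames, _ = biotic_design_tables(a.pool, a.community, a.traits.values, [NN])
        m = fit_biotic_model(frames[NN], ModelSpec("biotic", NN, "none", ("trait_1",)))
        assert m.params["trait_1"] > 0


class TestBackwardElimination:
    def _design(self, rng, n=300, n_traits=3):
        X = pd.DataFrame(
            rng.uniform(size=(n, n_traits)),
            columns=[f"t{j}" for j in range(n_traits)],
            index=[f"sp{i}" for i in range(n)],
        )
        eta = 1.5 - 3.0 * X["t0"] - 2.0 * X["t1"]  # no true interactions
        y = pd.Series((rng.uniform(size=n) < expit(eta)).astype(int), index=X.index)
        return X, y

    def _refit(self, X, y):
        def refit(interactions):
            spec = ModelSpec("environmental", 1.0, "parsimonious",
                             tuple(X.columns), tuple(interactions))
            return fit_env_model(X, y, spec)
        return refit

    def test_fixed_point_when_no_drop_improves(self, rng):
        X, y = self._design(rng)
        # keep only a strongly informative structure: elimination of the sole
        # remaining interaction must be accepted or rejected on AICc alone
        refit = self._refit(X, y)
        full = refit([("t0", "t1")])
        best = backward_eliminate(refit, full)
        manual = min([full, refit([])], key=lambda m: m.aicc)
        assert best.aicc == pytest.approx(manual.aicc, abs=1e-9)

    def test_noise_interactions_are_pruned(self, rng):
        X, y = self._design(rng)
        refit = self._refit(X, y)
        pairs = interaction_pairs(X.columns)
        full = refit(pairs)
        best = backward_eliminate(refit, full)
        assert best.aicc <= full.aicc
        assert len(best.spec.interactions) < len(pairs)

    def test_greedy_within_exhaustive_range_and_never_above_full(self, rng):
        from darkneighbors.models import exhaustive_eliminate

        X, y = self._design(rng, n=200)
        refit = self._refit(X, y)
        pairs = interaction_pairs(X.columns)  # 3 pairs -> 8 subsets
        full = refit(pairs)
        greedy = backward_eliminate(refit, full)
        exact = exhaustive_eliminate(refit, full)
        assert greedy.aicc <= full.aicc + 1e-9
        assert exact.aicc <= greedy.aicc + 1e-9  # exact optimum bounds greedy
        assert exact.aicc <= full.aicc + 1e-9

    def test_exhaustive_search_refuses_large_term_sets(self, rng):
        from darkneighbors.models import exhaustive_eliminate

        X, y = self._design(rng, n=200)
        refit = self._refit(X, y)
        many = [(f"a{i}", f"b{i}") for i in range(7)]
        full = refit([])
        full.spec = full.spec.with_interactions(many)
        with pytest.raises(ValueError, match="exhaustive"):
            exhaustive_eliminate(refit, full)


class TestDiagnose:
    def test_runaway_quasi_separated_low_variance_fixture(self):
        x = np.concatenate([np.ones(100), np.full(100, 1.001)])
        y = pd.Series(np.concatenate([np.r_[np.zeros(50), np.ones(50)],
                                      np.ones(100)]).astype(int))
        X = pd.DataFrame({"d": x}, index=y.index)
        m = fit_env_model(X, y, ModelSpec("environmental", NN, "none"))
        flags = diagnose(m, X)
        assert any(f.startswith("runaway estimate") for f in flags)
        assert any(f.startswith("insufficient distance variation") for f in flags)
        assert abs(m.params["d"]) > 10 and m.pvalues["d"] > 0.95

    def test_well_conditioned_fit_is_clean(self, rng):
        x = rng.uniform(0, 1, 200)
        y = pd.Series((rng.uniform(size=200) < expit(1 - 3 * x)).astype(int))
        X = pd.DataFrame({"d": x}, index=y.index)
        m = fit_env_model(X, y, ModelSpec("environmental", 0.5, "none"))
        assert diagnose(m, X) == []

    def test_constant_predictor_flagged(self, rng):
        y = pd.Series(rng.integers(0, 2, 60).astype(int))
        X = pd.DataFrame({"d": rng.uniform(size=60), "c": 0.7}, index=y.index)
        m = fit_env_model(X, y, ModelSpec("environmental", 0.5, "none"))
        flags = diagnose(m, X)
        assert "insufficient distance variation: c" in flags


class TestPrediction:
    def test_zero_standardized_predictors_give_intercept_probability(self, rng):
        x = rng.uniform(0, 1, 120)
        y = pd.Series((rng.uniform(size=120) < expit(0.5 - 2 * x)).astype(int))
        X = pd.DataFrame({"d": x}, index=y.index)
        m = fit_env_model(X, y, ModelSpec("environmental", 0.5, "none"))
        at_mean = pd.DataFrame({"d": [X["d"].mean()]}, index=["new"])
        assert predict_env(m, at_mean)["new"] == pytest.approx(
            expit(m.params["intercept"]), abs=1e-10
        )

    def test_standardization_round_trip(self, rng):
        x = rng.uniform(0, 1, 150)
        y = pd.Series((rng.uniform(size=150) < expit(1 - 4 * x)).astype(int))
        X = pd.DataFrame({"d": x}, index=y.index)
        spec = ModelSpec("environmental", 0.5, "none")
        m = fit_env_model(X, y, spec)
        direct = predict_env(m, X)
        Z, _, _ = build_design(X, m.spec, m.constants)
        manual = expit(m.params["intercept"] + Z["d"] * m.params["d"])
        np.testing.assert_allclose(direct, manual, atol=1e-10)
        assert ((direct > 0) & (direct < 1)).all()

    def test_biotic_average_over_plots(self, rng):
        frame = TestBioticModel()._frame(rng, n_plots=8, n_species=25, re_sd=0.8)
        m = fit_biotic_model(frame, ModelSpec("biotic", 1.0, "none", ("dist",)))
        new = pd.DataFrame({
            "plot_id": [f"p{i}" for i in range(8)],
            "species_id": "col1",
            "dist": 0.4,
        })
        per_plot, avg = predict_biotic(m, new)
        assert avg["col1"] == pytest.approx(per_plot["p_biotic"].mean())
        pop_plot, pop_avg = predict_biotic(m, new, re_prediction="population")
        assert pop_plot["p_biotic"].nunique() == 1  # same predictors, RE zeroed

    def test_zero_re_model_per_plot_equals_fixed_effect_prediction(self, rng):
        frame = TestBioticModel()._identical_plots(rng)
        m = fit_biotic_model(frame, ModelSpec("biotic", 1.0, "none", ("dist",)))
        assert "zero RE variance" in m.degenerate
        new = pd.DataFrame({
            "plot_id": [f"p{i}" for i in range(10)],
            "species_id": "col1",
            "dist": 0.1,
        })
        per_plot, avg = predict_biotic(m, new)
        assert per_plot["p_biotic"].nunique() == 1
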