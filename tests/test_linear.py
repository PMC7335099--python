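"""Bayesian linear regression, exact LOO, model grammar and screening."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from forestdiv.bayes import (
    BayesianLinearModel,
    enumerate_models,
    loo_compare,
    prune_correlated,
    soil_pca,
)
from forestdiv.bayes.loo import exact_loo
from forestdiv.bayes.models import ModelSpec


class TestFit:
    def test_slope_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        y = 2.0 * x + rng.normal(0, 0.1, 100)
        res = BayesianLinearModel(y, pd.DataFrame({"x": x})).fit(seed=1)
        assert 1.9 < np.median(res.coef_draws_raw("x")) < 2.1
        assert res.converged

    def test_intercept_only_matches_sample_mean(self):
        rng = np.random.default_rng(1)
        y = rng.normal(3.0, 1.0, 100)
        res = BayesianLinearModel(y, pd.DataFrame(index=range(100))).fit(
            seed=2
        )
        sem = y.std(ddof=1) / 10
        assert abs(np.median(res.coef_draws("intercept")) - y.mean()) < 2 * sem

    def test_noise_covariate_large_rope_on_average(self):
        rng = np.random.default_rng(2)
        ropes = []
        for k in range(10):
            noise = rng.normal(size=100)
            y = rng.normal(0, 1, 100)
            res = BayesianLinearModel(y, pd.DataFrame({"z": noise})).fit(
                chains=2, iterations=1000, seed=3 + k
            )
            ropes.append(res.rope("z"))
        assert np.mean(ropes) > 0.5

    def test_standardize_backtransform_round_trip(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({
            "a": 100 + 50 * rng.normal(size=60),
            "b": rng.normal(size=60) * 1e-3,
        })
        y = 0.01 * X["a"].to_numpy() + 200 * X["b"].to_numpy() \
            + rng.normal(0, 0.4, 60)
        Z = (X - X.mean()) / X.std(ddof=1)
        r_raw = BayesianLinearModel(y, X).fit(seed=4)
        r_std = BayesianLinearModel(y, Z).fit(seed=4)
        for term in ("a", "b"):
            d1, d2 = r_raw.coef_draws(term), r_std.coef_draws(term)
            mc = d1.std() / np.sqrt(200)  # generous effective-size bound
            assert abs(np.median(d1) - np.median(d2)) < 6 * mc

    def test_constant_predictor_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"c": np.ones(30), "x": rng.normal(size=30)})
        with caplog.at_level("WARNING"):
            m = BayesianLinearModel(rng.normal(size=30), X)
        assert m.term_names == ["intercept", "x"]
        assert "constant" in caplog.text

    def test_summary_has_table_columns(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        res = BayesianLinearModel(
            x + rng.normal(size=40), pd.DataFrame({"x": x})
        ).fit(chains=2, iterations=800, seed=6)
        s = res.summary()
        assert {"median", "hdi50_l", "hdi89_h", "hdi95_l", "rope",
                "rhat"} <= set(s.columns)
        assert list(s.index) == ["intercept", "x"]


class TestLOO:
    def test_looic_is_minus_twice_elpd(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=15)
        y = x + rng.normal(0, 0.5, 15)
        loo = exact_loo(BayesianLinearModel(y, pd.DataFrame({"x": x})),
                        seed=1)
        assert loo.looic == pytest.approx(-2 * loo.elpd, abs=1e-9)

    def test_seed_stability_within_mc_error(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=15)
        y = x + rng.normal(0, 0.5, 15)
        m = BayesianLinearModel(y, pd.DataFrame({"x": x}))
        l1 = exact_loo(m, chains=2, iterations=1500, seed=10)
        l2 = exact_loo(m, chains=2, iterations=1500, seed=20)
        tol = 2 * np.sqrt(l1.se**2 / len(l1.pointwise)
                          + l2.se**2 / len(l2.pointwise)) + 0.5
        assert abs(l1.elpd - l2.elpd) < tol

    def test_mismatched_response_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        l1 = exact_loo(BayesianLinearModel(
            x + rng.normal(size=12), pd.DataFrame({"x": x})), seed=1)
        l2 = exact_loo(BayesianLinearModel(
            rng.normal(size=12), pd.DataFrame({"x": x})), seed=1)
        with pytest.raises(ValueError, match="different response"):
            loo_compare([l1, l2])

    def test_ranking_prefers_true_covariate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=21)
        z = rng.normal(size=21)
        y = x + rng.normal(0, 0.7, 21)
        la = exact_loo(BayesianLinearModel(y, pd.DataFrame({"x": x})), seed=4)
        lb = exact_loo(BayesianLinearModel(y, pd.DataFrame({"z": z})), seed=5)
        assert la.elpd > lb.elpd

    def test_elpd_matches_quadrature_oracle(self):
        """Refit-LOO against sigma-grid quadrature with conjugate beta."""
        rng = np.random.default_rng(6)
        n = 12
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(0, 0.6, n)
        X = pd.DataFrame({"x": x})
        model = BayesianLinearModel(y, X)
        loo = exact_loo(model, chains=3, iterations=4000, seed=7)

        def oracle_point(i):
            mask = np.arange(n) != i
            sub = BayesianLinearModel(
                y[mask], X.iloc[mask].reset_index(drop=True),
                sigma_prior_rate=model.sigma_prior_rate,
            )
            Z, yy = sub.Z, sub.y
            xstar = np.concatenate(
                [[1.0], (X.iloc[i].to_numpy() - sub._mean) / sub._sd]
            )
            prior_cov = np.linalg.inv(sub._prior_prec)
            sigmas = np.geomspace(sub.sd_y / 60, sub.sd_y * 60, 600)
            log_post = np.empty(len(sigmas))
            pred_mu = np.empty(len(sigmas))
            pred_var = np.empty(len(sigmas))
            for k, s in enumerate(sigmas):
                cov_y = s**2 * np.eye(len(yy)) + Z @ prior_cov @ Z.T
                sign, logdet = np.linalg.slogdet(cov_y)
                log_ml = -0.5 * (logdet + yy @ np.linalg.solve(cov_y, yy)
                                 + len(yy) * np.log(2 * np.pi))
                log_prior = -model.sigma_prior_rate * s
                log_post[k] = log_ml + log_prior + np.log(s)  # log-grid meas.
                Q = Z.T @ Z / s**2 + sub._prior_prec
                mean = np.linalg.solve(Q, Z.T @ yy / s**2)
                V = np.linalg.inv(Q)
                pred_mu[k] = xstar @ mean
                pred_var[k] = s**2 + xstar @ V @ xstar
            w = log_post - logsumexp(log_post)
            dens = norm.logpdf(y[i], pred_mu, np.sqrt(pred_var))
            return logsumexp(w + dens)

        for i in range(n):
            assert loo.pointwise[i] == pytest.approx(
                oracle_point(i), abs=0.05
            )


class TestModelGrammar:
    def test_default_grammar_has_35_specs_with_plot_area(self):
        specs = enumerate_models("d_fdis_r")
        assert len(specs) == 35
        assert all("plot_area" in s.main_terms for s in specs)
        names = [s.name for s in specs]
        assert len(set(names)) == 35

    def test_interaction_terms_pair_soil_with_climate(self):
        specs = enumerate_models("d_mpd_r")
        for s in specs:
            for pc, cl in s.interaction_terms:
                assert pc.startswith("PC")
                assert not cl.startswith("PC")
        full = max(specs, key=lambda s: len(s.interaction_terms))
        assert len(full.interaction_terms) == 9

    def test_no_interactions_without_config(self):
        spec = ModelSpec("y", ("a", "plot_area"))
        assert all(":" not in t for t in spec.term_names)

    def test_design_matrix_builds_products(self):
        data = pd.DataFrame({
            "y": [1.0, 2.0, 3.0], "a": [1.0, 2.0, 3.0],
            "b": [2.0, 0.5, 1.0], "plot_area": [1.0, 1.0, 0.5],
        })
        spec = ModelSpec("y", ("a", "b", "plot_area"), (("a", "b"),))
        _, X = spec.build_design(data)
        assert np.allclose(X["a:b"], data["a"] * data["b"])


class TestScreening:
    def test_duplicate_column_pruned_by_priority(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"keep": x, "drop": x * 2.0})
        assert prune_correlated(df, priority=["keep"]) == ["keep"]

    def test_threshold_is_strict(self):
        # |r| just under the cutoff is kept, just over it is dropped
        rng = np.random.default_rng(1)
        a = rng.normal(size=2000)
        e = rng.normal(size=2000)
        e -= a * (a @ e) / (a @ a)  # orthogonal residual

        def pair(r):
            b = r * (a - a.mean()) / a.std() \
                + np.sqrt(1 - r**2) * (e - e.mean()) / e.std()
            return pd.DataFrame({"a": a, "b": b})

        assert prune_correlated(pair(0.69), threshold=0.7) == ["a", "b"]
        assert prune_correlated(pair(0.71), threshold=0.7,
                                priority=["a"]) == ["a"]

    def test_independent_drivers_all_retained(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(1000, 5)),
                          columns=list("abcde"))
        assert prune_correlated(df) == list("abcde")

    def test_constant_driver_dropped(self, caplog):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"c": np.ones(50), "x": rng.normal(size=50),
                           "y": rng.normal(size=50)})
        with caplog.at_level("WARNING"):
            got = prune_correlated(df)
        assert got == ["x", "y"]


@pytest.fixture(scope="module")
def noisy_table():
    from forestdiv.simulate import generate_soils

    return generate_soils(21, seed=5)


class TestSoilPCA:
    def test_variance_fractions_sum_to_one(self, noisy_table):
        res = soil_pca(noisy_table)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)

    def test_scores_reproduce_from_loadings(self, noisy_table):
        res = soil_pca(noisy_table)
        X = noisy_table.to_numpy(dtype=float)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        assert np.allclose(
            Z @ res.loadings.to_numpy(), res.scores.to_numpy(), atol=1e-8
        )

    def test_axes_orthogonal(self, noisy_table):
        res = soil_pca(noisy_table)
        sel = res.scores[res.selected_axes].to_numpy()
        c = np.corrcoef(sel, rowvar=False)
        off = c[~np.eye(len(res.selected_axes), dtype=bool)]
        assert np.all(np.abs(off) < 1e-8)

    def test_ten_percent_selection_rule(self):
        rng = np.random.default_rng(7)
        # construct data with known variance profile via scaled factors
        base = rng.normal(size=(200, 6))
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        X = base @ np.diag([5.0, 2.0, 1.5, 0.4, 0.3, 0.2]) @ q
        res = soil_pca(pd.DataFrame(X, columns=list("abcdef")))
        assert len(res.selected_axes) == 3

    def test_rank3_table_has_three_positive_axes(self):
        from forestdiv.simulate import generate_soils

        res = soil_pca(generate_soils(40, seed=1, noise_sd=0.0))
        assert len(res.selected_axes) == 3
        assert np.all(res.variance_fraction.to_numpy()[3:] < 1e-10)

    def test_sign_convention(self, noisy_table):
        res = soil_pca(noisy_table)
        for ax in res.loadings.columns:
            lead = res.loadings[ax].abs().idxmax()
            assert res.loadings.loc[lead, ax] > 0
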