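"""Model-fitting checks against independent optimizers and implementations."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from packmark import synthetic
from packmark.inference import (
    SeparationError,
    expand_terms,
    fit_logratio,
    fit_rpsf,
    fit_rsf,
)


def _toy_rsf_design(rng, n_used=60, ratio=5, beta=(0.8, -0.5), packs=2):
    """Weighted design with used rows upweighted toward exp(beta.x)."""
    n_avail = ratio * n_used
    rows = []
    for pid in range(packs):
        xa = rng.normal(size=(n_avail // packs, 2))
        # used covariates sampled with density prop to exp(beta.x) under N(0,1):
        # that tilted density is again normal with mean beta (per axis)
        xu = rng.normal(loc=beta, size=(n_used // packs, 2))
        for x in xu:
            rows.append({"x1": x[0], "x2": x[1], "response": 1, "weight": 1.0,
                         "pack_id": f"p{pid}"})
        for x in xa:
            rows.append({"x1": x[0], "x2": x[1], "response": 0, "weight": 100.0,
                         "pack_id": f"p{pid}"})
    return pd.DataFrame(rows)


class TestFitRSF:
    def test_null_covariate_has_small_coefficient(self, rng):
        df = _toy_rsf_design(rng, n_used=100, beta=(0.0, 0.0))
        fit = fit_rsf(df, ["x1", "x2"])
        for t in ("x1", "x2"):
            assert abs(fit.beta[t]) < 2.0 * fit.se[t]

    def test_matches_independent_weighted_optimizer(self, rng):
        # brute-force maximization of the same weighted Bernoulli likelihood
        # with Nelder-Mead, fully independent of the Newton path
        df = _toy_rsf_design(rng, n_used=20, ratio=9, packs=1)
        fit = fit_rsf(df, ["x1", "x2"])
        X = np.column_stack(
            [np.ones(len(df)), df["x1"].to_numpy(), df["x2"].to_numpy()]
        )
        y = df["response"].to_numpy(float)
        w = df["weight"].to_numpy(float)

        def negll(b):
            eta = X @ b
            return -np.sum(w * (y * eta - np.logaddexp(0.0, eta)))

        start = np.array(
            [fit.intercepts["p0"], fit.beta["x1"], fit.beta["x2"]]
        ) + 0.3
        res = optimize.minimize(negll, start, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
        assert fit.beta["x1"] == pytest.approx(res.x[1], abs=1e-5)
        assert fit.beta["x2"] == pytest.approx(res.x[2], abs=1e-5)

    def test_recovers_known_coefficients(self, rng):
        df = _toy_rsf_design(rng, n_used=200, ratio=14, beta=(0.8, -0.5))
        fit = fit_rsf(df, ["x1", "x2"])
        # single replicate: 3-SE band (the 2-SE coverage rate is asserted
        # over replicates in the acceptance suite)
        assert abs(fit.beta["x1"] - 0.8) < 3 * fit.se["x1"]
        assert abs(fit.beta["x2"] + 0.5) < 3 * fit.se["x2"]

    def test_unit_weights_reduce_to_ordinary_logistic(self, rng):
        import statsmodels.api as sm

        df = _toy_rsf_design(rng, n_used=80, ratio=4, packs=1)
        df["weight"] = 1.0
        fit = fit_rsf(df, ["x1", "x2"])
        X = sm.add_constant(df[["x1", "x2"]].to_numpy())
        ref = sm.GLM(df["response"].to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        assert fit.beta["x1"] == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.beta["x2"] == pytest.approx(ref.params[2], abs=1e-6)
        assert fit.se["x1"] == pytest.approx(ref.bse[1], rel=1e-4)

    def test_loglik_monotone_across_iterations(self, rng):
        df = _toy_rsf_design(rng, n_used=50)
        fit = fit_rsf(df, ["x1", "x2"])
        trace = np.array(fit.extra["loglik_trace"])
        assert (np.diff(trace) >= -1e-10).all()
        assert fit.converged

    def test_doubling_availability_changes_slopes_little(self, rng):
        # weighted used/available estimates are design-robust: ratio 30 vs
        # 15 moves each slope by less than one standard error
        seed_rng = np.random.default_rng(17)
        df15 = _toy_rsf_design(seed_rng, n_used=200, ratio=15, packs=1)
        seed_rng = np.random.default_rng(17)
        df30 = _toy_rsf_design(seed_rng, n_used=200, ratio=30, packs=1)
        f15 = fit_rsf(df15, ["x1", "x2"])
        f30 = fit_rsf(df30, ["x1", "x2"])
        for t in ("x1", "x2"):
            assert abs(f15.beta[t] - f30.beta[t]) < f15.se[t]

    def test_complete_separation_raises(self):
        df = pd.DataFrame(
            {
                "x1": np.concatenate([np.ones(30), -np.ones(30)]),
                "response": [1] * 30 + [0] * 30,
                "weight": 1.0,
                "pack_id": "p0",
            }
        )
        with pytest.raises(SeparationError):
            fit_rsf(df, ["x1"])

    def test_single_class_rejected(self):
        df = pd.DataFrame({"x1": [0.1, 0.2], "response": [1, 1],
                           "weight": [1.0, 1.0], "pack_id": "p0"})
        with pytest.raises(ValueError):
            fit_rsf(df, ["x1"])


def _toy_rpsf_design(rng, n_follows=8, n_events=40, beta=(0.9,), a=-0.5):
    rows = []
    for f in range(n_follows):
        x = rng.normal(size=n_events)
        p = 1 / (1 + np.exp(-(a + beta[0] * x)))
        y = (rng.random(n_events) < p).astype(int)
        for xi, yi in zip(x, y):
            rows.append({"pack_id": f"p{f % 2}", "follow_id": f"F{f}",
                         "x1": xi, "response": yi})
    return pd.DataFrame(rows)


class TestFitRPSF:
    def test_fitted_probabilities_in_unit_interval(self, rng):
        df = _toy_rpsf_design(rng)
        fit = fit_rpsf(df, ["x1"])
        p = fit.extra["fitted"]
        assert ((p > 0) & (p < 1)).all()

    def test_matches_independent_optimizer_on_small_design(self, rng):
        df = _toy_rpsf_design(rng, n_follows=3, n_events=30)
        fit = fit_rpsf(df, ["x1"])
        # independent route: statsmodels logistic with the same dummies
        import statsmodels.api as sm

        D = pd.get_dummies(
            df["pack_id"].astype(str) + "|" + df["follow_id"].astype(str)
        ).to_numpy(float)
        X = np.hstack([D, df[["x1"]].to_numpy()])
        ref = sm.GLM(df["response"].to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        assert fit.beta["x1"] == pytest.approx(ref.params[-1], abs=1e-6)

    def test_single_class_follow_dropped_with_warning(self, rng):
        df = _toy_rpsf_design(rng, n_follows=4)
        allzero = df["follow_id"] == "F0"
        df.loc[allzero, "response"] = 0
        with pytest.warns(UserWarning, match="single-class"):
            fit = fit_rpsf(df, ["x1"])
        assert fit.n == int((~allzero).sum())

    def test_recovers_truth_from_simulated_follows(self, sim_config, layers, events):
        # fitting the generator's own logistic model on its follows recovers
        # the configured coefficients within two standard errors
        center, scale = synthetic.layer_standardization(layers)
        df = events.copy()
        df["response"] = (df["behavior_class"] == "scent_mark").astype(int)
        for term in sim_config.truth_beta:
            lname = term.removeprefix("dist_")
            df[term] = (
                layers[lname].sample(df["x"], df["y"]) - center[term]
            ) / scale[term]
        # keep follows with both classes (as the model requires)
        fit = fit_rpsf(df, list(sim_config.truth_beta))
        for term, truth in sim_config.truth_beta.items():
            assert abs(fit.beta[term] - truth) < 2.5 * fit.se[term]

    def test_random_intercept_variant_close_to_truth(self, rng):
        df = _toy_rpsf_design(rng, n_follows=12, n_events=60, beta=(0.9,))
        fit = fit_rpsf(df, ["x1"], intercepts="random")
        assert fit.model == "rpsf_random"
        assert abs(fit.beta["x1"] - 0.9) < 0.3


class TestFitLogratio:
    def _balanced_af(self, rng, n_packs=4, per_pack=10, beta=1.2, tau=0.5,
                     sigma=0.4):
        return synthetic.simulate_aggregates(
            rng, n_packs, per_pack, {"x1": beta}, intercept=0.7,
            sigma=sigma, tau=tau,
        )

    def test_zero_between_pack_variance_equals_ols(self, rng):
        # tau = 0: REML boundary estimate degenerates to OLS
        af = self._balanced_af(rng, n_packs=6, per_pack=12, tau=0.0)
        fit = fit_logratio(af, ["x1"])
        X = np.column_stack([np.ones(len(af)), af["x1"]])
        ols = np.linalg.lstsq(X, af["log_ratio"], rcond=None)[0]
        if fit.extra["zero_variance"]:
            assert fit.beta["(intercept)"] == pytest.approx(ols[0], abs=1e-8)
            assert fit.beta["x1"] == pytest.approx(ols[1], abs=1e-8)
        else:
            # tiny estimated variance: still nearly OLS
            assert fit.beta["x1"] == pytest.approx(ols[1], abs=1e-3)

    def test_intercept_only_balanced_equals_grand_mean_at_boundary(self, rng):
        af = self._balanced_af(rng, n_packs=3, per_pack=8, beta=0.0, tau=0.0)
        fit = fit_logratio(af, [])
        if fit.extra["zero_variance"]:
            assert fit.beta["(intercept)"] == pytest.approx(
                af["log_ratio"].mean(), abs=1e-8
            )
        else:
            # with balanced groups GLS intercept equals the grand mean too
            assert fit.beta["(intercept)"] == pytest.approx(
                af["log_ratio"].mean(), abs=1e-6
            )

    def test_matches_statsmodels_mixedlm_reml(self, rng):
        import statsmodels.formula.api as smf

        af = self._balanced_af(rng, n_packs=5, per_pack=9)
        fit = fit_logratio(af, ["x1"])
        ref = smf.mixedlm("log_ratio ~ x1", af, groups=af["pack_id"]).fit(
            reml=True, method="lbfgs"
        )
        assert fit.beta["(intercept)"] == pytest.approx(
            ref.params["Intercept"], abs=1e-4
        )
        assert fit.beta["x1"] == pytest.approx(ref.params["x1"], abs=1e-4)
        assert fit.extra["sigma2"] == pytest.approx(ref.scale, rel=1e-3)
        assert fit.extra["tau2"] == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=1e-2, abs=1e-4
        )

    def test_recovers_truth_within_two_se(self, rng):
        af = self._balanced_af(rng, n_packs=8, per_pack=15, beta=1.2)
        fit = fit_logratio(af, ["x1"])
        assert abs(fit.beta["x1"] - 1.2) < 2 * fit.se["x1"]

    def test_needs_two_packs(self, rng):
        af = self._balanced_af(rng, n_packs=4)
        single = af[af["pack_id"] == "pack_0"]
        with pytest.raises(ValueError):
            fit_logratio(single, ["x1"])


class TestExpandTerms:
    def test_interaction_is_product(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        X = expand_terms(df, ["a", "b", "a:b"])
        np.testing.assert_allclose(X[:, 2], [3.0, 8.0])

    def test_missing_component_named(self):
        df = pd.DataFrame({"a": [1.0]})
        with pytest.raises(KeyError, match="zzz"):
            expand_terms(df, ["a:zzz"])
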