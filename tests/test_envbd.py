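"""Environment-dependent birth-death likelihoods, fits, and model comparison."""
import math

import numpy as np
import pandas as pd
import pytest

from andesdiv import envbd, simulate
from andesdiv.envbd import (
    EnvBDParams,
    build_env_function,
    fit_envbd,
    loglik_constant_bd,
    loglik_envbd,
    present_rate,
)
from andesdiv.fitting import ModelFit, compare_models
from andesdiv.simulate import UpliftCurveSpec, make_uplift_curve


def flat_env(elev=1500.0):
    ages = np.linspace(0, 30, 31)
    return build_env_function(
        pd.DataFrame({"age_ma": ages, "elev_m": np.full_like(ages, elev)}),
        smoothing=0.0,
    )


class TestEnvCurve:
    def test_constant_samples_give_constant_curve(self):
        env = flat_env(1500.0)
        t = np.linspace(0, 40, 100)  # includes constant extension beyond range
        np.testing.assert_allclose(env.elevation(t), 1500.0, atol=1e-8)

    def test_zero_smoothing_interpolates_samples(self):
        spec = UpliftCurveSpec()
        df = make_uplift_curve(spec, t_max=20, n=41)
        env = build_env_function(df, smoothing=0.0)
        np.testing.assert_allclose(
            env.elevation(df.age_ma.to_numpy()), df.elev_m.to_numpy(), atol=1e-6
        )

    def test_dense_refit_tracks_generator(self):
        spec = UpliftCurveSpec()
        df = make_uplift_curve(spec, t_max=20, n=201)
        env = build_env_function(df)  # GCV smoothing
        t = np.linspace(0, 20, 500)
        err = np.max(np.abs(env.elevation(t) - spec.elevation(t)))
        assert err < 0.01 * spec.e_max

    def test_input_validation(self):
        with pytest.raises(ValueError):
            build_env_function(pd.DataFrame({"age_ma": [0, 1, 2], "elev_m": [1, 2, 3]}))
        with pytest.raises(ValueError):
            build_env_function(
                pd.DataFrame({"age_ma": [0, 1, 1, 2], "elev_m": [1, 2, 3, 4]})
            )


class TestLikelihoods:
    def test_two_tip_pure_birth_closed_form(self, two_tip_tree):
        # P(no speciation on either crown branch) = exp(-2 lambda T)
        p = EnvBDParams(0.1, 0, 0, 0, 1.0, "constant", "constant")
        ll = loglik_envbd(two_tip_tree, p, None, condition_on_survival=False)
        assert ll == pytest.approx(-2.0, abs=1e-9)
        cf = loglik_constant_bd(two_tip_tree, 0.1, 0.0, 1.0,
                                condition_on_survival=False)
        assert cf == pytest.approx(-2.0, abs=1e-12)

    @pytest.mark.parametrize("cond", [True, False])
    def test_ode_matches_closed_form_on_simulated_trees(self, cond):
        for seed in range(10):
            lam, mu, f = 0.25, 0.1, 0.6
            tree = simulate.simulate_bd_tree(lam, mu, 12.0, f=f, seed=seed)
            p = EnvBDParams(lam, 0, mu, 0, f, "constant", "constant")
            a = loglik_envbd(tree, p, None, condition_on_survival=cond)
            b = loglik_constant_bd(tree, lam, mu, f, condition_on_survival=cond)
            assert a == pytest.approx(b, abs=1e-6)

    def test_sampling_fraction_changes_likelihood(self):
        tree = simulate.simulate_bd_tree(0.3, 0.1, 10.0, seed=3)
        lls = [
            loglik_envbd(
                tree, EnvBDParams(0.3, 0, 0.3, 0, f, "constant", "constant"), None
            )
            for f in (1.0, 0.5)
        ]
        assert abs(lls[0] - lls[1]) > 1e-3

    def test_env_form_with_alpha_zero_equals_constant_form(self):
        tree = simulate.simulate_bd_tree(0.3, 0.05, 8.0, seed=5)
        env = flat_env(2000.0)
        a = loglik_envbd(tree, EnvBDParams(0.3, 0.0, 0.05, 0.0, 1.0, "env", "env"), env)
        b = loglik_envbd(
            tree, EnvBDParams(0.3, 0.0, 0.05, 0.0, 1.0, "constant", "constant"), None
        )
        assert a == pytest.approx(b, abs=1e-9)

    def test_tip_label_permutation_invariance(self):
        tree = simulate.simulate_bd_tree(0.3, 0.05, 8.0, seed=6)
        relabeled = simulate.simulate_bd_tree(0.3, 0.05, 8.0, seed=6)
        relabeled.labels = [f"x_{lab}" for lab in relabeled.labels]
        p = EnvBDParams(0.2, 0, 0.05, 0, 1.0, "constant", "constant")
        assert loglik_envbd(tree, p, None) == pytest.approx(
            loglik_envbd(relabeled, p, None), abs=1e-12
        )

    def test_zero_speciation_signals_minus_inf(self, two_tip_tree):
        p = EnvBDParams(0.0, 0, 0.1, 0, 1.0, "constant", "constant")
        assert loglik_envbd(two_tip_tree, p, None) == -np.inf

    def test_constant_bd_rejects_nonpositive_lambda(self, two_tip_tree):
        with pytest.raises(ValueError):
            loglik_constant_bd(two_tip_tree, 0.0, 0.0)


class TestFitting:
    def test_optimum_at_least_as_good_as_truth(self):
        env = flat_env(2000.0)
        for seed in (0, 1):
            tree = simulate.simulate_bd_tree(0.3, 0.1, 10.0, seed=seed)
            fit = fit_envbd(tree, env, lambda_form="constant", seed=seed,
                            compute_ci=False)
            truth_ll = loglik_envbd(
                tree, EnvBDParams(0.3, 0, 0.1, 0, 1.0, "constant", "constant"), None
            )
            assert fit.logL >= truth_ll - 1e-6

    def test_time_exponential_variant_fits(self):
        tree = simulate.simulate_bd_tree(0.3, 0.05, 10.0, seed=2)
        fit = fit_envbd(tree, None, lambda_form="time", seed=0, compute_ci=False)
        assert fit.k == 3 and np.isfinite(fit.logL)

    def test_present_rate_arithmetic(self):
        base = dict(model="bd(lambda~env, mu~constant)", logL=-1.0, k=3,
                    n_obs=50, converged=True, n_restarts=1, data_id="x")
        env = flat_env(2000.0)
        fit = ModelFit(params={"lambda0": 0.1, "alpha": 0.5, "mu0": 0.07,
                               "beta": 0.0, "f": 1.0}, **base)
        lam0, mu0 = present_rate(fit, env)
        assert lam0 == pytest.approx(0.1 * math.e, rel=1e-12)  # E(0) = 2 km
        assert mu0 == pytest.approx(0.07)
        fit2 = ModelFit(params={"lambda0": 0.2, "alpha": 0.0, "mu0": 0.0,
                                "beta": 0.0, "f": 1.0}, **base)
        assert present_rate(fit2, env)[0] == pytest.approx(0.2)


class TestModelComparison:
    @staticmethod
    def _fit(model, logL, k, data_id="d", n_obs=50):
        return ModelFit(model=model, params={}, logL=logL, k=k, n_obs=n_obs,
                        converged=True, n_restarts=1, data_id=data_id)

    def test_equal_aic_ties(self):
        table = compare_models([self._fit("m4", -100, 4), self._fit("m3", -101, 3)])
        assert table.AIC.tolist() == pytest.approx([208.0, 208.0])
        assert table.dAIC.tolist() == pytest.approx([0.0, 0.0])

    def test_weights_sum_to_one(self):
        fits = [self._fit(f"m{k}", -100 - k, k) for k in range(1, 5)]
        table = compare_models(fits)
        assert table.weight.sum() == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_model_keeps_best_identity(self):
        fits = [self._fit("best", -90, 2), self._fit("worse", -120, 2)]
        with_dup = fits + [self._fit("worse2", -120, 2)]
        assert compare_models(with_dup).iloc[0]["model"] == "best"

    def test_refuses_different_data(self):
        with pytest.raises(ValueError):
            compare_models([self._fit("a", -10, 2, "d1"), self._fit("b", -11, 2, "d2")])

    def test_aicc_exceeds_aic_and_converges(self):
        diffs = [
            self._fit("m", -100, 4, n_obs=n).aicc - self._fit("m", -100, 4, n_obs=n).aic
            for n in (10, 30, 100, 1000)
        ]
        assert all(d > 0 for d in diffs)
        assert diffs == sorted(diffs, reverse=True)
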