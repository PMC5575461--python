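"""GeoSSE likelihood, constrained fits, permutation null, and MCMC."""
import numpy as np
import pytest

from andesdiv import simulate
from andesdiv._kernels import geosse_e_grid
from andesdiv._reference import euler_geosse_loglik
from andesdiv.fitting import ModelFit
from andesdiv.geosse import (
    GeoSSEParams,
    add_one_p_value,
    delta_aic_test,
    fit_geosse,
    loglik_geosse,
    mcmc_geosse,
    posterior_probability,
)
from andesdiv.trees import parse_newick


@pytest.fixture
def small_data():
    tree = simulate.random_ultrametric_tree(6, 1.0, seed=42)
    ranges = dict(zip(tree.labels, ["A", "B", "AB", "A", "B", "AB"]))
    return tree, ranges


class TestLikelihood:
    def test_all_rates_zero_is_impossible(self, small_data):
        tree, ranges = small_data
        ll = loglik_geosse(tree, ranges, GeoSSEParams(0, 0),
                           condition_on_survival=False)
        assert ll == -np.inf

    def test_extinction_fixed_point_with_zero_rates(self):
        # dE/dt = 0 when all rates vanish: E stays at 1 - f
        E = geosse_e_grid(0.01, 100, np.zeros(7), np.array([0.7, 0.5, 0.9]))
        np.testing.assert_allclose(E[-1], [0.3, 0.5, 0.1], atol=1e-14)

    def test_extinction_probabilities_stay_in_unit_interval(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1.5, 7)
            E = geosse_e_grid(0.02, 500, p, np.array([1.0, 1.0, 1.0]))
            assert E.min() >= 0.0 and E.max() <= 1.0

    def test_matches_euler_oracle_on_small_trees(self, rng):
        for seed in range(5):
            T = rng.uniform(0.7, 1.2)
            tree = simulate.random_ultrametric_tree(5, T, seed=seed)
            ranges = dict(zip(tree.labels, rng.choice(["A", "B", "AB"], 5)))
            p = GeoSSEParams(*rng.uniform(0.02, 0.25, 7))
            ll = loglik_geosse(tree, ranges, p)
            oracle = euler_geosse_loglik(tree, ranges, p, dt=1e-4)
            assert ll == pytest.approx(oracle, abs=1e-4)

    def test_region_label_swap_invariance(self, small_data):
        tree, ranges = small_data
        p = GeoSSEParams(sA=0.3, sB=0.1, sAB=0.05, xA=0.08, xB=0.02,
                         dA=0.15, dB=0.04, fA=0.9, fB=0.7, fAB=0.8)
        swapped_ranges = {
            k: {"A": "B", "B": "A", "AB": "AB"}[v] for k, v in ranges.items()
        }
        swapped_p = GeoSSEParams(sA=p.sB, sB=p.sA, sAB=p.sAB, xA=p.xB, xB=p.xA,
                                 dA=p.dB, dB=p.dA, fA=p.fB, fB=p.fA, fAB=p.fAB)
        assert loglik_geosse(tree, ranges, p) == pytest.approx(
            loglik_geosse(tree, swapped_ranges, swapped_p), abs=1e-9
        )

    def test_unlabelled_tip_raises(self, small_data):
        tree, ranges = small_data
        ranges = dict(ranges)
        ranges.popitem()
        with pytest.raises(KeyError):
            loglik_geosse(tree, ranges, GeoSSEParams(0.2, 0.2))

    def test_root_options(self, small_data):
        tree, ranges = small_data
        p = GeoSSEParams(0.3, 0.2, 0.1, 0.05, 0.05, 0.1, 0.1)
        lls = {
            opt: loglik_geosse(tree, ranges, p, root=opt)
            for opt in ("fitzjohn", "equal")
        }
        lls["fixed_A"] = loglik_geosse(tree, ranges, p, root=[1, 0, 0])
        assert len({round(v, 10) for v in lls.values()}) == 3
        with pytest.raises(ValueError):
            loglik_geosse(tree, ranges, p, root="bogus")


class TestFitting:
    def test_free_fit_dominates_constrained(self):
        p = GeoSSEParams(0.25, 0.25, 0.1, 0.05, 0.05, 0.05, 0.05)
        tree, ranges = simulate.simulate_geosse(p, n_tips=40, seed=1)
        free = fit_geosse(tree, ranges, n_restarts=1, seed=0)
        con = fit_geosse(tree, ranges, constraints=("sA=sB",), n_restarts=1, seed=0)
        assert free.logL >= con.logL - 1e-6
        assert free.k == 7 and con.k == 6

    def test_constraints_tie_parameters(self):
        p = GeoSSEParams(0.25, 0.25, 0.1, 0.05, 0.05, 0.05, 0.05)
        tree, ranges = simulate.simulate_geosse(p, n_tips=30, seed=2)
        fit = fit_geosse(tree, ranges, constraints=("sA=sB", "xA=xB", "dA=dB"),
                         n_restarts=1, seed=0)
        assert fit.k == 4
        assert fit.params["sA"] == fit.params["sB"]
        assert fit.params["xA"] == fit.params["xB"]
        assert fit.params["dA"] == fit.params["dB"]

    def test_bad_constraint_rejected(self, small_data):
        tree, ranges = small_data
        with pytest.raises(ValueError):
            fit_geosse(tree, ranges, constraints=("sA=zZ",))


class TestDeltaAIC:
    @staticmethod
    def _fit(logL, k, constraints=(), data_id="d"):
        return ModelFit(model="geosse", params={}, logL=logL, k=k, n_obs=50,
                        converged=True, n_restarts=1, data_id=data_id,
                        constraints=constraints)

    def test_arithmetic_example(self):
        # AIC_con - AIC_free = 212 - 214 = -2
        free = self._fit(-100.0, 7)
        con = self._fit(-101.0, 5, constraints=("sA=sB", "xA=xB"))
        assert delta_aic_test(free, con) == pytest.approx(-2.0)

    def test_identical_loglik_gives_two_delta_k(self):
        free = self._fit(-77.0, 7)
        con = self._fit(-77.0, 4, constraints=("sA=sB", "xA=xB", "dA=dB"))
        assert delta_aic_test(free, con) == pytest.approx(-2.0 * 3)

    def test_refuses_non_nested_or_mismatched(self):
        with pytest.raises(ValueError):
            delta_aic_test(self._fit(-10, 7), self._fit(-11, 5, data_id="other"))
        with pytest.raises(ValueError):
            delta_aic_test(self._fit(-10, 5, constraints=("sA=sB",)),
                           self._fit(-11, 7))

    @pytest.mark.parametrize(
        "observed, nulls, expected",
        [
            (5.0, np.arange(99) - 100.0, 0.01),   # observed above all 99 nulls
            (-300.0, np.arange(99) - 100.0, 1.0),  # observed below all nulls
            (0.0, np.array([1.0, -1.0, 0.0]), 0.75),  # ties count as >=
        ],
    )
    def test_add_one_p_rule(self, observed, nulls, expected):
        assert add_one_p_value(observed, nulls) == pytest.approx(expected)


class TestMCMC:
    def test_prior_recovery_without_likelihood(self):
        tree = parse_newick("((a:1,b:1):1,c:2);")
        ranges = {"a": "A", "b": "B", "c": "AB"}
        m = 0.8
        samples, acc = mcmc_geosse(
            tree, ranges, n_steps=6000, seed=0, prior_mean=m,
            use_likelihood=False,
        )
        tail = samples.iloc[2000:]
        # exponential prior: mean m, median m ln 2
        assert tail.sA.mean() == pytest.approx(m, rel=0.15)
        assert np.median(tail.xB) == pytest.approx(m * np.log(2), rel=0.2)
        assert 0.05 < acc < 0.8

    def test_symmetric_data_gives_indifferent_posterior(self):
        p = GeoSSEParams(0.25, 0.25, 0.1, 0.05, 0.05, 0.05, 0.05)
        tree, ranges = simulate.simulate_geosse(p, n_tips=50, seed=3)
        samples, acc = mcmc_geosse(tree, ranges, n_steps=3000, seed=1)
        prob = posterior_probability(samples.iloc[1000:])
        assert 0.05 < prob < 0.95
        assert "netdivA_minus_netdivB" in samples.columns
        assert "dA_minus_dB" in samples.columns
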