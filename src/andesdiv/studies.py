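"""Simulation studies that validate the whole stack end to end.

Each function generates data under known conditions, runs the relevant
estimator, and returns summary statistics (oracle agreement, parameter
recovery, test calibration, power, spatial contrast, interval coverage).
The test suite asserts on these summaries at reduced replicate counts;
``scripts/acceptance.py`` runs them at the sizes documented in
docs/methods.md and reports the numbers.
"""
from __future__ import annotations

import math
from typing import Dict

import numpy as np
from shapely.geometry import box as shapely_box

from . import elevtraits, envbd, geosse, ratemap, simulate
from ._reference import euler_geosse_loglik

__all__ = [
    "constant_limit_study",
    "geosse_oracle_study",
    "envbd_recovery_study",
    "geosse_type1_study",
    "geosse_power_study",
    "ratemap_contrast_study",
    "bm_coverage_study",
    "recovery_generating_conditions",
]


def _child_seeds(seed, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


# ---------------------------------------------------------------------- #
def constant_limit_study(n_trees: int = 100, seed: int = 0) -> Dict[str, float]:
    """ODE likelihood vs closed-form constant-rate likelihood.

    Simulates constant-rate trees spanning roughly 10-200 tips with
    assorted extinction fractions and sampling fractions, and measures
    the largest absolute log-likelihood discrepancy between the
    numerically integrated model (alpha = beta = 0) and the closed form,
    under both conditioning conventions.
    """
    seeds = _child_seeds(seed, n_trees)
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    sizes = []
    for s in seeds:
        lam = rng.uniform(0.1, 0.4)
        mu = rng.uniform(0.0, 0.7) * lam
        f = rng.uniform(0.5, 1.0)
        n_target = math.exp(rng.uniform(math.log(10), math.log(200)))
        T = math.log(max(n_target / (2.0 * f), 2.0)) / max(lam - mu, 0.02)
        T = min(max(T, 1.0), 60.0)
        tree = simulate.simulate_bd_tree(lam, mu, T, f=f, seed=int(s))
        sizes.append(tree.n_tips)
        cond = bool(rng.integers(2))
        p = envbd.EnvBDParams(lam, 0.0, mu, 0.0, f, "constant", "constant")
        ll_ode = envbd.loglik_envbd(tree, p, None, condition_on_survival=cond)
        ll_cf = envbd.loglik_constant_bd(tree, lam, mu, f, condition_on_survival=cond)
        max_diff = max(max_diff, abs(ll_ode - ll_cf))
    return {
        "max_abs_diff": max_diff,
        "n_trees": n_trees,
        "median_tips": float(np.median(sizes)),
    }


def geosse_oracle_study(
    n_trees: int = 20, seed: int = 0, dt: float = 1e-4, n_tips: int = 5
) -> Dict[str, float]:
    """GeoSSE likelihood vs an independent fixed-step Euler integrator.

    Small trees (crown ages 1-2 Myr) and moderate rates keep the Euler
    oracle's own O(dt) discretisation error well below the comparison
    scale. Returns the maximum absolute log-likelihood difference.
    """
    seeds = _child_seeds(seed, n_trees)
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for i, s in enumerate(seeds):
        T = rng.uniform(0.7, 1.2)
        tree = simulate.random_ultrametric_tree(n_tips, T, seed=int(s))
        states = rng.choice(["A", "B", "AB"], size=n_tips)
        ranges = dict(zip(tree.labels, states))
        fs = (1.0, 1.0, 1.0) if i % 4 else (0.8, 0.6, 0.9)
        p = geosse.GeoSSEParams(
            sA=rng.uniform(0.08, 0.25), sB=rng.uniform(0.08, 0.25),
            sAB=rng.uniform(0.0, 0.1), xA=rng.uniform(0.0, 0.1),
            xB=rng.uniform(0.0, 0.1), dA=rng.uniform(0.0, 0.18),
            dB=rng.uniform(0.0, 0.18), fA=fs[0], fB=fs[1], fAB=fs[2],
        )
        ll = geosse.loglik_geosse(tree, ranges, p)
        ll_oracle = euler_geosse_loglik(tree, ranges, p, dt=dt)
        max_diff = max(max_diff, abs(ll - ll_oracle))
    return {"max_abs_diff": max_diff, "n_trees": n_trees}


# ---------------------------------------------------------------------- #
def recovery_generating_conditions(
    lambda0: float = 0.2,
    alpha: float = 0.5,
    mu0: float = 0.05,
    crown_age: float = 9.0,
    n_target: float = 100.0,
):
    """Generating conditions of the uplift-tracking recovery study.

    Speciation follows the logistic Northern-Andes-style uplift curve
    (plateau 4000 m, inflection 6 Ma) with sensitivity ``alpha`` per km;
    the uniform tip sampling fraction is set so the expected number of
    sampled tips is ``n_target``, mimicking the heavy undersampling of
    real mega-diverse clades. Returns (env, lam_fn, mu_fn, f).
    """
    spec = simulate.UpliftCurveSpec()
    samples = simulate.make_uplift_curve(spec, t_max=max(12.0, crown_age + 2), n=121)
    env = envbd.build_env_function(samples, smoothing=0.0)
    p = envbd.EnvBDParams(lambda0, alpha, mu0, 0.0, 1.0, "env", "constant")
    lam_fn, mu_fn = envbd.rate_functions(p, env)
    tgrid = np.linspace(0.0, crown_age, 2001)
    net = lam_fn(tgrid) - mu_fn(tgrid)
    expected_n = 2.0 * math.exp(float(np.trapezoid(net, tgrid)))
    f = min(1.0, n_target / expected_n)
    return env, lam_fn, mu_fn, f


def envbd_recovery_study(
    n_reps: int = 200,
    seed: int = 0,
    lambda0: float = 0.2,
    alpha: float = 0.5,
    mu0: float = 0.05,
    crown_age: float = 9.0,
    n_target: float = 100.0,
    min_tips: int = 20,
    n_restarts: int = 6,
) -> Dict[str, float]:
    """Parameter recovery for the elevation-dependent speciation model.

    For each replicate, a chronogram is simulated under
    lambda(t) = lambda0 exp(alpha E(t)), constant mu, on the logistic
    uplift curve, then both the environment-dependent and the constant
    model are fitted by ML. Reports median relative bias of lambda0-hat
    and alpha-hat, 95%-CI coverage of alpha, and how often the
    environment model beats the constant model by AIC.
    """
    env, lam_fn, mu_fn, f = recovery_generating_conditions(
        lambda0, alpha, mu0, crown_age, n_target
    )
    seeds = _child_seeds(seed, 4 * n_reps)
    lam_hat, alpha_hat, cover, env_wins, tips = [], [], [], [], []
    si = 0
    while len(lam_hat) < n_reps and si < seeds.size:
        s = int(seeds[si]); si += 1
        try:
            tree = simulate.simulate_bd_tree(
                lam_fn, mu_fn, crown_age, f=f, seed=s, max_tries=200
            )
        except simulate.DegenerateSimulationError:
            continue
        if tree.n_tips < min_tips:
            continue
        fit_env = envbd.fit_envbd(
            tree, env, lambda_form="env", mu_form="constant", f=f,
            n_restarts=n_restarts, seed=s,
        )
        fit_const = envbd.fit_envbd(
            tree, env, lambda_form="constant", mu_form="constant", f=f,
            n_restarts=max(2, n_restarts // 2), seed=s, compute_ci=False,
        )
        lam_hat.append(fit_env.params["lambda0"])
        alpha_hat.append(fit_env.params["alpha"])
        lo, hi = fit_env.ci.get("alpha", (np.nan, np.nan))
        cover.append(bool(lo <= alpha <= hi) if np.isfinite(lo) else False)
        env_wins.append(fit_env.aic < fit_const.aic)
        tips.append(tree.n_tips)
    lam_hat = np.asarray(lam_hat)
    alpha_hat = np.asarray(alpha_hat)
    return {
        "n_reps": len(lam_hat),
        "median_tips": float(np.median(tips)),
        "sampling_fraction": f,
        "median_rel_bias_lambda0": abs(float(np.median((lam_hat - lambda0) / lambda0))),
        "median_rel_bias_alpha": abs(float(np.median((alpha_hat - alpha) / alpha))),
        "alpha_ci_coverage": float(np.mean(cover)),
        "env_beats_constant_frac": float(np.mean(env_wins)),
    }


# ---------------------------------------------------------------------- #
_SYMMETRIC = dict(sA=0.2, sB=0.2, sAB=0.1, xA=0.05, xB=0.05, dA=0.05, dB=0.05)
_ASYMMETRIC = dict(sA=0.3, sB=0.15, sAB=0.1, xA=0.05, xB=0.05, dA=0.05, dB=0.05)


def geosse_type1_study(
    n_reps: int = 30,
    n_perm: int = 19,
    n_tips: int = 100,
    seed: int = 0,
    alpha_level: float = 0.05,
) -> Dict[str, float]:
    """Type-I calibration of the permutation-null dAIC test.

    Trees and ranges are simulated under a region-symmetric GeoSSE
    process, so the free model has no real advantage over the sA = sB
    constrained model; the reshuffled-states permutation test should then
    reject at close to its nominal level.
    """
    seeds = _child_seeds(seed, 2 * n_reps)
    p = geosse.GeoSSEParams(**_SYMMETRIC)
    rejections, pvals = [], []
    si = 0
    while len(pvals) < n_reps and si < seeds.size:
        s = int(seeds[si]); si += 1
        try:
            tree, ranges = simulate.simulate_geosse(
                p, root_state="AB", n_tips=n_tips, seed=s
            )
        except simulate.DegenerateSimulationError:
            continue
        null = geosse.permutation_null(
            tree, ranges, constraints=("sA=sB",), n_perm=n_perm, seed=s,
            n_restarts=1, perm_restarts=1,
        )
        pvals.append(null.p_value)
        rejections.append(null.p_value <= alpha_level)
    return {
        "n_reps": len(pvals),
        "rejection_rate": float(np.mean(rejections)),
        "median_p": float(np.median(pvals)),
    }


def geosse_power_study(
    n_reps: int = 100, n_tips: int = 150, seed: int = 0
) -> Dict[str, float]:
    """Power to recover sA > sB when the focal region speciates 2x faster."""
    seeds = _child_seeds(seed, 2 * n_reps)
    p = geosse.GeoSSEParams(**_ASYMMETRIC)
    wins = []
    si = 0
    while len(wins) < n_reps and si < seeds.size:
        s = int(seeds[si]); si += 1
        try:
            tree, ranges = simulate.simulate_geosse(
                p, root_state="AB", n_tips=n_tips, seed=s
            )
        except simulate.DegenerateSimulationError:
            continue
        fit = geosse.fit_geosse(tree, ranges, n_restarts=2, seed=s)
        wins.append(fit.params["sA"] > fit.params["sB"])
    return {"n_reps": len(wins), "sA_gt_sB_frac": float(np.mean(wins))}


# ---------------------------------------------------------------------- #
def ratemap_contrast_study(
    n_seeds: int = 50,
    n_species_per_region: int = 20,
    seed: int = 0,
    cell: float = 0.5,
) -> Dict[str, float]:
    """Map-level contrast when Andes-box tip rates double lowland rates.

    Each seed builds a synthetic clade whose region-A species carry twice
    the speciation rate of region-B species, simulates occurrences, thins
    them to one record per grid cell, interpolates by IDW, and checks
    whether the raster mean inside box A exceeds that inside box B.
    """
    seeds = _child_seeds(seed, n_seeds)
    spec = simulate.OccurrenceSpec()
    box_a = shapely_box(*_reorder(spec.region_boxes["A"]))
    box_b = shapely_box(*_reorder(spec.region_boxes["B"]))
    wins = []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        rates, regions = {}, {}
        for i in range(n_species_per_region):
            base = rng.lognormal(math.log(0.2), 0.15)
            rates[f"a{i}"] = 2.0 * base
            regions[f"a{i}"] = "A"
            rates[f"b{i}"] = rng.lognormal(math.log(0.2), 0.15)
            regions[f"b{i}"] = "B"
        occ = simulate.simulate_occurrences(rates, regions, spec, seed=int(s))
        thinned = ratemap.thin_occurrences(occ, cell=cell, seed=int(s))
        rated = ratemap.attach_tip_rates(thinned, rates)
        raster = ratemap.idw_interpolate(rated, cell=cell)
        mean_a = _raster_box_mean(raster, box_a)
        mean_b = _raster_box_mean(raster, box_b)
        wins.append(mean_a > mean_b)
    return {"n_seeds": n_seeds, "andes_mean_gt_lowland_frac": float(np.mean(wins))}


def _reorder(bx):
    x0, y0, x1, y1 = bx
    return x0, y0, x1, y1


def _raster_box_mean(raster: ratemap.RateRaster, poly) -> float:
    import shapely

    gx, gy = np.meshgrid(raster.lon_centers(), raster.lat_centers())
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
    vals = raster.values.ravel()[inside]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else math.nan


# ---------------------------------------------------------------------- #
def bm_coverage_study(
    n_reps: int = 200,
    n_tips: int = 100,
    sigma2: float = 100.0,
    root_value: float = 1000.0,
    crown_age: float = 20.0,
    seed: int = 0,
) -> Dict[str, float]:
    """Coverage of the Brownian-motion root interval on simulated data.

    Simulates BM (sigma^2 in m^2/Myr) on random chronograms and checks
    how often the root estimate's 95% interval covers the true root
    value.
    """
    seeds = _child_seeds(seed, n_reps)
    cover = []
    for s in seeds:
        tree = simulate.random_ultrametric_tree(n_tips, crown_age, seed=int(s))
        _, tips = simulate.simulate_bm_on_tree(tree, sigma2, root_value, seed=int(s))
        table, _sig2 = elevtraits.bm_ancestral_states(tree, tips)
        root_row = table[table["node"] == tree.root].iloc[0]
        half = 1.959964 * math.sqrt(root_row.variance_m2)
        cover.append(abs(root_row.estimate_m - root_value) <= half)
    return {"n_reps": n_reps, "root_ci_coverage": float(np.mean(cover))}
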