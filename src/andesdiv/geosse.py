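"""Two-region geographic state-dependent diversification (GeoSSE).

Lineages occupy the focal region A (here: "restricted to the Northern
Andes"), the complement B, or both (AB). The seven rates are
within-region speciation sA/sB, between-region speciation of widespread
lineages sAB, extirpation xA/xB (death for a single-region lineage, range
contraction for AB), and range expansion dA/dB. The likelihood follows
the standard coupled extinction/clade-probability ODE system integrated
along branches, with the state-dependent speciation kernel applied at
nodes and state-specific tip sampling fractions.

Beyond the likelihood the module provides constrained maximum-likelihood
fits (equality constraints among the seven rates), the free-versus-
constrained dAIC statistic, a permutation null for that statistic built
by reshuffling tip range states, and an adaptive Metropolis-Hastings
sampler for Bayesian summaries such as P(sA > sB).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._kernels import geosse_e_grid, geosse_loglik_kernel
from .fitting import ModelFit, data_id_for, multistart_minimize, wald_ci
from .simulate import reshuffle_ranges
from .trees import Chronogram, NotUltrametricError, validate_ultrametric

__all__ = [
    "GeoSSEParams",
    "NullDistribution",
    "RATE_NAMES",
    "loglik_geosse",
    "fit_geosse",
    "delta_aic_test",
    "add_one_p_value",
    "permutation_null",
    "mcmc_geosse",
    "posterior_probability",
]

RATE_NAMES = ("sA", "sB", "sAB", "xA", "xB", "dA", "dB")
_STATE_CODE = {"A": 0, "B": 1, "AB": 2}


@dataclass(frozen=True)
class GeoSSEParams:
    """The seven GeoSSE rates (per Myr per lineage) and sampling fractions."""

    sA: float
    sB: float
    sAB: float = 0.0
    xA: float = 0.0
    xB: float = 0.0
    dA: float = 0.0
    dB: float = 0.0
    fA: float = 1.0
    fB: float = 1.0
    fAB: float = 1.0

    def __post_init__(self):
        if min(self.sA, self.sB, self.sAB, self.xA, self.xB, self.dA, self.dB) < 0:
            raise ValueError("rates must be non-negative")
        for fr in (self.fA, self.fB, self.fAB):
            if not (0.0 < fr <= 1.0):
                raise ValueError("sampling fractions must be in (0, 1]")

    def rates(self) -> np.ndarray:
        return np.array([self.sA, self.sB, self.sAB, self.xA, self.xB, self.dA, self.dB])

    def fractions(self) -> np.ndarray:
        return np.array([self.fA, self.fB, self.fAB])

    def net_diversification(self) -> Tuple[float, float]:
        """(sA - xA, sB - xB), the per-region net diversification rates."""
        return self.sA - self.xA, self.sB - self.xB


@dataclass
class NullDistribution:
    """Permutation null for the free-vs-constrained dAIC statistic."""

    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    n_failed: int
    seed: Optional[int]


def _tip_states(tree: Chronogram, ranges: Mapping[str, str]) -> np.ndarray:
    states = np.empty(tree.n_tips, dtype=np.int64)
    for i, lab in enumerate(tree.labels):
        if lab not in ranges:
            raise KeyError(f"tip without a range state: {lab!r}")
        st = ranges[lab]
        if st not in _STATE_CODE:
            raise ValueError(f"invalid range state {st!r} for tip {lab!r}")
        states[i] = _STATE_CODE[st]
    return states


def _e_rhs(E: np.ndarray, p: np.ndarray) -> np.ndarray:
    sA, sB, sAB, xA, xB, dA, dB = p
    ea, eb, ec = E[:, 0], E[:, 1], E[:, 2]
    out = np.empty_like(E)
    out[:, 0] = xA - (sA + dA + xA) * ea + dA * ec + sA * ea * ea
    out[:, 1] = xB - (sB + dB + xB) * eb + dB * ec + sB * eb * eb
    out[:, 2] = (
        -(sA + sB + sAB + xA + xB) * ec
        + xA * eb + xB * ea
        + sA * ea * ec + sB * eb * ec + sAB * ea * eb
    )
    return out


def loglik_geosse(
    tree: Chronogram,
    ranges: Mapping[str, str],
    params: GeoSSEParams,
    *,
    root: Union[str, Sequence[float]] = "fitzjohn",
    condition_on_survival: bool = True,
    grid_size: int = 1500,
    d_step: Optional[float] = None,
) -> float:
    """Log-likelihood of tree + tip ranges under the GeoSSE model.

    The three extinction probabilities are integrated once on a uniform
    RK4 grid over [0, T]; the clade probabilities are integrated
    branch-by-branch (RK4, step <= ``d_step``, default T/400) in a
    compiled postorder sweep with per-node rescaling. ``root`` selects the
    root-state weighting: "fitzjohn" (likelihood-proportional, default),
    "equal", or an explicit 3-vector of weights over (A, B, AB).
    Conditioning on survival divides by the root-state-weighted
    lambda_s (1 - E_s(T))^2, the two-region analogue of crown-survival
    conditioning. Returns -inf for degenerate inputs (e.g. all speciation
    rates zero on a tree with internal nodes).
    """
    ok, spread = validate_ultrametric(tree)
    if not ok:
        raise NotUltrametricError(f"tree not ultrametric (spread {spread:.4g} Myr)")
    states = _tip_states(tree, ranges)
    T = tree.crown_age
    m = int(grid_size)
    h = T / m
    p = params.rates()
    fs = params.fractions()
    E = geosse_e_grid(h, m, p, fs)
    Edot = _e_rhs(E, p)
    hstep = d_step if d_step is not None else T / 400.0
    status, logscale, da, db, dc = geosse_loglik_kernel(
        tree.n_tips, tree.children, tree.age, states, p, fs, E, Edot, h, m, hstep
    )
    if status != 0:
        return -np.inf
    droot = np.array([da, db, dc])
    if isinstance(root, str):
        if root == "fitzjohn":
            tot = droot.sum()
            if tot <= 0:
                return -np.inf
            w = droot / tot
        elif root == "equal":
            w = np.full(3, 1.0 / 3.0)
        else:
            raise ValueError(f"unknown root option {root!r}")
    else:
        w = np.asarray(root, float)
        if w.shape != (3,) or w.min() < 0 or w.sum() <= 0:
            raise ValueError("root weights must be 3 non-negative numbers")
        w = w / w.sum()
    if condition_on_survival:
        e_root = E[m]
        lam_eff = np.array([p[0], p[1], p[0] + p[1] + p[2]])
        denom = float(np.sum(w * lam_eff * (1.0 - e_root) ** 2))
        if denom <= 0:
            return -np.inf
        droot = droot / denom
    L = float(np.sum(w * droot))
    if L <= 0 or not np.isfinite(L):
        return -np.inf
    return math.log(L) + logscale


# ---------------------------------------------------------------------- #
# constrained ML fitting

def _parse_constraints(constraints: Iterable[str]) -> List[List[str]]:
    """Union-find over rate names; returns groups of tied parameters."""
    parent = {n: n for n in RATE_NAMES}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for c in constraints:
        try:
            lhs, rhs = (s.strip() for s in c.split("="))
        except ValueError:
            raise ValueError(f"bad constraint {c!r}; expected 'name=name'") from None
        if lhs not in RATE_NAMES or rhs not in RATE_NAMES:
            raise ValueError(f"unknown rate in constraint {c!r}")
        parent[find(lhs)] = find(rhs)
    groups: Dict[str, List[str]] = {}
    for n in RATE_NAMES:
        groups.setdefault(find(n), []).append(n)
    # keep canonical ordering of groups by first member's position
    ordered = sorted(groups.values(), key=lambda g: RATE_NAMES.index(g[0]))
    return ordered


def fit_geosse(
    tree: Chronogram,
    ranges: Mapping[str, str],
    *,
    constraints: Sequence[str] = (),
    sampling_fractions: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_restarts: int = 2,
    seed=0,
    warm_start: Optional[Mapping[str, float]] = None,
    root: Union[str, Sequence[float]] = "fitzjohn",
    condition_on_survival: bool = True,
    grid_size: int = 1500,
    d_step: Optional[float] = None,
    compute_ci: bool = False,
) -> ModelFit:
    """Constrained maximum-likelihood GeoSSE fit.

    ``constraints`` is a set of equalities among the seven rate names,
    e.g. ``("sA=sB", "xA=xB")``; tied rates share a single free
    parameter, so ``k`` = number of tied groups. Optimization runs in
    log-rate space with multi-start L-BFGS-B; ``warm_start`` (a rate
    dict, e.g. from a previous fit) replaces the heuristic initial point.
    """
    groups = _parse_constraints(constraints)
    k = len(groups)
    states = _tip_states(tree, ranges)  # validates labels early
    rng = np.random.default_rng(seed)
    fA, fB, fAB = sampling_fractions

    def expand(x: np.ndarray) -> GeoSSEParams:
        vals: Dict[str, float] = {}
        for g, xi in zip(groups, x):
            for name in g:
                vals[name] = math.exp(xi)
        return GeoSSEParams(**vals, fA=fA, fB=fB, fAB=fAB)

    def neg(x: np.ndarray) -> float:
        try:
            ll = loglik_geosse(
                tree, ranges, expand(x), root=root,
                condition_on_survival=condition_on_survival,
                grid_size=grid_size, d_step=d_step,
            )
        except (ValueError, OverflowError):
            return 1e10
        return -ll if np.isfinite(ll) else 1e10

    T = tree.crown_age
    s_scale = max(math.log(max(tree.n_tips, 3)) / T, 1e-3)
    default_init = {
        "sA": s_scale, "sB": s_scale, "sAB": 0.5 * s_scale,
        "xA": 0.25 * s_scale, "xB": 0.25 * s_scale,
        "dA": 0.25 * s_scale, "dB": 0.25 * s_scale,
    }
    init_map = dict(default_init)
    if warm_start is not None:
        init_map.update({n: max(float(warm_start[n]), 1e-6)
                         for n in RATE_NAMES if n in warm_start})
    x0 = np.array([math.log(init_map[g[0]]) for g in groups])
    bounds = [(math.log(1e-6), math.log(50.0))] * k
    starts = [x0]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(x0 + rng.normal(0.0, 0.4, size=k))
    best_x, best_f, ok = multistart_minimize(neg, starts, bounds)
    pars = expand(best_x)
    names = [g[0] for g in groups]
    ci = wald_ci(neg, best_x, [f"log_{n}" for n in names]) if compute_ci else {}
    params = {n: float(getattr(pars, n)) for n in RATE_NAMES}
    return ModelFit(
        model="geosse[" + (",".join(constraints) if constraints else "free") + "]",
        params=params,
        logL=-best_f,
        k=k,
        n_obs=tree.n_tips,
        converged=ok,
        n_restarts=len(starts),
        data_id=data_id_for(tree, {"ranges": tuple(sorted(ranges.items()))}),
        ci=ci,
        constraints=tuple(constraints),
    )


def delta_aic_test(free_fit: ModelFit, constrained_fit: ModelFit) -> float:
    """dAIC = AIC(constrained) - AIC(free); positive favours the free model.

    Refuses non-nested inputs: the fits must be on identical data and the
    constrained model must tie strictly more rates.
    """
    if free_fit.data_id != constrained_fit.data_id:
        raise ValueError("fits are not on the same data")
    if not set(free_fit.constraints) <= set(constrained_fit.constraints):
        raise ValueError("constrained fit does not nest within the free fit")
    if constrained_fit.k >= free_fit.k:
        raise ValueError("constrained model must have fewer free parameters")
    return constrained_fit.aic - free_fit.aic


def add_one_p_value(observed: float, nulls: np.ndarray) -> float:
    """Permutation p-value with the add-one rule: (1 + #{null >= obs}) / (n + 1)."""
    nulls = np.asarray(nulls, float)
    return (1.0 + float(np.sum(nulls >= observed))) / (nulls.size + 1.0)


def permutation_null(
    tree: Chronogram,
    ranges: Mapping[str, str],
    *,
    constraints: Sequence[str] = ("sA=sB",),
    n_perm: int = 99,
    seed=0,
    n_restarts: int = 2,
    perm_restarts: int = 1,
    **fit_kwargs,
) -> NullDistribution:
    """Reshuffled-states null distribution of the free-vs-constrained dAIC.

    Fits the free and constrained models to the observed ranges, then for
    each of ``n_perm`` uniform permutations of the tip states refits both
    models (warm-started from the observed optima) and records the dAIC.
    The p-value uses the add-one rule
    ``p = (1 + #{null >= observed}) / (n_valid + 1)``. Permutations whose
    refit fails are excluded and counted in ``n_failed``.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be at least 19 for a 5% test")
    rng = np.random.default_rng(seed)
    free = fit_geosse(tree, ranges, constraints=(), n_restarts=n_restarts,
                      seed=int(rng.integers(2**31)), **fit_kwargs)
    con = fit_geosse(tree, ranges, constraints=constraints, n_restarts=n_restarts,
                     seed=int(rng.integers(2**31)), **fit_kwargs)
    observed = delta_aic_test(free, con)
    nulls = []
    n_failed = 0
    for _ in range(n_perm):
        shuffled = reshuffle_ranges(ranges, seed=int(rng.integers(2**31)))
        try:
            f_p = fit_geosse(tree, shuffled, constraints=(),
                             n_restarts=perm_restarts, seed=int(rng.integers(2**31)),
                             warm_start=free.params, **fit_kwargs)
            c_p = fit_geosse(tree, shuffled, constraints=constraints,
                             n_restarts=perm_restarts, seed=int(rng.integers(2**31)),
                             warm_start=con.params, **fit_kwargs)
            nulls.append(delta_aic_test(f_p, c_p))
        except (RuntimeError, ValueError):
            n_failed += 1
    nulls = np.asarray(nulls)
    p = add_one_p_value(observed, nulls)
    return NullDistribution(
        observed_stat=observed,
        null_stats=nulls,
        p_value=p,
        n_perm=n_perm,
        n_failed=n_failed,
        seed=seed,
    )


# ---------------------------------------------------------------------- #
# Bayesian MCMC

def mcmc_geosse(
    tree: Chronogram,
    ranges: Mapping[str, str],
    *,
    n_steps: int = 5000,
    seed=0,
    prior_mean: Optional[float] = None,
    init: Optional[Mapping[str, float]] = None,
    sampling_fractions: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    root: Union[str, Sequence[float]] = "fitzjohn",
    condition_on_survival: bool = True,
    use_likelihood: bool = True,
    adapt_until: Optional[int] = None,
    target_accept: float = 0.3,
    grid_size: int = 1500,
    d_step: Optional[float] = None,
) -> Tuple[pd.DataFrame, float]:
    """Adaptive Metropolis-Hastings over the seven GeoSSE rates.

    Proposals are joint Gaussian random walks in log-rate space with a
    globally adapted step size (first ``adapt_until`` iterations, default
    n_steps/4). Priors are independent exponentials with mean
    ``prior_mean`` (default 2 ln(n)/T, a net-diversification scale).
    ``use_likelihood=False`` samples the prior alone (prior-recovery
    check). Returns the sample table - the seven rates plus the derived
    contrasts sA-sB, dA-dB and (sA-xA)-(sB-xB) - and the post-adaptation
    acceptance rate.
    """
    rng = np.random.default_rng(seed)
    T = tree.crown_age
    if prior_mean is None:
        prior_mean = 2.0 * math.log(max(tree.n_tips, 3)) / T
    if adapt_until is None:
        adapt_until = n_steps // 4
    fA, fB, fAB = sampling_fractions

    def logpost(y: np.ndarray) -> float:
        r = np.exp(y)
        # exponential prior on rates + log-Jacobian of the log transform
        lp = float(np.sum(-r / prior_mean + y)) - 7 * math.log(prior_mean)
        if use_likelihood:
            ll = loglik_geosse(
                tree, ranges, GeoSSEParams(*r, fA=fA, fB=fB, fAB=fAB),
                root=root, condition_on_survival=condition_on_survival,
                grid_size=grid_size, d_step=d_step,
            )
            if not np.isfinite(ll):
                return -np.inf
            lp += ll
        return lp

    if init is not None:
        y = np.log(np.maximum([init[n] for n in RATE_NAMES], 1e-6))
    else:
        y = np.full(7, math.log(max(prior_mean / 2.0, 1e-4)))
    lp = logpost(y)
    if not np.isfinite(lp):
        y = np.full(7, math.log(max(prior_mean / 2.0, 1e-4)))
        lp = logpost(y)
    step = 0.3
    rows = np.empty((n_steps, 8))
    acc_post = 0
    n_post = 0
    for it in range(n_steps):
        prop = y + rng.normal(0.0, step, size=7)
        lp_prop = logpost(prop)
        accept = math.log(rng.random()) < lp_prop - lp if np.isfinite(lp_prop) else False
        if accept:
            y, lp = prop, lp_prop
        if it < adapt_until:
            step *= math.exp((1.0 if accept else 0.0) - target_accept) ** (
                5.0 / (it + 10.0)
            )
        else:
            n_post += 1
            acc_post += int(accept)
        rows[it, :7] = np.exp(y)
        rows[it, 7] = lp
    df = pd.DataFrame(rows, columns=list(RATE_NAMES) + ["logpost"])
    df["sA_minus_sB"] = df.sA - df.sB
    df["dA_minus_dB"] = df.dA - df.dB
    df["netdivA_minus_netdivB"] = (df.sA - df.xA) - (df.sB - df.xB)
    acc_rate = acc_post / max(n_post, 1)
    if n_post > 50 and acc_rate == 0.0:
        import warnings

        warnings.warn("MCMC accepted no proposals after adaptation", RuntimeWarning)
    return df, acc_rate


def posterior_probability(samples: pd.DataFrame, column: str = "sA_minus_sB") -> float:
    """Posterior probability that the given contrast is positive."""
    return float((samples[column] > 0).mean())
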