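"""Slow, brute-force reference implementations used for validation.

These deliberately share no numerical code with the production paths:
the GeoSSE reference integrates the coupled ODEs with fixed-step forward
Euler straight from the rate definitions, and the Brownian-motion
reference solves the dense graph-Laplacian GLS system. They exist so the
test suite (and the acceptance script) can cross-check the fast
implementations against independently coded arithmetic.
"""
from __future__ import annotations

import math
from typing import Dict, Mapping, Tuple

import numpy as np

from .trees import Chronogram

__all__ = ["euler_geosse_loglik", "bm_gls_dense"]


def euler_geosse_loglik(
    tree: Chronogram,
    ranges: Mapping[str, str],
    params,
    *,
    dt: float = 1e-4,
    root: str = "fitzjohn",
    condition_on_survival: bool = True,
) -> float:
    """Fixed-step Euler evaluation of the GeoSSE log-likelihood.

    Integrates the three extinction equations on a global Euler grid of
    step ``dt`` over [0, T], then sweeps the tree in postorder integrating
    the clade probabilities with the same step, applying the speciation
    kernel at nodes. Accurate to O(dt); intended for tiny trees only.
    """
    sA, sB, sAB, xA, xB, dA, dB = (
        params.sA, params.sB, params.sAB, params.xA, params.xB, params.dA, params.dB
    )
    fs = {"A": params.fA, "B": params.fB, "AB": params.fAB}
    T = tree.crown_age
    nsteps = max(1, int(math.ceil(T / dt)))
    step = T / nsteps
    EA = np.empty(nsteps + 1)
    EB = np.empty(nsteps + 1)
    EC = np.empty(nsteps + 1)
    EA[0], EB[0], EC[0] = 1.0 - fs["A"], 1.0 - fs["B"], 1.0 - fs["AB"]
    for i in range(nsteps):
        ea, eb, ec = EA[i], EB[i], EC[i]
        EA[i + 1] = ea + step * (xA - (sA + dA + xA) * ea + dA * ec + sA * ea * ea)
        EB[i + 1] = eb + step * (xB - (sB + dB + xB) * eb + dB * ec + sB * eb * eb)
        EC[i + 1] = ec + step * (
            -(sA + sB + sAB + xA + xB) * ec
            + xA * eb + xB * ea
            + sA * ea * ec + sB * eb * ec + sAB * ea * eb
        )

    code = {"A": 0, "B": 1, "AB": 2}
    logscale = 0.0
    D: Dict[int, np.ndarray] = {}
    for i, lab in enumerate(tree.labels):
        d = np.zeros(3)
        st = ranges[lab]
        d[code[st]] = fs[st]
        D[i] = d

    def integrate(d: np.ndarray, t0: float, t1: float) -> np.ndarray:
        # exact branch span, fixed Euler step <= dt; E read off the global
        # Euler grid at the containing interval
        span = t1 - t0
        ns = max(1, int(math.ceil(span / step)))
        h = span / ns
        da, db, dc = d
        for k in range(ns):
            t = t0 + k * h
            gi = min(int(t / step), nsteps - 1)
            ea, eb, ec = EA[gi], EB[gi], EC[gi]
            na = da + h * (-(sA + dA + xA) * da + dA * dc + 2.0 * sA * da * ea)
            nb = db + h * (-(sB + dB + xB) * db + dB * dc + 2.0 * sB * db * eb)
            nc = dc + h * (
                -(sA + sB + sAB + xA + xB) * dc
                + xA * db + xB * da
                + sA * (ea * dc + ec * da)
                + sB * (eb * dc + ec * db)
                + sAB * (ea * db + eb * da)
            )
            da, db, dc = na, nb, nc
        return np.array([da, db, dc])

    for node in tree.postorder_internal():
        a, b = tree.children[node]
        dl = integrate(D[a], tree.age[a], tree.age[node])
        dr = integrate(D[b], tree.age[b], tree.age[node])
        na = sA * dl[0] * dr[0]
        nb = sB * dl[1] * dr[1]
        nc = 0.5 * (
            sA * (dl[0] * dr[2] + dl[2] * dr[0])
            + sB * (dl[1] * dr[2] + dl[2] * dr[1])
            + sAB * (dl[0] * dr[1] + dl[1] * dr[0])
        )
        d = np.array([na, nb, nc])
        tot = d.sum()
        if tot <= 0 or not np.isfinite(tot):
            return -np.inf
        D[node] = d / tot
        logscale += math.log(tot)

    droot = D[tree.root]
    if root == "fitzjohn":
        w = droot / droot.sum()
    elif root == "equal":
        w = np.full(3, 1.0 / 3.0)
    else:
        raise ValueError(f"unknown root option {root!r}")
    if condition_on_survival:
        e_root = np.array([EA[-1], EB[-1], EC[-1]])
        lam_eff = np.array([sA, sB, sA + sB + sAB])
        droot = droot / float(np.sum(w * lam_eff * (1.0 - e_root) ** 2))
    L = float(np.sum(w * droot))
    if L <= 0:
        return -np.inf
    return math.log(L) + logscale


def bm_gls_dense(
    tree: Chronogram, tip_values: Mapping[str, float]
) -> Tuple[np.ndarray, np.ndarray]:
    """Dense GLS ancestral estimates under Brownian motion.

    Builds the graph-Laplacian precision over all nodes (edge weights
    1/branch-length), conditions on the tips, and solves for the internal
    node expectations and their variances (per unit sigma^2). Returns
    ``(estimates, variances)`` indexed by internal node order
    ``tree.n_tips .. 2n-2``.
    """
    n = tree.n_nodes
    Q = np.zeros((n, n))
    for i in range(n - 1):
        p = tree.parent[i]
        bl = tree.age[p] - tree.age[i]
        if bl <= 0:
            raise ValueError("non-positive branch length makes GLS singular")
        w = 1.0 / bl
        Q[i, i] += w
        Q[p, p] += w
        Q[i, p] -= w
        Q[p, i] -= w
    tips = np.arange(tree.n_tips)
    internal = np.arange(tree.n_tips, n)
    y = np.array([tip_values[lab] for lab in tree.labels])
    Qii = Q[np.ix_(internal, internal)]
    Qit = Q[np.ix_(internal, tips)]
    est = np.linalg.solve(Qii, -Qit @ y)
    var = np.diag(np.linalg.inv(Qii)).copy()
    return est, var
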