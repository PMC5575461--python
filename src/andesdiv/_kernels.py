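"""Numba inner loops for the birth-death and GeoSSE pruning likelihoods.

Both likelihoods integrate extinction probabilities E on a uniform time
grid with classical RK4 (rates supplied at half-steps, so the midpoint
evaluations are exact), then evaluate E between grid nodes with cubic
Hermite interpolation using the analytically known slope dE/dt. Clade
probabilities D are integrated branch-by-branch with RK4 in the GeoSSE
kernel; in the single-type birth-death case D reduces to the accumulated
integral Phi of psi(t) = lambda + mu - 2*lambda*E, which is carried along
with E in the same RK4 sweep.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["bd_e_phi_grid", "geosse_e_grid", "geosse_loglik_kernel", "hermite_eval"]


@njit(cache=True)
def bd_e_phi_grid(h, lam_half, mu_half, e0):
    """Integrate dE/dt = mu - (lam+mu)E + lam E^2 and dPhi/dt = psi.

    ``lam_half``/``mu_half`` hold rate values at t = 0, h/2, h, 3h/2, ...
    (2m+1 entries for m steps). Returns (E, Phi) at the m+1 grid nodes.
    """
    m = (lam_half.size - 1) // 2
    E = np.empty(m + 1)
    PHI = np.empty(m + 1)
    E[0] = e0
    PHI[0] = 0.0
    e = e0
    phi = 0.0
    for i in range(m):
        l0 = lam_half[2 * i]
        m0 = mu_half[2 * i]
        l1 = lam_half[2 * i + 1]
        m1 = mu_half[2 * i + 1]
        l2 = lam_half[2 * i + 2]
        m2 = mu_half[2 * i + 2]

        k1e = m0 - (l0 + m0) * e + l0 * e * e
        k1p = l0 + m0 - 2.0 * l0 * e

        e2 = e + 0.5 * h * k1e
        k2e = m1 - (l1 + m1) * e2 + l1 * e2 * e2
        k2p = l1 + m1 - 2.0 * l1 * e2

        e3 = e + 0.5 * h * k2e
        k3e = m1 - (l1 + m1) * e3 + l1 * e3 * e3
        k3p = l1 + m1 - 2.0 * l1 * e3

        e4 = e + h * k3e
        k4e = m2 - (l2 + m2) * e4 + l2 * e4 * e4
        k4p = l2 + m2 - 2.0 * l2 * e4

        e = e + (h / 6.0) * (k1e + 2.0 * k2e + 2.0 * k3e + k4e)
        phi = phi + (h / 6.0) * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
        if e < 0.0:
            e = 0.0
        elif e > 1.0:
            e = 1.0
        E[i + 1] = e
        PHI[i + 1] = phi
    return E, PHI


def hermite_eval(t, h, y, dy):
    """Vectorized cubic Hermite interpolation on a uniform grid.

    ``y``/``dy`` are values and slopes at nodes ``0, h, 2h, ...``;
    ``t`` may be scalar or array and is clamped to the grid range.
    """
    t = np.asarray(t, dtype=np.float64)
    m = y.size - 1
    idx = np.clip((t / h).astype(np.int64), 0, m - 1)
    s = t / h - idx
    s2 = s * s
    s3 = s2 * s
    h00 = 2.0 * s3 - 3.0 * s2 + 1.0
    h10 = s3 - 2.0 * s2 + s
    h01 = -2.0 * s3 + 3.0 * s2
    h11 = s3 - s2
    return (
        h00 * y[idx]
        + h10 * h * dy[idx]
        + h01 * y[idx + 1]
        + h11 * h * dy[idx + 1]
    )


@njit(cache=True)
def geosse_e_grid(h, m, p, fs):
    """RK4 grid solution of the three coupled GeoSSE extinction ODEs.

    ``p`` = (sA, sB, sAB, xA, xB, dA, dB); ``fs`` = (fA, fB, fAB).
    Returns an (m+1, 3) array of (E_A, E_B, E_AB) at the grid nodes.
    Rates are time-constant, so the system is autonomous.
    """
    sA, sB, sAB, xA, xB, dA, dB = p[0], p[1], p[2], p[3], p[4], p[5], p[6]
    E = np.empty((m + 1, 3))
    ea = 1.0 - fs[0]
    eb = 1.0 - fs[1]
    eab = 1.0 - fs[2]
    E[0, 0] = ea
    E[0, 1] = eb
    E[0, 2] = eab
    for i in range(m):
        # k1
        k1a = xA - (sA + dA + xA) * ea + dA * eab + sA * ea * ea
        k1b = xB - (sB + dB + xB) * eb + dB * eab + sB * eb * eb
        k1c = (
            -(sA + sB + sAB + xA + xB) * eab
            + xA * eb + xB * ea
            + sA * ea * eab + sB * eb * eab + sAB * ea * eb
        )
        a2 = ea + 0.5 * h * k1a
        b2 = eb + 0.5 * h * k1b
        c2 = eab + 0.5 * h * k1c
        k2a = xA - (sA + dA + xA) * a2 + dA * c2 + sA * a2 * a2
        k2b = xB - (sB + dB + xB) * b2 + dB * c2 + sB * b2 * b2
        k2c = (
            -(sA + sB + sAB + xA + xB) * c2
            + xA * b2 + xB * a2
            + sA * a2 * c2 + sB * b2 * c2 + sAB * a2 * b2
        )
        a3 = ea + 0.5 * h * k2a
        b3 = eb + 0.5 * h * k2b
        c3 = eab + 0.5 * h * k2c
        k3a = xA - (sA + dA + xA) * a3 + dA * c3 + sA * a3 * a3
        k3b = xB - (sB + dB + xB) * b3 + dB * c3 + sB * b3 * b3
        k3c = (
            -(sA + sB + sAB + xA + xB) * c3
            + xA * b3 + xB * a3
            + sA * a3 * c3 + sB * b3 * c3 + sAB * a3 * b3
        )
        a4 = ea + h * k3a
        b4 = eb + h * k3b
        c4 = eab + h * k3c
        k4a = xA - (sA + dA + xA) * a4 + dA * c4 + sA * a4 * a4
        k4b = xB - (sB + dB + xB) * b4 + dB * c4 + sB * b4 * b4
        k4c = (
            -(sA + sB + sAB + xA + xB) * c4
            + xA * b4 + xB * a4
            + sA * a4 * c4 + sB * b4 * c4 + sAB * a4 * b4
        )
        ea = ea + (h / 6.0) * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
        eb = eb + (h / 6.0) * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)
        eab = eab + (h / 6.0) * (k1c + 2.0 * k2c + 2.0 * k3c + k4c)
        if ea < 0.0:
            ea = 0.0
        elif ea > 1.0:
            ea = 1.0
        if eb < 0.0:
            eb = 0.0
        elif eb > 1.0:
            eb = 1.0
        if eab < 0.0:
            eab = 0.0
        elif eab > 1.0:
            eab = 1.0
        E[i + 1, 0] = ea
        E[i + 1, 1] = eb
        E[i + 1, 2] = eab
    return E


@njit(cache=True, inline="always")
def _e_interp(t, h, m, E, Edot):
    """Cubic Hermite evaluation of the three E components at time t."""
    i = int(t / h)
    if i >= m:
        i = m - 1
    if i < 0:
        i = 0
    s = t / h - i
    s2 = s * s
    s3 = s2 * s
    h00 = 2.0 * s3 - 3.0 * s2 + 1.0
    h10 = s3 - 2.0 * s2 + s
    h01 = -2.0 * s3 + 3.0 * s2
    h11 = s3 - s2
    ea = h00 * E[i, 0] + h10 * h * Edot[i, 0] + h01 * E[i + 1, 0] + h11 * h * Edot[i + 1, 0]
    eb = h00 * E[i, 1] + h10 * h * Edot[i, 1] + h01 * E[i + 1, 1] + h11 * h * Edot[i + 1, 1]
    ec = h00 * E[i, 2] + h10 * h * Edot[i, 2] + h01 * E[i + 1, 2] + h11 * h * Edot[i + 1, 2]
    return ea, eb, ec


@njit(cache=True)
def geosse_loglik_kernel(
    n_tips, children, age, tip_state, p, fs, E, Edot, h_grid, m, h_target
):
    """Postorder pruning pass for the GeoSSE clade probabilities D.

    Returns ``(status, logscale, D_A, D_B, D_AB)`` at the root (after the
    node combination rule has been applied there). status 0 = ok,
    1 = non-finite/zero likelihood encountered.
    """
    sA, sB, sAB, xA, xB, dA, dB = p[0], p[1], p[2], p[3], p[4], p[5], p[6]
    n_nodes = 2 * n_tips - 1
    D = np.zeros((n_nodes, 3))
    for i in range(n_tips):
        st = tip_state[i]
        D[i, st] = fs[st]
    logscale = 0.0
    res = np.empty((2, 3))
    for node in range(n_tips, n_nodes):
        t1 = age[node]
        for side in range(2):
            c = children[node, side]
            t0 = age[c]
            span = t1 - t0
            da = D[c, 0]
            db = D[c, 1]
            dc = D[c, 2]
            if span > 0.0:
                nst = int(span / h_target) + 1
                hh = span / nst
                for st_i in range(nst):
                    t = t0 + st_i * hh
                    ea, eb, ec = _e_interp(t, h_grid, m, E, Edot)
                    k1a = -(sA + dA + xA) * da + dA * dc + 2.0 * sA * da * ea
                    k1b = -(sB + dB + xB) * db + dB * dc + 2.0 * sB * db * eb
                    k1c = (
                        -(sA + sB + sAB + xA + xB) * dc
                        + xA * db + xB * da
                        + sA * (ea * dc + ec * da)
                        + sB * (eb * dc + ec * db)
                        + sAB * (ea * db + eb * da)
                    )
                    tm = t + 0.5 * hh
                    ea, eb, ec = _e_interp(tm, h_grid, m, E, Edot)
                    a2 = da + 0.5 * hh * k1a
                    b2 = db + 0.5 * hh * k1b
                    c2 = dc + 0.5 * hh * k1c
                    k2a = -(sA + dA + xA) * a2 + dA * c2 + 2.0 * sA * a2 * ea
                    k2b = -(sB + dB + xB) * b2 + dB * c2 + 2.0 * sB * b2 * eb
                    k2c = (
                        -(sA + sB + sAB + xA + xB) * c2
                        + xA * b2 + xB * a2
                        + sA * (ea * c2 + ec * a2)
                        + sB * (eb * c2 + ec * b2)
                        + sAB * (ea * b2 + eb * a2)
                    )
                    a3 = da + 0.5 * hh * k2a
                    b3 = db + 0.5 * hh * k2b
                    c3 = dc + 0.5 * hh * k2c
                    k3a = -(sA + dA + xA) * a3 + dA * c3 + 2.0 * sA * a3 * ea
                    k3b = -(sB + dB + xB) * b3 + dB * c3 + 2.0 * sB * b3 * eb
                    k3c = (
                        -(sA + sB + sAB + xA + xB) * c3
                        + xA * b3 + xB * a3
                        + sA * (ea * c3 + ec * a3)
                        + sB * (eb * c3 + ec * b3)
                        + sAB * (ea * b3 + eb * a3)
                    )
                    te = t + hh
                    ea, eb, ec = _e_interp(te, h_grid, m, E, Edot)
                    a4 = da + hh * k3a
                    b4 = db + hh * k3b
                    c4 = dc + hh * k3c
                    k4a = -(sA + dA + xA) * a4 + dA * c4 + 2.0 * sA * a4 * ea
                    k4b = -(sB + dB + xB) * b4 + dB * c4 + 2.0 * sB * b4 * eb
                    k4c = (
                        -(sA + sB + sAB + xA + xB) * c4
                        + xA * b4 + xB * a4
                        + sA * (ea * c4 + ec * a4)
                        + sB * (eb * c4 + ec * b4)
                        + sAB * (ea * b4 + eb * a4)
                    )
                    da = da + (hh / 6.0) * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
                    db = db + (hh / 6.0) * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)
                    dc = dc + (hh / 6.0) * (k1c + 2.0 * k2c + 2.0 * k3c + k4c)
            res[side, 0] = da
            res[side, 1] = db
            res[side, 2] = dc
        la0, lb0, lc0 = res[0, 0], res[0, 1], res[0, 2]
        ra0, rb0, rc0 = res[1, 0], res[1, 1], res[1, 2]
        na = sA * la0 * ra0
        nb = sB * lb0 * rb0
        nc = 0.5 * (
            sA * (la0 * rc0 + lc0 * ra0)
            + sB * (lb0 * rc0 + lc0 * rb0)
            + sAB * (la0 * rb0 + lb0 * ra0)
        )
        tot = na + nb + nc
        if not np.isfinite(tot) or tot <= 0.0:
            return 1, logscale, na, nb, nc
        D[node, 0] = na / tot
        D[node, 1] = nb / tot
        D[node, 2] = nc / tot
        logscale += np.log(tot)
    r = n_nodes - 1
    return 0, logscale, D[r, 0], D[r, 1], D[r, 2]
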