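"""Shared maximum-likelihood fitting machinery and AIC model comparison."""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = ["ModelFit", "multistart_minimize", "compare_models", "fd_hessian", "data_id_for"]

_BIG = 1e10


@dataclass
class ModelFit:
    """Result of a maximum-likelihood model fit.

    ``params`` holds the full parameter set on the natural scale
    (including values pinned by constraints); ``k`` counts only the free
    parameters. ``ci`` maps free parameter names to Wald 95% intervals
    (NaN bounds when the Hessian was not usable).
    """

    model: str
    params: Dict[str, float]
    logL: float
    k: int
    n_obs: int
    converged: bool
    n_restarts: int
    data_id: str
    ci: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    constraints: Tuple[str, ...] = ()

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.logL

    @property
    def aicc(self) -> float:
        denom = self.n_obs - self.k - 1
        if denom <= 0:
            return np.inf
        return self.aic + 2.0 * self.k * (self.k + 1) / denom


def data_id_for(tree, extra: Optional[Mapping] = None) -> str:
    """Stable fingerprint of the data a fit was computed on."""
    h = hashlib.sha256()
    h.update(str(tree.n_tips).encode())
    h.update(np.asarray(tree.age).round(10).tobytes())
    for lab in tree.labels:
        h.update(lab.encode())
    if extra:
        for kk in sorted(extra):
            h.update(str(kk).encode())
            h.update(str(extra[kk]).encode())
    return h.hexdigest()[:16]


def multistart_minimize(
    neg: Callable[[np.ndarray], float],
    starts: Sequence[np.ndarray],
    bounds: Sequence[Tuple[float, float]],
) -> Tuple[np.ndarray, float, bool]:
    """Bounded quasi-Newton from several starts; returns the best optimum."""
    best_x = None
    best_f = np.inf
    any_ok = False
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, float), [b[0] for b in bounds], [b[1] for b in bounds])
        try:
            res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
        except Exception:
            continue
        if np.isfinite(res.fun) and res.fun < best_f:
            best_f = float(res.fun)
            best_x = np.asarray(res.x)
            any_ok = any_ok or bool(res.success)
    if best_x is None:
        raise RuntimeError("optimization failed from every start")
    return best_x, best_f, any_ok


def fd_hessian(fn: Callable[[np.ndarray], float], x: np.ndarray,
               rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian (small, dense problems only)."""
    x = np.asarray(x, float)
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    f0 = fn(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                H[i, i] = (fn(xp) - 2.0 * f0 + fn(xm)) / h[i] ** 2
            else:
                xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                H[i, j] = H[j, i] = (
                    fn(xpp) - fn(xpm) - fn(xmp) + fn(xmm)
                ) / (4.0 * h[i] * h[j])
    return H


def wald_ci(neg: Callable[[np.ndarray], float], x: np.ndarray,
            names: Sequence[str]) -> Dict[str, Tuple[float, float]]:
    """95% Wald intervals from the finite-difference observed information."""
    out: Dict[str, Tuple[float, float]] = {}
    try:
        H = fd_hessian(neg, x)
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except Exception:
        se = np.full(len(names), np.nan)
    for i, name in enumerate(names):
        s = se[i] if i < len(se) else np.nan
        if not np.isfinite(s) or s == 0:
            out[name] = (np.nan, np.nan)
        else:
            out[name] = (float(x[i] - 1.959964 * s), float(x[i] + 1.959964 * s))
    return out


def compare_models(fits: Sequence[ModelFit], criterion: str = "aic") -> pd.DataFrame:
    """Rank fits of the same data by AIC with dAIC and Akaike weights."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    ids = {f.data_id for f in fits}
    if len(ids) != 1:
        raise ValueError("fits were computed on different data; refusing to compare")
    vals = np.array([getattr(f, criterion) for f in fits])
    order = np.argsort(vals)
    best = vals[order[0]]
    delta = vals - best
    w = np.exp(-0.5 * delta)
    w = w / w.sum()
    rows = []
    for i in order:
        f = fits[i]
        rows.append({
            "model": f.model,
            "k": f.k,
            "logL": f.logL,
            "AIC": f.aic,
            "AICc": f.aicc,
            "dAIC": delta[i],
            "weight": w[i],
            "converged": f.converged,
        })
    return pd.DataFrame(rows).reset_index(drop=True)
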