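"""Tip elevation summaries, Brownian-motion ancestral elevation, and
richness-elevation profiles.

Species' elevational positions are summarized from occurrence records
(mean/min/max per species), classified into lowland versus montane with
the 1100 m sub-Andean forest threshold, and treated as a continuous
character evolving by Brownian motion for ancestral-state estimation on
a chronogram. The BM rate sigma^2 is estimated by REML from phylogenetic
independent contrasts; ancestral expectations and variances come from
the standard two-pass pruning recursion (equivalent to GLS under BM with
a flat root prior).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .trees import Chronogram

__all__ = [
    "tip_mean_elevation",
    "classify_elevation",
    "bm_ancestral_states",
    "richness_by_elevation",
    "MONTANE_THRESHOLD_M",
]

#: Sub-Andean (montane) forest lower limit in metres.
MONTANE_THRESHOLD_M = 1100.0


def tip_mean_elevation(occ: pd.DataFrame) -> Tuple[pd.DataFrame, list]:
    """Per-species elevation summary from occurrence records.

    Returns ``(table, excluded)`` where the table has one row per species
    with usable (non-missing) elevations - columns mean_elev_m, n_records,
    min_elev_m, max_elev_m - and ``excluded`` lists species whose records
    all lack elevations.
    """
    if "elev_m" not in occ.columns:
        raise ValueError("occurrence table has no elev_m column")
    usable = occ.dropna(subset=["elev_m"])
    grouped = usable.groupby("species")["elev_m"]
    table = pd.DataFrame({
        "mean_elev_m": grouped.mean(),
        "n_records": grouped.size(),
        "min_elev_m": grouped.min(),
        "max_elev_m": grouped.max(),
    }).reset_index()
    excluded = sorted(set(occ["species"]) - set(table["species"]))
    return table, excluded


def classify_elevation(
    table: pd.DataFrame, threshold: float = MONTANE_THRESHOLD_M
) -> Dict[str, str]:
    """Lowland/montane classification of species mean elevations.

    Montane iff mean elevation is strictly greater than the threshold;
    a mean exactly at the threshold is classified lowland (the boundary
    point is not covered by the two strict inequalities of the ecoregion
    definition, so the convention here is documented rather than implied).
    """
    if table.empty:
        raise ValueError("empty elevation table")
    return {
        row.species: ("montane" if row.mean_elev_m > threshold else "lowland")
        for row in table.itertuples()
    }


def richness_by_elevation(
    table: pd.DataFrame,
    bin_width: float = 250.0,
    max_elev: Optional[float] = None,
) -> pd.DataFrame:
    """Species counts per half-open elevation bin of the given width.

    Bins are ``[i*bin_width, (i+1)*bin_width)`` starting at 0; counts sum
    to the number of species in the table.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    elev = table["mean_elev_m"].to_numpy(float)
    top = max_elev if max_elev is not None else (elev.max() if elev.size else 0.0)
    n_bins = max(1, int(math.floor(top / bin_width)) + 1)
    idx = np.clip(np.floor(elev / bin_width).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame({
        "bin_low_m": np.arange(n_bins) * bin_width,
        "bin_high_m": (np.arange(n_bins) + 1) * bin_width,
        "n_species": counts,
    })


# ---------------------------------------------------------------------- #
# Brownian-motion ancestral states

def bm_ancestral_states(
    tree: Chronogram, tip_values: Mapping[str, float]
) -> Tuple[pd.DataFrame, float]:
    """Ancestral expectations and variances under Brownian motion.

    sigma^2 is the REML (independent-contrasts) estimate; node
    expectations and variances come from the two-pass pruning algorithm:
    an uppass computing each subtree's conditional mean and scaled
    variance, and a downpass folding in the information from the rest of
    the tree. The root estimate equals the GLS best linear unbiased
    estimate, and every estimate is a convex combination of tip values.

    Returns ``(table, sigma2)``; the table has one row per internal node
    with columns node, age_ma, estimate_m, variance_m2 (variance already
    scaled by the estimated sigma^2).
    """
    n = tree.n_tips
    if n < 2:
        raise ValueError("need at least 2 tips for BM estimation")
    missing = [lab for lab in tree.labels if lab not in tip_values]
    if missing:
        raise KeyError(f"tips without values: {missing}")

    # uppass: subtree conditional (mean x, scaled variance v)
    x = np.zeros(tree.n_nodes)
    v = np.zeros(tree.n_nodes)
    for i in range(n):
        x[i] = float(tip_values[tree.labels[i]])
    contrast_sum = 0.0
    for node in tree.postorder_internal():
        a, b = tree.children[node]
        pa = v[a] + (tree.age[node] - tree.age[a])
        pb = v[b] + (tree.age[node] - tree.age[b])
        if pa <= 0 or pb <= 0:
            raise ValueError(
                "zero-length branch pair below a node makes the GLS system singular"
            )
        x[node] = (x[a] / pa + x[b] / pb) / (1.0 / pa + 1.0 / pb)
        v[node] = pa * pb / (pa + pb)
        contrast_sum += (x[a] - x[b]) ** 2 / (pa + pb)
    sigma2 = contrast_sum / (n - 1)

    # downpass: rest-of-tree information (mean y, scaled variance w);
    # infinite w (no information) is carried as precision 0
    y = np.zeros(tree.n_nodes)
    w_prec = np.zeros(tree.n_nodes)  # 1/w
    est = np.zeros(tree.n_nodes)
    var = np.zeros(tree.n_nodes)
    root = tree.root
    est[root] = x[root]
    var[root] = v[root]
    for node in reversed(list(tree.postorder_internal())):
        a, b = tree.children[node]
        for child, sib in ((a, b), (b, a)):
            psib = v[sib] + (tree.age[node] - tree.age[sib])
            prec_other = 1.0 / psib + w_prec[node]
            mean_other = (
                x[sib] / psib + y[node] * w_prec[node]
            ) / prec_other
            bl = tree.age[node] - tree.age[child]
            w_child = 1.0 / prec_other + bl
            y[child] = mean_other
            w_prec[child] = 1.0 / w_child
            if child >= n:  # internal node: fold both sides together
                prec = 1.0 / v[child] if v[child] > 0 else np.inf
                if np.isinf(prec):
                    est[child] = x[child]
                    var[child] = 0.0
                else:
                    tot = prec + w_prec[child]
                    est[child] = (x[child] * prec + y[child] * w_prec[child]) / tot
                    var[child] = 1.0 / tot
    rows = []
    for node in tree.postorder_internal():
        rows.append({
            "node": int(node),
            "age_ma": float(tree.age[node]),
            "estimate_m": float(est[node]),
            "variance_m2": float(var[node] * sigma2),
        })
    return pd.DataFrame(rows), float(sigma2)
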