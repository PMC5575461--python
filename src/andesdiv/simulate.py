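"""Synthetic phylogenies, geographic ranges, occurrences and uplift curves.

The generators produce data with the statistical structure the analysis
stack assumes: ultrametric chronograms simulated forward under
time-varying or region-dependent birth-death processes, two-region tip
range labels from a Gillespie GeoSSE process, spatially clustered
occurrence records with elevations, and a sigmoidal mountain-uplift
curve that plateaus near 4000 m at the present. Everything is seeded and
deterministic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import special, stats

from .trees import Chronogram, ChronogramError, _canonicalize, _splice_to_tips

__all__ = [
    "UpliftCurveSpec",
    "OccurrenceSpec",
    "DegenerateSimulationError",
    "make_uplift_curve",
    "simulate_bd_tree",
    "simulate_geosse",
    "simulate_occurrences",
    "reshuffle_ranges",
    "random_ultrametric_tree",
    "simulate_bm_on_tree",
]

RateLike = Union[float, Callable[[np.ndarray], np.ndarray]]


class DegenerateSimulationError(RuntimeError):
    """The process produced no usable tree (e.g. all rates zero, or
    extinction/unsampling left fewer than two tips after all retries)."""


# ---------------------------------------------------------------------- #
# uplift curve

@dataclass(frozen=True)
class UpliftCurveSpec:
    """Logistic mountain-uplift curve E(t) as a function of age t (Ma).

    ``E(t) = e_floor + (e_max - e_floor) / (1 + exp(-k * (t_mid - t)))``,
    so elevation rises from ``e_floor`` in the deep past to a plateau of
    ``e_max`` at the present, with inflection at ``t_mid``. Defaults mimic
    a Northern-Andes-style history peaking near 4000 m with the fastest
    uplift around 6 Ma.
    """

    e_max: float = 4000.0  # m, plateau mean elevation at present
    t_mid: float = 6.0     # Ma, inflection point of the uplift
    k: float = 1.0         # 1/Ma, steepness of the rise
    e_floor: float = 0.0   # m, pre-uplift elevation

    def __post_init__(self):
        if not self.e_max > self.e_floor >= 0:
            raise ValueError("require e_max > e_floor >= 0")
        if self.k <= 0:
            raise ValueError("require k > 0")

    def elevation(self, age):
        """Mean elevation (m) at the given age(s) in Ma."""
        age = np.asarray(age, dtype=float)
        return self.e_floor + (self.e_max - self.e_floor) * special.expit(
            self.k * (self.t_mid - age)
        )


def make_uplift_curve(
    spec: UpliftCurveSpec,
    ages: Optional[Sequence[float]] = None,
    t_max: float = 30.0,
    n: int = 61,
) -> pd.DataFrame:
    """Sample the uplift curve into an (age_ma, elev_m) table."""
    if ages is None:
        ages = np.linspace(0.0, t_max, n)
    ages = np.asarray(ages, dtype=float)
    if ages.size and ages.min() < 0:
        raise ValueError("ages must be non-negative")
    return pd.DataFrame({"age_ma": ages, "elev_m": spec.elevation(ages)})


# ---------------------------------------------------------------------- #
# forward-simulation bookkeeping shared by both tree simulators

def _assemble_tree(
    birth: List[float],
    end: List[float],
    events: List[List[Tuple[float, int]]],
    cut: float,
    sampled: Sequence[int],
    crown_pair: Optional[Tuple[int, int]] = None,
    label_prefix: str = "sp",
) -> Chronogram:
    """Build the reconstructed chronogram at forward time ``cut``.

    ``events[i]`` lists (time, child_lineage) birth events of lineage i in
    increasing time order. Lineages alive at ``cut`` become candidate tips;
    only those in ``sampled`` are kept. If ``crown_pair`` is given, those
    two lineages hang from an explicit root node at age ``cut``.
    """
    children: Dict[int, List[int]] = {}
    age: Dict[int, float] = {}
    tip_label: Dict[int, str] = {}
    next_id = 0

    def new_node(a: float) -> int:
        nonlocal next_id
        nid = next_id
        next_id += 1
        age[nid] = a
        return nid

    n_lin = len(birth)
    entry: List[Optional[int]] = [None] * n_lin
    chain_nodes: List[List[int]] = [[] for _ in range(n_lin)]
    term: List[Optional[int]] = [None] * n_lin
    for lin in range(n_lin):
        if birth[lin] >= cut:
            continue
        evs = [(t, c) for (t, c) in events[lin] if t < cut]
        ids = [new_node(cut - t) for (t, _) in evs]
        chain_nodes[lin] = ids
        if end[lin] >= cut:
            tid = new_node(0.0)
            tip_label[tid] = f"{label_prefix}{lin}"
            term[lin] = tid
        entry[lin] = ids[0] if ids else term[lin]
    # link chains (children of lineage lin were created after lin, but their
    # entry nodes are already assigned above)
    for lin in range(n_lin):
        ids = chain_nodes[lin]
        if not ids:
            continue
        evs = [(t, c) for (t, c) in events[lin] if t < cut]
        for j, (t, c) in enumerate(evs):
            kids: List[int] = []
            nxt = ids[j + 1] if j + 1 < len(ids) else term[lin]
            if nxt is not None:
                kids.append(nxt)
            ce = entry[c]
            if ce is not None:
                kids.append(ce)
            children[ids[j]] = kids
    sampled_tip_ids = [term[lin] for lin in sampled if term[lin] is not None]
    if len(sampled_tip_ids) < 2:
        raise ChronogramError("fewer than 2 sampled tips")
    if crown_pair is not None:
        root = new_node(cut)
        kids = [entry[crown_pair[0]], entry[crown_pair[1]]]
        children[root] = [k for k in kids if k is not None]
    else:
        root = entry[0]
        if root is None:
            raise ChronogramError("root lineage left no descendants")
    return _splice_to_tips(children, age, root, tip_label, sampled_tip_ids)


def _tip_lineage_index(label: str, prefix: str = "sp") -> int:
    return int(label[len(prefix):])


# ---------------------------------------------------------------------- #
# time-varying birth-death simulator

def simulate_bd_tree(
    lam: RateLike,
    mu: RateLike,
    crown_age: float,
    *,
    f: float = 1.0,
    seed=None,
    max_tries: int = 1000,
    max_lineages: int = 2_000_000,
    rate_grid: int = 4096,
) -> Chronogram:
    """Simulate a reconstructed chronogram under a time-varying birth-death.

    Rates ``lam``/``mu`` are functions of age (Myr before present) or
    constants; simulation runs forward from two crown lineages using a
    thinning (rejection) Gillespie scheme with a global rate bound taken
    from a dense grid. Extinct and unsampled lineages are pruned; each
    extant tip is retained independently with probability ``f``. Trees are
    rejection-resampled until both crown lineages retain at least one
    sampled descendant, so the reconstructed crown age equals
    ``crown_age`` exactly.
    """
    if crown_age <= 0:
        raise ValueError("crown_age must be positive")
    rng = np.random.default_rng(seed)
    T = float(crown_age)
    ages_grid = np.linspace(0.0, T, rate_grid + 1)
    lam_g = np.broadcast_to(np.asarray(lam(ages_grid) if callable(lam) else lam, float), ages_grid.shape).astype(float)
    mu_g = np.broadcast_to(np.asarray(mu(ages_grid) if callable(mu) else mu, float), ages_grid.shape).astype(float)
    if not (np.all(np.isfinite(lam_g)) and np.all(np.isfinite(mu_g))):
        raise ValueError("rates must be finite on [0, crown_age]")
    if lam_g.min() < 0 or mu_g.min() < 0:
        raise ValueError("rates must be non-negative")
    bound = float((lam_g + mu_g).max()) * (1.0 + 1e-9)
    dgrid = T / rate_grid

    for _ in range(max_tries):
        birth = [0.0, 0.0]
        end = [math.inf, math.inf]
        events: List[List[Tuple[float, int]]] = [[], []]
        side = [0, 1]
        alive = [0, 1]
        s = 0.0
        if bound > 0:
            while alive:
                s += rng.exponential(1.0 / (len(alive) * bound))
                if s >= T:
                    break
                j = int(rng.integers(len(alive)))
                lin = alive[j]
                a = T - s
                gi = a / dgrid
                i0 = min(int(gi), rate_grid - 1)
                w = gi - i0
                lt = lam_g[i0] * (1 - w) + lam_g[i0 + 1] * w
                mt = mu_g[i0] * (1 - w) + mu_g[i0 + 1] * w
                u = rng.random() * bound
                if u < lt:
                    k = len(birth)
                    if k >= max_lineages:
                        raise RuntimeError(
                            "simulation exceeded max_lineages; rates too high "
                            "for this crown age"
                        )
                    birth.append(s)
                    end.append(math.inf)
                    events[lin].append((s, k))
                    events.append([])
                    side.append(side[lin])
                    alive.append(k)
                elif u < lt + mt:
                    end[lin] = s
                    alive[j] = alive[-1]
                    alive.pop()
        if not alive:
            continue
        keep = rng.random(len(alive)) < f
        sampled = [lin for lin, k in zip(alive, keep) if k]
        if len(sampled) < 2 or len({side[lin] for lin in sampled}) < 2:
            continue
        return _assemble_tree(birth, end, events, T, sampled, crown_pair=(0, 1))
    raise DegenerateSimulationError(
        f"no surviving sampled tree in {max_tries} attempts"
    )


# ---------------------------------------------------------------------- #
# GeoSSE Gillespie simulator

_STATE_CODE = {"A": 0, "B": 1, "AB": 2}
_STATE_NAME = ("A", "B", "AB")


def simulate_geosse(
    params,
    root_state: str = "AB",
    *,
    n_tips: Optional[int] = None,
    t_max: Optional[float] = None,
    seed=None,
    sampling_fractions: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    max_tries: int = 200,
    t_cap: float = 10_000.0,
    max_lineages: int = 1_000_000,
    label_prefix: str = "sp",
) -> Tuple[Chronogram, Dict[str, str]]:
    """Gillespie simulation of the two-region GeoSSE process.

    Event semantics: within-region speciation sA/sB splits an A (or AB)
    lineage adding an A (or B) daughter; between-region speciation sAB
    splits a widespread AB lineage into an A and a B daughter; extirpation
    xA kills an A lineage but contracts an AB lineage to B; dispersal
    dA/dB expands a single-region lineage to AB. The process starts from a
    single stem lineage in ``root_state`` and is stopped either at
    ``t_max`` or, with ``n_tips``, at a time drawn uniformly from the
    epochs during which exactly ``n_tips`` lineages were extant
    (GSA-style sampling, avoiding first-passage bias). Extinct lineages
    are pruned and each surviving tip is kept with the state-specific
    sampling fraction.

    Returns the reconstructed chronogram and the tip -> {A,B,AB} range map.
    """
    from .geosse import GeoSSEParams  # local import to avoid cycle at import time

    if isinstance(params, GeoSSEParams):
        p = params
    else:
        p = GeoSSEParams(*params)
    if (n_tips is None) == (t_max is None):
        raise ValueError("specify exactly one of n_tips, t_max")
    if root_state not in _STATE_CODE:
        raise ValueError(f"invalid root state {root_state!r}")
    rates = np.array([p.sA, p.sB, p.sAB, p.xA, p.xB, p.dA, p.dB], float)
    if rates.min() < 0:
        raise ValueError("rates must be non-negative")
    sA, sB, sAB, xA, xB, dA, dB = rates
    # per-state total event rates
    RA = sA + xA + dA
    RB = sB + xB + dB
    RAB = sA + sB + sAB + xA + xB
    Rmax = max(RA, RB, RAB)
    if Rmax == 0.0:
        raise DegenerateSimulationError(
            "all rates are zero: the process never leaves a single lineage"
        )
    rng = np.random.default_rng(seed)
    stop_n = n_tips
    horizon = t_max if t_max is not None else t_cap

    for _ in range(max_tries):
        birth = [0.0]
        end = [math.inf]
        events: List[List[Tuple[float, int]]] = [[]]
        state_hist: List[List[Tuple[float, int]]] = [[(0.0, _STATE_CODE[root_state])]]
        state = [_STATE_CODE[root_state]]
        alive = [0]
        s = 0.0
        intervals: List[Tuple[float, float]] = []
        in_target_since = 0.0 if stop_n == 1 else None
        while alive and s < horizon:
            n_alive = len(alive)
            if stop_n is not None and n_alive >= 2 * stop_n:
                break
            s_new = s + rng.exponential(1.0 / (n_alive * Rmax))
            if s_new >= horizon:
                s = horizon
                break
            s = s_new
            j = int(rng.integers(n_alive))
            lin = alive[j]
            st = state[lin]
            Rlin = RA if st == 0 else (RB if st == 1 else RAB)
            u = rng.random() * Rmax
            if u >= Rlin:
                continue
            changed = False
            if st == 0:  # A
                if u < sA:  # speciation, A daughter
                    _spawn(birth, end, events, state_hist, state, alive, lin, s, 0)
                elif u < sA + xA:  # death
                    end[lin] = s
                    alive[j] = alive[-1]
                    alive.pop()
                    changed = True
                else:  # dispersal -> AB
                    state[lin] = 2
                    state_hist[lin].append((s, 2))
            elif st == 1:  # B
                if u < sB:
                    _spawn(birth, end, events, state_hist, state, alive, lin, s, 1)
                elif u < sB + xB:
                    end[lin] = s
                    alive[j] = alive[-1]
                    alive.pop()
                    changed = True
                else:
                    state[lin] = 2
                    state_hist[lin].append((s, 2))
            else:  # AB
                if u < sA:  # within-A speciation, A daughter
                    _spawn(birth, end, events, state_hist, state, alive, lin, s, 0)
                elif u < sA + sB:  # within-B speciation, B daughter
                    _spawn(birth, end, events, state_hist, state, alive, lin, s, 1)
                elif u < sA + sB + sAB:  # between-region split: A + B
                    state[lin] = 0
                    state_hist[lin].append((s, 0))
                    _spawn(birth, end, events, state_hist, state, alive, lin, s, 1)
                elif u < sA + sB + sAB + xA:  # extirpated from A -> B
                    state[lin] = 1
                    state_hist[lin].append((s, 1))
                else:  # extirpated from B -> A
                    state[lin] = 0
                    state_hist[lin].append((s, 0))
            if len(birth) > max_lineages:
                raise RuntimeError("simulation exceeded max_lineages")
            if stop_n is not None:
                n_alive = len(alive)
                if n_alive == stop_n and in_target_since is None:
                    in_target_since = s
                elif n_alive != stop_n and in_target_since is not None:
                    intervals.append((in_target_since, s))
                    in_target_since = None
        if stop_n is not None:
            if in_target_since is not None:
                intervals.append((in_target_since, s))
            if not intervals:
                continue
            lens = np.array([b - a for a, b in intervals])
            if lens.sum() <= 0:
                continue
            pick = rng.choice(len(intervals), p=lens / lens.sum())
            a, b = intervals[pick]
            cut = rng.uniform(a, b)
        else:
            cut = t_max
        extant = [
            lin for lin in range(len(birth)) if birth[lin] < cut and end[lin] >= cut
        ]
        if len(extant) < 2:
            continue
        fs = np.asarray(sampling_fractions, float)
        sampled = []
        tip_state: Dict[int, int] = {}
        for lin in extant:
            st = state_hist[lin][0][1]
            for (t, sstate) in state_hist[lin]:
                if t <= cut:
                    st = sstate
            if rng.random() < fs[st]:
                sampled.append(lin)
                tip_state[lin] = st
        if len(sampled) < 2:
            continue
        try:
            tree = _assemble_tree(
                birth, end, events, cut, sampled, crown_pair=None,
                label_prefix=label_prefix,
            )
        except ChronogramError:
            continue
        ranges = {
            lab: _STATE_NAME[tip_state[_tip_lineage_index(lab, label_prefix)]]
            for lab in tree.labels
        }
        return tree, ranges
    raise DegenerateSimulationError(
        f"no usable GeoSSE tree in {max_tries} attempts"
    )


def _spawn(birth, end, events, state_hist, state, alive, parent, s, child_state):
    k = len(birth)
    birth.append(s)
    end.append(math.inf)
    events[parent].append((s, k))
    events.append([])
    state_hist.append([(s, child_state)])
    state.append(child_state)
    alive.append(k)


# ---------------------------------------------------------------------- #
# occurrences

Box = Tuple[float, float, float, float]  # lon_min, lat_min, lon_max, lat_max


@dataclass(frozen=True)
class OccurrenceSpec:
    """Spatially clustered, region-structured occurrence generator.

    Each species gets a centroid drawn uniformly inside its region's
    lon/lat box; records scatter around it with isotropic Gaussian noise
    of ``scatter_sd`` degrees, and elevations are drawn from a per-region
    normal truncated at 0 m. Defaults sketch a Northern-Andes box ("A")
    against an adjacent lowland box ("B").
    """

    region_boxes: Mapping[str, Box] = field(
        default_factory=lambda: {
            "A": (-79.0, -5.0, -70.0, 12.0),
            "B": (-69.0, -15.0, -45.0, 5.0),
        }
    )
    records_per_species: float = 20.0  # Poisson mean, min 1 record
    scatter_sd: float = 0.5            # degrees
    elevation_model: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {"A": (2000.0, 600.0), "B": (300.0, 250.0)}
    )
    seed: Optional[int] = None

    def __post_init__(self):
        if not self.region_boxes:
            raise ValueError("region_boxes must be non-empty")
        if self.scatter_sd <= 0:
            raise ValueError("scatter_sd must be positive")
        for name, (x0, y0, x1, y1) in self.region_boxes.items():
            if not (x1 > x0 and y1 > y0):
                raise ValueError(f"empty box for region {name!r}")


def simulate_occurrences(
    tip_rates: Mapping[str, float],
    tip_regions: Mapping[str, str],
    spec: OccurrenceSpec = OccurrenceSpec(),
    seed=None,
) -> pd.DataFrame:
    """Generate (species, lon, lat, elev_m) records for every rated species.

    Widespread ("AB") species split their records between both boxes, with
    an independent centroid in each. Deterministic for a given seed.
    """
    if not tip_rates:
        raise ValueError("empty tip rate table")
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    rows = []
    for sp in tip_rates:
        if sp not in tip_regions:
            raise KeyError(f"species without region label: {sp!r}")
        region = tip_regions[sp]
        n_rec = max(1, int(rng.poisson(spec.records_per_species)))
        if region == "AB":
            n_a = int(rng.binomial(n_rec, 0.5))
            parts = [("A", n_a), ("B", n_rec - n_a)]
        else:
            if region not in spec.region_boxes:
                raise KeyError(f"species {sp!r} has unresolvable region {region!r}")
            parts = [(region, n_rec)]
        for box_name, n_part in parts:
            if n_part == 0:
                continue
            x0, y0, x1, y1 = spec.region_boxes[box_name]
            cx = rng.uniform(x0, x1)
            cy = rng.uniform(y0, y1)
            lon = np.clip(cx + rng.normal(0, spec.scatter_sd, n_part), -180, 180)
            lat = np.clip(cy + rng.normal(0, spec.scatter_sd, n_part), -90, 90)
            emean, esd = spec.elevation_model[box_name]
            elev = stats.truncnorm.rvs(
                a=(0.0 - emean) / esd, b=np.inf, loc=emean, scale=esd,
                size=n_part, random_state=rng,
            )
            for i in range(n_part):
                rows.append((sp, float(lon[i]), float(lat[i]), float(elev[i])))
    return pd.DataFrame(rows, columns=["species", "lon", "lat", "elev_m"])


def reshuffle_ranges(ranges: Mapping[str, str], seed=None) -> Dict[str, str]:
    """Uniform random permutation of the range states over the species set.

    The multiset of states is exactly preserved; only the assignment of
    states to species changes.
    """
    if not ranges:
        raise ValueError("empty range table")
    rng = np.random.default_rng(seed)
    species = list(ranges.keys())
    states = list(ranges.values())
    perm = rng.permutation(len(states))
    return {sp: states[i] for sp, i in zip(species, perm)}


# ---------------------------------------------------------------------- #
# auxiliary generators used by the validation studies

def random_ultrametric_tree(n_tips: int, crown_age: float, seed=None) -> Chronogram:
    """Random ultrametric topology with iid uniform branching times.

    Starts from two crown lineages at ``crown_age`` and adds n-2 splits at
    times drawn uniformly on (0, crown_age), attaching each to a uniformly
    chosen extant lineage. Useful for likelihood cross-checks where the
    tree-generating process itself is irrelevant.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    T = float(crown_age)
    times = np.sort(rng.uniform(0.0, T, n_tips - 2))[::-1]
    children: Dict[int, List[int]] = {}
    age: Dict[int, float] = {}
    next_id = 0

    def new_node(a: float) -> int:
        nonlocal next_id
        nid = next_id
        next_id += 1
        age[nid] = a
        return nid

    root = new_node(T)
    a0, b0 = new_node(0.0), new_node(0.0)
    children[root] = [a0, b0]
    # "open" lineages represented by their current terminal placeholder node
    open_tips = [(root, 0, a0), (root, 1, b0)]  # (parent, slot, tip_node)
    for t in times:
        pick = int(rng.integers(len(open_tips)))
        parent, slot, tipnode = open_tips[pick]
        node = new_node(t)
        na, nb = new_node(0.0), new_node(0.0)
        children[node] = [na, nb]
        children[parent][slot] = node
        open_tips[pick] = (node, 0, na)
        open_tips.append((node, 1, nb))
    tip_label = {}
    for i, (_, _, tipnode) in enumerate(open_tips):
        tip_label[tipnode] = f"t{i}"
    return _canonicalize(children, age, root, tip_label)


def simulate_bm_on_tree(
    tree: Chronogram, sigma2: float, root_value: float, seed=None
) -> Tuple[np.ndarray, Dict[str, float]]:
    """Brownian motion along the tree; returns all node values and tip map."""
    rng = np.random.default_rng(seed)
    vals = np.empty(tree.n_nodes)
    vals[tree.root] = root_value
    for node in reversed(range(tree.n_nodes - 1)):
        p = tree.parent[node]
        bl = tree.age[p] - tree.age[node]
        vals[node] = vals[p] + rng.normal(0.0, math.sqrt(max(sigma2 * bl, 0.0)))
    tips = {tree.labels[i]: float(vals[i]) for i in range(tree.n_tips)}
    return vals, tips
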