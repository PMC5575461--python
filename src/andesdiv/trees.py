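"""Chronogram container, Newick I/O and ultrametric utilities.

A chronogram is a rooted, binary, time-calibrated tree. Node ages are
measured backwards from the present in Myr: extant tips sit at age 0 and
the root at the crown age T. All downstream likelihoods (environment-
dependent birth-death, GeoSSE) and the ancestral-state machinery consume
this representation.

Nodes are integer indices. Tips occupy ``0 .. n_tips-1`` (matching the
order of :attr:`Chronogram.labels`); internal nodes follow in postorder,
so children always precede their parent and the root is the last index,
``2*n_tips - 2``.
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "ChronogramError",
    "NotUltrametricError",
    "parse_newick",
    "to_newick",
    "branching_times",
    "validate_ultrametric",
    "prune_to",
    "DEFAULT_ULTRAMETRIC_RTOL",
]

#: Default ultrametricity tolerance, as a fraction of the crown age.
DEFAULT_ULTRAMETRIC_RTOL = 1e-4


class ChronogramError(ValueError):
    """Malformed or unsupported tree input."""


class NotUltrametricError(ChronogramError):
    """Root-to-tip path lengths differ by more than the tolerance."""


class Chronogram:
    """Rooted binary ultrametric tree with ages in Myr before present.

    Parameters
    ----------
    labels :
        Tip labels; ``labels[i]`` names tip ``i``.
    parent :
        ``parent[i]`` is the parent index of node ``i`` (-1 for the root).
    children :
        ``(2n-1, 2)`` array; row ``i`` holds the two child indices of
        internal node ``i``, or ``(-1, -1)`` for tips.
    age :
        Node ages in Myr before present; tips 0, root = crown age.
    tip_depth_spread :
        Max minus min root-to-tip path length observed when the tree was
        built, retained so ultrametricity can be re-reported later.
    """

    __slots__ = ("n_tips", "labels", "parent", "children", "age", "tip_depth_spread")

    def __init__(
        self,
        labels: Sequence[str],
        parent: np.ndarray,
        children: np.ndarray,
        age: np.ndarray,
        tip_depth_spread: float = 0.0,
    ):
        self.n_tips = len(labels)
        if self.n_tips < 2:
            raise ChronogramError("a chronogram needs at least 2 tips")
        if len(set(labels)) != self.n_tips:
            raise ChronogramError("duplicate tip labels")
        n_nodes = 2 * self.n_tips - 1
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = np.asarray(children, dtype=np.int64)
        self.age = np.asarray(age, dtype=np.float64)
        if self.parent.shape != (n_nodes,) or self.children.shape != (n_nodes, 2):
            raise ChronogramError("inconsistent node arrays for a binary tree")
        if self.age.shape != (n_nodes,):
            raise ChronogramError("age array has wrong length")
        self.tip_depth_spread = float(tip_depth_spread)

    # ------------------------------------------------------------------ #
    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return 2 * self.n_tips - 2

    @property
    def crown_age(self) -> float:
        return float(self.age[self.root])

    def postorder_internal(self) -> range:
        """Internal node indices, children-before-parent (root last)."""
        return range(self.n_tips, self.n_nodes)

    def branch_length(self, i: int) -> float:
        """Length in Myr of the branch subtending node ``i``."""
        p = self.parent[i]
        if p < 0:
            return 0.0
        return float(self.age[p] - self.age[i])

    def tip_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"tip label not in tree: {label!r}") from None

    def total_branch_length(self) -> float:
        p = self.parent
        mask = p >= 0
        return float(np.sum(self.age[p[mask]] - self.age[np.nonzero(mask)[0]]))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Chronogram n_tips={self.n_tips} crown_age={self.crown_age:.4g} Myr>"


# ---------------------------------------------------------------------- #
# construction helpers

def _canonicalize(
    children: Mapping[int, Sequence[int]],
    age: Mapping[int, float],
    root: int,
    tip_label: Mapping[int, str],
    tip_depth_spread: float = 0.0,
) -> Chronogram:
    """Renumber an arbitrary-index binary tree into canonical postorder form."""
    order: List[int] = []
    stack: List[Tuple[int, bool]] = [(root, False)]
    while stack:
        node, done = stack.pop()
        kids = children.get(node, ())
        if done or not kids:
            order.append(node)
            continue
        stack.append((node, True))
        for c in reversed(list(kids)):
            stack.append((c, False))
    tips = [n for n in order if not children.get(n)]
    internals = [n for n in order if children.get(n)]
    n_tips = len(tips)
    if n_tips < 2:
        raise ChronogramError("fewer than 2 tips")
    new_id: Dict[int, int] = {t: i for i, t in enumerate(tips)}
    for j, n in enumerate(internals):
        new_id[n] = n_tips + j
    n_nodes = 2 * n_tips - 1
    if len(internals) != n_tips - 1:
        raise ChronogramError("tree is not strictly binary")
    parent = np.full(n_nodes, -1, dtype=np.int64)
    ch = np.full((n_nodes, 2), -1, dtype=np.int64)
    ages = np.zeros(n_nodes)
    labels = [tip_label[t] for t in tips]
    for n in order:
        ages[new_id[n]] = age[n]
        kids = children.get(n, ())
        if kids:
            if len(kids) != 2:
                raise ChronogramError(
                    f"polytomy or unifurcation at a node with {len(kids)} children; "
                    "only strictly binary trees are supported"
                )
            for c in kids:
                parent[new_id[c]] = new_id[n]
                if ch[new_id[n], 0] < 0:
                    ch[new_id[n], 0] = new_id[c]
                else:
                    ch[new_id[n], 1] = new_id[c]
    return Chronogram(labels, parent, ch, ages, tip_depth_spread)


def _splice_to_tips(
    children: Mapping[int, Sequence[int]],
    age: Mapping[int, float],
    root: int,
    tip_label: Mapping[int, str],
    keep_tips: Iterable[int],
    tip_depth_spread: float = 0.0,
) -> Chronogram:
    """Restrict a (possibly degenerate) rooted tree to a set of tips.

    Nodes left with a single surviving child are spliced out, nodes with
    none are dropped, and the new root is the MRCA of the kept tips.
    Accepts chains with 1 or 2 children per node, as produced by the
    forward simulators.
    """
    keep = set(keep_tips)
    order: List[int] = []
    stack: List[Tuple[int, bool]] = [(root, False)]
    while stack:
        node, done = stack.pop()
        kids = children.get(node, ())
        if done or not kids:
            order.append(node)
            continue
        stack.append((node, True))
        for c in reversed(list(kids)):
            stack.append((c, False))
    rep: Dict[int, Optional[int]] = {}
    new_children: Dict[int, List[int]] = {}
    for n in order:
        kids = children.get(n, ())
        if not kids:
            rep[n] = n if n in keep else None
        else:
            got = [rep[c] for c in kids if rep.get(c) is not None]
            if len(got) >= 2:
                new_children[n] = got
                rep[n] = n
            elif len(got) == 1:
                rep[n] = got[0]
            else:
                rep[n] = None
    new_root = rep.get(root)
    if new_root is None or new_root not in new_children:
        raise ChronogramError("fewer than 2 tips survive pruning")
    return _canonicalize(new_children, age, new_root, tip_label, tip_depth_spread)


# ---------------------------------------------------------------------- #
# public operations

def parse_newick(
    text: str,
    *,
    strict: bool = True,
    tol: Optional[float] = None,
) -> Chronogram:
    """Parse a Newick string with branch lengths into a :class:`Chronogram`.

    Branch lengths are mandatory and interpreted in Myr; comments and
    internal node labels are ignored. In strict mode (default) a tree whose
    root-to-tip path lengths differ by more than ``tol`` (default
    ``1e-4 * crown_age``) raises :class:`NotUltrametricError`; with
    ``strict=False`` the spread is recorded on the returned tree instead.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise ChronogramError(f"malformed Newick: {exc}") from exc

    children: Dict[int, List[int]] = {}
    depth: Dict[int, float] = {}
    tip_label: Dict[int, str] = {}
    seen_labels = set()
    root = id(dtree.seed_node)
    depth[root] = 0.0
    for nd in dtree.preorder_node_iter():
        nid = id(nd)
        kids = nd.child_nodes()
        if kids:
            children[nid] = [id(c) for c in kids]
        else:
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if not label:
                raise ChronogramError("tip without a label")
            if label in seen_labels:
                raise ChronogramError(f"duplicate tip label: {label!r}")
            seen_labels.add(label)
            tip_label[nid] = label
        if nid != root:
            bl = nd.edge.length
            if bl is None:
                raise ChronogramError("branch without a length")
            if bl < 0:
                raise ChronogramError(f"negative branch length: {bl}")
            depth[nid] = depth[id(nd.parent_node)] + float(bl)
    if len(tip_label) < 2:
        raise ChronogramError("a chronogram needs at least 2 tips")
    if root in tip_label or len(children.get(root, ())) < 2:
        raise ChronogramError("root must have two children (no basal unifurcation)")

    tip_depths = np.array([depth[t] for t in tip_label])
    crown = float(tip_depths.max())
    if crown <= 0:
        raise ChronogramError("crown age must be positive")
    spread = float(tip_depths.max() - tip_depths.min())
    tol_abs = tol if tol is not None else DEFAULT_ULTRAMETRIC_RTOL * crown
    if strict and spread > tol_abs:
        raise NotUltrametricError(
            f"tree is not ultrametric: tip depth spread {spread:.6g} Myr "
            f"exceeds tolerance {tol_abs:.6g} Myr"
        )
    age = {n: crown - d for n, d in depth.items()}
    if strict:
        for t in tip_label:
            age[t] = 0.0
    return _canonicalize(children, age, root, tip_label, spread)


def to_newick(tree: Chronogram, precision: int = 17) -> str:
    """Serialize to Newick with branch lengths (round-trips to 1e-9)."""
    frag: Dict[int, str] = {}
    for i in range(tree.n_tips):
        frag[i] = _quote_label(tree.labels[i])
    for n in tree.postorder_internal():
        a, b = tree.children[n]
        pa = f"{frag[a]}:{tree.age[n] - tree.age[a]:.{precision}g}"
        pb = f"{frag[b]}:{tree.age[n] - tree.age[b]:.{precision}g}"
        frag[n] = f"({pa},{pb})"
    return frag[tree.root] + ";"


def _quote_label(label: str) -> str:
    if any(c in label for c in "(),:;[]' \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def branching_times(tree: Chronogram, *, tol: Optional[float] = None) -> np.ndarray:
    """Internal node ages in Myr, sorted descending (crown age first)."""
    ok, spread = validate_ultrametric(tree, tol=tol)
    if not ok:
        raise NotUltrametricError(
            f"branching times undefined: tip depth spread {spread:.6g} Myr"
        )
    return np.sort(tree.age[tree.n_tips:])[::-1].copy()


def validate_ultrametric(
    tree: Chronogram, tol: Optional[float] = None
) -> Tuple[bool, float]:
    """Return ``(is_ultrametric, tip_depth_spread)``.

    The spread combines the deviation recorded at parse/build time with any
    nonzero tip ages present in the array representation.
    """
    tip_ages = tree.age[: tree.n_tips]
    spread = max(tree.tip_depth_spread, float(tip_ages.max() - tip_ages.min()))
    tol_abs = tol if tol is not None else DEFAULT_ULTRAMETRIC_RTOL * tree.crown_age
    return spread <= tol_abs, spread


def prune_to(tree: Chronogram, labels: Iterable[str]) -> Chronogram:
    """Prune the tree to the given tip labels (MRCA becomes the new root)."""
    keep_labels = set(labels)
    missing = keep_labels - set(tree.labels)
    if missing:
        raise KeyError(f"labels not in tree: {sorted(missing)}")
    keep = [i for i, lab in enumerate(tree.labels) if lab in keep_labels]
    if len(keep) < 2:
        raise ChronogramError("pruning must keep at least 2 tips")
    children = {
        int(n): [int(tree.children[n, 0]), int(tree.children[n, 1])]
        for n in tree.postorder_internal()
    }
    age = {i: float(tree.age[i]) for i in range(tree.n_nodes)}
    tip_label = {i: tree.labels[i] for i in range(tree.n_tips)}
    return _splice_to_tips(
        children, age, tree.root, tip_label, keep, tree.tip_depth_spread
    )
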