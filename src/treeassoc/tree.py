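"""Rooted, timed binary trees and the tree algorithms used throughout.

A genealogy for ``n`` haplotypes is a rooted binary tree with ``n`` tips at
time 0 and ``n - 1`` internal nodes at strictly positive times (coalescent
units, one unit = 2Ne generations).  Nodes are integer ids: tips are
``0 .. n-1`` and internal nodes ``n .. 2n-2``; the root is whichever node has
no parent.  The topology is held as a parent-pointer array, which keeps
copying cheap inside the MCMC sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RootedTree",
    "Bipartition",
    "TreeError",
    "eligibility_threshold",
    "enumerate_eligible_bipartitions",
    "tmrca",
    "rf_distance",
]

_TIP_TIME_TOL = 1e-9


class TreeError(ValueError):
    """Raised for structurally invalid trees or invalid tree operations."""


@dataclass(frozen=True)
class Bipartition:
    """Two-group split of the tips induced by cutting one internal branch.

    ``cluster`` is the set of tip indices descending from ``branch`` (the id
    of the child node of the cut edge); the complement is the second group.
    """

    cluster: frozenset
    branch: int


class RootedTree:
    """Rooted ultrametric binary tree with node times.

    Parameters
    ----------
    parent
        Length ``2n - 1`` integer array; ``parent[v]`` is the parent node id
        of ``v``, and ``-1`` marks the root.
    time
        Length ``2n - 1`` float array of node times; tips must be at 0.
    tip_labels
        ``n`` unique labels, one per tip node ``0 .. n-1``.
    validate
        Skip structural validation when False (internal fast path; the
        caller guarantees validity).
    """

    __slots__ = ("parent", "time", "tip_labels", "n_tips", "_children", "_postorder")

    def __init__(
        self,
        parent: Sequence[int],
        time: Sequence[float],
        tip_labels: Sequence[str],
        *,
        validate: bool = True,
    ):
        self.parent = np.asarray(parent, dtype=np.int64).copy()
        self.time = np.asarray(time, dtype=np.float64).copy()
        self.tip_labels = tuple(str(x) for x in tip_labels)
        self.n_tips = len(self.tip_labels)
        self._children = None
        self._postorder = None
        if validate:
            self._validate()

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        return int(roots[0])

    @property
    def children(self) -> np.ndarray:
        """``(2n-1, 2)`` child ids per node; ``-1`` for tips."""
        if self._children is None:
            n_nodes = self.n_nodes
            ch = np.full((n_nodes, 2), -1, dtype=np.int64)
            count = np.zeros(n_nodes, dtype=np.int64)
            for v in range(n_nodes):
                p = self.parent[v]
                if p >= 0:
                    if count[p] >= 2:
                        raise TreeError(f"node {p} has more than two children")
                    ch[p, count[p]] = v
                    count[p] += 1
            self._children = ch
        return self._children

    def postorder(self) -> np.ndarray:
        """Node ids, children always before parents."""
        if self._postorder is None:
            ch = self.children
            order = np.empty(self.n_nodes, dtype=np.int64)
            stack = [self.root]
            k = self.n_nodes
            # reverse of a preorder DFS puts children before parents
            while stack:
                v = stack.pop()
                k -= 1
                order[k] = v
                if ch[v, 0] >= 0:
                    stack.append(ch[v, 0])
                    stack.append(ch[v, 1])
            if k != 0:
                raise TreeError("tree is not connected")
            self._postorder = order
        return self._postorder

    def _validate(self) -> None:
        n = self.n_tips
        if n < 2:
            raise TreeError("tree needs at least 2 tips")
        if len(set(self.tip_labels)) != n:
            raise TreeError("tip labels must be unique")
        if self.parent.shape != (2 * n - 1,) or self.time.shape != (2 * n - 1,):
            raise TreeError("parent/time arrays must have length 2n-1")
        root = self.root  # checks single root
        ch = self.children  # checks <=2 children
        n_children = (ch >= 0).sum(axis=1)
        if np.any(n_children[:n] != 0):
            raise TreeError("tip nodes must have no children")
        if np.any(n_children[n:] != 2):
            raise TreeError("internal nodes must have exactly two children")
        if np.any(np.abs(self.time[:n]) > _TIP_TIME_TOL):
            raise TreeError("tips must be at time 0")
        if np.any(self.time < 0):
            raise TreeError("node times must be nonnegative")
        non_root = np.arange(2 * n - 1) != root
        if np.any(self.time[self.parent[non_root]] <= self.time[non_root]):
            raise TreeError("child node time must be strictly below parent time")
        self.postorder()  # raises if not connected

    def copy(self) -> "RootedTree":
        return RootedTree(self.parent, self.time, self.tip_labels, validate=False)

    # ------------------------------------------------------------------
    # derived quantities
    # ------------------------------------------------------------------
    def tmrca(self) -> float:
        """Time to the most recent common ancestor (the root time)."""
        return float(self.time[self.root])

    def total_branch_length(self) -> float:
        root = self.root
        mask = np.arange(self.n_nodes) != root
        return float(np.sum(self.time[self.parent[mask]] - self.time[mask]))

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        out = np.zeros(self.n_nodes)
        root = self.root
        mask = np.arange(self.n_nodes) != root
        out[mask] = self.time[self.parent[mask]] - self.time[mask]
        return out

    def cluster_sizes(self) -> np.ndarray:
        """Number of descendant tips per node (1 for tips)."""
        return self.accumulate_tip_values(np.ones(self.n_tips))

    def accumulate_tip_values(self, tip_values: np.ndarray) -> np.ndarray:
        """Sum ``tip_values`` over descendant tips, for every node."""
        vals = np.zeros(self.n_nodes, dtype=np.float64)
        vals[: self.n_tips] = tip_values
        ch = self.children
        for v in self.postorder():
            if ch[v, 0] >= 0:
                vals[v] = vals[ch[v, 0]] + vals[ch[v, 1]]
        return vals

    def clades(self) -> dict:
        """Descendant tip-label frozenset for each internal non-root node."""
        root = self.root
        ch = self.children
        sets: dict = {}
        out = {}
        for v in self.postorder():
            if ch[v, 0] < 0:
                sets[v] = frozenset((self.tip_labels[v],))
            else:
                sets[v] = sets[ch[v, 0]] | sets[ch[v, 1]]
                if v != root:
                    out[v] = sets[v]
        return out

    def tip_index_clusters(self) -> dict:
        """Descendant tip-index frozenset for each internal non-root node."""
        root = self.root
        ch = self.children
        sets: dict = {}
        out = {}
        for v in self.postorder():
            if ch[v, 0] < 0:
                sets[v] = frozenset((v,))
            else:
                sets[v] = sets[ch[v, 0]] | sets[ch[v, 1]]
                if v != root:
                    out[v] = sets[v]
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RootedTree(n_tips={self.n_tips}, tmrca={self.tmrca():.4g})"


# ----------------------------------------------------------------------
# module-level operations
# ----------------------------------------------------------------------
def tmrca(tree: RootedTree) -> float:
    """Root time of the genealogy."""
    return tree.tmrca()


def eligibility_threshold(n_tips: int, min_frac: float) -> int:
    """Minimum cluster size ``ceil(min_frac * n)``.

    A small epsilon guards against binary floating point pushing exact
    products such as ``0.05 * 40`` just above the integer they represent.
    """
    return int(math.ceil(min_frac * n_tips - 1e-9))


def enumerate_eligible_bipartitions(tree: RootedTree, min_frac: float) -> list:
    """All eligible bipartition clusterings of a tree.

    One bipartition per internal branch (edge whose child is an internal,
    non-root node); eligible iff both the cluster and its complement contain
    at least ``ceil(min_frac * n)`` tips.  Ordered by branch child id.
    """
    if not (0 <= min_frac < 0.5):
        raise ValueError("min_frac must be in [0, 0.5)")
    n = tree.n_tips
    thr = eligibility_threshold(n, min_frac)
    out = []
    clusters = tree.tip_index_clusters()
    for v in sorted(clusters):
        size = len(clusters[v])
        if size >= thr and n - size >= thr:
            out.append(Bipartition(cluster=clusters[v], branch=int(v)))
    return out


def rf_distance(t1: RootedTree, t2: RootedTree) -> int:
    """Robinson–Foulds symmetric distance between two rooted trees.

    The size of the symmetric difference between the trees' sets of
    non-trivial clades (descendant tip-label sets of internal non-root
    branches).  Used as an MCMC mixing diagnostic.
    """
    if set(t1.tip_labels) != set(t2.tip_labels):
        raise TreeError("trees must share an identical tip label set")
    c1 = set(t1.clades().values())
    c2 = set(t2.clades().values())
    return len(c1 ^ c2)
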