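"""Metropolis-Hastings sampler of genealogies and rates at a focal point.

The augmented state holds the marginal genealogy at the focal point, the
(latent) haplotypes at its internal nodes, and the scaled mutation and
recombination rates theta and rho.  The unnormalized target combines a
Kingman coalescent prior over the tree, a uniform prior over theta, a gamma
prior over rho, and an emission likelihood for the observed window
haplotypes.

Emission model
--------------
Recombination breakpoints are integrated out by a per-marker
linked/unlinked mixture.  A marker at base-pair distance d from the focal
point stays linked to the focal genealogy with probability
w = exp(-(rho/2) * d * L_total), where L_total is the total branch length
-- the probability that no recombination between the marker and the focal
point hits any branch.  Conditional on being linked, every child allele
follows a symmetric two-state mutation chain along its branch of duration
t with flip probability (1 - exp(-theta * t)) / 2, and the root allele is
drawn from the marker's sample allele frequency.  An unlinked marker
carries no tree information: all its node alleles are modelled as
independent draws from the sample allele frequency.  This keeps the
defining features of the model -- coalescent prior, per-SNP mutation event
rate theta/2, per-bp recombination event rate rho/2, and decay of tree
information with distance from the focal point -- in a tractable,
fully-testable likelihood.

Five proposal kernels modify, respectively, theta, rho, one internal-node
allele, the topology locally (nearest-neighbour swap with a time
resample), and the topology globally (subtree prune-regraft).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .io import HaplotypeDataset
from .tree import RootedTree, rf_distance

__all__ = [
    "AugmentedState",
    "SamplerConfig",
    "FocalPointResult",
    "PROPOSAL_KINDS",
    "log_target",
    "mh_acceptance",
    "propose",
    "run_sampler",
    "summarize_rates",
    "initial_tree",
]

PROPOSAL_KINDS = ("theta", "rho", "internal_haplotype", "topology_local", "topology_spr")

_FREQ_CLAMP = 1e-3  # sample allele frequencies clamped away from 0/1


def _tree_unchecked(parent, time, tip_labels, children=None) -> RootedTree:
    """Wrap arrays without copying or validating (sampler-internal)."""
    t = RootedTree.__new__(RootedTree)
    t.parent = parent
    t.time = time
    t.tip_labels = tip_labels
    t.n_tips = len(tip_labels)
    t._children = children
    t._postorder = None
    return t


@dataclass(slots=True)
class AugmentedState:
    """Tree + internal haplotypes + rates: one point of the MCMC state space.

    ``internal_haplotypes`` has one row per internal node (node id ``n + i``
    maps to row ``i``) and one column per window SNP.
    """

    tree: RootedTree
    internal_haplotypes: np.ndarray
    theta: float
    rho: float

    def copy(self) -> "AugmentedState":
        tr = self.tree
        return AugmentedState(
            _tree_unchecked(
                tr.parent.copy(),
                tr.time.copy(),
                tr.tip_labels,
                tr.children.copy(),
            ),
            self.internal_haplotypes.copy(),
            self.theta,
            self.rho,
        )


@dataclass
class SamplerConfig:
    """Chain-length, proposal and prior settings for one focal-point run.

    The priors default to theta ~ Uniform(0.0001, 10) and
    rho ~ Gamma(shape 1, scale 0.1), with theta initialised at 0.1 and rho
    at 0.0004 (the coalescent-unit equivalent of 1 cM/Mb at Ne = 10,000).
    ``proposal_probs`` orders the kernels as :data:`PROPOSAL_KINDS`.
    """

    n_iterations: int
    burn_in: int
    thin: int = 1
    proposal_probs: Tuple[float, ...] = (0.1, 0.1, 0.3, 0.25, 0.25)
    theta_prior: Tuple[float, float] = (0.0001, 10.0)
    rho_prior: Tuple[float, float] = (1.0, 0.1)  # shape, scale
    theta_init: float = 0.1
    rho_init: float = 0.0004
    seed: int = 0
    delta_theta: float = 0.5
    delta_rho: float = 0.5

    def __post_init__(self):
        if self.n_iterations < 1 or not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("need 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        probs = np.asarray(self.proposal_probs, dtype=np.float64)
        if probs.shape != (5,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("proposal_probs must be 5 nonnegative values summing to 1")
        lo, hi = self.theta_prior
        if not (0 < lo < hi):
            raise ValueError("theta prior must satisfy 0 < lo < hi")
        shape, scale = self.rho_prior
        if shape <= 0 or scale <= 0:
            raise ValueError("rho prior shape and scale must be positive")
        if not (lo <= self.theta_init <= hi):
            raise ValueError("theta_init must lie in the prior support")
        if self.rho_init <= 0:
            raise ValueError("rho_init must be positive")
        if self.delta_theta <= 0 or self.delta_rho <= 0:
            raise ValueError("proposal windows must be positive")


@dataclass
class FocalPointResult:
    """Retained (post burn-in, thinned) samples and diagnostics."""

    focal_bp: float
    window: Tuple[int, int]
    sampled_trees: list
    sampled_theta: np.ndarray
    sampled_rho: np.ndarray
    acceptance_rates: dict
    diagnostics: dict

    @property
    def n_samples(self) -> int:
        return len(self.sampled_trees)


# ----------------------------------------------------------------------
# target density
# ----------------------------------------------------------------------
class _Ctx:
    """Precomputed, per-run constants of the target density."""

    __slots__ = (
        "tip_alleles", "dist", "freq", "n_tips", "log_f", "log_1mf",
        "tip_bg_cols", "coal_coeff",
        "theta_lo", "theta_hi", "log_theta_norm",
        "rho_shape", "rho_scale", "log_rho_norm",
    )

    def __init__(self, data: Optional[HaplotypeDataset], focal_bp: float,
                 n_tips: int, config: SamplerConfig):
        self.n_tips = n_tips
        if data is None or data_is_empty(data):
            self.tip_alleles = np.zeros((n_tips, 0), dtype=np.uint8)
            self.dist = np.zeros(0)
            self.freq = np.zeros(0)
        else:
            self.tip_alleles = data.alleles
            self.dist = np.abs(data.positions.astype(np.float64) - focal_bp)
            f = data.alleles.mean(axis=0)
            self.freq = np.clip(f, _FREQ_CLAMP, 1.0 - _FREQ_CLAMP)
        self.log_f = np.log(self.freq) if len(self.freq) else np.zeros(0)
        self.log_1mf = np.log1p(-self.freq) if len(self.freq) else np.zeros(0)
        self.tip_bg_cols = np.where(
            self.tip_alleles == 1, self.log_f, self.log_1mf
        ).sum(axis=0)
        # sorted internal times t_(1) <= ... <= t_(n-1) give coalescent
        # log-density -sum_i (n - i) * t_(i)
        self.coal_coeff = np.arange(n_tips - 1, 0, -1, dtype=np.float64)
        self.theta_lo, self.theta_hi = config.theta_prior
        self.log_theta_norm = -math.log(self.theta_hi - self.theta_lo)
        self.rho_shape, self.rho_scale = config.rho_prior
        self.log_rho_norm = -(
            self.rho_shape * math.log(self.rho_scale) + math.lgamma(self.rho_shape)
        )


def data_is_empty(data: HaplotypeDataset) -> bool:
    return data.alleles.shape[1] == 0


def _log_coalescent_prior(tree: RootedTree) -> float:
    """Kingman log-density of topology and times (labelled history).

    With k lineages the waiting time is Exp(k(k-1)/2) and the merging pair
    is uniform among C(k, 2); the product collapses to
    exp(-sum_k C(k, 2) * w_k) over inter-coalescence intervals w_k, which
    telescopes to -sum_i (n - i) * t_(i) over sorted internal times.
    """
    n = tree.n_tips
    times = np.sort(tree.time[n:])
    return float(-np.dot(np.arange(n - 1, 0, -1, dtype=np.float64), times))


def _log_likelihood(state: AugmentedState, ctx: _Ctx) -> float:
    L = ctx.tip_alleles.shape[1]
    if L == 0:
        return 0.0
    tree = state.tree
    n = tree.n_tips
    parent = tree.parent
    time = tree.time
    root = int(np.flatnonzero(parent == -1)[0])
    A = np.concatenate((ctx.tip_alleles, state.internal_haplotypes), axis=0)
    idx = np.concatenate((np.arange(root), np.arange(root + 1, 2 * n - 1)))
    t = time[parent[idx]] - time[idx]
    total_len = float(t.sum())
    flip = np.maximum(0.5 * (1.0 - np.exp(-state.theta * t)), 1e-300)
    child = A[idx]
    match = child == A[parent[idx]]
    with np.errstate(divide="ignore"):
        log_mut = np.where(match, np.log1p(-flip)[:, None], np.log(flip)[:, None])
        log_node_bg = np.log(np.where(A == 1, ctx.freq, 1.0 - ctx.freq))
        # linked: mutation chain over branches + root from allele frequency
        log_tree = log_mut.sum(axis=0) + log_node_bg[root]
        # unlinked: every node allele an independent frequency draw
        log_bg = log_node_bg.sum(axis=0)
        log_w = (-0.5 * state.rho * total_len) * ctx.dist
        log_1mw = np.log1p(-np.exp(log_w))
    ll = np.logaddexp(log_w + log_tree, log_1mw + log_bg).sum()
    return float(ll)


def _log_target_ctx(state: AugmentedState, ctx: _Ctx) -> float:
    theta, rho = state.theta, state.rho
    if not (ctx.theta_lo <= theta <= ctx.theta_hi) or rho <= 0:
        return -np.inf
    lp = _log_coalescent_prior(state.tree)
    lp += ctx.log_theta_norm
    lp += (
        (ctx.rho_shape - 1.0) * math.log(rho) - rho / ctx.rho_scale + ctx.log_rho_norm
    )
    return lp + _log_likelihood(state, ctx)


class _CachedTarget:
    """Incremental evaluation of the target along the chain.

    The per-marker pieces of the log-likelihood factorise as
    ``logaddexp(log_w + log_tree, log(1-w) + log_bg)``; proposals touch
    only some pieces (a rho move only the linkage weights, an internal
    allele flip only three branch terms of one marker), so the chain can
    avoid full recomputation.  ``_log_target_ctx`` remains the reference
    implementation; the two are checked against each other in the tests.
    """

    def __init__(self, ctx: _Ctx, state: AugmentedState):
        self.ctx = ctx
        self.state = state
        self.L = ctx.tip_alleles.shape[1]
        self._pending = None
        self._full_refresh(state)

    # -- piece computations -------------------------------------------
    def _tree_pieces(self, state):
        ctx = self.ctx
        tree = state.tree
        parent = tree.parent
        root = int(parent.argmin())
        parent_full = parent.copy()
        parent_full[root] = root  # zero-length pseudo-branch: contributes 0
        t = tree.time[parent_full] - tree.time
        total_len = float(t.sum())
        log_coal = float(-np.dot(ctx.coal_coeff, np.sort(tree.time[ctx.n_tips:])))
        return root, parent_full, t, total_len, log_coal

    def _mut_cols(self, state, root, parent_full, t):
        ctx = self.ctx
        # floor keeps log(flip) finite on (near-)zero branches, including
        # the zero-length pseudo-branch above the root (whose row always
        # matches and contributes log1p(-flip) ~ 0)
        flip = np.maximum(0.5 * (1.0 - np.exp(-state.theta * t)), 1e-300)
        A = np.concatenate((ctx.tip_alleles, state.internal_haplotypes), axis=0)
        match = A == A[parent_full]
        with np.errstate(divide="ignore"):
            log_flip = np.log(flip)
        log_stay = np.log1p(-flip)
        log_mut = np.where(match, log_stay[:, None], log_flip[:, None]).sum(axis=0)
        root_bg = np.where(A[root] == 1, ctx.log_f, ctx.log_1mf)
        return flip, A, log_mut + root_bg

    def _bg_cols(self, state):
        ctx = self.ctx
        internal = np.where(
            state.internal_haplotypes == 1, ctx.log_f, ctx.log_1mf
        ).sum(axis=0)
        return ctx.tip_bg_cols + internal

    def _w_cols(self, state, total_len):
        log_w = (-0.5 * state.rho * total_len) * self.ctx.dist
        with np.errstate(divide="ignore"):
            log_1mw = np.log1p(-np.exp(log_w))
        return log_w, log_1mw

    def _rate_priors(self, state):
        ctx = self.ctx
        if not (ctx.theta_lo <= state.theta <= ctx.theta_hi) or state.rho <= 0:
            return -np.inf
        return (
            ctx.log_theta_norm
            + (ctx.rho_shape - 1.0) * math.log(state.rho)
            - state.rho / ctx.rho_scale
            + ctx.log_rho_norm
        )

    def _assemble(self, log_tree_cols, bg_cols, log_w, log_1mw):
        if self.L == 0:
            return 0.0
        return float(np.logaddexp(log_w + log_tree_cols, log_1mw + bg_cols).sum())

    def _full_refresh(self, state):
        self.root, self.parent_full, self.t, self.total_len, self.log_coal = (
            self._tree_pieces(state)
        )
        self.flip, self.A, self.log_tree_cols = self._mut_cols(
            state, self.root, self.parent_full, self.t
        )
        self.bg_cols = self._bg_cols(state)
        self.log_w, self.log_1mw = self._w_cols(state, self.total_len)
        self.ll = self._assemble(self.log_tree_cols, self.bg_cols,
                                 self.log_w, self.log_1mw)
        self.lt = self.log_coal + self._rate_priors(state) + self.ll
        self.state = state

    # -- proposal evaluation ------------------------------------------
    def eval_candidate(self, kind: int, cand: AugmentedState) -> float:
        """Log target of a candidate; stashes pieces for ``accept``."""
        self._pending = None
        if kind == 0:  # theta: mutation-chain terms change
            pri = self._rate_priors(cand)
            if pri == -np.inf:
                return -np.inf
            flip, A, log_tree_cols = self._mut_cols(
                cand, self.root, self.parent_full, self.t
            )
            ll = self._assemble(log_tree_cols, self.bg_cols, self.log_w, self.log_1mw)
            lt = self.log_coal + pri + ll
            self._pending = ("theta", cand, flip, log_tree_cols, ll, lt)
            return lt
        if kind == 1:  # rho: only the linkage weights change
            pri = self._rate_priors(cand)
            if pri == -np.inf:
                return -np.inf
            log_w, log_1mw = self._w_cols(cand, self.total_len)
            ll = self._assemble(self.log_tree_cols, self.bg_cols, log_w, log_1mw)
            lt = self.log_coal + pri + ll
            self._pending = ("rho", cand, log_w, log_1mw, ll, lt)
            return lt
        if kind == 2 and self.L > 0:  # one internal allele flipped
            diff = np.argwhere(cand.internal_haplotypes != self.state.internal_haplotypes)
            i, j = (int(diff[0][0]), int(diff[0][1]))
            node = self.ctx.n_tips + i
            new_allele = int(cand.internal_haplotypes[i, j])
            lf, l1 = float(self.ctx.log_f[j]), float(self.ctx.log_1mf[j])
            d_tree = 0.0
            d_bg = (lf - l1) if new_allele == 1 else (l1 - lf)
            # branch above the node (or the root background term)
            if node == self.root:
                d_tree += d_bg
            else:
                old_match = self.A[node, j] == self.A[self.parent_full[node], j]
                d_tree += self._mut_term(node, not old_match) - self._mut_term(node, old_match)
            # branches to the two children
            ch = self.state.tree.children
            for c in (int(ch[node, 0]), int(ch[node, 1])):
                old_match = self.A[c, j] == self.A[node, j]
                d_tree += self._mut_term(c, not old_match) - self._mut_term(c, old_match)
            log_tree_j = self.log_tree_cols[j] + d_tree
            bg_j = self.bg_cols[j] + d_bg
            old_term = np.logaddexp(self.log_w[j] + self.log_tree_cols[j],
                                    self.log_1mw[j] + self.bg_cols[j])
            new_term = np.logaddexp(self.log_w[j] + log_tree_j,
                                    self.log_1mw[j] + bg_j)
            ll = self.ll - float(old_term) + float(new_term)
            lt = self.lt - self.ll + ll
            self._pending = ("flip", cand, node, i, j, log_tree_j, bg_j, ll, lt)
            return lt
        if kind in (3, 4):  # topology: tree pieces change, background doesn't
            root, parent_full, t, total_len, log_coal = self._tree_pieces(cand)
            flip, A, log_tree_cols = self._mut_cols(cand, root, parent_full, t)
            log_w, log_1mw = self._w_cols(cand, total_len)
            ll = self._assemble(log_tree_cols, self.bg_cols, log_w, log_1mw)
            lt = log_coal + self._rate_priors(cand) + ll
            self._pending = ("topology", cand, root, parent_full, t, total_len,
                             log_coal, flip, A, log_tree_cols, log_w, log_1mw, ll, lt)
            return lt
        # fallback (e.g. a zero-SNP haplotype no-op): recompute everything
        self._pending = ("full", cand)
        return _log_target_ctx(cand, self.ctx)

    def _mut_term(self, node: int, matched: bool) -> float:
        f = self.flip[node]
        return math.log1p(-f) if matched else math.log(f)

    def accept(self) -> None:
        tag = self._pending[0]
        if tag == "theta":
            _, cand, flip, log_tree_cols, ll, lt = self._pending
            self.flip, self.log_tree_cols, self.ll, self.lt = flip, log_tree_cols, ll, lt
            self.state = cand
        elif tag == "rho":
            _, cand, log_w, log_1mw, ll, lt = self._pending
            self.log_w, self.log_1mw, self.ll, self.lt = log_w, log_1mw, ll, lt
            self.state = cand
        elif tag == "topology":
            (_, cand, self.root, self.parent_full, self.t, self.total_len,
             self.log_coal, self.flip, self.A, self.log_tree_cols,
             self.log_w, self.log_1mw, self.ll, self.lt) = self._pending
            self.state = cand
        elif tag == "flip":
            _, cand, node, i, j, log_tree_j, bg_j, ll, lt = self._pending
            self.A[node, j] = cand.internal_haplotypes[i, j]
            self.log_tree_cols[j] = log_tree_j
            self.bg_cols[j] = bg_j
            self.ll, self.lt = ll, lt
            self.state = cand
        else:
            self._full_refresh(self._pending[1])
        self._pending = None


def log_target(state: AugmentedState, data: HaplotypeDataset, focal_bp: float,
               config: Optional[SamplerConfig] = None) -> float:
    """Unnormalized log posterior density of an augmented state.

    ``data`` is the haplotype window (possibly zero SNPs wide, in which
    case the target reduces to the priors).  Tip labels of the state's tree
    must match the dataset's haplotype ids.
    """
    if config is None:
        config = SamplerConfig(n_iterations=2, burn_in=0)
    if data is not None and not data_is_empty(data):
        if state.tree.tip_labels != data.haplotype_ids:
            raise ValueError("tree tip labels do not match dataset haplotype ids")
        if state.internal_haplotypes.shape != (state.tree.n_tips - 1, data.n_snps):
            raise ValueError("internal haplotypes must be (n_tips - 1) x n_snps")
    ctx = _Ctx(data, focal_bp, state.tree.n_tips, config)
    return _log_target_ctx(state, ctx)


def mh_acceptance(log_target_new: float, log_target_old: float,
                  log_q_reverse: float, log_q_forward: float) -> float:
    """Metropolis-Hastings acceptance probability.

    min(1, exp(log f(new) - log f(old) + log q(old|new) - log q(new|old))).
    """
    if not np.isfinite(log_target_old):
        raise ValueError("current state must have finite target density")
    if log_target_new == -np.inf:
        return 0.0
    log_ratio = log_target_new - log_target_old + log_q_reverse - log_q_forward
    return float(min(1.0, math.exp(min(log_ratio, 0.0))))


# ----------------------------------------------------------------------
# proposal kernels
# ----------------------------------------------------------------------
def _propose_rate(state: AugmentedState, which: str, delta: float,
                  rng: np.random.Generator):
    """Log-scale random-walk multiplier; Hastings term is the Jacobian."""
    u = float(rng.uniform(-delta, delta))
    new = state.copy()
    if which == "theta":
        old = state.theta
        new.theta = old * math.exp(u)
        newval = new.theta
    else:
        old = state.rho
        new.rho = old * math.exp(u)
        newval = new.rho
    log_q_forward = -math.log(2 * delta * newval)
    log_q_reverse = -math.log(2 * delta * old)
    return new, log_q_forward, log_q_reverse


def _propose_internal_haplotype(state: AugmentedState, rng: np.random.Generator):
    """Flip one uniformly chosen internal-node allele (symmetric)."""
    n_int, L = state.internal_haplotypes.shape
    if L == 0:
        return state.copy(), 0.0, 0.0
    i = int(rng.integers(n_int))
    j = int(rng.integers(L))
    new = state.copy()
    new.internal_haplotypes[i, j] ^= 1
    return new, 0.0, 0.0


def _propose_topology_local(state: AugmentedState, rng: np.random.Generator):
    """Nearest-neighbour subtree swap plus a node-time resample.

    A uniformly chosen internal node ``v`` swaps one of its children with
    its sibling, and its time is redrawn uniformly in the valid interval;
    choosing the root instead redraws the root time with an exponential
    gap above its older child.
    """
    tree = state.tree
    n = tree.n_tips
    new = state.copy()
    parent, time, children = new.tree.parent, new.tree.time, new.tree._children
    log_choice = -math.log(n - 1)
    v = n + int(rng.integers(n - 1))
    if parent[v] == -1:  # root: time-only move
        lo = max(time[children[v, 0]], time[children[v, 1]])
        old_gap = time[v] - lo
        gap = float(rng.exponential(1.0))
        time[v] = lo + gap
        return new, log_choice - gap, log_choice - old_gap
    p = parent[v]
    s = children[p, 0] if children[p, 1] == v else children[p, 1]
    ci = int(rng.integers(2))
    c = children[v, ci]
    other = children[v, 1 - ci]
    hi = time[p]
    lo_old = max(time[other], time[c])
    lo_new = max(time[other], time[s])
    # swap s and c
    children[v, ci] = s
    parent[s] = v
    if children[p, 0] == v:
        children[p, 1] = c
    else:
        children[p, 0] = c
    parent[c] = p
    time[v] = float(rng.uniform(lo_new, hi))
    log_q_forward = log_choice - math.log(2.0) - math.log(hi - lo_new)
    log_q_reverse = log_choice - math.log(2.0) - math.log(hi - lo_old)
    return new, log_q_forward, log_q_reverse


def _subtree_mask(children: np.ndarray, v: int, n_nodes: int) -> np.ndarray:
    mask = np.zeros(n_nodes, dtype=bool)
    stack = [v]
    while stack:
        u = stack.pop()
        mask[u] = True
        if children[u, 0] >= 0:
            stack.append(children[u, 0])
            stack.append(children[u, 1])
    return mask


def _propose_topology_spr(state: AugmentedState, rng: np.random.Generator):
    """Subtree prune-regraft with uniform target edge and time.

    A uniform non-root subtree is detached (its parent node is spliced
    out), then reattached either onto a compatible edge of the remaining
    tree (new attachment time uniform in the valid interval) or above the
    remaining root (exponential gap).  Both directions enumerate targets on
    the same spliced tree, so the target counts cancel in the Hastings
    ratio and only the attachment-time densities remain.
    """
    tree = state.tree
    n = tree.n_tips
    n_nodes = 2 * n - 1
    new = state.copy()
    parent, time, children = new.tree.parent, new.tree.time, new.tree._children
    root = int(np.flatnonzero(parent == -1)[0])

    r = int(rng.integers(n_nodes - 1))
    v = r if r < root else r + 1
    p = int(parent[v])
    s = children[p, 0] if children[p, 1] == v else children[p, 1]
    s = int(s)
    g = int(parent[p])
    tv = time[v]

    # splice out p
    if g >= 0:
        if children[g, 0] == p:
            children[g, 0] = s
        else:
            children[g, 1] = s
        parent[s] = g
        spliced_root = root
        rev_logdens = -math.log(time[g] - max(tv, time[s]))
    else:
        parent[s] = -1
        spliced_root = s
        rev_logdens = -(time[p] - max(tv, time[s]))
    parent[p] = -2  # temporarily detached

    mask = ~_subtree_mask(children, v, n_nodes)
    mask[p] = False
    mask[spliced_root] = False
    idxs = np.flatnonzero(mask)  # all have a valid parent in the spliced tree
    cand = idxs[time[parent[idxs]] > tv]
    k_targets = len(cand) + 1  # +1 for the virtual above-root target

    pick = int(rng.integers(k_targets))
    if pick == len(cand):  # attach above the spliced root
        lo = max(tv, time[spliced_root])
        gap = float(rng.exponential(1.0))
        time[p] = lo + gap
        children[p, 0], children[p, 1] = v, spliced_root
        parent[spliced_root] = p
        parent[p] = -1
        fwd_logdens = -gap
    else:
        a = int(cand[pick])
        q = int(parent[a])
        lo = max(tv, time[a])
        hi = time[q]
        time[p] = float(rng.uniform(lo, hi))
        children[p, 0], children[p, 1] = v, a
        parent[a] = p
        parent[p] = q
        if children[q, 0] == a:
            children[q, 0] = p
        else:
            children[q, 1] = p
        fwd_logdens = -math.log(hi - lo)

    base = -math.log(n_nodes - 1) - math.log(k_targets)
    return new, base + fwd_logdens, base + rev_logdens


def propose(state: AugmentedState, kind: str, rng: np.random.Generator,
            config: Optional[SamplerConfig] = None):
    """Draw one proposal of the given kind.

    Returns ``(new_state, log_q_forward, log_q_reverse)``.
    """
    if config is None:
        config = SamplerConfig(n_iterations=2, burn_in=0)
    if kind == "theta":
        return _propose_rate(state, "theta", config.delta_theta, rng)
    if kind == "rho":
        return _propose_rate(state, "rho", config.delta_rho, rng)
    if kind == "internal_haplotype":
        return _propose_internal_haplotype(state, rng)
    if kind == "topology_local":
        return _propose_topology_local(state, rng)
    if kind == "topology_spr":
        return _propose_topology_spr(state, rng)
    raise ValueError(f"unknown proposal kind {kind!r}")


# ----------------------------------------------------------------------
# initialisation
# ----------------------------------------------------------------------
def initial_tree(window_alleles: np.ndarray, tip_labels: Sequence[str],
                 marker_weights: Optional[np.ndarray] = None) -> RootedTree:
    """Deterministic UPGMA starting tree, rescaled to the coalescent scale.

    Average-linkage clustering on (optionally weighted) Hamming distances
    of the window haplotypes; tied or zero merge heights are separated by
    a small epsilon so node times strictly increase, then all times are
    rescaled so the TMRCA matches its coalescent expectation 2(1 - 1/n).
    ``marker_weights`` lets the caller down-weight markers that are
    unlikely to reflect the focal-point genealogy (distant markers), so
    the chain starts near the mode where nearby markers are tree-linked.
    """
    n = window_alleles.shape[0]
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if window_alleles.shape[1] == 0:
        dists = np.zeros(n * (n - 1) // 2)
    else:
        x = window_alleles.astype(np.float64)
        if marker_weights is not None and marker_weights.sum() > 0:
            x = x * np.sqrt(marker_weights)  # squared-diff = weighted mismatch
        dists = pdist(x, metric="sqeuclidean") / x.shape[1]
    Z = linkage(dists, method="average")
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    eps = 1e-6
    for i in range(n - 1):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        node = n + i
        parent[a] = node
        parent[b] = node
        time[node] = max(Z[i, 2] / 2.0, time[a] + eps, time[b] + eps)
    target = 2.0 * (1.0 - 1.0 / n)
    time *= target / time[2 * n - 2]
    return RootedTree(parent, time, tip_labels)


def _initial_internal_haplotypes(tree: RootedTree, tip_alleles: np.ndarray) -> np.ndarray:
    """Majority-vote alleles over descendant tips (ties -> 1)."""
    n, L = tip_alleles.shape
    if L == 0:
        return np.zeros((n - 1, 0), dtype=np.uint8)
    counts = np.zeros((tree.n_nodes, L))
    sizes = np.zeros(tree.n_nodes)
    counts[:n] = tip_alleles
    sizes[:n] = 1
    ch = tree.children
    for v in tree.postorder():
        if ch[v, 0] >= 0:
            counts[v] = counts[ch[v, 0]] + counts[ch[v, 1]]
            sizes[v] = sizes[ch[v, 0]] + sizes[ch[v, 1]]
    internal = counts[n:] >= (sizes[n:, None] / 2.0)
    return internal.astype(np.uint8)


# ----------------------------------------------------------------------
# main loop
# ----------------------------------------------------------------------
def run_sampler(data: Optional[HaplotypeDataset], focal_bp: float,
                window: Optional[Tuple[int, int]], config: SamplerConfig,
                tip_labels: Optional[Sequence[str]] = None,
                n_tips: Optional[int] = None) -> FocalPointResult:
    """Run one focal-point MCMC chain and return retained samples.

    ``window`` is a half-open SNP index range into ``data``; an empty
    window (or ``data=None`` with ``n_tips`` given) runs the chain against
    the priors alone, which is the standard prior-recovery check of the
    sampler.  Retains ``floor((n_iterations - burn_in) / thin)`` states.
    """
    if data is not None:
        if window is None:
            window = (0, data.n_snps)
        wdata = data.window(*window) if window[1] > window[0] else None
        labels = data.haplotype_ids
        tips = data.n_haplotypes
        tip_alleles = wdata.alleles if wdata is not None else np.zeros((tips, 0), np.uint8)
    else:
        if n_tips is None:
            raise ValueError("need data or n_tips")
        wdata = None
        window = (0, 0)
        labels = tuple(f"h{i}" for i in range(n_tips)) if tip_labels is None else tuple(tip_labels)
        tips = n_tips
        tip_alleles = np.zeros((tips, 0), dtype=np.uint8)
    if tips < 2:
        raise ValueError("need at least two haplotypes")

    rng = np.random.default_rng(config.seed)
    ctx = _Ctx(wdata, focal_bp, tips, config)

    # initialisation weights: prior linkage probability of each marker at
    # rho_init, with the coalescent-expected total length 2*H_{n-1}
    exp_total_len = 2.0 * np.sum(1.0 / np.arange(1, tips))
    init_weights = np.exp(-0.5 * config.rho_init * exp_total_len * ctx.dist)
    tree0 = initial_tree(tip_alleles, labels, marker_weights=init_weights)
    state = AugmentedState(
        tree0,
        _initial_internal_haplotypes(tree0, tip_alleles),
        config.theta_init,
        config.rho_init,
    )
    state = state.copy()  # normalise to the unchecked-array representation
    tgt = _CachedTarget(ctx, state)
    if not np.isfinite(tgt.lt):
        raise ValueError("initial state has zero target density")

    kinds = rng.choice(5, size=config.n_iterations, p=np.asarray(config.proposal_probs))
    unif = rng.random(config.n_iterations)

    n_prop = np.zeros(5, dtype=np.int64)
    n_acc = np.zeros(5, dtype=np.int64)
    trees, thetas, rhos, tmrcas, rfs = [], [], [], [], []
    prev_tree = None

    for it in range(config.n_iterations):
        kind = int(kinds[it])
        if kind == 0:
            cand, lqf, lqr = _propose_rate(state, "theta", config.delta_theta, rng)
        elif kind == 1:
            cand, lqf, lqr = _propose_rate(state, "rho", config.delta_rho, rng)
        elif kind == 2:
            cand, lqf, lqr = _propose_internal_haplotype(state, rng)
        elif kind == 3:
            cand, lqf, lqr = _propose_topology_local(state, rng)
        else:
            cand, lqf, lqr = _propose_topology_spr(state, rng)
        lt_new = tgt.eval_candidate(kind, cand)
        n_prop[kind] += 1
        if lt_new > -np.inf and math.log(unif[it] + 1e-300) < lt_new - tgt.lt + lqr - lqf:
            state = cand
            tgt.accept()
            n_acc[kind] += 1
        post = it - config.burn_in + 1
        if post >= 1 and post % config.thin == 0:
            tr = state.tree
            snap = RootedTree(tr.parent, tr.time, tr.tip_labels, validate=False)
            trees.append(snap)
            thetas.append(state.theta)
            rhos.append(state.rho)
            tmrcas.append(snap.tmrca())
            rfs.append(0 if prev_tree is None else rf_distance(prev_tree, snap))
            prev_tree = snap

    rates = {
        PROPOSAL_KINDS[i]: (n_acc[i] / n_prop[i] if n_prop[i] else float("nan"))
        for i in range(5)
    }
    return FocalPointResult(
        focal_bp=focal_bp,
        window=window,
        sampled_trees=trees,
        sampled_theta=np.asarray(thetas),
        sampled_rho=np.asarray(rhos),
        acceptance_rates=rates,
        diagnostics={"tmrca": np.asarray(tmrcas), "rf_prev": np.asarray(rfs)},
    )


def summarize_rates(result: FocalPointResult):
    """Posterior-mean recombination and mutation rates, ``(mean_rho, mean_theta)``."""
    if result.n_samples == 0:
        raise ValueError("no retained samples")
    return float(np.mean(result.sampled_rho)), float(np.mean(result.sampled_theta))
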