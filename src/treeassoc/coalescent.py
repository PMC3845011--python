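"""Neutral coalescent simulation and synthetic case/control panels.

Two jobs live here: (i) sampling Kingman coalescent genealogies, which act
as the prior over trees and as the null distribution for the fuzzy p-value;
(ii) generating synthetic case/control haplotype panels with a planted
causal variant and linkage that decays with distance, used for testing and
for end-to-end demonstrations.

Time is measured in coalescent units (one unit = 2Ne generations): while k
lineages remain, the waiting time to the next coalescence is
Exponential with rate k(k-1)/2 and the merging pair is uniform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .io import HaplotypeDataset
from .tree import RootedTree

__all__ = [
    "PriorSample",
    "SyntheticScenario",
    "CaseControlSim",
    "sample_coalescent_tree",
    "sample_prior_statistics",
    "simulate_case_control",
    "simulate_case_control_full",
]


@dataclass
class PriorSample:
    """Association statistics computed on trees drawn from the coalescent prior.

    ``statistics`` holds the max-correlation statistic of each of ``m``
    neutral coalescent trees with a fixed case/control labelling of the
    tips; it estimates the null distribution used by the latent p-value.
    """

    statistics: np.ndarray
    m: int
    n_tips: int
    min_frac: float

    def __post_init__(self):
        self.statistics = np.asarray(self.statistics, dtype=np.float64)
        if self.m < 1 or self.statistics.shape != (self.m,):
            raise ValueError("m must be >= 1 and match the statistics length")
        if np.any((self.statistics < 0) | (self.statistics > 1)):
            raise ValueError("prior statistics must lie in [0, 1]")


def sample_coalescent_tree(n_tips: int, rng: np.random.Generator) -> RootedTree:
    """Draw one genealogy from the neutral (Kingman) coalescent.

    Tips are labelled ``h0 .. h{n-1}``; returns an ultrametric binary tree
    with tips at time 0.
    """
    if n_tips < 2:
        raise ValueError("coalescent tree needs at least 2 tips")
    n = n_tips
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = rng.integers(k)
        j = rng.integers(k - 1)
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = nxt
        parent[b] = nxt
        time[nxt] = t
        # drop the two merged lineages, append the new one
        hi, lo = (i, j) if i > j else (j, i)
        active[hi] = active[-1]
        active.pop()
        if lo < len(active):
            active[lo] = active[-1]
            active.pop()
        else:
            active.pop()
        active.append(nxt)
        nxt += 1
    labels = [f"h{i}" for i in range(n)]
    return RootedTree(parent, time, labels, validate=False)


def sample_prior_statistics(
    n_tips: int,
    phenotype: np.ndarray,
    m: int,
    min_frac: float,
    rng: np.random.Generator,
) -> PriorSample:
    """Null distribution of the max-correlation statistic under the coalescent.

    Draws ``m`` neutral trees and scores each against the fixed phenotype
    vector (bound to tips by index).  Coalescent tips are exchangeable, so
    fixing the labels is equivalent to permuting them per draw.
    """
    from .association import max_correlation_statistic_counts

    phenotype = np.asarray(phenotype)
    if phenotype.shape != (n_tips,):
        raise ValueError("phenotype length must equal n_tips")
    if phenotype.min() == phenotype.max():
        raise ValueError("phenotype must contain both classes")
    if m < 1:
        raise ValueError("m must be >= 1")
    stats = np.empty(m)
    phen = phenotype.astype(np.float64)
    for i in range(m):
        tree = sample_coalescent_tree(n_tips, rng)
        stats[i] = max_correlation_statistic_counts(tree, phen, min_frac)
    return PriorSample(stats, m, n_tips, min_frac)


# ----------------------------------------------------------------------
# synthetic case/control generator
# ----------------------------------------------------------------------
@dataclass
class SyntheticScenario:
    """Parameters of a synthetic case/control panel with a planted variant.

    The defaults describe a densely typed fine-mapping core: 50 haplotypes,
    recombination at the genome-average 1 cM/Mb converted to coalescent
    units (rho = 4e-4 per adjacent bp pair), a causal variant of
    intermediate frequency and strong but imperfect penetrance.  Linkage to
    the focal genealogy decays over ``d* = 2 / (rho_true * L_total)`` base
    pairs (about 550 bp here, with total tree length ``L_total ~ 9`` for
    n = 50), so the default 20 markers span 5 kb -- roughly nine decay
    lengths -- giving the panel both tightly linked and effectively
    independent markers, as a real fine-mapping panel around a causal site
    would have.

    ``penetrance`` gives the probability that a haplotype is labelled a
    case for non-carriers (g0) and carriers (g1) of the causal allele.
    ``theta_true`` is recorded in provenance for completeness; under the
    one-mutation-per-ascertained-SNP convention the generator does not
    consume it.
    """

    n_case: int = 25
    n_control: int = 25
    n_snps: int = 20
    region_bp: int = 5_000
    theta_true: float = 1.0
    rho_true: float = 4e-4
    causal_freq_range: tuple = (0.35, 0.55)
    penetrance: tuple = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self):
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one case and one control")
        if self.n_snps < 1 or self.region_bp < self.n_snps:
            raise ValueError("need n_snps >= 1 markers placeable on region_bp")
        if not (0 < self.causal_freq_range[0] < self.causal_freq_range[1] < 1):
            raise ValueError("causal_freq_range must be an interval inside (0, 1)")
        g0, g1 = self.penetrance
        if not (0 <= g0 <= g1 <= 1):
            raise ValueError("penetrance must satisfy 0 <= g0 <= g1 <= 1")
        if self.theta_true <= 0 or self.rho_true < 0:
            raise ValueError("rates must be positive")


class CaseControlSim(NamedTuple):
    """Full output of the generator, including provenance fields."""

    dataset: HaplotypeDataset
    tree: RootedTree
    causal_bp: int
    carriers: np.ndarray  # tip indices carrying the causal allele
    causal_branch: int


def _choose_causal_branch(
    tree: RootedTree, lo_count: int, hi_count: int, rng: np.random.Generator
):
    """Uniform choice among branches whose descendant count is in range."""
    sizes = tree.cluster_sizes()
    root = tree.root
    cand = [
        v
        for v in range(tree.n_nodes)
        if v != root and lo_count <= sizes[v] <= hi_count
    ]
    if not cand:
        return None
    return int(cand[rng.integers(len(cand))])


def _descendant_tips(tree: RootedTree, v: int) -> np.ndarray:
    ch = tree.children
    out = []
    stack = [v]
    while stack:
        u = stack.pop()
        if ch[u, 0] < 0:
            out.append(u)
        else:
            stack.append(ch[u, 0])
            stack.append(ch[u, 1])
    return np.array(sorted(out), dtype=np.int64)


def _drop_mutation(tree: RootedTree, rng: np.random.Generator) -> np.ndarray:
    """One mutation on a branch chosen proportionally to branch length.

    Returns the 0/1 allele per tip (descendants of the branch carry 1).
    """
    bl = tree.branch_lengths()
    probs = bl / bl.sum()
    v = int(rng.choice(tree.n_nodes, p=probs))
    alleles = np.zeros(tree.n_tips, dtype=np.uint8)
    alleles[_descendant_tips(tree, v)] = 1
    return alleles


_MAX_TREE_REDRAWS = 1000
_MAX_LABEL_ATTEMPTS = 10_000


def simulate_case_control_full(scenario: SyntheticScenario) -> CaseControlSim:
    """Generate a case/control panel around a planted causal variant.

    Procedure: draw a focal-point genealogy for all haplotypes; pick a
    causal branch whose carrier frequency falls in ``causal_freq_range``
    (redrawing the tree if none exists); label haplotypes case/control by
    the penetrance model, conditioned on exactly ``n_case`` cases; scatter
    marker positions uniformly over the region; each marker stays linked to
    the focal genealogy with probability ``exp(-rho * d * L_total / 2)``
    (d = distance to the causal site, L_total = total branch length) and
    otherwise mutates on an independent genealogy, so allelic association
    with the causal site decays with distance.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    n = sc.n_case + sc.n_control
    lo = sc.causal_freq_range[0] * n
    hi = sc.causal_freq_range[1] * n
    lo_count = int(np.ceil(lo - 1e-9))
    hi_count = int(np.floor(hi + 1e-9))

    tree = None
    causal_branch = None
    for _ in range(_MAX_TREE_REDRAWS):
        cand = sample_coalescent_tree(n, rng)
        branch = _choose_causal_branch(cand, lo_count, hi_count, rng)
        if branch is not None:
            tree, causal_branch = cand, branch
            break
    if tree is None:
        raise RuntimeError(
            f"no branch with carrier frequency in {sc.causal_freq_range} "
            f"after {_MAX_TREE_REDRAWS} tree redraws"
        )
    carriers = _descendant_tips(tree, causal_branch)
    carrier_mask = np.zeros(n, dtype=bool)
    carrier_mask[carriers] = True

    g0, g1 = sc.penetrance
    p_case = np.where(carrier_mask, g1, g0)
    phenotype = None
    for _ in range(_MAX_LABEL_ATTEMPTS):
        draw = (rng.random(n) < p_case).astype(np.uint8)
        if draw.sum() == sc.n_case:
            phenotype = draw
            break
    if phenotype is None:
        raise RuntimeError(
            f"could not realise exactly {sc.n_case} cases in "
            f"{_MAX_LABEL_ATTEMPTS} penetrance draws"
        )

    # distinct, sorted 1-based marker positions
    positions = rng.choice(sc.region_bp, size=sc.n_snps, replace=False) + 1
    positions.sort()
    causal_bp = int(rng.integers(1, sc.region_bp + 1))

    total_len = tree.total_branch_length()
    alleles = np.empty((n, sc.n_snps), dtype=np.uint8)
    for j, pos in enumerate(positions):
        d = abs(int(pos) - causal_bp)
        p_linked = np.exp(-sc.rho_true * d * total_len / 2.0)
        if rng.random() < p_linked:
            alleles[:, j] = _drop_mutation(tree, rng)
        else:
            alleles[:, j] = _drop_mutation(sample_coalescent_tree(n, rng), rng)

    dataset = HaplotypeDataset(alleles, positions, phenotype, tree.tip_labels)
    return CaseControlSim(dataset, tree, causal_bp, carriers, causal_branch)


def simulate_case_control(scenario: SyntheticScenario):
    """As :func:`simulate_case_control_full`, returning only
    ``(dataset, focal tree, causal position)``."""
    sim = simulate_case_control_full(scenario)
    return sim.dataset, sim.tree, sim.causal_bp
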