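"""Tree-based association statistics and fuzzy p-values.

The association statistic for one genealogy is the maximum, over all
eligible bipartition clusterings of the tips, of the absolute Pearson (phi)
correlation between cluster membership and case status.  Because the
genealogy is latent, the statistic is latent too: evidence is expressed as
the fuzzy p-value, the posterior distribution of latent p-values obtained
by ranking each posterior-tree statistic within the statistic's null
distribution under the neutral coalescent prior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sp_stats

from .coalescent import PriorSample
from .io import HaplotypeDataset
from .tree import RootedTree, eligibility_threshold

__all__ = [
    "FuzzyPValue",
    "FisherResult",
    "NoEligibleBipartitionError",
    "binary_correlation",
    "max_correlation_statistic",
    "max_correlation_statistic_counts",
    "latent_pvalue",
    "fuzzy_pvalue",
    "permutation_fuzzy",
    "fisher_exact_per_snp",
    "bonferroni_threshold",
]


class NoEligibleBipartitionError(ValueError):
    """No bipartition met the minimum cluster-size fraction."""


def binary_correlation(cluster_member: np.ndarray, phenotype: np.ndarray) -> float:
    """Absolute phi correlation between two binary vectors.

    For the 2x2 table (a, b; c, d) this is |ad - bc| / sqrt of the product
    of the margins.  Both vectors must be non-constant.
    """
    x = np.asarray(cluster_member).astype(np.int64)
    y = np.asarray(phenotype).astype(np.int64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-d and of equal length")
    if x.min() == x.max():
        raise ValueError("cluster membership vector is constant")
    if y.min() == y.max():
        raise ValueError("phenotype vector is constant")
    n = len(x)
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = n - a - b - c
    num = abs(a * d - b * c)
    den = np.sqrt(float((a + b) * (c + d) * (a + c) * (b + d)))
    return float(num / den)


def max_correlation_statistic_counts(
    tree: RootedTree, phenotype: np.ndarray, min_frac: float
) -> float:
    """Fast max-correlation statistic via descendant counts.

    Equivalent to scoring every eligible bipartition with
    :func:`binary_correlation` and taking the maximum, but computed in one
    postorder pass (phi only needs the cluster size and the case count in
    the cluster).
    """
    n = tree.n_tips
    n_cases = float(np.sum(phenotype))
    if n_cases == 0 or n_cases == n:
        raise ValueError("phenotype vector is constant")
    thr = eligibility_threshold(n, min_frac)
    ch = tree.children
    root = tree.root
    size = np.zeros(tree.n_nodes)
    cases = np.zeros(tree.n_nodes)
    size[:n] = 1.0
    cases[:n] = phenotype
    best = -1.0
    denom_const = n_cases * (n - n_cases)
    for v in tree.postorder():
        c0 = ch[v, 0]
        if c0 < 0:
            continue
        c1 = ch[v, 1]
        s = size[c0] + size[c1]
        k = cases[c0] + cases[c1]
        size[v] = s
        cases[v] = k
        if v == root or s < thr or n - s < thr:
            continue
        # phi from the 2x2 table margins
        num = abs(k * n - s * n_cases)
        den = np.sqrt(s * (n - s) * denom_const)
        phi = num / den
        if phi > best:
            best = phi
    if best < 0:
        raise NoEligibleBipartitionError(
            f"no eligible bipartition for n={n}, min_frac={min_frac}"
        )
    return float(min(best, 1.0))


def max_correlation_statistic(
    tree: RootedTree, phenotype: np.ndarray, min_frac: float
) -> float:
    """Maximum absolute correlation between cluster membership and case status.

    Phenotype is bound to tips by tip index (tip ``i`` carries
    ``phenotype[i]``); the maximum runs over all eligible bipartitions.
    """
    phenotype = np.asarray(phenotype, dtype=np.float64)
    if phenotype.shape != (tree.n_tips,):
        raise ValueError("phenotype length must equal the number of tips")
    return max_correlation_statistic_counts(tree, phenotype, min_frac)


# ----------------------------------------------------------------------
# latent / fuzzy p-values
# ----------------------------------------------------------------------
def latent_pvalue(t_c: float, prior: PriorSample) -> float:
    """Fraction of prior statistics at least as large as ``t_c`` (inclusive)."""
    return float(np.mean(prior.statistics >= t_c))


@dataclass
class FuzzyPValue:
    """Posterior distribution of latent p-values plus standard summaries.

    ``latent_p[j]`` ranks the statistic of the j-th posterior tree within
    the M-draw coalescent null, so each value lies on the grid 0, 1/M, ...,
    1.  ``zero_replaced_for_log`` flags that at least one summary is
    exactly 0 and would be reported as 1/M on a log scale.
    """

    latent_p: np.ndarray
    m_prior: int
    median: float
    q25: float
    q75: float
    q90: float
    zero_replaced_for_log: bool

    def summary_for_log(self, name: str) -> float:
        """Summary with 0 replaced by 1/M so -log10 is finite."""
        val = getattr(self, name)
        return max(val, 1.0 / self.m_prior)


def fuzzy_pvalue(t_c_vector: Sequence[float], prior: PriorSample) -> FuzzyPValue:
    """Latent p-value of every posterior-tree statistic, with summaries."""
    t_c = np.asarray(t_c_vector, dtype=np.float64)
    if t_c.ndim != 1 or len(t_c) < 1:
        raise ValueError("need at least one posterior statistic")
    # p_j = (#{T_u >= t_c_j}) / M for all j at once
    sorted_prior = np.sort(prior.statistics)
    p = 1.0 - np.searchsorted(sorted_prior, t_c, side="left") / prior.m
    median, q25, q75, q90 = np.quantile(p, [0.5, 0.25, 0.75, 0.9])
    zero = any(v == 0.0 for v in (median, q25, q75, q90))
    return FuzzyPValue(p, prior.m, float(median), float(q25), float(q75), float(q90), zero)


def permutation_fuzzy(
    trees: Sequence[RootedTree],
    phenotype: np.ndarray,
    prior: PriorSample,
    min_frac: float,
    rng: np.random.Generator,
) -> FuzzyPValue:
    """Fuzzy p-value after one uniform permutation of the phenotype labels.

    The trees are *not* resampled: tree sampling never sees the phenotype,
    so permuting labels against previously sampled trees yields a valid
    null diagnostic.
    """
    if not trees:
        raise ValueError("need at least one tree")
    labels = trees[0].tip_labels
    phenotype = np.asarray(phenotype, dtype=np.float64)
    if phenotype.shape != (len(labels),):
        raise ValueError("phenotype length must match the trees' tip count")
    for tr in trees:
        if tr.tip_labels != labels:
            raise ValueError("all trees must share one tip label set and order")
    perm = rng.permutation(len(labels))
    permuted = phenotype[perm]
    stats = [max_correlation_statistic_counts(tr, permuted, min_frac) for tr in trees]
    return fuzzy_pvalue(stats, prior)


# ----------------------------------------------------------------------
# single-SNP comparator and thresholds
# ----------------------------------------------------------------------
class FisherResult(NamedTuple):
    """Per-SNP two-sided Fisher exact p-values; monomorphic SNPs get p=1."""

    pvalues: np.ndarray
    monomorphic: np.ndarray


def fisher_exact_per_snp(data: HaplotypeDataset) -> FisherResult:
    """Two-sided Fisher exact test of allele vs case/control status per SNP."""
    data.require_both_classes()
    case = data.phenotype == 1
    pvals = np.ones(data.n_snps)
    mono = np.zeros(data.n_snps, dtype=bool)
    for j in range(data.n_snps):
        col = data.alleles[:, j]
        if col.min() == col.max():
            mono[j] = True
            continue
        a = int(np.sum((col == 1) & case))
        b = int(np.sum((col == 1) & ~case))
        c = int(np.sum((col == 0) & case))
        d = int(np.sum((col == 0) & ~case))
        pvals[j] = sp_stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    return FisherResult(pvals, mono)


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Per-test significance level alpha / k."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k
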