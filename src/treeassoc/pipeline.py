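"""Region-level orchestration: focal grid, windows, per-focal runs.

A region analysis lays an even grid of focal points over the genotyped
region, selects a SNP window around each (fixed physical width, expanded
to a minimum SNP count where markers are sparse), runs the focal sampler
at each point, scores every retained tree with the max-correlation
statistic, and converts the scores to fuzzy p-values against one shared
coalescent prior sample.  A permutation companion re-scores the same trees
against permuted phenotype labels as a negative control.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from . import association as assoc
from .coalescent import PriorSample, sample_prior_statistics
from .io import FocalSummary, HaplotypeDataset, write_newick_file, write_results_table
from .sampler import FocalPointResult, SamplerConfig, run_sampler, summarize_rates

__all__ = [
    "RegionConfig",
    "RegionResult",
    "focal_grid",
    "select_window",
    "convert_map_rate",
    "run_region",
    "write_region_outputs",
]


@dataclass
class RegionConfig:
    """Settings of a full region analysis.

    Defaults follow the reference analysis protocol: 100 kb total window
    width expanded to at least 20 SNPs, 5% minimum cluster fraction and
    M = 35,000 coalescent prior draws.  The sampler settings (chain length,
    priors, thinning) live in ``sampler``.
    """

    sampler: SamplerConfig
    n_focal_points: int = 100
    window_bp: float = 100_000.0
    min_snps: int = 20
    min_frac: float = 0.05
    prior_m: int = 35_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_focal_points < 1:
            raise ValueError("need at least one focal point")
        if self.min_snps < 2:
            raise ValueError("min_snps must be >= 2")
        if not (0 <= self.min_frac < 0.5):
            raise ValueError("min_frac must be in [0, 0.5)")
        if self.prior_m < 1:
            raise ValueError("prior_m must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclass
class RegionResult:
    """Everything a region run produces, ready for writing."""

    config: RegionConfig
    focal_bps: np.ndarray
    focal_results: list  # FocalPointResult per focal point
    fuzzy: list  # FuzzyPValue per focal point
    fuzzy_permuted: list  # FuzzyPValue per focal point, permuted labels
    prior: PriorSample
    summaries: list  # FocalSummary rows
    summaries_permuted: list
    permutation: np.ndarray  # the shared label permutation


def focal_grid(region_start: float, region_end: float, k: int) -> np.ndarray:
    """``k`` evenly spaced focal points, inset by half a spacing (grid centers)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if region_end <= region_start:
        raise ValueError("region_end must exceed region_start")
    spacing = (region_end - region_start) / k
    return region_start + spacing * (np.arange(k) + 0.5)


def select_window(positions: np.ndarray, focal_bp: float, window_bp: float,
                  min_snps: int) -> Tuple[int, int]:
    """Half-open SNP index range around a focal point.

    All SNPs within ``window_bp / 2`` of the focal point; when fewer than
    ``min_snps`` fall inside, the window grows to the ``min_snps`` SNPs
    closest to the focal point (distance ties go to the lower position).
    Near the region edges the window is clipped, never re-centered.
    """
    positions = np.asarray(positions)
    L = len(positions)
    if min_snps > L:
        raise ValueError(f"min_snps={min_snps} exceeds the {L} SNPs available")
    half = window_bp / 2.0
    lo = int(np.searchsorted(positions, focal_bp - half, side="left"))
    hi = int(np.searchsorted(positions, focal_bp + half, side="right"))
    if hi - lo >= min_snps:
        return lo, hi
    # expand to the min_snps closest SNPs; ties prefer the lower position
    dist = np.abs(positions.astype(np.float64) - focal_bp)
    order = np.lexsort((positions, dist))
    chosen = np.sort(order[:min_snps])
    return int(chosen[0]), int(chosen[-1]) + 1


def convert_map_rate(rate_cM_per_Mb: float, ne: float) -> float:
    """Genetic-map rate (cM/Mb) to rho per adjacent bp pair per coalescent unit.

    1 cM/Mb is a per-generation recombination probability of about 1e-8
    per bp; with effective population size Ne and time in units of 2Ne
    generations (event rate rho/2), rho = 4 * Ne * c.  At Ne = 10,000 this
    maps 1 cM/Mb to 4e-4.
    """
    if rate_cM_per_Mb < 0:
        raise ValueError("map rate must be nonnegative")
    if ne <= 0:
        raise ValueError("effective population size must be positive")
    c_per_bp = rate_cM_per_Mb * 1e-8
    return 4.0 * ne * c_per_bp


def _focal_seed(master: int, index: int) -> int:
    return (int(master) ^ int(index)) & 0x7FFFFFFF


_PRIOR_SEED_SALT = 0x5EEDF00D  # keeps the shared prior stream off the focal streams


def run_region(data: HaplotypeDataset, config: RegionConfig) -> RegionResult:
    """Full tree-based association scan of a region.

    For each focal point on the grid: select the SNP window, run the
    sampler, score every retained tree, and form the fuzzy p-value against
    one prior sample shared across focal points (the coalescent null does
    not depend on the focal point).  Also computes the permutation
    companion with one shared label permutation.  Fully reproducible from
    ``config.seed``; per-focal sampler seeds are ``seed XOR focal index``.
    """
    data.require_both_classes()
    phen = data.phenotype.astype(np.float64)
    n = data.n_haplotypes

    prior_rng = np.random.default_rng((config.seed ^ _PRIOR_SEED_SALT) & 0x7FFFFFFF)
    prior = sample_prior_statistics(n, phen, config.prior_m, config.min_frac, prior_rng)

    perm_rng = np.random.default_rng((config.seed ^ _PRIOR_SEED_SALT ^ 0x1) & 0x7FFFFFFF)
    permutation = perm_rng.permutation(n)
    phen_perm = phen[permutation]

    focal_bps = focal_grid(float(data.positions[0]), float(data.positions[-1]),
                           config.n_focal_points)
    results, fuzzies, fuzzies_perm, rows, rows_perm = [], [], [], [], []
    for i, x in enumerate(focal_bps):
        try:
            window = select_window(data.positions, x, config.window_bp, config.min_snps)
            scfg = SamplerConfig(
                n_iterations=config.sampler.n_iterations,
                burn_in=config.sampler.burn_in,
                thin=config.sampler.thin,
                proposal_probs=config.sampler.proposal_probs,
                theta_prior=config.sampler.theta_prior,
                rho_prior=config.sampler.rho_prior,
                theta_init=config.sampler.theta_init,
                rho_init=config.sampler.rho_init,
                seed=_focal_seed(config.seed, i),
                delta_theta=config.sampler.delta_theta,
                delta_rho=config.sampler.delta_rho,
            )
            res = run_sampler(data, x, window, scfg)
            stats = [
                assoc.max_correlation_statistic_counts(tr, phen, config.min_frac)
                for tr in res.sampled_trees
            ]
            stats_perm = [
                assoc.max_correlation_statistic_counts(tr, phen_perm, config.min_frac)
                for tr in res.sampled_trees
            ]
            fz = assoc.fuzzy_pvalue(stats, prior)
            fz_perm = assoc.fuzzy_pvalue(stats_perm, prior)
            mean_rho, mean_theta = summarize_rates(res)
        except Exception as exc:
            raise RuntimeError(f"focal point {i} at {x:.1f} bp failed: {exc}") from exc
        results.append(res)
        fuzzies.append(fz)
        fuzzies_perm.append(fz_perm)
        rows.append(_summary_row(x, window, res, fz, mean_rho, mean_theta, config))
        rows_perm.append(_summary_row(x, window, res, fz_perm, mean_rho, mean_theta, config))
    return RegionResult(
        config=config,
        focal_bps=focal_bps,
        focal_results=results,
        fuzzy=fuzzies,
        fuzzy_permuted=fuzzies_perm,
        prior=prior,
        summaries=rows,
        summaries_permuted=rows_perm,
        permutation=permutation,
    )


def _summary_row(x, window, res: FocalPointResult, fz, mean_rho, mean_theta,
                 config: RegionConfig) -> FocalSummary:
    return FocalSummary(
        focal_bp=float(x),
        n_snps_window=int(window[1] - window[0]),
        mean_rho=mean_rho,
        mean_theta=mean_theta,
        median_latent_p=fz.median,
        q25=fz.q25,
        q75=fz.q75,
        q90=fz.q90,
        n_tree_samples=res.n_samples,
        m_prior=fz.m_prior,
    )


def write_region_outputs(result: RegionResult, outdir: str) -> None:
    """Write results/permutation tables, Newick streams and the run log."""
    os.makedirs(outdir, exist_ok=True)
    write_results_table(result.summaries, os.path.join(outdir, "results.tsv"))
    write_results_table(result.summaries_permuted, os.path.join(outdir, "permutation.tsv"))
    for res in result.focal_results:
        name = f"trees_{int(round(res.focal_bp))}.nwk"
        write_newick_file(res.sampled_trees, os.path.join(outdir, name))
    log = {
        "seed": result.config.seed,
        "n_focal_points": int(result.config.n_focal_points),
        "prior_m": int(result.config.prior_m),
        "min_frac": result.config.min_frac,
        "bonferroni_alpha": assoc.bonferroni_threshold(
            result.config.alpha, result.config.n_focal_points
        ),
        "permutation": [int(v) for v in result.permutation],
        "acceptance_rates": [
            {k: (None if np.isnan(v) else float(v)) for k, v in res.acceptance_rates.items()}
            for res in result.focal_results
        ],
    }
    with open(os.path.join(outdir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2)
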