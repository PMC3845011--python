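"""MCMC machinery: target density, kernels, Hastings ratios, chain behavior.

The deepest check here compares the chain's long-run topology frequencies
on a 3-tip, 1-SNP problem against direct numerical integration of the
unnormalized target over node times and internal haplotypes.
"""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sp_stats

from treeassoc.coalescent import SyntheticScenario, simulate_case_control
from treeassoc.io import HaplotypeDataset
from treeassoc.sampler import (
    AugmentedState,
    SamplerConfig,
    _Ctx,
    _log_target_ctx,
    log_target,
    mh_acceptance,
    propose,
    run_sampler,
    summarize_rates,
)
from treeassoc.tree import RootedTree


def make_state(parent, time, labels, n_snps, theta=0.1, rho=4e-4, haps=None):
    tree = RootedTree(parent, time, labels)
    n_int = tree.n_tips - 1
    if haps is None:
        haps = np.zeros((n_int, n_snps), dtype=np.uint8)
    return AugmentedState(tree, haps, theta, rho)


class TestMhAcceptance:
    def test_equal_targets_symmetric_proposal(self):
        assert mh_acceptance(-5.0, -5.0, -1.0, -1.0) == 1.0

    def test_ratio_two_capped_at_one(self):
        assert mh_acceptance(math.log(2.0), 0.0, 0.0, 0.0) == 1.0

    def test_ratio_half(self):
        assert mh_acceptance(math.log(0.5), 0.0, 0.0, 0.0) == pytest.approx(0.5)

    def test_impossible_proposal(self):
        assert mh_acceptance(-np.inf, -1.0, 0.0, 0.0) == 0.0

    def test_infinite_current_state_rejected(self):
        with pytest.raises(ValueError):
            mh_acceptance(0.0, -np.inf, 0.0, 0.0)


class TestLogTarget:
    def test_zero_snp_window_is_priors_only(self):
        # empty likelihood: target = coalescent prior + theta and rho priors
        cfg = SamplerConfig(n_iterations=2, burn_in=0)
        st = make_state([2, 2, -1], [0.0, 0.0, 0.7], ["h0", "h1"], 0)
        got = log_target(st, None, 0.0, cfg)
        coal = -0.7  # 2 lineages: exp(-1 * t) log-density contribution
        theta_prior = sp_stats.uniform(1e-4, 10 - 1e-4).logpdf(0.1)
        rho_prior = sp_stats.gamma(a=1.0, scale=0.1).logpdf(4e-4)
        assert got == pytest.approx(coal + theta_prior + rho_prior, rel=1e-12)

    def test_theta_outside_prior_support(self):
        st = make_state([2, 2, -1], [0.0, 0.0, 0.7], ["h0", "h1"], 0, theta=5e-5)
        assert log_target(st, None, 0.0) == -np.inf

    def test_two_tip_closed_form_mutation_chain(self):
        # SNP at the focal point (fully linked): discordant tips under a
        # shared internal allele cost (1-e^{-theta t})/2 * (1+e^{-theta t})/2
        from treeassoc.sampler import _Ctx, _log_likelihood

        theta, t = 0.8, 0.7
        cfg = SamplerConfig(n_iterations=2, burn_in=0)
        ctx = _Ctx(None, 0.0, 2, cfg)
        ctx.tip_alleles = np.array([[0], [1]], dtype=np.uint8)
        ctx.dist = np.array([0.0])
        ctx.freq = np.array([0.5])
        st = make_state([2, 2, -1], [0.0, 0.0, t], ["h0", "h1"], 1, theta=theta,
                        haps=np.array([[0]], dtype=np.uint8))
        flip = (1 - math.exp(-theta * t)) / 2
        stay = (1 + math.exp(-theta * t)) / 2
        expect = math.log(0.5) + math.log(stay) + math.log(flip)
        assert _log_likelihood(st, ctx) == pytest.approx(expect, rel=1e-12)

    def test_mismatched_tip_labels_rejected(self):
        ds = HaplotypeDataset(
            [[0], [1], [0], [1]], [100], [1, 1, 0, 0], ["a", "b", "c", "d"]
        )
        st = make_state([4, 4, 5, 6, 5, 6, -1],
                        [0, 0, 0, 0, 0.2, 0.5, 1.0][:7],
                        ["h0", "h1", "h2", "h3"], 1)
        with pytest.raises(ValueError, match="tip labels"):
            log_target(st, ds, 100.0)


class TestProposals:
    def base_state(self, n_snps=2, seed=0):
        gen = np.random.default_rng(seed)
        from treeassoc.coalescent import sample_coalescent_tree

        tree = sample_coalescent_tree(8, gen)
        haps = gen.integers(0, 2, size=(7, n_snps)).astype(np.uint8)
        return AugmentedState(tree.copy(), haps, 0.1, 4e-4)

    def test_theta_jacobian(self, rng):
        st = self.base_state()
        new, lqf, lqr = propose(st, "theta", rng)
        assert lqr - lqf == pytest.approx(math.log(new.theta / st.theta))
        assert new.rho == st.rho
        assert np.array_equal(new.internal_haplotypes, st.internal_haplotypes)

    def test_rho_jacobian(self, rng):
        st = self.base_state()
        new, lqf, lqr = propose(st, "rho", rng)
        assert lqr - lqf == pytest.approx(math.log(new.rho / st.rho))

    def test_internal_haplotype_flip_symmetric_single_site(self, rng):
        st = self.base_state()
        new, lqf, lqr = propose(st, "internal_haplotype", rng)
        assert lqf == lqr == 0.0
        assert (new.internal_haplotypes != st.internal_haplotypes).sum() == 1
        assert np.array_equal(new.tree.parent, st.tree.parent)

    def test_two_tip_local_move_keeps_topology(self, rng):
        st = make_state([2, 2, -1], [0.0, 0.0, 0.7], ["h0", "h1"], 0)
        st = st.copy()
        new, lqf, lqr = propose(st, "topology_local", rng)
        assert np.array_equal(new.tree.parent, st.tree.parent)
        assert new.tree.time[2] != st.tree.time[2]
        RootedTree(new.tree.parent, new.tree.time, new.tree.tip_labels)  # valid

    @pytest.mark.parametrize("kind", ["topology_local", "topology_spr"])
    def test_topology_moves_produce_valid_trees(self, kind):
        rng = np.random.default_rng(7)
        st = self.base_state(seed=3)
        for _ in range(300):
            new, lqf, lqr = propose(st, kind, rng)
            assert np.isfinite(lqf) and np.isfinite(lqr)
            RootedTree(new.tree.parent, new.tree.time, new.tree.tip_labels)
            st = new

    def test_unknown_kind(self, rng):
        with pytest.raises(ValueError):
            propose(self.base_state(), "slide", rng)


class TestRunSampler:
    def test_retention_count(self):
        cfg = SamplerConfig(n_iterations=1000, burn_in=500, thin=50, seed=1)
        res = run_sampler(None, 0.0, None, cfg, n_tips=6)
        assert res.n_samples == 10

    def test_determinism(self):
        ds, _, causal = simulate_case_control(SyntheticScenario(seed=4))
        cfg = SamplerConfig(n_iterations=2000, burn_in=500, thin=20, seed=9)
        a = run_sampler(ds, float(causal), (0, ds.n_snps), cfg)
        b = run_sampler(ds, float(causal), (0, ds.n_snps), cfg)
        assert np.array_equal(a.sampled_theta, b.sampled_theta)
        assert np.array_equal(a.sampled_rho, b.sampled_rho)
        assert all(
            np.array_equal(x.parent, y.parent)
            for x, y in zip(a.sampled_trees, b.sampled_trees)
        )

    def test_retained_trees_valid_and_rates_in_unit_interval(self):
        ds, _, causal = simulate_case_control(SyntheticScenario(seed=6))
        cfg = SamplerConfig(n_iterations=5000, burn_in=1000, thin=20, seed=2)
        res = run_sampler(ds, float(causal), (0, ds.n_snps), cfg)
        for tr in res.sampled_trees[:20]:
            RootedTree(tr.parent, tr.time, tr.tip_labels)
        for kind, rate in res.acceptance_rates.items():
            assert 0.0 < rate < 1.0, kind

    def test_invalid_config_fails_before_running(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            SamplerConfig(n_iterations=100, burn_in=10,
                          proposal_probs=(0.4, 0.2, 0.2, 0.1, 0.2))

    def test_summarize_rates(self):
        cfg = SamplerConfig(n_iterations=400, burn_in=100, thin=10, seed=3)
        res = run_sampler(None, 0.0, None, cfg, n_tips=5)
        mean_rho, mean_theta = summarize_rates(res)
        assert mean_rho == pytest.approx(res.sampled_rho.mean())
        assert mean_theta == pytest.approx(res.sampled_theta.mean())


class TestCachedTarget:
    def test_incremental_evaluation_matches_reference(self):
        """The chain's cached target equals full recomputation everywhere."""
        from treeassoc.sampler import (
            _Ctx, _CachedTarget, _log_target_ctx, _propose_rate,
            _propose_internal_haplotype, _propose_topology_local,
            _propose_topology_spr, _initial_internal_haplotypes, initial_tree,
        )

        ds, _, causal = simulate_case_control(SyntheticScenario(seed=0))
        cfg = SamplerConfig(n_iterations=2, burn_in=0)
        ctx = _Ctx(ds, float(causal), ds.n_haplotypes, cfg)
        tree0 = initial_tree(ds.alleles, ds.haplotype_ids)
        st = AugmentedState(
            tree0, _initial_internal_haplotypes(tree0, ds.alleles), 0.1, 4e-4
        ).copy()
        tgt = _CachedTarget(ctx, st)
        rng = np.random.default_rng(42)
        proposers = [
            lambda s: _propose_rate(s, "theta", 0.5, rng),
            lambda s: _propose_rate(s, "rho", 0.5, rng),
            lambda s: _propose_internal_haplotype(s, rng),
            lambda s: _propose_topology_local(s, rng),
            lambda s: _propose_topology_spr(s, rng),
        ]
        for _ in range(2000):
            kind = int(rng.integers(5))
            cand, _, _ = proposers[kind](st)
            lt_cached = tgt.eval_candidate(kind, cand)
            assert lt_cached == pytest.approx(_log_target_ctx(cand, ctx), abs=1e-8)
            if np.isfinite(lt_cached) and rng.random() < 0.5:
                st = cand
                tgt.accept()


class TestDetailedBalance:
    """Chain vs direct numerical integration on a 3-tip, 1-SNP state space."""

    THETA, RHO, D, F = 1.0, 2e-3, 300.0, 1 / 3

    def enumerated_topology_posterior(self):
        theta, rho, d, f = self.THETA, self.RHO, self.D, self.F
        # tip alleles (i, j, k) with cherry {i, j}: the three topologies are
        # cherry={0,1}, {0,2}, {1,2}; data fixed at (0, 0, 1)
        alleles = np.array([0, 0, 1])

        def density(topology, t1, t2):
            i, j = topology
            k = ({0, 1, 2} - set(topology)).pop()
            prior = math.exp(-3 * t1) * math.exp(-(t2 - t1)) / 3.0
            l_total = t1 + 2 * t2
            w = math.exp(-rho / 2 * d * l_total)
            flip1 = 0.5 * (1 - math.exp(-theta * t1))
            flip_mid = 0.5 * (1 - math.exp(-theta * (t2 - t1)))
            flip_k = 0.5 * (1 - math.exp(-theta * t2))
            total = 0.0
            for a1 in (0, 1):  # cherry-node allele
                for a2 in (0, 1):  # root allele
                    p_tree = (
                        (flip1 if alleles[i] != a1 else 1 - flip1)
                        * (flip1 if alleles[j] != a1 else 1 - flip1)
                        * (flip_mid if a1 != a2 else 1 - flip_mid)
                        * (flip_k if alleles[k] != a2 else 1 - flip_k)
                        * (f if a2 == 1 else 1 - f)
                    )
                    p_bg = 1.0
                    for x in (alleles[i], alleles[j], alleles[k], a1, a2):
                        p_bg *= f if x == 1 else 1 - f
                    total += w * p_tree + (1 - w) * p_bg
            return prior * total

        masses = []
        for topology in ((0, 1), (0, 2), (1, 2)):
            val, _ = integrate.dblquad(
                lambda t2, t1: density(topology, t1, t2), 0, 40,
                lambda t1: t1, lambda t1: 40, epsabs=1e-12,
            )
            masses.append(val)
        masses = np.array(masses)
        return masses / masses.sum()

    def test_topology_frequencies_match_enumeration(self):
        class ThreeHapPanel(HaplotypeDataset):
            # 3 haplotypes keep the state space enumerable; bypass the
            # 4-haplotype panel minimum, which is irrelevant to the chain
            def window(self, start, stop):
                return self

        data3 = ThreeHapPanel.__new__(ThreeHapPanel)
        data3.alleles = np.array([[0], [0], [1]], dtype=np.uint8)
        data3.positions = np.array([300], dtype=np.int64)
        data3.phenotype = np.array([1, 0, 1], dtype=np.uint8)
        data3.haplotype_ids = ("h0", "h1", "h2")
        cfg = SamplerConfig(
            n_iterations=120_000, burn_in=20_000, thin=10, seed=0,
            proposal_probs=(0.0, 0.0, 0.4, 0.3, 0.3),
            theta_init=self.THETA, rho_init=self.RHO,
        )
        res = run_sampler(data3, 0.0, (0, 1), cfg)
        # cherry = pair of tips under the younger internal node
        counts = np.zeros(3)
        pairs = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
        for tr in res.sampled_trees:
            ch = tr.children
            young = 3 if tr.time[3] < tr.time[4] else 4
            cherry = tuple(sorted(int(c) for c in ch[young]))
            counts[pairs[cherry]] += 1
        freq = counts / counts.sum()
        expect = self.enumerated_topology_posterior()
        # batch-means standard error accounts for chain autocorrelation
        inds = np.array([
            pairs[tuple(sorted(int(c) for c in tr.children[3 if tr.time[3] < tr.time[4] else 4]))]
            for tr in res.sampled_trees
        ])
        for topo in range(3):
            x = (inds == topo).astype(float)
            batches = x[: len(x) // 50 * 50].reshape(50, -1).mean(axis=1)
            se = batches.std(ddof=1) / math.sqrt(len(batches))
            assert abs(freq[topo] - expect[topo]) < 3 * max(se, 1e-3), (
                f"topology {topo}: chain {freq[topo]:.4f} vs exact {expect[topo]:.4f}"
            )
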