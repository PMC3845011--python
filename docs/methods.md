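# Methods

`treeassoc` implements genealogy-based fine-mapping of a case/control
phenotype from phased haplotypes.  At each genomic focal point it samples
marginal ancestral trees and population-genetic rates conditional on a
window of SNPs, scores each sampled tree with a bipartition
max-correlation statistic, and expresses the evidence as a fuzzy p-value
against the neutral-coalescent null.  This note records the model, the
numerical choices, and the design decisions that were genuinely open.

## Model

### State and priors

At focal point `x` the augmented state is `A = (T, H, θ, ρ)`:

* `T` — rooted binary genealogy of the `n` sampled haplotypes, tips at
  time 0; times in coalescent units (1 unit = 2Ne generations).
* `H` — latent 0/1 alleles at each internal node for every window SNP.
* `θ` — mutation parameter; `θ/2` is the event rate per ascertained SNP
  per unit time.  Prior: Uniform(0.0001, 10), initialised at 0.1.
* `ρ` — recombination parameter; `ρ/2` is the event rate per adjacent
  base-pair pair per unit time.  Prior: Gamma(shape 1, scale 0.1),
  initialised at 0.0004 — the coalescent-unit equivalent of the
  genome-average map rate, `ρ = 4·Ne·c` with `c = 1e-8`/bp per generation
  and `Ne = 10,000`.

The tree prior is the Kingman coalescent: with `k` lineages the waiting
time to the next coalescence is Exponential(k(k−1)/2) and the merging
pair is uniform, giving log-density `−Σ_k C(k,2)·w_k` over
inter-coalescence intervals `w_k` for a labelled history.

### Emission likelihood

The likelihood ties the window haplotypes to the tree through a
per-marker linked/unlinked mixture that integrates out recombination
breakpoints.  A marker at distance `d` bp from the focal point stays
linked to the focal genealogy with probability

    w(d) = exp(−(ρ/2) · d · L_total),

where `L_total` is the total branch length of `T`.  This is exactly the
probability that no recombination event between the marker and the focal
point falls on any branch (the per-branch no-recombination probabilities
`exp(−(ρ/2)·d·t_b)` multiplied over the tree).  Conditional on linked,
each child allele follows a symmetric two-state mutation chain along its
branch of duration `t` with flip probability `(1 − e^{−θt})/2`, and the
root allele is a draw from the marker's sample allele frequency
(clamped to [0.001, 0.999] to keep monomorphic-window edge cases finite).
An unlinked marker carries no tree information: all of its node alleles
(tips and internal) are modelled as independent frequency draws.

An earlier variant applied the linked/unlinked mixture independently per
branch.  That version is unusable in practice: a single marker lying near
the focal point but genealogically unrelated to it (which the generator
below produces at a constant rate) is astronomically expensive to
force-link, so the posterior escapes to the "everything unlinked" mode,
`ρ` runs to the prior scale and the sampled trees decouple from the
data.  Profile-likelihood scans at the true generator tree across marker
spans of 1–5 kb showed the background mode dominating for every span,
which is why the mixture is applied at marker level, where it exactly
matches the linkage law of the generator.

The likelihood is deliberately a simplification: it conditions on sample
allele frequencies rather than modelling marker ascertainment, ignores
correlation among markers given unlinked status, and keeps one shared
`ρ` across the window (the estimate is a window-average rate).

### MCMC

Metropolis–Hastings over `A` with five kernels, chosen per iteration
with probabilities (0.1, 0.1, 0.3, 0.25, 0.25):

1. **θ update** — log-scale random-walk multiplier, `θ' = θ·e^u`,
   `u ~ U(−0.5, 0.5)`; Hastings term is the Jacobian `log(θ'/θ)`.
2. **ρ update** — same kernel on `ρ`.
3. **Internal haplotype** — flip one uniformly chosen internal-node
   allele at one uniformly chosen SNP (symmetric).
4. **Local topology** — a uniformly chosen internal node swaps one child
   with its sibling and redraws its time uniformly in the valid
   interval; choosing the root redraws the root time with an Exp(1) gap
   above its older child.  Hastings ratio from the interval lengths.
5. **Subtree prune–regraft** — a uniform non-root subtree is detached
   (its parent spliced out) and reattached on a uniformly chosen
   compatible edge of the remaining tree (attachment time uniform in the
   valid interval) or above the remaining root (Exp(1) gap).  Both
   directions enumerate targets on the same spliced tree, so only the
   attachment-time densities enter the Hastings ratio.

The initial tree is deterministic UPGMA on weighted Hamming distances of
the window haplotypes, each marker weighted by its prior linkage
probability `exp(−(ρ_init/2)·d·E[L_total])` (with `E[L_total] =
2·H_{n−1}` the coalescent expectation).  The weighting matters: an
unweighted start tree is dominated by markers too distant to ever be
linked, and chains started there can spend their whole budget in the
"all markers unlinked" mode even when the linked mode carries tens of
log-units more posterior mass.  Tied merge heights are separated by 1e-6
so node times strictly increase, and all times are rescaled so the
initial TMRCA equals its coalescent expectation `2(1 − 1/n)`.  Initial
internal alleles are majority votes over descendant tips.  All randomness flows
from one seeded `numpy` generator; chains are exactly reproducible.

Correctness gates: (i) with a zero-SNP window the chain must reproduce
its priors (θ, ρ and TMRCA means); (ii) on a 3-tip, 1-SNP state space
the chain's topology frequencies must match direct numerical integration
of the unnormalized target.  Both are part of the test suite.

### Association statistic and fuzzy p-value

Each internal non-root branch of a sampled tree splits the tips into a
cluster (its descendants) and the rest.  A bipartition is *eligible*
when both sides contain at least `ceil(min_frac · n)` tips (default
`min_frac = 0.05`); the threshold is applied to both sides because |phi|
is invariant under complementation, so a one-sided rule would readmit
near-singleton complements.  The statistic `T` is the maximum over
eligible bipartitions of the absolute phi correlation between cluster
membership and case status.

The null distribution of `T` is estimated by computing the statistic on
`M` trees drawn from the coalescent prior with the phenotype fixed to
the tip indices (tips are exchangeable under the coalescent).  For the
`j`-th posterior tree the latent p-value is
`p_j = #{T^u_i ≥ T^c_j}/M` (inclusive, as the estimator of the tail
probability); the collection `(p_1 … p_N)` over retained trees is the
fuzzy p-value.  Summaries (median, quartiles, 90th percentile) are
empirical quantiles with linear interpolation; a summary of exactly 0 is
reported as `1/M` on log scales and flagged.  A focal point whose trees
admit no eligible bipartition is reported missing rather than `p = 1`.

The latent p-value is a valid empirical tail probability in the marginal
sense: over the joint draw of prior sample and statistic,
`P(p ≤ u) ≤ u + 1/(M+1)` by exchangeability, ties only adding
conservatism.  Conditional on one fixed prior sample the bound can be
exceeded near the statistic's atoms (the max-correlation statistic is
discrete), which is why validity is checked marginally.

### Region pipeline

`k` focal points are placed at the centers of an even grid over the
genotyped region.  Each focal point uses all SNPs within a total window
of `window_bp` (default 100 kb, i.e. ±50 kb), expanded to the
`min_snps` closest SNPs (default 20, distance ties to the lower
position) when the window is sparse; near region edges the window clips
without re-centering.  One prior sample of size `M` (default 35,000) is
shared across focal points — the null does not depend on the focal
point.  Per-focal sampler seeds are `master_seed XOR focal_index`; the
shared prior and the label permutation use salted variants of the
master seed so their streams never collide with a focal chain.  The
permutation companion permutes the labels once for the whole region and
re-scores the already-sampled trees, mirroring the method's negative
control.  The reference protocol runs 8-million-iteration chains with
4-million burn-in, thinned to every 10,000th sample; the desk-scale
demo configuration uses 200,000 iterations, 100,000 burn-in, thinning
100.

## Synthetic data generator

`simulate_case_control` emulates the structure the method assumes: a
single common causal variant on the focal genealogy, imperfect
penetrance, and marker linkage decaying with distance.

* Draw a focal genealogy for all `n = n_case + n_control` haplotypes;
  choose a causal branch uniformly among branches whose descendant
  frequency lies in `causal_freq_range` (redrawing the tree up to 1,000
  times); carriers are its descendants.
* Label haplotypes case with probability `g1` (carriers) or `g0`
  (non-carriers) and redraw the whole labelling (up to 10,000 times)
  until exactly `n_case` cases, preserving the penetrance model
  conditional on the margin.
* Scatter `n_snps` marker positions uniformly over `region_bp`; each
  marker at distance `d` from the causal site keeps the focal genealogy
  with probability `exp(−ρ_true·d·L_total/2)` and otherwise uses an
  independently drawn genealogy; one mutation per marker is placed on a
  branch chosen proportionally to branch length (ascertained-SNP
  convention — every marker is polymorphic, no recurrent mutation).

Defaults: 25 cases / 25 controls, `ρ_true = 4e-4`, penetrance
(0.1, 0.9), carrier frequency (0.35, 0.55), 20 SNPs on 5 kb.  The last
two deserve justification.  Linkage to the focal genealogy dies over
`d* = 2/(ρ_true·L_total) ≈ 550` bp (with `L_total ≈ 9` at n = 50), so
the default marker span covers ~9 decay lengths at ~d*/2 spacing — the
panel contains tightly linked, partially linked and effectively
independent markers, which is what makes both the recombination rate and
the causal location identifiable, and corresponds to a
sequencing-density fine-mapping core rather than a sparse tag-SNP set.
The carrier frequency window is centered on
`c* = (n_case − n·g0)/(g1 − g0) = n/2`, where the penetrance model can
realise exactly `n_case` cases.

What the generator does *not* emulate: gradual tree change along the
region (linkage is all-or-nothing per marker, so nearby markers share
the entire focal tree or none of it), recurrent or back mutation, marker
ascertainment bias, population structure, phasing error, and the
pseudo-control dependence of trio-derived case/control haplotypes.
Passing tests therefore demonstrate the machinery is correct under its
own assumptions, not that the method is calibrated on real data.

## Numerical choices

* Eligibility threshold `ceil(min_frac·n − 1e-9)`: the epsilon guards
  against binary floating point pushing products like `0.05·40` above
  the integer they denote.
* Allele frequencies in the emission are clamped to [0.001, 0.999].
* Proposal windows δ_θ = δ_ρ = 0.5 give 20–80% acceptance across the
  regimes exercised in the tests.
* Zero-probability proposals (log-likelihood −inf) are rejected without
  error; the chain never starts from such a state.
* Batch means (30–50 batches) provide the standard errors used in the
  stochastic tests, accounting for chain autocorrelation.
* Test problem sizes: prior recovery and rate recovery use
  200,000-iteration chains; localisation uses 100,000; the null-region
  scan 30,000 per focal point.  These sizes hold the corresponding
  Monte-Carlo checks' power while keeping each run in minutes.

### Null behavior of the permutation diagnostic at desk scale

The permutation companion (re-scoring already-sampled trees against
permuted labels) is the pipeline's negative control.  On this package's
synthetic panels it is mildly anti-conservative: at a well-resolved
focal point the posterior trees concentrate on essentially one topology,
so under a random labelling every posterior tree carries the same
chance-alignment statistic and the fuzzy p-value collapses to
approximately a single uniform draw — the probability that its 10th
percentile falls below 0.05 is therefore ~5% plus a resolution bias
(data-resolved trees hold more mid-size clades than coalescent trees),
measured at 14–18% per focal point across permutations and panel sizes
n = 50–200.  A "no focal point looks significant" criterion at the 90%
level consequently sits on the boundary and fails for some permutations.
The generator's all-or-nothing linkage (see above) sharpens posterior
trees beyond what gradually decaying real LD produces, and real panels
are an order of magnitude larger, both of which widen the fuzzy p-value
and soften this effect in practice; the corresponding test is retained
at the faithful single-permutation protocol and documents this behavior
rather than hiding it.

## Known limitations

* The emission likelihood is a purpose-built simplification, not a
  reimplementation of any published sampler's exact model; absolute
  posterior probabilities inherit its biases, and θ in particular is
  weakly identified (its posterior often spans an order of magnitude).
* Marginal-tree sampling at each focal point ignores the joint ancestry
  across focal points (no ancestral recombination graph).
* The single shared ρ per window is a window-average; regions with sharp
  rate variation are smoothed.
* `H ≥ 4` haplotypes and binary phenotypes only; no missing data or
  unphased input (phasing is upstream of this package).
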