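# treeassoc

Genealogy-based association fine-mapping for phased case/control
haplotypes.

At a disease-associated locus, haplotypes carrying the causal variant
are more closely related to each other than the rest of the sample: in
the (latent) ancestral tree at the causal position, cases cluster.
`treeassoc` turns that observation into a mapping method:

1. **Sample trees.**  At each genomic focal point `x`, a
   Metropolis–Hastings sampler draws marginal genealogies `T_x`,
   internal-node haplotypes, and the scaled mutation and recombination
   rates θ and ρ from their posterior given the SNPs in a window around
   `x` (Kingman coalescent prior over trees; θ ~ U(0.0001, 10);
   ρ ~ Gamma(1, 0.1)).
2. **Score trees.**  Each internal branch of a tree bipartitions the
   tips; over all bipartitions whose both sides hold at least 5% of the
   haplotypes, the association statistic is
   `T = max |phi(cluster membership, case status)|`.
3. **Fuzzy p-values.**  Because the tree is latent, so is `T`.  Each
   posterior tree's statistic `T_j` is ranked within `M` statistics from
   the neutral coalescent prior, giving a latent p-value
   `p_j = #{T_u ≥ T_j}/M`; the distribution `(p_1 … p_N)` across
   sampled trees — the *fuzzy p-value* — expresses evidence and tree
   uncertainty together.  The median of the latent p-values, per focal
   point, traces the association signal along the region; posterior-mean
   ρ per focal point gives a window-averaged recombination-rate profile.

A synthetic-data module generates coalescent case/control panels with a
planted causal variant and distance-decaying linkage, so the whole
pipeline runs end to end without external data.  Inputs follow standard
conventions: haplotype panels as whitespace matrix text or phased VCF,
trees as Newick, results as TSV.

## Worked example

Generate a 50-haplotype panel (20 SNPs on 5 kb, causal variant with
penetrance 0.9 vs 0.1), sample trees at the causal position, and score
them:

```
$ treeassoc simulate --seed 7 --out demo
wrote panel.txt, true_tree.nwk, provenance.json to demo
$ python -c "import json; print(json.load(open('demo/provenance.json'))['causal_bp'])"
3769
$ treeassoc sample --data demo/panel.txt --focal-bp 3769 \
    --iterations 50000 --burn-in 25000 --thin 100 --seed 1 --out demo/fp
retained 250 samples; mean_rho=0.032922 mean_theta=1.44525
$ treeassoc assoc --trees demo/fp.trees.nwk --phenotype demo/phen.tsv \
    --prior-m 5000 --seed 2 --out demo/assoc.tsv
median latent p = 0.2368 (m=5000)
$ treeassoc permute --trees demo/fp.trees.nwk --phenotype demo/phen.tsv \
    --prior-m 5000 --seed 2 --out demo/perm.tsv
median latent p = 0.5391 (m=5000)
```

(`demo/phen.tsv` is the two-column id/phenotype table, here extracted
from columns 1–2 of `panel.txt`.)  Reading the numbers: of the 250
retained posterior trees at the causal position, the median tree has a
max-correlation statistic larger than all but 23.7% of 5,000 neutral
coalescent trees — case haplotypes cluster more than expected under
neutrality, though with this small panel the evidence is moderate and
the fuzzy p-value's spread (q25 = 0.10, q75 = 0.54) shows how much of
it is tree uncertainty.  The same trees re-scored against permuted
labels drop to a null-looking median of 0.54.  A short 50k-iteration
chain like this demo leaves mean ρ above its posterior scale; the
200k-iteration configuration used in the tests recovers ρ within a
factor of 3 of the truth in ≥80% of panels.

`treeassoc run-region --data panel.txt --config region.toml --out dir/`
scans a whole region: an even grid of focal points, per-focal windows
(100 kb, expanded to ≥20 SNPs), one shared coalescent prior sample, a
results table (`focal_bp`, window size, mean ρ/θ, latent-p summaries),
per-focal Newick tree streams, and a permutation companion table as a
negative control.

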