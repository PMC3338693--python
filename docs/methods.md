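# Methods

`radsplit` assesses the phylogenetic utility of individual markers for
resolving a rapid species radiation. The package is organized as a
pipeline of five stages — simulate (or load), characterize, infer, score,
test — each usable on its own through the library API or the `radsplit`
CLI. This note documents the models, the numerical choices, and what the
synthetic data does and does not capture.

## The study design being emulated

The synthetic generator reproduces the shape of a marker-utility study of
a primate-like radiation: 18 taxa (14 ingroup species in six genera plus
4 outgroups), 44 slow nuclear non-coding loci of 337–868 aligned columns
targeting ≈4% mean pairwise divergence, and one fast mitochondrial
molecule of 16,527 columns in 17 sub-partitions (13 protein genes, 2
rRNAs, pooled tRNAs, control region) targeting ≈18.5% divergence overall,
with per-partition relative rates spanning ≈0.6–1.6× of the molecule-wide
rate. The true species tree is ultrametric in coalescent units; its
ingroup radiation nodes are separated by short (0.4 unit) internodes so
that individual gene trees disagree with the species tree at realistic
rates (a 0.4-unit internode is concordant in only
1 − (2/3)e^(−0.4) ≈ 55% of gene trees), while the generic and outgroup
divergences are deep and essentially always recovered.

## Multispecies coalescent with an introgression pulse

Gene trees are sampled by the standard backwards-in-time (Hudson)
construction: one haploid lineage per species, branch lengths in units of
2N generations, and within any species-tree branch carrying j lineages,
coalescence at exponential rate j(j−1)/2 per unit. The mitochondrial
molecule is simulated as a single non-recombining locus: all 17
sub-partitions share one gene tree. Nuclear loci get independent gene
trees.

Introgression is a single pulse, not continuous migration: at the event
time, each lineage currently in the recipient branch is rerouted to the
donor branch with the stated probability (looking backwards in time,
which is how hybrid ancestry appears to sampled gene copies). The
shipped discordance regime moves the Presbytis-like mitochondrial
lineage into the Trachypithecus-like clade (donor branch: the
(T. hatinhensis, T. shortridgei) stem, pulse at 1.05 units, proportion
1.0) — chosen so the captured lineage almost always coalesces inside the
donor's clade, producing a clean, repeatable mito-nuclear discordance
signal while leaving the nuclear genome untouched.

Each lineage integrates (per-branch rate scaler × time) along its path,
so per-branch rate variation, when configured, is applied exactly; with
the default scalers of 1 gene-tree branch lengths are plain coalescent
units.

### Calibration of substitution rates

The per-locus conversion from coalescent units to expected substitutions
per site is solved analytically rather than tuned: the expected mean
pairwise gene-tree path length is computed from the species tree (twice
the species divergence plus a coalescent excess of 2 per pair), the
expected p-distance at substitution distance d under the locus's model is
computed from its transition matrices (mixture-averaged over +I/+G
categories), and the rate is the root of "expected p-distance = target"
divided by the mean path. Realized divergences land within sampling noise
of the targets (≈4% nuclear, ≈17–19% mt over seeds).

## Sequence evolution

Sites evolve independently along the gene tree under a reversible
nucleotide model (JC69, K80, HKY85, TN93, or GTR), with optional
invariant-sites class (+I) and Yang-style discrete gamma (+G, k=4
equal-probability categories with mean-of-category rates computed from
the regularized incomplete gamma function). Each site draws one category
for its whole history. The +I/+G mixture is rescaled to mean rate 1 so
branch lengths remain expected substitutions per site under the full
model — the same convention the likelihood engine uses, so simulation and
inference are mutually consistent. Defaults: nuclear loci HKY85+G
(α = 0.7034, κ = 4); mt loci GTR+I+G (I = 0.4328, α = 1.0995, AT-rich
frequencies, transition-heavy exchangeabilities). Alignments are
generated gap-free; indel evolution, recombination within loci, and
demographic size changes are out of scope.

## Inference engines

**Likelihood.** Felsenstein pruning over compressed site patterns, with
gaps and IUPAC ambiguities entered as partial likelihood 1 over their
compatible states and per-node rescaling against underflow. Transition
matrices come from the symmetrized eigendecomposition of the
unit-mean-rate GTR generator. Branch lengths are optimized
coordinate-wise in [1e−9, 10] substitutions/site by bounded scalar
minimization; each sweep caches inside/outside partials per edge so the
likelihood is a cheap one-dimensional function of the focal branch, and
the sweep is re-checked with a full evaluation (and rolled back if
stale-cache drift ever hurt it), making lnL monotone across sweeps.
Convergence tolerance 1e−6 lnL units. Tree search is NNI hill-climbing:
both rearrangements of every internal edge are scored with internal
branches re-optimized, the best strictly improving move is accepted and
followed by a full sweep, and exact ties break to the lexicographically
smallest canonical newick, so the search is deterministic.

**Parsimony.** Fitch counting on bitmask-encoded states (missing data is
the full state set and never costs a step). The heuristic search is
random stepwise addition followed by NNI swapping; trees on ≤7 taxa are
searched exhaustively. Point estimates use 5 random-addition starts;
bootstrap replicates use 1 (replicate trees only feed split frequencies,
where occasional local optima wash out).

**Distance.** Saitou–Nei neighbor joining; negative branch-length
estimates are clamped to zero with the deficit shifted to the sibling
edge. p-distance and Kimura two-parameter distances use pairwise
deletion: for each pair, any site where either sequence carries a gap or
ambiguity is excluded. Pairwise deletion (rather than complete deletion)
is the deliberate choice for control-region-like data where indel-rich
columns would otherwise delete most of the alignment.

**Support and consensus.** Nonparametric bootstrap resamples columns
with replacement; replicate seeds derive from the master seed via
`numpy` seed sequences. Combined-data trees are reported as the
point-estimate tree annotated with replicate split frequencies; per-gene
trees are the 50% majority-rule consensus of the replicate trees
(standing in for a per-gene Bayesian consensus, with bootstrap
frequencies in place of posterior probabilities). Inference internally
sorts taxa, so all supports are invariant to input row order.

**Model selection.** AIC (2k − 2lnL, k counting model parameters plus
branch lengths) over a 12-model ladder {JC69, K80, HKY85, GTR} ×
{—, +I, +G}, each candidate fitted on a fixed NJ base topology by
alternating Nelder-Mead over transformed parameters (log rates, softmax
frequencies, logistic I, log α; initial values: empirical frequencies,
κ = 2, α = 0.5, I ≈ 0) with branch-length sweeps. Branch-length
precision during selection is relaxed to 1e−3 lnL — an order of
magnitude below AIC-relevant differences. On concatenations the
selection runs on a random subsample of up to 2,000 columns; richer
models' parameters are stable at that depth and selection cost stays
proportionate. A `fixed` model policy is available when selection is not
wanted.

## Congruent-node scoring

The reference node set is every internal bipartition of the combined-data
tree separating ≥2 ingroup taxa from the rest, numbered in preorder; a
user-supplied subset (e.g. a published 10-node list) can override the
default. A gene tree recovers a node iff the node's bipartition,
restricted to the taxa the trees share, occurs among the gene tree's
bipartitions; recovered nodes split into strong/weak by the gene tree's
support on that edge at a configurable threshold (default 0.95, applied
to the gene tree's own supports; edges without support count as weak).
Genes are ranked by total recovered nodes (then strong count, then name)
and classed good/medium/poor by tertiles of the total, ties sharing the
better class.

## Topology tests

Site-wise log-likelihoods are computed per topology with branch lengths
re-optimized under the dataset's model; their sums match the total lnL to
1e−8 by construction. The SH test uses RELL resampling (B = 10,000 site
bootstraps, no re-optimization): bootstrap totals are centered by their
per-topology replicate means, the null statistic for topology i is
max_j(centered_j) − centered_i, and p is the fraction of replicates
reaching the observed delta. The ML topology has delta 0 and p exactly 1.
The test is simultaneous and conservative in the per-topology sense: the
chance that any fixed topology is rejected at 0.05 under an exchangeable
null stays at or below nominal. The KH test is the two-topology,
two-sided special case on centered lnL differences. The AU test is not
implemented; reports are labeled SH/KH.

## Pipeline and problem sizes

A full run writes characterization TSVs, support-annotated newick trees,
the gene-performance table, SH/KH tables, a manifest and a log, and is a
pure function of (config, seed). Default inference settings are
maximum parsimony with 100 bootstrap replicates per gene and per
combined matrix — parsimony rather than full ML for the combined
matrices keeps a complete 45-locus run in the minutes range on one core,
while ML (with NNI search) drives the topology tests and is available as
an inference method throughout. The test suite exercises the same
machinery at reduced sizes (4–10 loci, 10–30 replicates); the acceptance
script runs the full 44 + 17 locus design.

## What passing tests show — and don't

The synthetic data has gap-free alignments, a correct guide topology for
rate calibration, no alignment error, no base-composition
heterogeneity across lineages, no saturation beyond what the models
describe, and ILS/introgression as the only sources of discordance.
Passing the suite therefore demonstrates the estimators and tests are
implemented correctly and behave as theory predicts under the model —
not that the pipeline is robust to misalignment, numts, or model
violations in real data. The numt screen (premature-stop detection under
the vertebrate mt code) is provided for replay data but cannot be
triggered by the simulator, whose coding loci are not constrained to be
stop-free.

## Known limitations

- MP search uses NNI after stepwise addition; TBR/SPR are not
  implemented, so deep local optima are handled only via random restarts.
- Combined analyses use a single model on the concatenation; partitioned
  joint likelihood is not implemented.
- The SH/KH implementation consumes site-wise vectors from a single
  model per dataset; per-partition site weights are not supported.
- Consensus trees below a 0.5 cutoff fall back to greedy compatibility.
- The coalescent excess used by the rate calibration (2 units per pair)
  is exact for a lone pair and a slight underestimate when many lineages
  co-occur; realized divergences can sit ~5% below target, well inside
  the calibration bands asserted in the tests.
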