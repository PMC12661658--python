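# Methods

This document describes the algorithms implemented in `clefam` and the
reasoning behind them. Sections follow the analysis order of the
pipeline.

## Synthetic families with planted truth

`synthdata.generate_family` simulates a peptide gene family whose
precursors consist of a fixed hydrophobic signal segment, a variable
domain, and a C-terminal 12-residue motif (the dodecapeptide). Clades
descend a balanced binary tree from an ancestral precursor; each branch
applies BLOSUM62-biased substitutions at a configurable per-site rate
(`motif_divergence`), and within-clade genes diverge at one tenth of
that rate. Coding sequences are inherited along the same tree: a
branch's CDS re-encodes only the residues that changed and additionally
accumulates Poisson-distributed synonymous changes, so codon usage
carries phylogenetic signal and synonymous distance grows with
divergence time rather than being randomized per gene.

Duplications copy a gene, lightly mutate the copy's protein at an
elevated motif rate (`paralog_rate_factor`, default 3x the within-clade
rate — the planted "burden" signal), plant a known number of synonymous
CDS changes (recorded as `dS_truth`), and erode complementary ends of
the shared conserved promoter block by `erosion_asymmetry` of its length
on each side, mimicking asymmetric regulatory degeneration between
paralogs.

`sample_potts_sequences` draws motif sequences from an arbitrary Potts
model by parallel Gibbs chains (one chain per output sequence,
vectorized across chains), and `generate_three_pool_experiment`
simulates pooled sequencing of three phenotype-sorted populations with
binomial sampling noise at both the pool-composition and read-depth
levels.

## Precursor similarity network

`simnet.align_pair` computes local alignments with BLOSUM62 and affine
gaps (open 11, extend 1; a gap of length *g* costs 11 + (*g*−1)).
Scores are converted to edge weights through a Karlin–Altschul-style
E-value: `w = max(0, −log10(K·m·n·exp(−λS)))` with the standard
ungapped-regime constants λ = 0.267, K = 0.041, where *m* is the query
length and *n* the summed database length. The weight is therefore the
number of orders of magnitude by which the pair beats an expectation of
one chance alignment. `prune_top_k` keeps the union of every node's
top-*k* edges, which preserves weak but locally important connections
while sparsifying hubs.

## Graph embedding

`embed.random_walks` generates node2vec-style second-order walks
(defaults p = q = 1, walk length 80, 20 walks per node; the heavier
200/600/100 configuration is available via `WalkConfig.large_scale`).
Instead of stochastic skip-gram training, `embed_walks` builds the
windowed walk co-occurrence matrix, forms its positive pointwise mutual
information (PPMI) transform, and factorizes it by truncated SVD — the
known closed-form equivalent of skip-gram with negative sampling,
chosen because it is deterministic given the walks. Vector signs follow
a fixed convention so embeddings are reproducible. `knn_graph` connects
each node to its *k* nearest embedding neighbours with weight
1/(1+distance). `project_2d` provides a small diffusion-map projection:
an α-decay kernel (α = 2, adaptive bandwidth from the 5th neighbour),
diffusion time chosen at the von Neumann entropy knee, log-potential
distances, and classical MDS.

## Multi-resolution hierarchy

`hierarchy.multires_communities` optimizes the constant Potts model
(CPM) objective with the Leiden algorithm across an ascending resolution
ladder (default: six values geometrically spaced around the graph's
weight density), taking the best of five seeded restarts per
resolution. CPM is used because its resolution parameter has an
absolute density interpretation, making a sweep meaningful.

`reconcile_tree` converts the coarse-to-fine partition stack into a
strictly nested tree. Leaves start as the finest partition's
communities; coordinate descent alternates (a) labelling each leaf at
every layer with the plurality community of its members and (b)
reassigning each gene to the leaf whose label vector disagrees least
with the gene's own input labels, until a fixed point. The prefix
structure of the converged label vectors defines the nested tree; the
total number of disagreements is reported as `n_reassignments`. On
small instances this reaches the exhaustive minimum over all leaf
assignments within the model class (leaf count bounded by the finest
layer), which the test suite verifies by brute force.

`prune_sisters_rf` merges sister leaves whose dodecapeptide motifs are
statistically indistinguishable: motifs are one-hot encoded (12
categorical positions), a random forest is trained to separate the two
leaves, and its out-of-bag vote-share statistic is compared against a
null distribution from leaf-label permutations. The pair merges unless
the observed statistic exceeds the (1−α) null quantile; the p-value
uses the (1 + #null ≥ observed)/(n_perm + 1) convention. Leaves with a
single member are auto-merged with a logged note (a classifier cannot
be validated on one sample). Under exchangeable motifs the
false-separation rate is calibrated to α (checked at α = 0.05 over 200
simulated pairs).

`resolve_polytomy_entropy` resolves nodes with more than two children
into a binary subtree minimizing the total member-weighted positional
Shannon entropy accumulated at internal nodes. All (2m−3)!! rooted
binary shapes are enumerated exhaustively for m ≤ 6 children; beyond
that a greedy agglomeration is used (its objective is never below the
exhaustive optimum, and equality is flagged when achieved). Ties break
deterministically by child id.

## Paralog groups from promoters

`paralogs.promoter_similarity` measures promoter relatedness as the
containment Jaccard of canonical (strand-independent) k-mer sets
(default k = 12): |K(a) ∩ K(b)| / min(|K(a)|, |K(b)|). Containment
rather than plain Jaccard is used because asymmetric erosion leaves one
promoter's conserved block a subset of the other's; containment stays
near 1 in that case while plain Jaccard halves. Genes whose promoters
are shorter than k are excluded with a warning.

`assign_paralog_groups` seeds groups from high-containment promoter
pairs and spreads them over the embedding kNN graph by label
propagation: synchronous weighted-majority votes with clamped seeds,
ties leaving a node unlabelled for the round and breaking
lexicographically at termination; confidence is the winning label's
weight share.

## Potts models of the motif

`potts.fit_potts` fits fields h and couplings J by asymmetric
pseudolikelihood maximization (L-BFGS-B with analytic gradients)
followed by coupling symmetrization. Sequences are reweighted by the
inverse count of neighbours at ≥ 80% identity; L2 regularization uses
λ_h = 0.01·A and λ_J = 0.01·A·(L−1). The sign convention is that
higher statistical energy means higher probability, so deleterious
substitutions have ΔE < 0.

`mutational_effect` computes single-substitution ΔE incrementally
(field difference plus coupling row differences), which equals the full
energy recomputation exactly and is gauge-invariant.
`mutational_landscape` tabulates all L×20 effects with wild-type cells
exactly zero. `coupling_map` reports Frobenius norms of zero-sum-gauged
coupling blocks with the average-product correction (APC), the standard
treatment for removing site-entropy bias.

Two validation regressions contextualize a fitted landscape:
`residualize_blosum` regresses effects on BLOSUM62 scores of the
corresponding substitutions and returns residuals plus fit statistics,
and `sneath_correlation` rank-correlates those residuals against a
biochemical-dissimilarity table, asking whether the model captures
more than generic exchangeability.

## Duplication age and mutational burden

`burden.synonymous_distance` implements Nei–Gojobori dS: fractional
synonymous site counts averaged between the two sequences, pathway
averaging over the orderings of multi-hit codons (pathways through stop
codons excluded), and the Jukes–Cantor multiple-hit correction
dS = −3/4·ln(1 − 4p_s/3). p_s ≥ 3/4 is outside the correction domain
and sets a saturation flag instead of extrapolating.

`burden_score` accumulates a gene's deleterious motif load relative to
a reference (the clade consensus): Σ max(0, −ΔE) over differing
positions. `paralog_burden_test` then asks whether paralogs carry
excess burden beyond what their duplication age explains: an OLS fit of
burden on dS and a paralogy flag, with significance from permuting the
flag within dS-quantile strata (so age is held fixed under the null),
two-sided, (1 + #extreme)/(n_perm + 1).

## Three-population candidate mapping

`threepop.mutational_index` summarizes each gene's disruptive variants
(frameshift, stop gain, motif disrupting) across the three pools: the
mutational index is the allele fraction of the strongest
mutant-pool variant, paired with that same variant's wild-type-pool and
segregating-pool fractions. `call_candidates` applies the bottom-right
rule — mutant-pool fraction ≥ τ_hi, wild-type fraction ≤ τ_lo, and a
segregating fraction strictly between the thresholds — excluding
off-target loci. `promoter_cluster_test` checks whether the called
candidates cluster in the promoter network (mean pairwise similarity
against same-size uniform node draws). `filter_expression_samples`
provides the standard expression QC: mapping-rate cutoff, then
replicate Spearman-correlation screening on log2(TPM+1).

## Determinism

All stochastic routines take explicit seeds derived from a single
pipeline seed; `run_pipeline` writes a manifest of SHA-256 checksums
over every artifact and is bit-reproducible at a fixed configuration
(wall-clock timings go to a separate sidecar so the manifest itself is
stable).
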