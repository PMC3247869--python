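# Methods

This note records the models, numerical choices and open design decisions
behind `genomecontext`, and what the synthetic-data tests do and do not
establish about real data.

## Homology model and profiles

A reference gene is a homolog of a target gene when a hit exists with
E-value **strictly below** the homology threshold (default `1e-4`, the
value that tends to be optimal for genome-context scoring across method
families). The boundary case E = threshold is excluded; this is a
convention, and the reader exposes the threshold everywhere it matters.
Coverage/percent-identity pre-filters are assumed applied upstream by
whatever produced the homology table; the readers only re-validate ranges.

Profile metrics are defined on the 2×2 co-occurrence table. Degenerate
inputs return "no evidence" values rather than NaN: Jaccard of two empty
profiles is 0, Pearson with a constant profile is 0, mutual information is
clipped at 0 (it can go an ulp negative in floating point). Mutual
information is reported in nats; switching to bits is a constant factor
and does not change any ranking.

### Weighted hypergeometric p-value

Organism *i* is assumed to contain a homolog of *any* target gene
independently with probability `w_i`, the fraction of target genes with a
homolog there (computed from the full profile matrix, never a subset).
The p-value `P(co-occurrences ≥ observed | row sums)` has no closed form;
we compute it by an exact dynamic program over organisms that tracks the
joint probability of (ones in profile 1, ones in profile 2,
co-occurrences), then conditions on the observed margins. Weights are
clamped to `[1e-6, 1 − 1e-6]`: weights at exactly 0 or 1 make the
conditional degenerate and the recursion numerically fragile. With all
weights equal the conditional law is exactly hypergeometric, which the
test suite verifies for every margin with M ≤ 10; small weighted cases
are verified against exhaustive enumeration of all weighted outcomes.
The DP is O(M · n₁ · n₂ · min(n₁, n₂)) per pair, which is why this metric
is the expensive one and is typically run on a clustered (pruned)
organism list.

### Runs heuristic

The product profile is read in the swiveled leaf order of the organism
tree, and the number of maximal blocks of consecutive 1s is compared to
its null: uniformly random placement of k ones in M **linear** (not
circular) positions, where `#{exactly r runs} = C(k−1, r−1)·C(M−k+1, r)`.
The tail direction is genuinely ambiguous in the literature this score
descends from: consecutive 1s sit in related organisms, so *few* runs
mean phylogenetically clumped (weaker) evidence and *many* runs mean
independent (stronger) evidence. `runs_pvalue` therefore exposes both
tails; the default used by `pp_wpval_with_runs` is the upper tail
`P(R ≥ r_obs)`, and the score is the ratio weighted-p-value / runs-p-value
with smaller = stronger, negated at the score-matrix boundary like every
p-value here. An observed run count beyond the support returns the most
extreme achievable term rather than 0, keeping the ratio finite. Whether
the organism ordering should be treated as circular is likewise unstated;
we treat it as linear.

## Gene neighbor

Rank distance is the number of genes between the two homologs plus one
(adjacent genes: 1; a shared homolog: defined as 1 rather than 0 so a
single fused/shared gene cannot zero out the whole product). On circular
replicons the shorter arc is used and the relative distance is
`p = 2d/(N − 1)`, clipped at 1 so `−ln p ≥ 0` always; linear replicons
use `p = d/(N − 1)`. Conventions the underlying model leaves open:

* multiple homologs per genome → the **minimum** rank distance over
  homolog pairs (most sensitive convention);
* homologs confined to *different* replicons of one organism → that
  organism contributes no evidence (the uniform null assumes a single
  chromosome); when several replicons carry both genes the best
  (smallest-p) replicon is used.

`gn-pval` is the Gamma(M̃, 1) upper tail at `−ln x`, evaluated with the
regularized incomplete gamma function rather than the explicit series —
identical analytically, stable for large M̃. Orientation: `gn-pval` is
stored negated; `gn-lnX` and `gn-norm-lnX` are already
higher-is-more-related.

## Gene cluster and gene fusion

Gene cluster scores only rank-adjacent, same-strand pairs (including the
wrap-around pair of a circular replicon); the raw score is intergenic
bases × m with m = gene count / total intergenic bases, making the score
invariant to uniform coordinate rescaling. Overlapping genes contribute a
gap of 0. All other pairs carry the missing sentinel, semantically
"+∞ distance". An N-gene genome therefore scores at most N pairs.

Gene fusion accepts a Rosetta Stone when coverage ≥ Q (inclusive, default
50) and E-value ≤ E (inclusive, default `1e-4`) for both genes. The
p-value margins are a reconstruction (the original formulation is cited,
not restated, in the literature): K = candidate genes scanned across the
reference list (defaulting to the distinct reference genes in the
homology table), n₁/n₂ = each gene's match counts at (Q, E), f = Rosetta
count, upper-tail hypergeometric. The reconstruction is isolated behind
`gene_fusion_pval` and enumeration-tested for K ≤ 12. Unscored pairs keep
the sentinel, semantically p-value 1.

## Normalization

Row statistics use the **population** standard deviation (a per-row
constant rescale; sample SD would change nothing downstream) and exclude
the diagonal and missing entries. A constant row z-normalizes to all
zeros with a warning. Quantile normalization maps within-row average
ranks onto the mean row-sorted distribution; ragged rows (unequal
non-missing counts) are handled by interpolating on a common quantile
grid, and ties receive the mean of their tied target positions. Median
and uniform target distributions are available behind a flag but
non-default (they gave no consistent gain). Composed variants repeat the
row pass on the transpose before symmetrizing; symmetrization averages
with the transpose, keeping a one-sided value where only one side exists.

Simple row normalization removes the first gene's additive bias only; on
a planted `b_i + b_j` bias the composed variant is what removes the
remainder (residual correlation with the bias < 0.05 on a 200-gene
matrix, vs ≈ 0.94 after the simple pass). Restricted-coverage matrices
are rejected outright: with at most a handful of scored pairs per row
there is nothing to estimate row statistics from.

## Reference-organism selection

Organism profiles (columns) are compared by Jaccard distance (a true
metric), clustered agglomeratively (average linkage default, complete
optional — the choice is not dictated by the model), and the tree is cut
at a maximum within-cluster *distortion*, defined here as cluster
diameter (max pairwise distance; mean pairwise available behind a flag).
Each cluster is represented by its medoid-like member (smallest average
distance, ties to the lowest index). Random subsets of matching sizes
(3 replicates by default) serve as the baseline selection.

The swivel ordering minimizes the summed distance between adjacent leaves
over all 2^(internal nodes) subtree rotations. Up to 25 leaves an exact
endpoint dynamic program is used (state = subtree × (first, last) leaf);
beyond that, greedy local swivels. The exact DP is validated against
brute-force enumeration of all rotations on small trees.

## Evaluation

Scores are always oriented higher = more related before evaluation;
missing-sentinel pairs rank strictly last. ROC points are emitted per
distinct score value (tied scores move together), and top-p% selection
resolves ties at the cut by stable pair order — documented because
sensitivities at small p are tie-sensitive. *Cumulative accuracy* is read
as precision among pairs scoring at or above the threshold (the reading
under which it calibrates a confidence); the literal-recall reading is
available behind a flag but is not the default and should not be changed
silently.

## Combination

The confidence-product combiner fits, per method, cumulative accuracy at
each distinct score, smooths it with a cubic smoothing spline (penalty by
generalized cross-validation unless given), clamps to [0, 1], and applies
an isotonic non-decreasing pass — an addition that guards against spline
wiggles and can be disabled. Outside the fitted range the map extends
with its endpoint values. A method that cannot score a pair contributes
confidence 0; combination is `1 − ∏(1 − sᵢ)` (or the maximum).

The tree combiner is a bagged ensemble of 10 sklearn decision trees with
cost-complexity pruning (`ccp_alpha = 1e-4`, `min_samples_leaf = 5` —
bagging-style light pruning) and Laplace-smoothed leaf probabilities
`(n⁺ + 1)/(n + 2)`; each tree sees P positives and 10 P negatives
resampled with replacement. Missing features are imputed with a
worst-case constant below the column minimum, serialized with the model.
Gene pairs involving genes with no homology information at all are
excluded from training; their scores are outliers that distort both the
spline and the trees.

Grouped cross-validation assigns folds to unordered pairs of similar-gene
groups (connected components at E < 1e-2 of the within-target similarity
graph) and expands them to gene pairs, guaranteeing that if G1~G3 and
G2~G4, the pairs (G1,G2) and (G3,G4) share a fold.

## Synthetic pangenomes: what they emulate, and what not

`simulate_world` draws a random binary phylogeny, evolves each gene's
presence down it as a two-state gain/loss process (so related organisms
have correlated profiles), lets module members copy a shared latent
pattern with the co-presence boost, places co-located modules as
contiguous same-strand blocks with small intergenic gaps, occasionally
emits fused reference genes covering both partners, pads genomes with
filler genes without target homologs, and writes the three input files.
E-values for present orthologs are drawn log-uniform in
`[1e-30, 1e-6]` — below the default homology threshold — and absent
homologs produce no row at all, like a sparse real BLAST table. One
circular replicon per organism keeps the gene-neighbor null exact.
`label_noise` symmetrically corrupts the emitted gold standard (a
fraction of positives dropped, an equal count of spurious positives),
emulating incomplete curation.

Default conditions: 30 organisms, 60 genes, 8 modules of 4, presence rate
0.65 ± 0.10 across genes, co-presence boost 0.85, 75% of modules
co-located, 2% presence-bit noise. The *null* preset removes all module
structure and pads genomes to ≈ 1800 genes — the scale of real bacterial
genomes — because the discrete rank-distance null converges to its
continuous uniform limit only as genomes grow (at ~120 genes the
per-genome bias in `−ln p` is ≈ 2.5%, visibly skewing the p-value
distribution; at ~1800 genes the Kolmogorov–Smirnov distance to uniform
is ≈ 0.015 on 2 500 pairs).

The combination study (`combine.combination_study`) freezes two regimes:
a well-curated matched world (80 genes, 10 modules, moderate signal,
clean labels) evaluated by grouped CV, and a train-distant condition
whose training worlds differ in organism count (60 vs 30), homolog
frequency (0.8, flatter), co-location tightness, intergenic gap scale,
and carry 30% gold-standard error — the situation faced when training a
combiner on distant, less-curated organisms. Under the matched regime the
tree combiner exploits feature conjunctions and beats the product rule at
specificity ≥ 0.99; under the shifted regime the trees' learned
thresholds and noise-fitted leaves no longer transfer and the ensemble
falls below the best single score, while the monotone per-feature
confidence maps of the product combiner preserve rankings and do not.
These orderings are properties of the frozen seed and world size
(60–100 positives); nearby seeds can flip the small margins involved.

What passing these tests does **not** show about real data: the generator
has no sequence-level realism (E-values are not tied to divergence),
no horizontal transfer, no operon rearrangement, no paralog families
(every target gene has at most one ortholog per genome plus explicit
fusions), and module structure is disjoint and binary. Absolute
sensitivities on synthetic worlds say nothing about absolute performance
on a real genome; the tests establish calibration, exactness of the
combinatorial nulls, and directional/ordering properties only.

## Problem sizes

The test suite and acceptance script run everything at small scale by
choice: 60–80-gene targets (≈ 1 800–3 200 pairs), 30–60 organisms,
enumeration oracles up to M, K ≤ 12 and exhaustive margins up to M = 10.
These sizes keep every oracle exhaustive and every run deterministic
while exercising the same code paths a genome-scale run would use.
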