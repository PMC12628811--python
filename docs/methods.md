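# Methods

`provmark` implements a complete desk-scale pipeline for extracting
geographic-provenance biomarkers from gut-bacteriome OTU tables: table
ingestion and filtering, diversity profiling, per-taxon differential
abundance, a multiclass gradient-boosted tree classifier with gain-based
feature selection, point-biserial indicator-species analysis, and
chained biomarker-panel extraction with suitability assessment. A
synthetic cohort generator with planted markers makes every stage
testable end to end.

## Data model

An OTU here is *any* taxonomic-rank assignment produced by a read
classifier (a phylum-level row and a species-level row coexist in one
table), each carrying a fixed 7-slot lineage
(kingdom, phylum, class, order, family, genus, species). Tables are
dense integer matrices (OTUs × samples); at realistic scale
(~50k × 120) this fits comfortably in memory, so no sparse storage is
used. A proportion-mode flag marks normalized tables whose columns sum
to 1.

Kraken2-style reports are ingested by keeping every ranked taxon line
(rank codes R, D, K, P, C, O, F, G, S and sub-ranks) as its own OTU and
reconstructing lineages from the report's two-space indentation
hierarchy; unclassified (`U`) lines are dropped. A rank-code whitelist
is exposed because different pipelines retain different rank sets before
filtering.

## Filtering and normalization

Three row-local rules, applied in the order prevalence → low count →
lineage (the retained set is order-independent because each rule
depends only on the row and the fixed sample set; a test asserts this):

* **prevalence** — keep an OTU only if present (count > 0) in *strictly
  more than* `min_prevalence_fraction` (default 0.25) of samples; a tie
  at exactly 25% is removed;
* **low count** — keep OTUs with total count ≥ `min_total_count`
  (default 5), computed on totals across samples (the convention of
  metacoder-style `min_count` preprocessing); a per-sample-maximum
  variant is available behind an option;
* **lineage** — optionally require a complete 7-rank lineage, limiting
  rank-aggregation bias from partially classified reads.

Prevalence is evaluated on raw counts before any normalization.
Normalization for uneven sequencing depth is total-sum scaling
(per-sample proportions). Rarefaction (exact subsampling without
replacement via multivariate hypergeometric draws) is provided
separately and deliberately not chained by default: proportions, not
rarefied counts, feed the downstream statistics.

## Diversity

Alpha indices are computed per sample on (unrarefied) filtered counts:
observed richness S, bias-corrected Chao1
`S + F1(F1−1)/(2(F2+1))` (the bias-corrected form is the default
because it remains defined when doubletons are absent, which is common
after filtering; the classic form is an option), ACE with the standard
rare/abundant cutoff of 10 and its coefficient-of-variation term floored
at zero, Shannon H with natural log, and Pielou J = H/ln S. Degenerate
cases are reported as NaN rather than coerced to 0: J with a single
observed taxon, and ACE when every rare taxon is a singleton (sample
coverage estimate 0).

Beta diversity is Jaccard dissimilarity on presence/absence; a pair of
samples that are both empty is assigned distance 0. Ordination is
classical metric scaling (double-center −D²/2, eigendecompose, keep
positive eigenvalues; per-axis variance share is λ divided by the sum of
positive λ). Clustering defaults to UPGMA because no linkage is
canonical for this analysis; complete and single linkage are options and
the choice is recorded in the run report.

Group comparisons use the tie-corrected Kruskal-Wallis H with a
chi-square p on k−1 degrees of freedom by default. A permutation mode
(exhaustive over all label assignments when their number is at most
`max_exhaustive`, Monte Carlo otherwise) exists because the chi-square
approximation is only asymptotic; on small samples the permutation p is
the exact reference, and tests validate the implementation against
brute-force enumeration in that mode.

## Differential abundance

For every taxon at every rank (obtained by rank aggregation, which
conserves totals through an `unassigned` pool) and every unordered group
pair, a two-sided Wilcoxon rank-sum test compares per-sample
proportions: exact p when the smaller group has ≤ 8 observations and no
ties, normal approximation with tie correction otherwise. Effect size
is log2(median_A/median_B); only when a median is zero is ε (half the
smallest nonzero proportion in the table) added to both medians, which
avoids infinities while preserving the swap antisymmetry of the ratio.
No multiple-testing correction is applied by default — the significance
flag mirrors raw p < 0.05 as used for heat-tree coloring — and
Benjamini-Hochberg is available behind a flag, recorded in the output.

## Provenance classifier

The classifier is a natively implemented multinomial-deviance gradient
boosting machine: per iteration, one depth-limited regression tree per
class is fit by exact squared-error split search to the softmax negative
gradient (one-hot label minus current probability); leaf values take the
standard per-leaf Newton step `(K−1)/K · Σr / Σ|r|(1−|r|)` scaled by the
learning rate; class scores start from log priors. Implementing the
learner directly (rather than delegating to an external boosting
library) keeps gain-importance semantics, tie-breaking (earliest sorted
split position, then lowest feature index) and determinism fully under
control; an external implementation serves as a cross-check in the test
suite, never as the implementation.

Defaults: 40 trees, maximum depth 8, learning rate 0.1 (the customary
boosting default, since no value is otherwise implied), minimum
one sample per leaf, no row or column subsampling, 5-fold
cross-validation reported on the training partition with multinomial
deviance recorded every 5 trees. The train/test split is stratified 70/30
per group (an unstratified split of 30-sample groups can starve a class);
the final model is refit on the whole training partition, CV being
reporting-only. Training accuracy is reported on the 70% partition (the
full-data value is available by predicting on the complete table).

Gain importance credits each split's squared-error reduction to its
feature and normalizes the totals to sum to 1. Feature selection takes
the shortest importance-ranked prefix whose sum reaches the threshold
(default 0.80), ties broken by OTU id for determinism; zero-importance
features are never selected.

## Indicator species and panels

Association of an OTU with a group is the point-biserial correlation r:
the Pearson correlation between per-sample relative abundance and the
0/1 group indicator (the plain, group-size-uncorrected index; a
group-size-equalized variant is available behind a flag). Each OTU is
assigned to its argmax-r group only (no group combinations), and
candidacy requires a one-sided label-permutation p ≤ α (default 0.05,
999 permutations, `p = (1 + #{r* ≥ r}) / (1 + n_perm)`); an exhaustive
enumeration mode is used on small inputs. Zero-variance abundances get
r = 0 with a degenerate flag and p = 1. No correction over OTUs is
applied by default (candidate counts are reported raw); BH is optional.

Note a deliberate asymmetry in calibration: the permutation p is exact
for a *fixed* group membership, and the test suite checks its size
there. The p attached to the argmax-assigned group is anti-conservative
by construction (the tested group is chosen to maximize observed r), so
null candidate rates per group are expected near 1−(1−α)^k rather
than α; candidate counts should be read as a screening, not as
size-α discoveries.

Panels chain the two selections: per group, indicator candidates ∩ the
cumulative-importance OTU list, ordered by model importance, truncated
to k = 5. An empty intersection yields an empty panel with a warning —
such a group is identified by exclusion against the other panels.
Suitability of each member and of the per-sample summed panel abundance
is assessed by Kruskal-Wallis across groups plus pairwise two-group rank
tests at α, summarized as a compact letter display built by the
insert-and-absorb algorithm (two groups share a letter iff their
pairwise test is non-significant; the agricolae-style t-based-LSD
internals are not reproduced). A member is flagged *discriminating* when
its home group's letters are disjoint from every other group's.

## Synthetic cohorts

The generator emulates the statistical shape of a post-classification
gut-bacteriome count table from a four-site fish cohort: 4 groups × 30
samples; 2,000 background OTUs with complete synthesized 7-rank lineages
over a random nested taxonomy; base composition drawn once from a
symmetric Dirichlet (θ = 0.5, giving the heavy right tail of real
communities) and reweighted so the dominant phylum carries 90% of reads;
per-sample depths log-normal around 40,000 reads (σ = 0.4); counts
multinomial given the group composition. Five marker OTUs per group
(disjoint across groups) are planted by multiplying the base proportion
by a fold change of 8 and renormalizing; markers are placed in the
0.5–0.9 base-abundance quantile band so default filters cannot remove
them. Per-sample Dirichlet resampling (an overdispersion parameter) is
available to stress robustness but is off by default, keeping the
generator the simplest structure the analysis assumes.

What the generator does **not** emulate: taxonomic misassignment,
within-group ecological covariance structure, compositional correlations
beyond renormalization, batch effects, and — most consequentially —
realistically *weak, partially redundant* signal. Its planted markers
are near-perfectly correlated within a group (every sample in a group
shares one composition), with a known consequence demonstrated by the
test suite: an exact greedy boosted-tree learner separates four groups
using roughly one marker per class, so the 80% cumulative-importance set
collapses to ~4–8 OTUs and chained panels recover only ~20–40% of the
planted markers, even though essentially all importance mass sits on
true markers. Spreading importance over dozens of OTUs, as observed on
real cohorts, requires individually weak features; passing the
recovery-oriented tests here therefore says nothing about panel
*completeness* on real data, only about ranking fidelity. The
redundancy-shadowing behavior is intrinsic to greedy gain importance,
not an implementation artifact.

## Numerical and reproducibility choices

* Split-gain threshold 1e-12; no split between equal feature values.
* Softmax is computed with max-subtraction; probabilities are clipped at
  1e-300 inside the deviance only.
* Proportion columns are validated to sum to 1 within 1e-9; proportion
  TSVs round-trip at 17 significant digits.
* The pipeline derives stage seeds from the single global seed with a
  splitmix-style mixer keyed by stage name (all below 2^31), so stages
  rerun independently yet reproducibly; identical config + seed gives
  byte-identical outputs (reports carry no timestamps).
* Permutation p-values use the add-one convention and a 1e-12 slack when
  comparing permuted statistics to the observed one.
* Statistical test sizes used by the slower checks are desk-scale by
  design: null-calibration cohorts use 300 background OTUs and the
  planted-recovery runs use the full 2,000-OTU default; the brute-force
  enumeration oracles run on n ≤ 9 toys.

## Known limitations

* The GBM has no early stopping, no subsampling and no hyperparameter
  search; it is the single selected configuration, not an AutoML run.
* Heat-tree and map rendering are out of scope; the package emits the
  statistics tables only.
* The compact letter display uses pairwise Kruskal-Wallis tests, not
  rank-based LSD; letters can differ from agricolae output on borderline
  pairs (an LSD-style choice would slot into the same interface).
* Indicator analysis covers single-group targets only, not site
  combinations or IndVal A/B components.
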