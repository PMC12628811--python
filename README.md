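# provmark

Gut-bacteriome provenance analysis: from an OTU count table to a
per-region biomarker panel.

Seafood provenance fraud is hard to police with morphology or DNA
barcoding alone, because the question is not *what species* but *where
it was caught*. The gut bacteriome of a fish integrates the signal of
its local environment, so samples of one species caught in different
fishing areas carry distinguishable microbial fingerprints. `provmark`
implements the full statistical chain for turning read-classification
OTU tables from such a cohort into a small, testable panel of
provenance biomarkers:

1. **Filtering** — keep OTUs present in > 25% of samples, with total
   count ≥ 5 and a complete 7-rank lineage; normalize to per-sample
   relative abundances.
2. **Diversity** — per-sample Chao1, ACE, Shannon H (natural log) and
   Pielou J = H/ln S with Kruskal-Wallis group contrasts; Jaccard
   dissimilarities ordinated by PCoA and clustered by UPGMA.
3. **Differential abundance** — per-taxon, per-rank, per-group-pair
   Wilcoxon rank-sum tests with log2 median-ratio effect sizes (the
   statistics behind comparative heat trees).
4. **Classification** — a natively implemented multiclass gradient
   boosting machine (one depth-limited regression tree per class per
   iteration, fit to the softmax negative gradient; 40 trees, depth 8,
   learning rate 0.1, stratified 70/30 split, 5-fold CV) with gain-based
   feature importance and selection of the shortest importance-ranked
   prefix reaching 80% cumulative gain.
5. **Biomarker panels** — point-biserial indicator-species analysis
   (r = Pearson correlation of abundance with the 0/1 group indicator,
   permutation-tested), intersected with the important-OTU list and
   truncated to the top 5 per group; suitability assessed by
   Kruskal-Wallis with compact letter displays.

A synthetic cohort generator (4 groups × 30 samples, 2,000 background
OTUs, one dominant phylum at ~90% of reads, log-normal depths around
40k reads, 5 planted markers per group at fold change 8) provides
ground truth for end-to-end testing. See `docs/methods.md` for the
models, defaults and their rationale.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
simulated cohort, writing tables under `results/`:

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_filter_normalize.py
python analysis/03_diversity.py
python analysis/04_differential_abundance.py
python analysis/05_train_classifier.py --seed 1
python analysis/06_select_biomarkers.py --seed 1
```

With seed 1 this prints, among other lines:

```
cohort: 2000 OTUs x 120 samples (4 groups)
2000 OTUs in, 1710 retained:
  prevalence: removed 290, retained 1710
shannon: H = 25.720, p = 1.09e-05
PCoA: first two axes explain 12.5% (PCo1 9.51%, PCo2 3.04%)
train accuracy: 100.0% (...)
test accuracy: 100.0% (...)
4 OTUs reach 80% cumulative gain importance
indicator candidates per group: {'Center-North': 81, 'Center': 68, 'Center-South': 106, 'South': 98}
planted-marker recovery: 0.20; 8 suitability contrasts fully discriminate the home group
```

Reading these numbers: the prevalence rule removes the rare tail of the
simulated community; Shannon diversity differs across groups because
planting markers shifts evenness; the planted fold-8 markers make the
classifier perfect on both partitions, and its gain importance
concentrates on ~1 marker per group — which is why only 4 OTUs reach the
80% cumulative cutoff and the chained panels recover 4 of the 20 planted
markers (one per group, each genuinely discriminating). The remaining
markers are *shadowed*: within a group they are statistically redundant
copies of the chosen one, a known property of greedy gain importance
discussed in `docs/methods.md`.

The same chain is available as a configured pipeline
(`provmark run config.yaml --out-dir run/`) or stage by stage
(`provmark simulate|filter|diversity|diffabund|classify|biomarkers`);
every run writes a `report.json` recording all effective parameters and
warnings, and identical config + seed reproduces every output byte for
byte.

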