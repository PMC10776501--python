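# Methods

## End-motif profiles

A sequenced cfDNA template aligned to the half-open interval [s, e) on
a contig has two 5' termini. Their motifs are read from the
**reference** sequence, not the read bases: the upstream motif is
`ref[s:s+4]` on the forward strand and the downstream motif is the
reverse complement of `ref[e-4:e]`. Reading from the reference makes
the profile robust to sequencing error and ties the motif to the
aligned cut site. By default both termini are counted (one motif per
5' end, i.e. one per read in paired-end data); a single-end mode that
keeps only read 1's terminus exists for ablation. Fragments shorter
than 4 bp contribute nothing, and motifs containing non-ACGT reference
bases are dropped.

Fragment QC before counting (all configurable, defaults in
parentheses): minimum MAPQ (30), properly-paired templates only
(true), duplicates dropped (true), secondary/supplementary alignments
always excluded. These are conventional WGS-fragmentomics settings;
the count vector records how many fragments were seen and filtered so
a run is auditable. Fragments are reconstructed by pairing mates by
query name, which makes counts invariant to record order in the file;
coordinates are 0-based half-open everywhere inside the package and
1-based only at the SAM boundary.

A sample's profile is `counts / total_ends`; an all-zero count vector
raises rather than emitting NaNs. Profiles are assembled into a
samples × 256 matrix over the canonical motif index (lexicographic,
A<C<G<T) and round-trip through TSV at 10 significant digits.

## Synthetic cohorts

The generator emulates the statistical structure the classifier
assumes, with defaults chosen as the study conditions:

* **Reference**: i.i.d. bases, length 100 kb, GC 0.50. The symmetric
  composition gives near-uniform 4-mer base rates, so the planted
  effect acts evenly across the thirteen motifs; GC is an exposed
  parameter (real genomes are AT-rich, and GC-skewed references
  down-weight the GC-rich planted motifs). The default base spectrum
  is the reference's empirical 4-mer frequency vector.
* **Class spectra**: cancer multiplies four motifs (AAAA, ATGA, ACAC,
  ACGA) and divides nine (AAGG, AGGC, AGGA, ACTG, AGGG, ACCC, ACCT,
  ACCG, AACG) by a fold change of **1.3**, then renormalises. The
  direction of each shift is fixed; the magnitude is a package choice
  (the source boxplots imply direction, not effect size) calibrated so
  the cross-validated AUC lands in the 0.90–0.95 regime at n = 206.
* **Per-sample variation**: a Dirichlet draw centred on the class
  spectrum with concentration **2000** (between-sample biological
  variability, per-motif sd ≈ √(p(1−p)/2001)), then multinomial counts
  with **50 000** fragment ends per sample (sampling noise; a
  desk-scale stand-in for ~5× WGS).
* **Fragment lengths**: a two-Gaussian mixture — tumor-like mode
  145 bp (sd 15), background mode 167 bp (sd 20) — with the short
  component weighted 0.40 in cancer and 0.15 in healthy samples,
  reflecting the enrichment of sub-150 bp fragments in tumor-derived
  DNA. Lengths are realism for the I/O path only; they are never
  classifier features.
* **Fragments and alignments**: a motif is drawn from the spectrum, a
  matching reference placement and strand uniformly among all
  occurrences, and a length from the mixture (clamped to the contig).
  Only the sampled 5' end is motif-controlled; the opposite end reads
  whatever the reference dictates (controlling both ends would
  over-constrain placement). Ground truth counts both ends. Fragments
  are written as coordinate-sorted paired-end SAM (MAPQ 60, proper
  pairs, perfect alignment).
* **Cohort composition**: 106 cancer / 100 healthy; cancer types
  lung/gastrointestinal/other at 33/54/19; stages II/III/IV at
  2.8/13.2/84.0%; 44 immunotherapy-treated patients with 13 (29.5%)
  responders; covariates (age, sex, BMI class) drawn with
  case-control imbalance. Composition is allocated by exact rounded
  counts and shuffled — not Bernoulli-sampled — so the printed cohort
  structure is reproduced deterministically at the default n.

What the generator does **not** emulate: sequencing error and base
qualities, alignment artifacts (soft clips, indels, mismapping), GC
and mappability bias, correlated motif co-variation beyond the
Dirichlet, nucleosome periodicity in fragment placement, and any
association between *response* labels and the profiles (the
immunotherapy labels are pure composition, so that model's expected
AUC on synthetic data is 0.5). Passing tests therefore demonstrate
correctness of the machinery and recoverability of a planted signal at
realistic noise — not clinical performance on real cohorts.

## Cohort handling

The 7:3 stratified split shuffles each label class by seed and assigns
the first ⌈0.7·n_class⌉ samples to training: with 106/100 this yields
75 + 70 = 145 training and 31 + 30 = 61 test samples (ceiling is the
only rounding consistent with that design). Baseline case-control
comparisons within each arm: Fisher's exact test (two-sided, sum of
tables no more probable than observed) for sex and BMI class;
Mann–Whitney for age, exact when both groups have n ≤ 12 and no ties,
otherwise the normal approximation with tie and continuity
corrections. No covariate adjustment is performed.

## Classifier

`RandomForestClassifier` with 500 trees, √p candidate features per
split, leaves grown pure, bootstrap sampling — the canonical forest
defaults. Importance is **out-of-bag permutation mean decrease
accuracy**: for each tree, its OOB accuracy is compared against the
accuracy after permuting one feature's OOB values, and the drop is
averaged over all trees (features a tree never splits on drop zero for
that tree; the reported value is the unscaled mean). OOB membership is
re-derived from each tree's stored bootstrap random state. Gini
importance is available as an option, never the default. Ranking ties
break lexicographically and a boundary tie at rank k is logged.

Cross-validation is stratified 5-fold; ranking and top-k selection are
re-run inside every training fold so held-out scores are leakage-free.
The deliberately leaky variant (selection once on the full data) is
retained as an ablation because it demonstrates the optimistic bias:
on no-signal data it inflates the out-of-fold AUC by ≳0.2 while the
in-fold default stays at chance. The reported final model is refit on
the whole training cohort (ranking, selection, fit), and both the CV
and final-model numbers are written side by side. The immunotherapy
model uses the identical pipeline with top-k = 6 and, because n = 44,
no holdout: out-of-fold scores are its only evaluation.

## Evaluation statistics

* **AUC** is the trapezoid area over all distinct score cut points,
  identically the Mann–Whitney U statistic / (n₊ n₋) with ties counted
  half.
* **DeLong CI**: placement values V₁₀, V₀₁ via midranks; Var(AUC) =
  S₁₀/n₊ + S₀₁/n₋; normal-theory interval clamped to [0, 1]. A
  degenerate variance (perfect separation with a clear margin) yields
  a zero-width interval with a warning; a seeded stratified bootstrap
  (2000 resamples) is available as the alternative.
* **Operating point**: Youden's J = sensitivity + specificity − 1,
  ties resolved toward higher specificity; with all-tied scores the
  +∞ boundary (predict all negative) is returned. Prediction is
  positive iff score ≥ threshold (closed lower bound, so counts are
  reproducible). Test-cohort metrics default to the threshold frozen
  from training out-of-fold scores (`youden-train`); `youden-self`
  re-derives it on the test scores.
* **Confusion metrics** follow the standard formulas; any ratio with a
  zero denominator is reported as NaN, never 0.
* **Sub-cohort ROC** compares each cancer subgroup (type, or stages
  pooled as II–III vs IV) against *all* healthy controls of the
  combined cohort.
* **Per-motif tests**: two-sided Wilcoxon rank-sum per motif, exact
  under the same n ≤ 12 no-ties rule; raw p-values are reported
  (mirroring the source annotation style) with a Benjamini–Hochberg
  column always written alongside.
* **ANOVA**: one-way, of cancer scores across strata of a covariate
  (sex, BMI class, age band <60/60–70/>70). The choice of cancer score
  as the response variable is an interpretation; the source analysis
  does not name one.
* **Heatmap**: per-motif z-scaling across samples (zero-variance
  motifs scale to zeros with a warning), complete-linkage Euclidean
  agglomerative clustering on both axes; leaf orders and the scaled
  matrix are exported for plotting.

## Reproducibility and problem sizes

All randomness flows from one root seed through named substreams
(simulation, split, folds, forest, bootstrap), so any stage can be
re-run in isolation; the run manifest records the config hash and the
substream seeds, and a rerun with the same config is byte-identical.

The test suite checks every statistic against an independent
brute-force oracle (pairwise enumeration for AUC, structural-component
enumeration for the DeLong variance, hypergeometric enumeration for
Fisher's exact test, full combination enumeration for the exact
Wilcoxon p, naive recounts for confusion metrics and motif profiles).
Problem sizes were chosen so the default suite completes in about a
minute: SAM-path oracle equivalence runs 8 samples × 10 000 fragments;
the planted-effect and null recovery checks run the full 206-sample
design at 50 000 ends per sample (out-of-fold AUC > 0.9 with ≥ 10/13
planted motifs recovered; null AUC within [0.35, 0.65] and maximum
importance inside a 12-permutation null band); DeLong coverage is
measured over 1000 null replicates at n = 50/50 (95% interval covers
0.5 for ~95% of replicates). The spectrum-fidelity check asserts the
fragment sampler sits inside the multinomial noise envelope (total
variation < 0.03 at 10⁵ draws, where an ideal sampler expects ≈ 0.02,
plus a χ² goodness-of-fit).

## Known limitations

Only binary classification; no alternative learners, hyperparameter
search, or score calibration beyond vote fractions. No comparison test
between correlated ROC curves. The simulator's independence
assumptions (i.i.d. reference, Dirichlet-multinomial profiles) are
idealisations; conclusions about real plasma WGS data require real
cohorts. Whether the original analysis counted one or two ends per
fragment and which MAPQ/duplicate policy it used is not stated
anywhere we could verify; the defaults above are flagged assumptions
and are configurable.
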