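# Methods

## Scope and data model

`cytomem` starts from feature-by-sample integer count matrices — peaks
quantified from H3K4me1 CUT&Tag or ATAC libraries, or genes from RNA-seq —
plus a sample sheet assigning each library a condition (stimulus,
timepoint, post-washout treatment, replicate). Everything upstream of the
count table (trimming, alignment, peak calling, track generation) is out
of scope; everything downstream of it (normalization, differential
testing, memory classification, clustering) is implemented here.

Genomic intervals are 0-based half-open (BED convention) everywhere,
including in memory; strand is ignored, as the assays are unstranded at
the peak level.

### Library sizes

CPM normalization divides by a per-library size. By default this is the
column sum of the provided matrix. When the sample sheet carries a
`library_size` column, those values are used instead and are interpreted
as the total aligned reads of the library. This distinction matters:
reads falling inside a consensus peak set (or a filtered gene panel) are
a minority of a real library, so the in-feature column sum both
underestimates depth and — more importantly — shifts with stimulation
when many features are induced, deflating fold changes of genuinely
induced features under plain CPM. Carrying the sequencing depth
explicitly keeps CPM estimates anchored to the library rather than to the
quantified subset. The simulator always writes `library_size` into its
sample sheet for the same reason: its features represent only the
responsive compartment of a genome (an in-feature read fraction of a few
percent, comparable to a FRiP value).

Normalization is plain CPM; composition-robust scale factors (TMM and
relatives) are deliberately not implemented.

## Differential test

Counts are modeled as negative binomial, `Var(y) = mu + phi * mu**2`, with
`mu_ij = s_j * lambda_{i,g(j)}` (library-size offsets, one concentration
per group). The two-group test is a likelihood-ratio test against the
common-concentration null, with p-values from chi-square with 1 df. With
`phi -> 0` the statistic reduces exactly to the Poisson LRT (the
`A=[5,5]` vs `B=[50,50]` fixture gives 2·(10 ln5 + 100 ln50 − 110 ln27.5)
≈ 85.47).

Numerics: the group MLE solves a score equation that is strictly
decreasing in log λ, so a vectorized Newton iteration on log λ (steps
clipped to ±4, convergence at |score| < 1e-10·(1+Σy)) is globally stable;
all-zero features get λ = 0 and are reported as p = 1, l2fc = 0 rather
than as errors. The implementation is cross-checked in the test suite
against brute-force numerical maximization of the same likelihood by a
generic optimizer (agreement to 1e-6 in p).

Dispersion estimation: per-feature method-of-moments on residuals around
the Poisson group means, with the residual sum of squares inflated by
n/(n−2) to offset the two estimated means; estimates are shrunk toward a
trended mean–dispersion fit with a fixed prior weight,

    phi* = (d0 * trend + df_res * raw) / (d0 + df_res),   d0 = 20.

The trend is the bin-mean of raw estimates over ~20 quantile bins of log
mean CPM, linearly interpolated. Bin means rather than medians: the raw
moment estimator is strongly right-skewed at 2–3 replicates and its
median sits well below the truth, which would make the LRT anticonservative.
With one replicate per group (df_res = 0) the trend is used as-is. The
prior weight d0 is exposed (`dispersion_prior_df`); any value of similar
order satisfies the calibration and recovery properties.

Fold changes are reported on the CPM scale with a 0.5 CPM pseudo-count on
both sides (`log2((b + 0.5)/(a + 0.5))`), keeping zero-count features
finite and the statistic antisymmetric. The pseudo-count is shared by
every module.

Multiple testing: an in-house Benjamini–Hochberg step-up (input order
preserved), tested against an independent transcription of the procedure
and against `statsmodels.multipletests`.

Replicates are treated as unpaired within a contrast; donors would be
analyzed separately.

## Peak memory

- **Abundance filter.** Per acute condition (unstimulated, IFNγ 8 h, LPS
  8 h), replicate-mean CPM per peak; a peak is kept iff it reaches the
  across-feature median in at least one condition (ties kept).
- **Induction.** L2FC > 2 and FDR < 0.01 vs unstimulated, both strict, per
  stimulus. Shared peaks are the intersection of the IFNγ- and
  LPS-induced sets.
- **Persistence.** Within the IFNγ-induced set, a peak persists under a
  post-washout treatment iff its washout-vs-unstimulated contrast has
  L2FC ≥ 0 and FDR < 0.01. The persistence statement does not name its
  reference condition unambiguously; the reading used here (still
  significantly above baseline) is the default, and the alternative
  (washout level at least the 8 h level) is available as
  `persistence_reference="stim_8h"`. The choice is recorded in the run
  manifest.
- **Washout shift.** Per-peak l2fc of replicate-mean CPM post-washout vs
  8 h, its arithmetic mean, and a two-sided paired Wilcoxon signed-rank
  test on the paired log2(CPM + 0.5) values. The signed-rank test drops
  zero differences, mid-ranks ties, enumerates the exact null by
  convolution up to 25 pairs (half-integer mid-ranks handled by doubling),
  and switches to a tie-corrected normal approximation with continuity
  correction beyond; two-sided p is `min(1, 2*min(cdf, sf))`.

## Behavior clustering

Rows (induced peaks) are z-scored with the sample standard deviation
(ddof = 1; constant rows map to zero) across the unstimulated, 8 h and
washout-media columns — replicate columns by default, switchable to
condition means (`cluster_columns`). k-means is Lloyd's algorithm with
k-means++ seeding from a seeded generator, best of 50 restarts by WCSS,
k = 3 by default; the per-iteration WCSS trajectory is retained and
verified non-increasing, and an empty cluster absorbs the point farthest
from its center. Clusters are labeled augment / persist / decay by
descending (mean washout z − mean 8 h z); acute-pattern clusterings are
labeled lps_specific / shared_jak / ifng_specific by a bipartite
assignment against the three condition signatures. Determinism given
(data, k, seed, restarts) is a contract, tested bit-level.

## Gene memory

Classifiers operate on replicate-mean CPM per condition, pseudo-count
0.5, inclusive thresholds throughout ("at least"):

- ISG induction: 8 h IFNγ CPM ≥ 5-fold over the reference. Time-matched
  vehicle (PBS 8 h) is the default reference, switchable to the naive 0 h
  (`isg_reference`).
- Persistence tiers for induced genes: retention
  `(CPM_washout + 0.5)/(CPM_8h + 0.5)` tiered at ≥ 0.9 / [0.2, 0.9) /
  < 0.2, computed per washout arm (media, ruxolitinib).
- LPS inducibility: max over post-LPS timepoints (1, 3, 6, 12 h) of the
  fold over the arm's own 0 h, cutoff 5 (media) or 4 (ruxolitinib arm).
  By default either pretreatment arm may satisfy the media rule
  (`inducible_mode="either_arm"`); arm-specific modes exist.
- Potentiation / tolerance: the IFNγ/PBS ratio must pass 2 (resp. 0.5)
  at two contiguous post-LPS timepoints; 0 h is reserved for the basal
  classifier and never counts toward contiguity. Tolerance additionally
  requires ≥ 4-fold LPS induction in the ruxolitinib arm.
- Basal set point: 0 h L2FC (IFNγ vs PBS) < 0.5 is `unchanged`, else
  `elevated` (tie to elevated).

Potentiated and tolerized are mutually exclusive: a gene satisfying both
contiguity rules at disjoint timepoint pairs (possible only for
pathological shapes) is called neither and flagged `ambiguous`. The
restriction to protein-coding genes is treated as a property of the input
gene list.

## Synthetic data generator

The generator emulates the two designs end to end with NB counts
(gamma–Poisson draws; Poisson below phi = 1e-10), per-feature log-normal
baseline CPM (log-mean ln 20, log-sd 1.0 — a realistic post-filter
abundance spread) and log-normal dispersion (log-mean ln 0.05, log-sd
0.5, bulk-assay overdispersion scale), and log-normal library sizes
(mean 5e6, CV 0.2). Two replicates per condition by default (matching
typical per-donor biological replication), configurable upward.

Peak archetypes: unresponsive, lps_specific (induced with and without
ruxolitinib, decaying after washout), shared_jak (induced by both
stimuli, absent under ruxolitinib), ifng_specific. Induced log2 effects
are N(3.5, 0.5) floored at 0.25; the mean/sd are chosen so induced
features sit clearly above the calling threshold, keeping truth-recovery
statements about the pipeline rather than about sub-threshold truths.
Each IFNγ-induced peak draws a washout behavior (persist 0.5 / decay
0.3 / augment 0.2) realized as the retained fraction of the induced
log2 effect (1.0 / 0.0 / 1.5), scaled by a per-treatment retention
multiplier (media 1.0, antibody 0.45, ruxolitinib 0.15). The multipliers
reproduce the qualitative media > antibody > ruxolitinib persistence
ordering, not any particular fractions.

Gene archetypes follow piecewise-constant per-timepoint shapes for
auditability: a shared LPS fold profile (1→3×, 3→8×, 6→10×, 12→6×) in
naive arms; potentiated genes multiply the PBS trajectory by 3 over the
whole course (elevated-basal class, basal L2FC 1.5) or at 6–12 h only
(unchanged-basal class); tolerized genes divide by ~3.3 at 1–3 h;
JAK-dependent-induction genes have their ruxolitinib-arm induction capped
at 1.5-fold; ISGs are induced 10-fold at 8 h and retain 95% / 25% / 2%
(persistent / transient / any-under-ruxolitinib) of the induced excess.
Ruxolitinib during washout erases all IFNγ-derived modifications of the
time course, so rux arms of memory archetypes follow the naive shape.

What the generator does **not** emulate: read-level artifacts (fragment
sizes, Tn5 insertion bias, GC effects, duplicates), sequence/motif
content, peak-width variation in signal, correlated features, donor
effects, batch structure, or composition-driven normalization bias beyond
the explicit library-size mechanism. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
model, not robustness to those real-data phenomena.

## Validation conditions and problem sizes

The acceptance checks (tests and `scripts/acceptance.py`) use: 5,000 null
features with phi = 0.05 and 3 replicates/group for calibration
(nominal-rate band 3–7% at p < 0.05); 2,000 features with 10% induced at
a constant true L2FC of 3 for recovery (sensitivity ≥ 0.9, empirical FDR
≤ 0.05); full 2,000-peak pipeline runs at defaults across three seeds for
the persistence ordering and a fixed seed for ≥ 95% behavior-label
agreement; 2,000 genes at the default archetype mix for classifier F1
(≥ 0.9) and JAK-exclusion specificity (≥ 0.95); 400-feature duplicate
runs for byte-identical determinism. These sizes give stable statistics
at interactive runtimes.

## Known limitations

- ISG retention tiers are noisy at 2 replicates (a truly 95%-retained
  gene frequently measures below 90%); tier counts should be read as
  threshold statistics, not recovered classes.
- The NB LRT with moderated dispersion is mildly liberal at very small
  replicate numbers (the calibration band, not exact nominal level, is
  the contract); no quasi-likelihood or exact test is provided.
- Persistence fractions depend on the induced set's effect-size and
  abundance distribution; only their ordering across treatments is a
  stable claim.
- No batch correction, covariate GLMs, paired-replicate testing, or TMM
  normalization.
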