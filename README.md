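# cytomem

Count-based analysis of cytokine-dependent chromatin and transcriptional
memory in macrophages.

## The problem

Macrophages pulsed with interferon-gamma (IFNγ) acquire *de novo*
enhancers (H3K4me1), open chromatin (ATAC) and elevated
interferon-stimulated gene (ISG) expression, and respond differently to a
later lipopolysaccharide (LPS) challenge — some genes are *potentiated*,
others *tolerized*. A central question is whether this memory survives
removal of the cytokine itself: after an 8 h pulse the stimulus is washed
out, cells are cultured a further 88 h in plain media, media with a JAK1/2
inhibitor (ruxolitinib), or media with anti-IFNγ neutralizing antibody,
and the marks and responses are re-measured.

`cytomem` implements the quantitative side of that experimental design for
feature-by-sample count matrices (peaks for CUT&Tag/ATAC, genes for
RNA-seq): differential testing, induction and persistence calls, washout
behavior clustering, and the time-course classifiers for potentiated and
tolerized genes. A seeded negative-binomial simulator generates matrices
with known ground-truth archetypes so every stage is testable without
deposited sequencing data.

## The statistics at the core

- **Counts model.** Counts y<sub>ij</sub> ~ NB(μ<sub>ij</sub>, φ<sub>i</sub>)
  with Var = μ + φμ², μ<sub>ij</sub> = s<sub>j</sub>λ<sub>ig(j)</sub>,
  where s<sub>j</sub> is the library size. Per-feature dispersions are
  method-of-moments estimates shrunk toward a trended mean–dispersion fit.
  Two-group comparisons use the NB likelihood-ratio test (χ², 1 df);
  as φ→0 it reduces to the Poisson LRT. Multiple testing is controlled by
  Benjamini–Hochberg FDR.
- **Normalization.** CPM = counts / library size × 10⁶; log2 fold changes
  (L2FC) add a 0.5 CPM pseudo-count to both sides.
- **Induction.** A peak/gene is induced at 8 h iff L2FC > 2 and FDR < 0.01
  versus unstimulated (strict inequalities).
- **Persistence.** An induced peak persists post-washout iff its
  washout-vs-unstimulated contrast keeps L2FC ≥ 0 at FDR < 0.01. ISGs
  (genes induced ≥ 5-fold by 8 h IFNγ) are tiered by post-washout
  retention: ≥ 90%, 20–90%, < 20%.
- **Washout behavior.** Induced peaks are clustered (k = 3, z-scored rows,
  seeded Lloyd k-means, 50 restarts) and labeled augment / persist / decay
  by their post-washout trend.
- **Restimulation classes.** A gene is LPS-inducible at ≥ 5-fold over its
  own 0 h (≥ 4-fold in the ruxolitinib arm); *potentiated* if the
  IFNγ-arm/PBS-arm CPM ratio is ≥ 2 at two contiguous post-LPS timepoints
  (1, 3, 6, 12 h); *tolerized* if that ratio is ≤ 0.5 at two contiguous
  timepoints with induction confirmed under JAK blockade; the 0 h basal
  set point is *elevated* at L2FC ≥ 0.5 vs PBS.

## Worked example

```bash
cytomem simulate --kind peaks --n-features 300 --seed 4 --out-dir demo
cytomem classify-peaks --counts demo/counts.tsv --design demo/samples.csv --out-dir demo/out
python -c "import json; print(json.load(open('demo/out/summary.json')))"
```

On this 300-peak simulation the summary reports (numbers printed by the
run above):

```
n_induced_ifng: 87          # peaks passing L2FC>2, FDR<0.01 vs unstim
n_shared: 42                # induced by both IFNγ and LPS
persistence_fraction_media: 0.736
persistence_fraction_anti_ifng_ab: 0.644
persistence_fraction_ruxolitinib: 0.057
washout_mean_l2fc_ifng_induced: -0.49
```

Read: about three quarters of IFNγ-induced peaks stay elevated 88 h after
washout in plain media, slightly fewer under neutralizing antibody, and
almost none under ruxolitinib — the JAK-dependence of persistence the
pipeline is built to quantify. Per-peak calls, per-contrast tables, BED
files of induced/persistent peaks and a JSON manifest of every threshold
and mode are written alongside.

The same works for genes:

```bash
cytomem simulate --kind genes --n-features 200 --seed 4 --out-dir demo_g
cytomem classify-genes --counts demo_g/counts.tsv --design demo_g/samples.csv --out-dir demo_g/out
```

yielding class counts (`n_potentiated: 29`, `n_tolerized: 13`, basal
split `elevated: 16 / unchanged: 13`, ISG retention tiers with and
without ruxolitinib) in `demo_g/out/summary.json`.

Library interface: `cytomem.simulate`, `cytomem.run_contrast`,
`cytomem.classify_peaks`, `cytomem.classify_genes`, `cytomem.kmeans`,
plus the low-level operations (`bh_adjust`, `paired_wilcoxon`,
`nb_test`, ...) — see the module docstrings.

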