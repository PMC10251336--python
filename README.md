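# sofdex

Downstream analysis of a separation-of-function (SoF) glucocorticoid
receptor (GR) nascent-RNA time course, packaged as a tested, reusable
pipeline that runs end to end on synthetic data with known ground truth.

## The problem

GR is a hormone-activated transcription factor that binds DNA at
glucocorticoid response elements and also binds RNA. A SoF point mutant with
selectively reduced RNA affinity (paired with a DNA-affinity-matched control
mutant, "Ctrl") lets one ask which genes are de-repressed when GR-RNA
binding is lost. The readout is a 4sU-seq time course (0–3 h dexamethasone)
across three genotypes (wt, SoF, Ctrl). The computational questions this
package answers:

1. **Which genes respond, and how differently between genotypes?**
   Negative-binomial Wald tests on gene counts for two contrast families:
   each treatment time versus the t = 0 ethanol control within a genotype,
   and each mutant versus wt pooled over time
   (`sofdex.diffexpr`). Size factors are median-of-ratios
   (`s_j = median_g k_gj / (prod_j k_gj)^(1/n)` over zero-free genes),
   dispersion is method-of-moments under `Var = mu + alpha*mu^2`, and
   p-values are Benjamini–Hochberg adjusted.
2. **Which genes are preferentially activated in the SoF mutant?** At 3 h,
   each gene gives a point (x = SoF log2FC, y = Ctrl log2FC). A regression
   line is fit over genes significant in either mutant; bivariate outliers
   are found with the minimum covariance determinant (MCD: the h-point
   subset minimizing det of its covariance, located by concentration steps;
   outliers have squared robust Mahalanobis distance beyond chi²₂(0.975)).
   Outliers *below* the line that are significant in SoF form the
   "SoF Dex-dep." set; the mirror image forms "SoF 3h Rep."; the time-pooled
   SoF-vs-wt contrast yields constitutive sets ("SoF Dex-ind.",
   "SoF Const. Rep.") (`sofdex.classify`, `sofdex.robust`).
3. **Are these genes direct GR targets?** Co-occurrence of gene TSSs with
   ChIP peaks: the relative-distance statistic (Uniform[0, 0.5] under
   independence), the fraction of TSSs with a peak within 30 kb, and a
   bedtools-shuffle-style null (`sofdex.cooccurrence`).
4. **Are dex-independent genes spatially clustered?** Hypergeometric
   chromosome enrichment and an exhaustive bounded-window scan for
   contiguous enriched regions with BH adjustment (`sofdex.positional`).
5. **Orthogonal quantification:** ΔΔCq relative expression from qPCR Cq
   tables (`rel = 2^-ΔΔCq`, `sofdex.qpcr`) and per-cell nuclear GR fraction
   from two-channel images (Otsu nuclear mask, 4-px cytoplasmic ring,
   `nuc/(nuc+cyt)`, `sofdex.imaging`).

Because the original sequencing data are multi-gigabyte external
repositories, the package ships a first-class synthetic-data module
(`sofdex.synthetic`) that generates genomes, truth-labeled NB count
matrices, ChIP peaks, Cq tables and cell images with the statistical
structure the analysis assumes, so every stage is testable offline against
planted truth.

## Worked example

```bash
sofdex run --seed 1 --out runs/demo
```

prints the recovered set sizes

```
{"sof_dexdep": 54, "sof_3h_rep": 4, "sof_dexind": 73, "sof_const_rep": 101}
```

and writes `runs/demo/summary.json` with, among other things,

```json
"recovery": {
  "sof_dexdep": {"n_predicted": 54, "n_true": 50,
                 "sensitivity": 0.9, "fdr": 0.167},
  "sof_dexind": {"n_predicted": 73, "n_true": 60,
                 "sensitivity": 0.983, "fdr": 0.192}
},
"positional": {"n_regions": 3,
               "enriched_chromosomes": ["chr3", "chr7", "chr8"]}
```

Reading: of the 50 genes planted with an amplified dex response in the SoF
genotype, 45 are recovered by the regression/MCD rule (sensitivity 0.90,
FDR 0.17); the 60 planted constitutively-up genes are recovered at 0.98
sensitivity; and the positional scan finds exactly the three chromosomes
carrying the planted contiguous runs. The `cooccurrence` block shows the
planted direct targets' 30-kb overlap ratio (0.785 at the default
`p_near = 0.8`) against the shuffle null (0.091, the genome fraction within
30 kb of a peak), while the dex-independent set sits at the null level
(0.055) — the signature separating direct from indirect activation.

Individual stages are available as `sofdex simulate`, `sofdex de`,
`sofdex classify-sets`, `sofdex cooccur`, `sofdex positional-cmd`,
`sofdex qpcr`, `sofdex image`, or as plain library calls.

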