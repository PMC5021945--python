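# ffpesig

Evaluation of frozen-tissue-derived prognostic gene expression
signatures in FFPE (formalin-fixed, paraffin-embedded) tumor samples
profiled on two platforms: a targeted count platform (NanoString
nCounter-style) and a genome-wide array platform (Affymetrix
HTA-style).

## The problem

Most archival clinical tumor specimens are FFPE-preserved, which
degrades RNA, while most published prognostic gene signatures for
colorectal cancer were derived from fresh-frozen tissue. Whether those
signatures remain detectable in FFPE material — and whether the answer
depends on the profiling platform — is the question this package's
pipeline answers. It is aimed at biostatisticians and computational
biologists validating expression-based risk classifiers on archival
cohorts.

The pipeline covers:

* **Count-platform QC and normalization** — samples fail when the mean
  raw endogenous count is ≤ 1000 or when ≥ 20% of genes fall at or
  below the per-sample detection threshold, mean(negative controls) +
  3 sd. Normalization scales by positive-control and housekeeping
  geometric means, subtracts negative-control background with clamping
  at 0, and moves to log2.
* **Array summarization** — quantile normalization, Tukey median-polish
  probe-set summarization, removal of probes mapping to multiple genes,
  and largest-IQR probe-set selection per gene.
* **Batch adjustment** — ComBat-style empirical-Bayes location/scale
  correction per platform, with negative values replaced by 0.
* **Survival screening** — for each gene *g* the univariate Cox model
  *h(t|x<sub>g</sub>) = h<sub>0</sub>(t) exp(β<sub>g</sub> x<sub>g</sub>)*
  is fitted by Newton–Raphson on the Efron partial likelihood against
  5-year overall survival (OS) and disease-free survival (DFS)
  (administrative censoring at 60 months). The reported p-value is the
  score test at β = 0 — the log-rank test generalized to a continuous
  covariate — with Benjamini–Hochberg adjustment across genes.
* **Cross-platform concordance** — per-pair and per-gene Pearson (and
  Spearman) correlations with percentile-bootstrap CIs on the mean,
  sign concordance of log hazard ratios, and a one-sided two-sample
  Kolmogorov–Smirnov comparison of the −log10 p-value distributions
  with asymptotic p = exp(−2mnD²/(m+n)).
* **Signature evaluation** — genes whose fitted hazard direction
  contradicts the published up/down annotation are filtered out (the
  unfiltered variant is always also produced); each sample receives
  the mean of median-centered, direction-aligned signature-gene
  values; a median split defines high/low-risk groups compared by KM
  curves and the two-group log-rank test.
* **Synthetic cohorts** — a generator producing matched two-platform
  measurements of one latent expression layer, negative-binomial
  counts with spike-in controls, multi-probe array renderings, batch
  effects, and Cox survival with a known set of prognostic genes, so
  every stage is testable against ground truth.

## Worked example

```python
import ffpesig as f

cfg = f.SimulationConfig(n_samples=42, n_genes=120, n_prognostic=12, seed=11)
cohort = f.simulate_cohort(cfg)

report = f.compute_qc(cohort.counts, cohort.controls)
kept = f.filter_samples(cohort.counts, report)
log2 = f.normalize_counts(kept, cohort.controls)
adj = f.clamp_negative(f.combat_adjust(log2, cohort.clinical["batch"].loc[log2.columns]))

res = f.screen_genes(adj, cohort.clinical.loc[adj.columns], "DFS")
sig = f.make_signature(cohort.truth, n_true=8, n_noise=2, seed=11)
ev = f.evaluate_signature(adj, sig, cohort.clinical.loc[adj.columns], filtered=True)
```

prints (via the obvious `print` calls):

```
QC: 34/42 samples pass
screen: 1/120 genes at q<0.05
signature 'synthetic-signature': 9 of 10 genes kept after direction filtering
risk groups: 17 high / 17 low
log-rank OS: chi2=1.51, p=0.2189
log-rank DFS: chi2=5.64, p=0.0176
```

Reading: 8 of the 42 samples were rendered with degraded efficiency
and fail QC. At n = 34 the per-gene screen has little power after FDR
adjustment (1 of 120 genes), yet the 10-gene signature — built from
truly prognostic genes — still separates the cohort into risk groups
with significantly different DFS (p = 0.018), while its OS separation
does not reach significance at this sample size. One signature gene is
dropped because its fitted hazard direction in this cohort contradicts
its annotation.

The same stages are available as CLI subcommands
(`ffpesig simulate | qc | normalize | summarize | adjust | screen |
concord | signatures | run`); `ffpesig run --config cfg.yaml --out out/`
executes the whole pipeline and writes `qc_report.tsv`,
`expression_*.tsv`, `cox_results.tsv`, `concordance.json`,
`signature_report.json` and per-group KM tables.

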