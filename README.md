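# aegmap

Adenocarcinoma of the esophagogastric junction (AEG) sits at the
boundary of two better-studied cancers: esophageal adenocarcinoma (EAC)
and gastric adenocarcinoma (GAC). A central question for an AEG tumor is
where its malignant cells actually come from — the esophagus, the
stomach, or the junction (EGJ) itself — because the EGJ-originating
subtype is poorly differentiated, metabolically distinct and carries a
worse prognosis. `aegmap` implements the computational pipeline for
resolving this from single-cell RNA-seq, bulk expression, spatial
transcriptomics and paired metabolomics, together with a synthetic-data
module that generates every input with planted ground truth, so the
whole analysis is testable without any external download.

The pipeline's core operators:

- **Signature scoring.** The activation of a marker gene set in a cell
  is scored from within-cell expression ranks via a Mann–Whitney
  U statistic: with descending ranks capped at `r_max` (default 1500),
  `U = Σ min(r_i, r_max+1) − n_s(n_s+1)/2` and
  `score = 1 − U / (n_s · r_max)`. Signed signatures score
  `positive − negative`. The AEG marker sets themselves are derived from
  paired tumor/NAT bulk data: paired t test on log2 values with BH
  adjustment, genes with |log2FC| < 1.2 removed, top 50 / bottom 50 by
  fold change.
- **Malignancy.** Per-cell CNV burden is inferred from expression:
  log2-scale normalized expression centered on immune reference cells,
  clamped, moving-averaged over k = 101 genes in genomic order within
  each chromosome; the burden is the mean squared smoothed value. A cell
  is called malignant iff it is high (1-D two-means split) on **both**
  CNV burden and the AEG marker score.
- **Origin typing.** EAC and GAC scores are genome-wide correlations of
  a malignant cell's profile with reference malignant centroids
  (class-mean-centered Pearson); together with the AEG score, the
  triplet is z-scaled across clusters (or cohort samples) and the argmax
  assigns AEG-like / EAC-like / GAC-like.
- **Survival.** Kaplan–Meier product-limit curves, the K-group log-rank
  test, and the optimal-cutoff scan (the score threshold with the most
  significant two-group split; its p is reported as selection-biased).
- **Metabolism.** Exact paired Wilcoxon signed-rank tests for tumor/NAT
  metabolite shifts; pathway differential-abundance score
  `DA = (n_up − n_down) / n_measured ∈ [−1, 1]`; metabolite-level flux
  as the product of a cell-type × reaction flux matrix with a signed
  reaction × metabolite stoichiometric matrix (positive = accumulation,
  negative = consumption).
- **Spatial.** Spot deconvolution by non-negative least squares against
  marker-gene centroids from the annotated single-cell data; each spot
  is annotated by its largest proportion; group fractions are compared
  with two-sided Mann–Whitney tests.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (seed 1) and print what they find:

```sh
python analysis/01_simulate.py       # writes results/sim/
python analysis/02_malignant_call.py
python analysis/03_origin_typing.py
python analysis/04_cohort_survival.py
python analysis/05_metabolism.py
python analysis/06_spatial.py
```

`02_malignant_call.py` prints:

```
QC: kept 2493/2500 cells (2 mito, 5 low-gene)
signature: 50 positive / 50 negative genes
malignant call: 492 cells (thresholds: CNV 0.0397, marker 0.0383)
vs planted truth: sensitivity 0.984, specificity 1.000
```

— of 2,500 simulated cells, 492 pass both the CNV-burden and marker
thresholds, recovering 98.4% of the 500 planted malignant cells with no
false positives among the epithelium. `03_origin_typing.py` then labels
all six planted malignant clusters correctly (each origin's clusters get
the highest z-scaled score of their own class), and
`04_cohort_survival.py` classifies the 248-sample cohort with perfect
agreement and finds the AEG-like group's shorter survival
(three-group log-rank p = 2.4e-04; KM median 18.9 months vs 34.5 and
38.6). `05_metabolism.py` recovers spermine, lithocholic acid and
adenine among the up-regulated metabolites and ranks the
arginine/proline pathway first (DA = 0.8); `06_spatial.py` deconvolves
200 spots with a mean absolute proportion error of 0.093.

The same stages are available as a CLI
(`aegmap simulate|qc|score|cnv|call-malignant|classify-origin|
classify-cohort|survival|metabolomics|flux|spots|run-all`); `run-all`
executes the full pipeline from one config/seed and writes a manifest
with per-stage counts and output checksums.

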