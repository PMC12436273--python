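# Methods

This note documents the models, parameter choices and numerical
conventions behind `aegmap`, and what the synthetic study conditions do
and do not establish about real data.

## Signature scoring

The activation score of a gene set in a cell is a normalized
Mann–Whitney U statistic over within-cell expression ranks. Genes are
ranked descending (rank 1 = highest expression) with average ranks on
ties; ranks of signature genes are capped at `r_max + 1`, and genes
absent from the matrix take the capped rank. With
`U = Σ r'_i − n_s(n_s+1)/2`, the score `1 − U/(n_s · r_max)` lies in
`[(n_s−1)/(2·r_max), 1]` for a positive-only set. Because only ranks
enter, any strictly increasing per-cell transform of expression leaves
scores unchanged, so raw counts and log-normalized values are
interchangeable inputs. `r_max = 1500` is the conventional cap: in a
typical cell only the top ~1500 genes are reliably ordered, everything
deeper is noise and should contribute equally.

A signed signature scores `positive − negative`, floored at 0 by
default so the result reads as an activation. The floor is configurable
off, and the pipeline's malignant-call step deliberately thresholds the
*unfloored* score: flooring collapses all inactive cells into a point
mass at 0, and a midpoint-of-means threshold between a point mass and a
dispersed active mode lands inside the active mode, costing
sensitivity.

Marker derivation from paired tumor/NAT bulk: per gene, a paired
t test on log2(x+1) values with Benjamini–Hochberg adjustment; genes
with q ≥ 0.05 or |log2FC| < 1.2 are dropped, the survivors are ranked
by log2FC, and the top/bottom 50 become the positive/negative sets. A
moderated (shrinkage) model would change nothing here: with ≥ 13 pairs
and the strong effects that survive a 1.2 log2FC filter, ordinary
t statistics select the same top/bottom genes.

## CNV burden and the malignant call

The CNV profile is a windowed stand-in for segmentation-based callers,
with the same contract (high burden ⇔ aneuploid): log2-scale normalized
expression (`log1p(CP10k)/ln 2`, so values read as approximate log2
copy ratios) is centered by the per-gene mean over reference immune
cells (T and B cells, which are diploid), clamped to ±3 to bound
outlier influence, and moving-averaged over k = 101 consecutive genes
within each chromosome, the window shrinking at chromosome ends so
smoothing never crosses a boundary. The window is in gene-index space,
not base pairs, which makes it robust to annotation density. The
mitochondrial contig is excluded. The per-cell burden is the mean of
squared smoothed values, so gains and losses both raise it.

"High" is defined by an exact 1-D two-means split (prefix-sum scan over
the sorted values; threshold = midpoint of the two cluster means), with
a quantile fallback for degenerate inputs. A cell is malignant iff it
is high on both the CNV burden and the bulk-derived marker score — the
AND is what lets two individually imperfect signals give a
specific call.

## Origin typing

EAC and GAC similarity scores are Pearson correlations between a
malignant cell's log-normalized profile and per-class centroids built
from reference malignant cells after site filtering (EAC: adenocarcinoma
sites only; GAC: body/antrum/distal), over the gene intersection of all
inputs (error below 200 common genes). Before correlating, query and
centroids are centered by the per-gene mean across the reference
classes. This removes the expression structure all profiles share —
housekeeping level, library composition — which otherwise dominates
genome-wide correlations and compresses the EAC-vs-GAC contrast to a few
hundredths; after centering, the correlation measures class-differential
signal, and a profile identical to a centroid still scores exactly 1.
The plain uncentered correlation (which is invariant to per-cell affine
rescaling) remains available via `center_classes=False`.

The three scores — two correlations and one rank-based activation —
live on different scales, so each is z-scaled (sample SD) across
clusters or cohort samples before the argmax; with fewer than two units
the code falls back to min-max scaling with a warning. Ties break
lexicographically, with a warning. Per-cluster values are means of
per-cell scores: cell-vs-cell all-pairs correlation would be quadratic
in cells for the same ordering.

For bulk cohorts the same machinery runs on log2(TPM+1) per sample;
labels are invariant to global rescaling of the TPM matrix.

## Survival

Kaplan–Meier product-limit estimation over distinct event times, with
events preceding censorings at tied times (the standard convention).
The K-group log-rank statistic uses observed-minus-expected event
counts with hypergeometric covariance of the first K−1 groups and a
chi-square reference with K−1 degrees of freedom; a vectorized
permutation p-value is available, and the two agree to within the
chi-square approximation's O(1/n) error (~0.01 at n = 40 and mid-range
p — relevant when comparing against Monte-Carlo references).

The optimal-cutoff scan considers every observed score value whose
high/low split leaves at least 10% of records on each side, and returns
the cutoff with the smallest two-group log-rank p. That minimum is a
scan statistic: it is reported with an explicit `selection_biased` flag
and no multiplicity correction, and under the null it is below 0.05 far
more often than 5% of the time — the package documents rather than
hides this property of the procedure.

## Metabolomics and flux

The paired Wilcoxon signed-rank test drops zero differences, assigns
average ranks to tied |differences|, and computes the exact two-sided p
for n ≤ 25 by dynamic programming over the doubled (hence integral)
ranks — valid under ties because the null conditions on the observed
rank multiset. Above n = 25 a normal approximation with continuity and
tie correction takes over. Direction comes from the median per-pair
log2(tumor/normal). Up/down calls gate on the raw p < 0.05 (BH q
reported alongside; configurable), matching the convention of
differential-abundance scoring where per-metabolite adjustment is not
applied before pathway aggregation.

Pathway DA score: `(n_up − n_down)/n_measured` over a pathway's
*measured* members; pathways with fewer than 3 measured members are
skipped to avoid ±1 scores from singletons. The score is antisymmetric
under swapping the up/down sets.

Metabolite-level flux is the plain matrix product `R·S` of cell-type ×
reaction flux intensities with signed reaction × metabolite
stoichiometry (products +, substrates −): positive entries mean net
accumulation, negative net consumption. z-scores across cell types use
the sample SD (n−1); constant columns map to 0 with a warning.

## Spot deconvolution

Markers per cell type are the top 50 genes by log-fold-change of the
type's mean log-normalized expression against the *strongest other
type* (one-vs-max). With related subtypes present — three malignant
origin subtypes sharing a malignancy program — a pooled-rest contrast
selects exactly the shared genes and the subtype centroids become
nearly collinear; the one-vs-max contrast selects the genes unique to
each subtype. Centroid values are `log1p` of the type's mean CP10k
profile (a pseudo-bulk centroid): spots are linear mixtures of cells,
and averaging in log space would insert a Jensen-gap bias between
centroids and every mixed spot. Deconvolution solves non-negative least
squares per spot on the shared marker genes of the log-normalized spot
profile and renormalizes the coefficients to sum to one; all-zero spots
get uniform proportions with a warning. Annotation is the row argmax;
proportions are scale-invariant in the spot's total counts.

## The synthetic study conditions

The generators emulate the data types the analysis consumes, with one
global seed fanned out to fixed per-generator streams (numpy
`SeedSequence` spawn keys), so outputs are bit-reproducible and adding
a generator never perturbs existing ones.

Counts are negative binomial (Gamma–Poisson, Var = μ + φμ², φ = 0.5)
on per-gene archetype means (lognormal, median ≈ 1.6 counts), 2,000
genes on ten chromosomes plus the 13 mitochondrial genes, ~5,500 UMIs
and ~1,300 detected genes per cell — QC-healthy droplet scale. Default
2,500 cells, 20% malignant. Planted structure, chosen to mirror the
biology the pipeline is built for:

- **CNV blocks**: four contiguous blocks covering 20% of the autosomal
  panel at |log2| ∈ {0.7, 0.8, 1.0}, multiplicative on expected
  expression — how expression-level CNV inference actually sees
  aneuploidy.
- **Origin programs**: three disjoint 200-gene programs at log2
  effect 1, one per origin (AEG/EAC/GAC), carried by malignant cells
  and by the matching reference sets and cohort pseudo-bulks.
- **Shared malignancy program**: 150 genes at log2 effect 2 in *all*
  malignant cells, and a 300-gene differentiation program expressed by
  normal epithelium (log2 1.5 above background) and lost in malignant
  cells. The planted bulk tumor/NAT differential genes are exactly
  these cell-level programs (up = malignancy + EGJ-specific genes,
  down = differentiation genes, at log2 shift 2 over 20 pairs): bulk
  AEG tumors are dominated by their malignant compartment, so the
  bulk-derived signature must be the one the single cells actually
  express — with shared-malignancy genes in the majority, since
  EGJ-originating cells are the rare subtype.
- **Cohort**: 248 samples (groups 20/40/40% AEG/EAC/GAC-like),
  exponential survival with a three-fold hazard for the AEG-like group
  (0.045 vs 0.015 per month), uniform independent censoring on
  [0, 60] months.
- **Metabolome**: 13 tumor/normal pairs, log-normal intensities, 25
  up- and 25 down-planted metabolites at log2 shift 2, one pathway
  seeded with up-metabolites and one with down.
- **Spots**: Dirichlet mixtures (α = 1) over the three malignant
  subtypes and four normal types, spot depth ~5,000 counts.

Effect sizes not fixed by the validation conditions (the malignancy and
differentiation program sizes and effects, marker effects, noise
levels) were set so that the planted signal levels are realistic for GI
tumors — tumor markers several-fold up, differentiation markers largely
lost — and so the default conditions carry enough signal for the
pipeline's documented operating points (marker-score separation of
several pooled SDs; dual-criterion call sensitivity and specificity
above 0.9).

What the synthetic conditions do **not** emulate: doublets and ambient
RNA, batch effects, cell-cycle structure, subclonal CNV heterogeneity,
overlapping or correlated gene programs, non-exponential hazards,
informative censoring, LC–MS missingness and batch drift, and spatial
autocorrelation of spot composition. Passing tests therefore establish
that the operators are implemented correctly and recover planted
structure under clean droplet-scale noise — not that the pipeline is
robust to every artifact of real tissue data.

## Numerical conventions

- Normalization: `log1p` of counts-per-10k throughout; CNV profiles
  rescaled to log2 units.
- Gene order: chromosome naturally sorted (chr2 < chr10), then 0-based
  start.
- Ties: average ranks inside scoring and Wilcoxon; lexicographic
  winners (with warnings) for label argmaxes.
- Determinism: same config and seed give byte-identical outputs; the
  pipeline manifest records config echo and SHA-256 checksums of every
  written table.
- Problem sizes in the validation suite: the default conditions above,
  with 10-seed replication for the malignant call, 50 seeds at 1,000
  cells for origin recovery, 20,000 permutations for the log-rank
  reference, and 5,000 null simulations for Wilcoxon calibration.
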