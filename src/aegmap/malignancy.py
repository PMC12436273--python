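"""QC filtering, expression-derived CNV burden and the malignant call.

Malignant epithelial cells are identified as cells that are high on BOTH
a CNV burden score (aneuploidy proxy inferred from expression) and the
activation score of tumor marker genes. The CNV profile is a windowed
stand-in for segmentation-based callers: log-normalized expression is
centered on a reference-cell per-gene mean, clamped, and moving-averaged
along the genome within each chromosome; the burden is the mean square
of the smoothed profile, so both gains and losses raise it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import lognorm_cp10k, order_genes
from .signatures import SignatureSet, rank_within_cell, ucell_score

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    n_input: int
    n_kept: int
    n_removed_mito: int
    n_removed_genes: int
    mito_genes_found: int


@dataclass
class CnvProfile:
    """Smoothed, reference-centered log2-like profile, cells x genes."""

    values: pd.DataFrame
    window: int
    reference_cells: pd.Index


@dataclass
class MalignantCall:
    is_malignant: pd.Series
    cnv_threshold: float
    score_threshold: float
    method: str


def _mito_mask(genes: pd.Index, annotation: pd.DataFrame | None) -> np.ndarray:
    if annotation is not None and "chrom" in annotation:
        ann = annotation.reindex(genes)
        mask = (ann["chrom"].astype(str).str.upper().isin({"MT", "CHRM", "CHRMT"})).to_numpy()
        if mask.any():
            return mask
    return np.asarray(genes.str.upper().str.startswith(("MT-", "MT.")))


def qc_filter(
    counts: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    *,
    max_mito: float = 0.20,
    min_genes: int = 1000,
) -> tuple[pd.DataFrame, QcReport]:
    """Keep cells with mito fraction <= max_mito and > min_genes detected
    non-mitochondrial genes.
    """
    mito = _mito_mask(counts.columns, annotation)
    if not mito.any():
        warnings.warn("no mitochondrial genes found; mito criterion skipped")
        mito_frac = np.zeros(counts.shape[0])
    else:
        total = counts.sum(axis=1).to_numpy(dtype=float)
        total[total == 0] = 1.0
        mito_frac = counts.loc[:, mito].sum(axis=1).to_numpy(dtype=float) / total
    detected = (counts.loc[:, ~mito] > 0).sum(axis=1).to_numpy()

    pass_mito = mito_frac <= max_mito
    pass_genes = detected > min_genes
    keep = pass_mito & pass_genes
    report = QcReport(
        n_input=counts.shape[0],
        n_kept=int(keep.sum()),
        n_removed_mito=int((~pass_mito).sum()),
        n_removed_genes=int((~pass_genes).sum()),
        mito_genes_found=int(mito.sum()),
    )
    logger.info(
        "QC kept %d/%d cells (%d failed mito<=%.2f, %d failed genes>%d)",
        report.n_kept, report.n_input, report.n_removed_mito, max_mito,
        report.n_removed_genes, min_genes,
    )
    return counts.loc[keep], report


def _moving_average_shrink(x: np.ndarray, k: int) -> np.ndarray:
    """Centered moving average over the last axis, window shrinking at the
    edges so every position averages the intersection of its window with
    the chromosome."""
    n = x.shape[-1]
    h = k // 2
    cs = np.zeros(x.shape[:-1] + (n + 1,))
    np.cumsum(x, axis=-1, out=cs[..., 1:])
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h + 1, n)
    return (cs[..., hi] - cs[..., lo]) / (hi - lo)


def infer_cnv_profile(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    reference_cells: Sequence | pd.Index,
    *,
    k: int = 101,
    clamp: float = 3.0,
    is_lognorm: bool = False,
    exclude_chroms: tuple[str, ...] = ("MT",),
) -> CnvProfile:
    """Windowed expression-CNV profile against a normal-cell reference.

    Expression is log-normalized (unless already) and rescaled to log2
    units so profile values read as approximate log2 copy ratios, then
    centered by the reference cells' per-gene mean, clamped to ±clamp,
    and averaged over k consecutive genes in genomic order within each
    chromosome.
    """
    if k % 2 == 0:
        raise ValueError("window k must be odd")
    ref = pd.Index(reference_cells)
    if len(ref) == 0:
        raise ValueError("reference cell set is empty")
    missing = ref.difference(expr.index)
    if len(missing):
        raise ValueError(f"{len(missing)} reference cells absent from the matrix")

    ln = expr if is_lognorm else lognorm_cp10k(expr) / np.log(2.0)
    ann = annotation.reindex(ln.columns).dropna(subset=["chrom", "start"])
    n_dropped = ln.shape[1] - ann.shape[0]
    if n_dropped:
        logger.info("dropping %d genes without genomic annotation", n_dropped)
    ann = ann[~ann["chrom"].astype(str).isin(exclude_chroms)]
    sizes = ann.groupby("chrom")["chrom"].transform("size")
    small = ann.loc[sizes < 3, "chrom"].unique()
    if len(small):
        warnings.warn(f"excluding chromosomes with <3 genes: {sorted(small)}")
        ann = ann[sizes >= 3]
    ordered = order_genes(ann)
    if len(ordered) == 0:
        raise ValueError("no annotated genes left for CNV inference")

    mat = ln[ordered].to_numpy(dtype=float)
    ref_pos = ln.index.get_indexer(ref)
    centered = mat - mat[ref_pos].mean(axis=0)
    centered = np.clip(centered, -clamp, clamp)

    chrom_of = ann.loc[ordered, "chrom"].to_numpy()
    smoothed = np.empty_like(centered)
    start = 0
    while start < len(ordered):
        stop = start
        while stop < len(ordered) and chrom_of[stop] == chrom_of[start]:
            stop += 1
        smoothed[:, start:stop] = _moving_average_shrink(centered[:, start:stop], k)
        start = stop
    values = pd.DataFrame(smoothed, index=ln.index, columns=ordered)
    return CnvProfile(values=values, window=k, reference_cells=ref)


def cnv_burden(profile: CnvProfile) -> pd.Series:
    """Per-cell CNV burden: mean of squared smoothed values."""
    v = profile.values.to_numpy()
    return pd.Series((v * v).mean(axis=1), index=profile.values.index, name="cnv_score")


def _two_means_threshold(x: np.ndarray) -> float:
    """Exact 1-D two-means: scan every split of the sorted values and
    return the midpoint of the two cluster means at the optimum."""
    xs = np.sort(x.astype(float))
    n = xs.size
    if xs[0] == xs[-1]:
        raise ValueError(
            "score has zero variance; two-means split undefined "
            "(consider method='quantile:q')"
        )
    cs = np.concatenate([[0.0], np.cumsum(xs)])
    css = np.concatenate([[0.0], np.cumsum(xs * xs)])
    m = np.arange(1, n)  # split: first m points vs rest
    mean1 = cs[m] / m
    mean2 = (cs[n] - cs[m]) / (n - m)
    ss = (css[m] - cs[m] ** 2 / m) + (css[n] - css[m] - (cs[n] - cs[m]) ** 2 / (n - m))
    best = int(np.argmin(ss))
    return float((mean1[best] + mean2[best]) / 2.0)


def call_malignant(
    cnv_score: pd.Series,
    marker_score: pd.Series,
    *,
    method: str = "kmeans2",
) -> MalignantCall:
    """Dual-criterion malignant call: high CNV burden AND high marker score.

    Each score is split into low/high — by exact 1-D two-means
    (``method="kmeans2"``) or at a quantile (``method="quantile:0.8"``) —
    and a cell is malignant iff it is high on both.
    """
    if not cnv_score.index.equals(marker_score.index):
        raise ValueError("cnv_score and marker_score are not aligned on the same cells")

    def threshold(x: pd.Series) -> float:
        arr = x.to_numpy(dtype=float)
        if method == "kmeans2":
            return _two_means_threshold(arr)
        if method.startswith("quantile:"):
            q = float(method.split(":", 1)[1])
            if not 0.0 < q < 1.0:
                raise ValueError("quantile must lie in (0, 1)")
            return float(np.quantile(arr, q))
        raise ValueError(f"unknown method {method!r}")

    t_cnv = threshold(cnv_score)
    t_sig = threshold(marker_score)
    call = (cnv_score >= t_cnv) & (marker_score >= t_sig)
    return MalignantCall(
        is_malignant=call.rename("is_malignant"),
        cnv_threshold=t_cnv,
        score_threshold=t_sig,
        method=method,
    )


def annotate_minor_types(
    expr: pd.DataFrame,
    marker_sets: dict[str, SignatureSet],
    cluster_labels: pd.Series,
) -> pd.Series:
    """Label each cluster by the marker set with the highest mean score.

    Exact ties go to the lexicographically first set name, with a warning.
    """
    if not marker_sets:
        raise ValueError("no marker sets given")
    labels = cluster_labels.reindex(expr.index)
    if labels.isna().any():
        raise ValueError("cluster labels missing for some cells")
    ranks = rank_within_cell(expr)
    scores = pd.DataFrame(
        {
            name: ucell_score(expr, sig, precomputed_ranks=ranks)
            for name, sig in marker_sets.items()
        }
    )
    cluster_means = scores.groupby(labels).mean()
    declared = pd.Index(pd.unique(cluster_labels.dropna()))
    empty = declared.difference(cluster_means.index)
    if cluster_means.empty or len(empty):
        raise ValueError(f"empty cluster(s): {list(empty)}")
    ordered_cols = sorted(cluster_means.columns)
    cm = cluster_means[ordered_cols]
    best = cm.idxmax(axis=1)
    tie = (cm.eq(cm.max(axis=1), axis=0).sum(axis=1) > 1)
    if tie.any():
        warnings.warn(
            f"score ties in clusters {list(cm.index[tie])}; "
            "using lexicographically first type"
        )
    return best.rename("minor_type")
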