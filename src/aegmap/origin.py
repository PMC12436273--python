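"""Cell-of-origin typing by correlation with reference malignant centroids.

EAC and GAC similarity scores are genome-wide Pearson correlations
between a malignant cell's (or bulk sample's) log-normalized profile and
the mean profile of reference malignant cells from esophageal or gastric
adenocarcinoma. Together with the activation score of bulk-derived AEG
tumor markers, the three scores — brought onto a common scale by
z-scaling across clusters or samples — assign each unit the origin with
the largest scaled score: AEG-like (esophagogastric junction itself),
EAC-like or GAC-like.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import lognorm_cp10k
from .signatures import SignatureSet, ucell_score

logger = logging.getLogger(__name__)

MIN_COMMON_GENES = 200

LABELS = {"EAC": "EAC-like", "GAC": "GAC-like", "AEG": "AEG-like"}


@dataclass
class ReferenceCentroids:
    """Per-class mean log-normalized expression over retained reference cells."""

    centroids: pd.DataFrame  # genes x classes
    kept_sites: dict[str, list[str]]
    n_cells: dict[str, int]


def build_reference_centroids(
    ref_sets: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    site_keep_lists: dict[str, list[str] | tuple[str, ...]],
    *,
    is_lognorm: bool = False,
) -> ReferenceCentroids:
    """Filter reference cells to malignant + kept sites and average them.

    ``ref_sets`` maps class name to (counts cells x genes, metadata with
    ``site`` and ``is_malignant`` columns). The gene axis of the result
    is the intersection over all classes.
    """
    if not ref_sets:
        raise ValueError("no reference sets given")
    common: pd.Index | None = None
    for cls, (counts, _) in ref_sets.items():
        common = counts.columns if common is None else common.intersection(counts.columns)
    if len(common) < MIN_COMMON_GENES:
        raise ValueError(
            f"only {len(common)} genes shared across references "
            f"(<{MIN_COMMON_GENES}); correlation would be unstable"
        )

    cols, n_cells, kept_sites = {}, {}, {}
    for cls, (counts, meta) in ref_sets.items():
        keep_sites = list(site_keep_lists.get(cls, meta["site"].unique()))
        keep = meta["is_malignant"].astype(bool) & meta["site"].isin(keep_sites)
        if keep.sum() == 0:
            raise ValueError(
                f"reference class {cls!r} empty after site/malignancy filtering"
            )
        sub = counts.loc[keep.to_numpy(), common]
        ln = sub if is_lognorm else lognorm_cp10k(sub)
        cols[cls] = ln.mean(axis=0)
        n_cells[cls] = int(keep.sum())
        kept_sites[cls] = keep_sites
        logger.info("reference %s: %d malignant cells from sites %s", cls, n_cells[cls], keep_sites)
    centroids = pd.DataFrame(cols)
    centroids.index.name = "gene_id"
    return ReferenceCentroids(centroids=centroids, kept_sites=kept_sites, n_cells=n_cells)


def _pearson_vs_centroids(mat: np.ndarray, cent: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of mat (units x genes) against each
    centroid column (genes x classes)."""
    xm = mat - mat.mean(axis=1, keepdims=True)
    cm = cent - cent.mean(axis=0, keepdims=True)
    xs = np.sqrt((xm * xm).sum(axis=1))
    csn = np.sqrt((cm * cm).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xm @ cm) / np.outer(xs, csn)
    return r


def similarity_scores(
    query_expr: pd.DataFrame,
    centroids: ReferenceCentroids,
    *,
    is_lognorm: bool = False,
    method: str = "pearson",
    center_classes: bool = True,
) -> pd.DataFrame:
    """Per-cell (or per-sample) correlation with each reference centroid.

    Returns one column per reference class, e.g. EAC and GAC scores.
    With ``center_classes`` (default), query and centroids are first
    centered by the per-gene mean across the reference classes, so the
    correlation measures class-differential signal rather than the
    expression structure all profiles share (the analogue of correlating
    variance-stabilized residuals). A profile identical to a centroid
    still scores exactly 1. Zero-variance profiles get NaN with a warning.
    """
    common = query_expr.columns.intersection(centroids.centroids.index)
    if len(common) < MIN_COMMON_GENES:
        raise ValueError(
            f"only {len(common)} genes shared with the centroids (<{MIN_COMMON_GENES})"
        )
    logger.info("similarity over %d common genes", len(common))
    ln = query_expr[common] if is_lognorm else lognorm_cp10k(query_expr[common])
    mat = ln.to_numpy(dtype=float)
    cent = centroids.centroids.loc[common].to_numpy(dtype=float)
    if method == "spearman":
        mat = pd.DataFrame(mat).rank(axis=1).to_numpy()
        cent = pd.DataFrame(cent).rank(axis=0).to_numpy()
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    if center_classes and cent.shape[1] >= 2:
        class_mean = cent.mean(axis=1)
        mat = mat - class_mean[None, :]
        cent = cent - class_mean[:, None]
    r = _pearson_vs_centroids(mat, cent)
    if np.isnan(r).any():
        warnings.warn("zero-variance profiles produced missing similarity scores")
    return pd.DataFrame(r, index=query_expr.index, columns=centroids.centroids.columns)


def _zscale(df: pd.DataFrame) -> pd.DataFrame:
    if df.shape[0] < 2:
        warnings.warn("fewer than 2 units; falling back to min-max scaling")
        rng = df.max() - df.min()
        rng = rng.replace(0.0, 1.0)
        return (df - df.min()) / rng
    sd = df.std(ddof=1).replace(0.0, 1.0)
    return (df - df.mean()) / sd


def _argmax_labels(scaled: pd.DataFrame) -> pd.Series:
    cols = sorted(scaled.columns)
    sc = scaled[cols]
    best = sc.idxmax(axis=1)
    ties = sc.eq(sc.max(axis=1), axis=0).sum(axis=1) > 1
    if ties.any():
        warnings.warn(f"score ties for {list(sc.index[ties])}; lexicographic winner used")
    return best.map(LABELS).rename("label")


def assign_origin(
    cell_scores: pd.DataFrame,
    aeg_scores: pd.Series,
    cluster_labels: pd.Series,
) -> pd.DataFrame:
    """Cluster-level origin assignment from per-cell EAC/GAC/AEG scores.

    Per cluster, each score is averaged and then z-scaled across
    clusters; the label is the argmax of the scaled triplet.
    """
    labels = cluster_labels.reindex(cell_scores.index)
    if labels.isna().any():
        raise ValueError("cluster labels missing for some cells")
    table = cell_scores.copy()
    table["AEG"] = aeg_scores.reindex(cell_scores.index)
    if table.isna().any().any():
        raise ValueError("missing scores; cannot assign origin")
    means = table.groupby(labels).mean()
    scaled = _zscale(means)
    out = means.add_suffix("_score")
    out[[f"{c}_z" for c in scaled.columns]] = scaled
    out["label"] = _argmax_labels(scaled)
    out.index.name = "cluster"
    return out


def classify_cohort(
    cohort_expr: pd.DataFrame,
    centroids: ReferenceCentroids,
    aeg_signature: SignatureSet,
) -> pd.DataFrame:
    """Project the origin typing onto a bulk cohort (samples x genes, TPM-like).

    EAC/GAC scores are correlations of each sample's log2(TPM+1) profile
    with the reference centroids; the AEG score is the rank-based
    activation score of the bulk-derived markers. The per-sample triplet
    is z-scaled across samples and the argmax assigns the group.
    """
    log_expr = pd.DataFrame(
        np.log2(cohort_expr.to_numpy(dtype=float) + 1.0),
        index=cohort_expr.index,
        columns=cohort_expr.columns,
    )
    sim = similarity_scores(log_expr, centroids, is_lognorm=True)
    aeg = ucell_score(log_expr, aeg_signature)
    table = sim.copy()
    table["AEG"] = aeg
    if table.isna().any().any():
        bad = table.index[table.isna().any(axis=1)]
        warnings.warn(f"dropping {len(bad)} samples with missing scores")
        table = table.dropna()
    scaled = _zscale(table)
    out = table.add_suffix("_score")
    out[[f"{c}_z" for c in scaled.columns]] = scaled
    out["label"] = _argmax_labels(scaled)
    out.index.name = "sample"
    return out
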