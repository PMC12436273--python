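"""Reference-based spot deconvolution and spot annotation.

Each Visium-scale spot mixes several cells, so its expression profile is
decomposed against a cell-type signature matrix (marker-gene centroids
from annotated single-cell data) by non-negative least squares; the
coefficients, renormalized to sum to one, are the spot's cell-type
proportions, and the spot is annotated with the largest one. Group-level
fraction differences are compared with a two-sided Mann-Whitney test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import mannwhitneyu

from ._utils import lognorm_cp10k

MIN_MARKERS_PER_TYPE = 5


@dataclass
class SignatureMatrix:
    """Cell types x marker genes centroid matrix (log-normalized)."""

    centroids: pd.DataFrame
    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        for t, mk in self.markers.items():
            if len(mk) < MIN_MARKERS_PER_TYPE:
                raise ValueError(
                    f"cell type {t!r} has {len(mk)} markers (<{MIN_MARKERS_PER_TYPE})"
                )
        row_norm = np.abs(self.centroids.to_numpy()).sum(axis=1)
        if (row_norm == 0).any():
            raise ValueError("signature matrix contains an all-zero cell type row")


def build_signature_matrix(
    sc_expr: pd.DataFrame,
    labels: pd.Series,
    *,
    n_markers: int = 50,
    is_lognorm: bool = False,
) -> SignatureMatrix:
    """Top-fold-change marker genes and centroid values per cell type.

    Per type, genes are ranked by mean log-normalized expression in the
    type minus the maximum mean over the other types (one-vs-strongest-
    other): genes uniquely high in a type outrank genes shared by
    related types, which a pooled-rest contrast would favor. The union
    of the top ``n_markers`` per type forms the gene axis. Centroid
    values are the log of the type's mean linear (CP10k) profile — a
    pseudo-bulk centroid — because spots are linear mixtures of cells:
    averaging in log space instead would bias the fit for every mixed
    spot.
    """
    labels = labels.reindex(sc_expr.index)
    if labels.isna().any():
        raise ValueError("cell type labels missing for some cells")
    ln = sc_expr if is_lognorm else lognorm_cp10k(sc_expr)
    types = sorted(pd.unique(labels))
    counts = labels.value_counts()
    small = [t for t in types if counts[t] < 5]
    if small:
        raise ValueError(f"cell types with <5 cells: {small}")

    linear = np.expm1(ln)  # back to CP10k scale for pseudo-bulk centroids
    log_means = pd.DataFrame(
        {t: ln.loc[(labels == t).to_numpy()].mean(axis=0) for t in types}
    )
    markers: dict[str, list[str]] = {}
    centroid_rows = {}
    for t in types:
        others = [c for c in types if c != t]
        lfc = (log_means[t] - log_means[others].max(axis=1)).sort_values(
            ascending=False, kind="mergesort"
        )
        markers[t] = list(lfc.index[:n_markers])
        centroid_rows[t] = np.log1p(
            linear.loc[(labels == t).to_numpy()].mean(axis=0)
        )
    union = pd.Index(sorted({g for mk in markers.values() for g in mk}))
    centroids = pd.DataFrame(
        {t: centroid_rows[t][union] for t in types}
    ).T
    centroids.index.name = "cell_type"
    return SignatureMatrix(centroids=centroids, markers=markers)


def deconvolve_spots(
    spot_counts: pd.DataFrame,
    sig: SignatureMatrix,
    *,
    is_lognorm: bool = False,
) -> pd.DataFrame:
    """Per-spot cell-type proportions by non-negative least squares.

    The spot's log-normalized profile over the shared marker genes is
    regressed on the signature centroids with non-negativity; the
    coefficients are renormalized to sum to one. All-zero spots get
    uniform proportions with a warning.
    """
    shared = spot_counts.columns.intersection(sig.centroids.columns)
    n_types = sig.centroids.shape[0]
    if len(shared) < n_types:
        raise ValueError(
            f"only {len(shared)} marker genes shared with the spots "
            f"(< {n_types} cell types)"
        )
    ln = spot_counts if is_lognorm else lognorm_cp10k(spot_counts)
    a = sig.centroids[shared].to_numpy(dtype=float).T  # genes x types
    props = np.empty((ln.shape[0], n_types))
    zero_spots = 0
    for i, (_, row) in enumerate(ln[shared].iterrows()):
        b = row.to_numpy(dtype=float)
        if not b.any():
            props[i] = 1.0 / n_types
            zero_spots += 1
            continue
        coef, _ = nnls(a, b)
        s = coef.sum()
        props[i] = coef / s if s > 0 else 1.0 / n_types
    if zero_spots:
        warnings.warn(f"{zero_spots} all-zero spots set to uniform proportions")
    return pd.DataFrame(props, index=spot_counts.index, columns=sig.centroids.index)


def annotate_spots(props: pd.DataFrame) -> pd.Series:
    """Annotate each spot by the cell type with the biggest proportion.

    Exact ties go to the lexicographically first type name, with a warning.
    """
    cols = sorted(props.columns)
    p = props[cols]
    best = p.idxmax(axis=1)
    ties = p.eq(p.max(axis=1), axis=0).sum(axis=1) > 1
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} spots with tied proportions; lexicographic winner used"
        )
    return best.rename("spot_type")


def compare_group_fractions(
    props: pd.DataFrame, spot_groups: pd.Series
) -> pd.DataFrame:
    """Two-sided Mann-Whitney rank-sum per cell type between two spot groups."""
    groups = spot_groups.reindex(props.index)
    if groups.isna().any():
        raise ValueError("group labels missing for some spots")
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 spot groups, got {levels}")
    a_mask = (groups == levels[0]).to_numpy()
    if a_mask.sum() == 0 or (~a_mask).sum() == 0:
        raise ValueError("a spot group is empty")
    rows = {}
    for ct in props.columns:
        x = props.loc[a_mask, ct].to_numpy()
        y = props.loc[~a_mask, ct].to_numpy()
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            u, p = len(x) * len(y) / 2.0, 1.0
        else:
            u, p = mannwhitneyu(x, y, alternative="two-sided")
        rows[ct] = {"U": float(u), "p_value": float(p)}
    out = pd.DataFrame(rows).T
    out.index.name = "cell_type"
    out.attrs["groups"] = levels
    return out
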