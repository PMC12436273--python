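"""Rank-based gene-signature scoring and marker-set derivation.

The activation score of a gene set in a cell is computed from within-cell
expression ranks through a Mann-Whitney U statistic: genes are ranked
descending by expression, ranks of signature genes are capped at
``r_max + 1``, and the score is ``1 - U / (n_s * r_max)`` where
``U = sum(capped ranks) - n_s (n_s + 1) / 2``. Because only ranks enter,
the score is invariant under any strictly increasing transform of a
cell's expression vector, so raw counts and log-normalized values give
identical scores.

A signed signature (positive and negative marker sets) is scored as
``score(positive) - score(negative)``, floored at zero by default so the
result stays an activation score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel

from ._utils import benjamini_hochberg

logger = logging.getLogger(__name__)

DEFAULT_R_MAX = 1500


@dataclass
class SignatureSet:
    """Positive (and optionally negative) marker gene lists.

    r_max caps within-cell ranks: genes ranked beyond it, or absent from
    the matrix, contribute rank ``r_max + 1``.
    """

    positive: list[str]
    negative: list[str] = field(default_factory=list)
    r_max: int = DEFAULT_R_MAX
    name: str = "signature"

    def __post_init__(self) -> None:
        if not self.positive:
            raise ValueError("signature needs at least one positive gene")
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(
                f"genes in both positive and negative sets: {sorted(overlap)[:5]}"
            )
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")


def rank_within_cell(expr: pd.DataFrame) -> pd.DataFrame:
    """Within-cell descending ranks, average ranks on ties.

    The top-expressed gene of a cell gets rank 1. Works on raw counts or
    any monotone transform of them.
    """
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError("cannot rank an empty expression matrix")
    return expr.rank(axis=1, ascending=False, method="average")


def _positive_score(
    ranks_sub: np.ndarray, n_found: int, n_missing: int, r_max: int
) -> np.ndarray:
    """Score from the ranks of present signature genes plus missing ones."""
    n_s = n_found + n_missing
    capped = np.minimum(ranks_sub, r_max + 1)
    u = capped.sum(axis=1) + n_missing * (r_max + 1) - n_s * (n_s + 1) / 2.0
    return 1.0 - u / (n_s * r_max)


def ucell_score(
    expr: pd.DataFrame,
    sig: SignatureSet,
    *,
    floor_at_zero: bool = True,
    precomputed_ranks: pd.DataFrame | None = None,
) -> pd.Series:
    """Signature activation score per cell (or per bulk sample).

    Missing positive genes are tolerated (they contribute the capped
    rank) unless *all* positive genes are absent. The signed score is
    ``positive - negative``, floored at 0 unless ``floor_at_zero=False``.
    """
    if sig.r_max < len(sig.positive) or (
        sig.negative and sig.r_max < len(sig.negative)
    ):
        raise ValueError(
            f"r_max={sig.r_max} smaller than the signature size"
        )
    ranks = precomputed_ranks if precomputed_ranks is not None else rank_within_cell(expr)

    pos_found = [g for g in sig.positive if g in ranks.columns]
    if not pos_found:
        raise ValueError(
            f"none of the positive genes present in the matrix: "
            f"{sig.positive[:5]}{'...' if len(sig.positive) > 5 else ''}"
        )
    n_missing = len(sig.positive) - len(pos_found)
    if n_missing:
        logger.warning(
            "%d/%d positive genes of %s absent; they take rank r_max+1",
            n_missing, len(sig.positive), sig.name,
        )
    score = _positive_score(
        ranks[pos_found].to_numpy(), len(pos_found), n_missing, sig.r_max
    )

    if sig.negative:
        neg_found = [g for g in sig.negative if g in ranks.columns]
        if neg_found:
            score_neg = _positive_score(
                ranks[neg_found].to_numpy(),
                len(neg_found),
                len(sig.negative) - len(neg_found),
                sig.r_max,
            )
            score = score - score_neg
            if floor_at_zero:
                score = np.maximum(score, 0.0)
        else:
            warnings.warn(
                f"all negative genes of {sig.name} absent; scoring positive set only"
            )
    return pd.Series(score, index=expr.index, name=sig.name)


def derive_signature_from_bulk(
    tumor: pd.DataFrame,
    nat: pd.DataFrame,
    *,
    fc_min: float = 1.2,
    top_n: int = 50,
    alpha: float = 0.05,
    log_input: bool = False,
    r_max: int = DEFAULT_R_MAX,
) -> SignatureSet:
    """Derive positive/negative marker sets from paired tumor/NAT bulk.

    Per gene: paired t test on log2 values with BH adjustment; genes with
    q >= alpha or |log2FC| < fc_min are dropped; the survivors are ranked
    by log2FC and the top ``top_n`` become the positive set, the bottom
    ``top_n`` the negative set. Matrices are samples x genes, rows paired
    by position.
    """
    if tumor.shape[0] != nat.shape[0]:
        raise ValueError(
            f"unpaired inputs: {tumor.shape[0]} tumor vs {nat.shape[0]} NAT samples"
        )
    if tumor.shape[0] < 3:
        raise ValueError("need at least 3 sample pairs")
    if not tumor.columns.equals(nat.columns):
        common = tumor.columns.intersection(nat.columns)
        if len(common) == 0:
            raise ValueError("tumor and NAT share no genes")
        tumor, nat = tumor[common], nat[common]

    t_log = tumor.to_numpy(dtype=float)
    n_log = nat.to_numpy(dtype=float)
    if not log_input:
        t_log = np.log2(t_log + 1.0)
        n_log = np.log2(n_log + 1.0)

    log2fc = (t_log - n_log).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = ttest_rel(t_log, n_log, axis=0)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    qvals = benjamini_hochberg(pvals)

    keep = (qvals < alpha) & (np.abs(log2fc) >= fc_min)
    if not keep.any():
        raise ValueError(
            f"no gene passes q<{alpha} and |log2FC|>={fc_min}; "
            "tumor and NAT may be identical"
        )
    genes = tumor.columns[keep]
    fc = log2fc[keep]
    order = np.argsort(-fc, kind="stable")
    up = [g for g, f in zip(genes[order], fc[order]) if f > 0][:top_n]
    down_order = order[::-1]
    down = [g for g, f in zip(genes[down_order], fc[down_order]) if f < 0][:top_n]
    if len(up) < top_n or len(down) < top_n:
        logger.warning(
            "fewer than %d genes survive on one side (up=%d, down=%d); using all",
            top_n, len(up), len(down),
        )
    if not up:
        raise ValueError("no up-regulated gene survives the filters")
    return SignatureSet(positive=up, negative=down, r_max=r_max, name="AEG")


def score_gep(
    expr: pd.DataFrame, gep_sets: dict[str, SignatureSet] | list[SignatureSet]
) -> pd.DataFrame:
    """Score several gene expression programs; one column per program.

    Ranks are computed once and shared across programs.
    """
    if isinstance(gep_sets, list):
        gep_sets = {s.name: s for s in gep_sets}
    if not gep_sets:
        raise ValueError("no GEP sets given")
    ranks = rank_within_cell(expr)
    cols = {
        name: ucell_score(expr, sig, precomputed_ranks=ranks)
        for name, sig in gep_sets.items()
    }
    return pd.DataFrame(cols, index=expr.index)
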