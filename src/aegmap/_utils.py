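"""Shared helpers: normalization, genomic ordering, seed fan-out."""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

# Fixed per-generator spawn keys. A single user-facing seed fans out through
# numpy SeedSequence spawn keys, so adding a generator never perturbs the
# streams of existing ones.
SEED_OFFSETS = {
    "scrna": 0,
    "reference": 1,
    "bulk": 2,
    "cohort": 3,
    "metabolome": 4,
    "flux": 5,
    "spots": 6,
    "archetypes": 7,
}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-stream generator derived from one global seed."""
    if stream not in SEED_OFFSETS:
        raise KeyError(f"unknown random stream {stream!r}")
    ss = np.random.SeedSequence(seed, spawn_key=(SEED_OFFSETS[stream],))
    return np.random.default_rng(ss)


def lognorm_cp10k(counts: pd.DataFrame) -> pd.DataFrame:
    """log1p of counts-per-10k, the pipeline's working normalization.

    Rows are cells/samples, columns genes. Cells with zero total counts are
    left as all-zero rows.
    """
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    totals[totals == 0] = 1.0
    scaled = counts.to_numpy(dtype=float) / totals[:, None] * 1e4
    return pd.DataFrame(np.log1p(scaled), index=counts.index, columns=counts.columns)


_CHUNK = re.compile(r"(\d+)")


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key putting chr2 before chr10 and letters after numbers."""
    parts = _CHUNK.split(str(chrom))
    return tuple(int(p) if p.isdigit() else p for p in parts)


def order_genes(annotation: pd.DataFrame) -> pd.Index:
    """Genomic order: (naturally sorted chromosome, start)."""
    ann = annotation.copy()
    ann["_key"] = ann["chrom"].map(natural_chrom_key)
    ann = ann.sort_values(["_key", "start"], kind="mergesort")
    return ann.index


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]
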