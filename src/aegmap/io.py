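"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel either as a 10x-style MTX triplet
(matrix.mtx[.gz] + features.tsv[.gz] + barcodes.tsv[.gz], genes x cells
on disk, cells x genes in memory) or as dense CSV/TSV with labeled axes.
Signatures are two-column TSV (gene, sign) or GMT; survival tables are
CSV with sample, time, event and optional group/score columns.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .signatures import DEFAULT_R_MAX, SignatureSet

_GENEY_NAMES = {"gene", "gene_id", "genes", "symbol", "feature", "features"}


def _maybe_gz(path: Path) -> Path | None:
    for cand in (path, path.with_suffix(path.suffix + ".gz")):
        if cand.exists():
            return cand
    return None


def _read_tsv_column(path: Path, col: int = 0) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[col] for line in fh if line.strip()]


def read_matrix(path: str | Path, *, transpose: bool | None = None) -> pd.DataFrame:
    """Read an expression matrix as cells/samples x genes.

    ``path`` may be a directory holding a 10x MTX triplet, a ``.mtx``
    file with sidecars, or a dense CSV/TSV with a header row and label
    column. Orientation of dense files is auto-detected from the index
    name (gene-like names imply genes-as-rows) unless ``transpose`` is
    given explicitly.
    """
    path = Path(path)
    if path.is_dir() or path.name.endswith((".mtx", ".mtx.gz")):
        d = path if path.is_dir() else path.parent
        mtx = _maybe_gz(d / "matrix.mtx")
        feats = _maybe_gz(d / "features.tsv") or _maybe_gz(d / "genes.tsv")
        bcs = _maybe_gz(d / "barcodes.tsv")
        if mtx is None or feats is None or bcs is None:
            raise FileNotFoundError(
                f"MTX triplet incomplete under {d}: need matrix.mtx, "
                "features.tsv (or genes.tsv) and barcodes.tsv"
            )
        mat = sparse.csr_matrix(spio.mmread(str(mtx)))
        genes = _read_tsv_column(feats)
        cells = _read_tsv_column(bcs)
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix is {mat.shape[0]}x{mat.shape[1]} but sidecars list "
                f"{len(genes)} features and {len(cells)} barcodes"
            )
        return pd.DataFrame(
            mat.T.toarray(),
            index=pd.Index(cells, name="cell"),
            columns=pd.Index(genes, name="gene_id"),
        )

    sep = "\t" if path.name.endswith((".tsv", ".tsv.gz", ".txt", ".txt.gz")) else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # surface the offending file, not just pandas' view
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"malformed matrix file {path}: no data columns in header")
    if transpose is None:
        idx_name = (df.index.name or "").strip().lower()
        transpose = idx_name in _GENEY_NAMES
    return df.T if transpose else df


def write_matrix_10x(counts: pd.DataFrame, outdir: str | Path) -> None:
    """Write cells x genes counts as a plain-text 10x MTX triplet."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csc_matrix(counts.to_numpy().T)  # genes x cells on disk
    spio.mmwrite(str(outdir / "matrix.mtx"), mat)
    (outdir / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in counts.columns)
    )
    (outdir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in counts.index))


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation {path} lacks columns {sorted(missing)}")
    ann["start"] = ann["start"].astype(int)
    return ann.set_index("gene_id")


def write_gene_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.reset_index().to_csv(path, sep="\t", index=False)


def read_signature_tsv(path: str | Path, *, r_max: int = DEFAULT_R_MAX) -> SignatureSet:
    """Two-column TSV: gene, sign in {+1, -1}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "sign"], comment="#")
    signs = df["sign"].astype(int)
    if not signs.isin((1, -1)).all():
        raise ValueError(f"signature {path}: sign column must be +1 or -1")
    return SignatureSet(
        positive=list(df.loc[signs == 1, "gene"]),
        negative=list(df.loc[signs == -1, "gene"]),
        r_max=r_max,
        name=Path(path).stem,
    )


def write_signature_tsv(sig: SignatureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sig.positive:
            fh.write(f"{g}\t1\n")
        for g in sig.negative:
            fh.write(f"{g}\t-1\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if not line.strip():
                    continue
                raise ValueError(f"{path}:{ln}: GMT line needs name, description, members")
            out[parts[0]] = [p for p in parts[2:] if p]
    return out


def write_gmt(pathways: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in pathways.items():
            fh.write("\t".join([name, name] + list(members)) + "\n")


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table {path} lacks columns {sorted(missing)}")
    df = df.set_index("sample")
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    if not df["event"].isin((0, 1)).all():
        raise ValueError("event column must be 0/1")
    return df


def write_survival_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.reset_index().to_csv(path, index=False)
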