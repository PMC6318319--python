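"""Readers and writers for the pipeline's plain-text formats.

Dense matrices travel as TSV (genes x cells, first column = gene id);
sparse matrices as MatrixMarket MTX with ``genes.tsv`` / ``cells.tsv``
sidecars.  Gene lists are one symbol per line; gene sets are GMT
(tab-separated: name, description, members).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_matrix",
    "write_matrix_tsv",
    "write_matrix_mtx",
    "read_gene_lengths",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
]


def read_matrix(path) -> pd.DataFrame:
    """Read a gene x cell matrix from TSV, or from a directory holding
    ``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv``."""
    path = Path(path)
    if path.is_dir():
        mtx = spio.mmread(path / "matrix.mtx")
        genes = pd.read_csv(path / "genes.tsv", header=None, sep="\t")[0]
        cells = pd.read_csv(path / "cells.tsv", header=None, sep="\t")[0]
        dense = mtx.toarray() if sparse.issparse(mtx) else mtx
        return pd.DataFrame(dense, index=genes, columns=cells)
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def write_matrix_mtx(df: pd.DataFrame, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"), sparse.csr_matrix(df.values))
    pd.Series(df.index).to_csv(outdir / "genes.tsv", index=False, header=False)
    pd.Series(df.columns).to_csv(outdir / "cells.tsv", index=False, header=False)


def read_gene_lengths(path, gene_col: str = "gene_id", length_col: str = "cds_length_bp") -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if gene_col not in df.columns or length_col not in df.columns:
        raise ValueError(f"annotation must have columns {gene_col!r} and {length_col!r}")
    return df.set_index(gene_col)[length_col]


def read_gene_list(path) -> list:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_gmt(path) -> dict:
    """GMT gene-set file -> {set_name: set(members)} (descriptions dropped)."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, members): {line[:60]!r}")
        name, _desc, *members = parts
        sets[name] = {m for m in members if m}
    return sets
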