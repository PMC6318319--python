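"""TPM normalization of CDS-restricted counts and the log2(TPM+1) transform.

TPM per cell: each gene's count is divided by its CDS length in kilobases
to give a rate, and rates are rescaled to sum to one million.  Counting is
CDS-restricted upstream, so the length used here is the CDS length, not
the full transcript length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "tpm_from_counts", "log_transform"]


@dataclass
class ExpressionMatrix:
    """Gene x cell TPM and log2(TPM+1) matrices with cell annotations."""

    tpm: pd.DataFrame
    log2_tpm1: pd.DataFrame
    patient_of_cell: pd.Series | None = field(default=None)

    @property
    def gene_ids(self) -> pd.Index:
        return self.tpm.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.tpm.columns

    @property
    def n_genes(self) -> int:
        return self.tpm.shape[0]

    @property
    def n_cells(self) -> int:
        return self.tpm.shape[1]


def tpm_from_counts(
    counts: pd.DataFrame,
    cds_lengths: pd.Series,
    patient_of_cell: pd.Series | None = None,
) -> ExpressionMatrix:
    """Convert a gene x cell count matrix to TPM and log2(TPM+1).

    Every gene of ``counts`` must appear in ``cds_lengths`` with a positive
    length (bp).  All-zero cells yield all-zero columns and a warning;
    dropping them is the QC stage's job, not this one's.
    """
    if (counts.values < 0).any():
        raise ValueError("count matrix contains negative entries")
    missing = counts.index.difference(cds_lengths.index)
    if len(missing) > 0:
        raise KeyError(f"gene(s) missing from annotation: {list(missing[:5])}")
    lengths = cds_lengths.reindex(counts.index).astype(float)
    bad = lengths <= 0
    if bad.any():
        raise ValueError(
            f"non-positive CDS length for gene(s): {list(lengths.index[bad][:5])}"
        )

    rate = counts.div(lengths / 1000.0, axis=0)
    colsum = rate.sum(axis=0)
    zero_cells = colsum == 0
    if zero_cells.any():
        warnings.warn(
            f"{int(zero_cells.sum())} all-zero cell(s) retained as zero columns: "
            f"{list(colsum.index[zero_cells][:5])}",
            stacklevel=2,
        )
    safe = colsum.replace(0, np.nan)
    tpm = rate.div(safe, axis=1).fillna(0.0) * 1e6
    return ExpressionMatrix(
        tpm=tpm, log2_tpm1=log_transform(tpm), patient_of_cell=patient_of_cell
    )


def log_transform(tpm: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Elementwise log2(x + 1); rejects negative input."""
    values = tpm.values if isinstance(tpm, pd.DataFrame) else np.asarray(tpm)
    if (values < 0).any():
        raise ValueError("log transform requires non-negative input")
    out = np.log2(values + 1.0)
    if isinstance(tpm, pd.DataFrame):
        return pd.DataFrame(out, index=tpm.index, columns=tpm.columns)
    return out
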