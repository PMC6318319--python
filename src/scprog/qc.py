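"""Per-cell sequencing-quality filtering.

A cell is low quality iff any metric falls strictly below its threshold
(values exactly at a threshold pass).  The three metrics are the total
read count, the percentage of mapped reads, and the median transcript
integrity number over non-zero transcripts (consumed precomputed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["QCThresholds", "QCResult", "filter_cells", "read_qc_table"]

METRIC_COLUMNS = ("total_reads", "pct_mapped", "median_tin")


@dataclass(frozen=True)
class QCThresholds:
    """Minimum acceptable values; a cell fails only when strictly below."""

    min_total_reads: float = 1_000_000
    min_pct_mapped: float = 55.0
    min_median_tin: float = 45.0

    def __post_init__(self) -> None:
        if min(self.min_total_reads, self.min_pct_mapped, self.min_median_tin) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class QCResult:
    pass_ids: list = field(default_factory=list)
    fail_records: dict = field(default_factory=dict)  # cell_id -> [criterion, ...]

    @property
    def n_pass(self) -> int:
        return len(self.pass_ids)

    @property
    def n_fail(self) -> int:
        return len(self.fail_records)


def filter_cells(
    records: pd.DataFrame, thresholds: QCThresholds | None = None
) -> QCResult:
    """Partition cells into pass/fail with per-criterion failure reasons.

    ``records`` needs columns ``cell_id``, ``total_reads``, ``pct_mapped``
    and ``median_tin``.  A missing (NaN) metric raises, naming the cell
    and field.
    """
    thresholds = thresholds or QCThresholds()
    required = ("cell_id",) + METRIC_COLUMNS
    missing_cols = [c for c in required if c not in records.columns]
    if missing_cols:
        raise ValueError(f"QC table missing columns: {missing_cols}")
    if records["cell_id"].duplicated().any():
        dup = records.loc[records["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell_id in QC table: {dup!r}")

    for col in METRIC_COLUMNS:
        na = records[col].isna()
        if na.any():
            cell = records.loc[na, "cell_id"].iloc[0]
            raise ValueError(f"cell {cell!r} has missing value for {col!r}")

    limits = {
        "total_reads": thresholds.min_total_reads,
        "pct_mapped": thresholds.min_pct_mapped,
        "median_tin": thresholds.min_median_tin,
    }
    result = QCResult()
    for _, row in records.iterrows():
        reasons = [col for col, lim in limits.items() if row[col] < lim]
        if reasons:
            result.fail_records[row["cell_id"]] = reasons
        else:
            result.pass_ids.append(row["cell_id"])
    return result


def read_qc_table(
    path,
    sep: str | None = None,
    column_map: dict | None = None,
) -> pd.DataFrame:
    """Read a QC metrics CSV/TSV, optionally renaming caller columns.

    ``column_map`` maps file header names to the canonical names
    (``cell_id``, ``patient_id``, ``total_reads``, ``pct_mapped``,
    ``median_tin``).
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if column_map:
        df = df.rename(columns=column_map)
    return df
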