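"""Per-gene statistics and variable-gene selection.

Two filters are provided and kept independent:

- the coefficient-of-variation selection (``cv >= 0.5`` and mean
  ``log2(TPM+1) >= 3``, both inclusive), with housekeeping-gene
  accounting; and
- the embedding prefilter (expressed in *more than* ``min_cells`` cells,
  mean log and SD both strictly above 1).

CV is computed on the log2(TPM+1) scale by default (``cv_scale="log"``);
a linear-TPM alternative is available.  SD uses the sample convention
(``ddof=1``) unless configured otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "GeneSelection",
    "compute_gene_stats",
    "select_variable_genes",
    "seurat_prefilter",
]


@dataclass
class GeneSelection:
    selected_ids: frozenset
    criteria: dict = field(default_factory=dict)
    hk_fraction_selected: float = 0.0
    hk_fraction_stable: float = 0.0

    @property
    def n_selected(self) -> int:
        return len(self.selected_ids)


def compute_gene_stats(
    expr: ExpressionMatrix,
    hk_list: set | None = None,
    ddof: int = 1,
    cv_scale: str = "log",
) -> pd.DataFrame:
    """One row per gene: mean_log, sd_log, cv, n_cells_expressed, is_housekeeping.

    ``cv`` is ``sd/mean`` on the scale chosen by ``cv_scale`` ("log" uses
    log2(TPM+1); "linear" uses TPM); a zero mean yields ``cv = 0`` so that
    any positive CV threshold excludes the gene.
    """
    if expr.n_genes == 0 or expr.n_cells == 0:
        raise ValueError("expression matrix is empty")
    if cv_scale not in ("log", "linear"):
        raise ValueError("cv_scale must be 'log' or 'linear'")
    hk_list = hk_list or set()

    log_vals = expr.log2_tpm1.values
    mean_log = log_vals.mean(axis=1)
    sd_log = log_vals.std(axis=1, ddof=ddof) if expr.n_cells > ddof else np.zeros_like(mean_log)

    if cv_scale == "log":
        cv_mean, cv_sd = mean_log, sd_log
    else:
        lin = expr.tpm.values
        cv_mean = lin.mean(axis=1)
        cv_sd = lin.std(axis=1, ddof=ddof) if expr.n_cells > ddof else np.zeros_like(cv_mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(cv_mean > 0, cv_sd / np.where(cv_mean > 0, cv_mean, 1.0), 0.0)

    return pd.DataFrame(
        {
            "mean_log": mean_log,
            "sd_log": sd_log,
            "cv": cv,
            "n_cells_expressed": (expr.tpm.values > 0).sum(axis=1),
            "is_housekeeping": [g in hk_list for g in expr.gene_ids],
        },
        index=expr.gene_ids.rename("gene_id"),
    )


def select_variable_genes(
    stats: pd.DataFrame, cv_min: float = 0.5, mean_log_min: float = 3.0
) -> GeneSelection:
    """Select genes with ``cv >= cv_min`` and ``mean_log >= mean_log_min``.

    Both comparisons are inclusive.  The result also reports the
    housekeeping fraction among selected genes and, for contrast, among
    the "stable" genes (high mean but ``cv <= cv_min``); on data with
    low-variability housekeeping genes the former should be depleted
    relative to the latter.
    """
    selected = stats.index[(stats["cv"] >= cv_min) & (stats["mean_log"] >= mean_log_min)]
    stable = stats.index[(stats["cv"] <= cv_min) & (stats["mean_log"] >= mean_log_min)]

    def _hk_frac(ids) -> float:
        if len(ids) == 0:
            return 0.0
        return float(stats.loc[ids, "is_housekeeping"].mean())

    return GeneSelection(
        selected_ids=frozenset(selected),
        criteria={"cv_min": cv_min, "mean_log_min": mean_log_min},
        hk_fraction_selected=_hk_frac(selected),
        hk_fraction_stable=_hk_frac(stable),
    )


def seurat_prefilter(
    expr: ExpressionMatrix,
    min_cells: int = 2,
    min_mean_log: float = 1.0,
    min_sd: float = 1.0,
    ddof: int = 1,
) -> frozenset:
    """Genes expressed in more than ``min_cells`` cells with mean log and SD
    both strictly above their minima (all three predicates strict)."""
    stats = compute_gene_stats(expr, ddof=ddof)
    keep = (
        (stats["n_cells_expressed"] > min_cells)
        & (stats["mean_log"] > min_mean_log)
        & (stats["sd_log"] > min_sd)
    )
    return frozenset(stats.index[keep])
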