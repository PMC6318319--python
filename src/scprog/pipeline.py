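"""End-to-end orchestration and the packaged cell-accounting fixture.

``run_all`` chains qc -> normalize -> select -> cluster -> signature
(-> survive when a cohort is supplied), logging every stage's parameters
and writing deterministic outputs whose checksums are part of the run
report, so identical configs reproduce identical artifacts.

``load_table1`` / ``summarize_table1`` expose the packaged per-patient
cell-accounting table (cells sequenced, cells passing QC, and the L1-L4
group counts for each of the 15 samples) and its column totals.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, expression, features, qc, signature, survival, synthetic
from . import io as sio

logger = logging.getLogger("scprog")

__all__ = ["PipelineConfig", "load_table1", "summarize_table1", "run_all"]

GROUP_COLUMNS = ("L1", "L2", "L3", "L4")


# ---------------------------------------------------------------------------
# packaged fixture
# ---------------------------------------------------------------------------

def load_table1() -> pd.DataFrame:
    """Load the packaged per-patient cell-accounting table."""
    with resources.files("scprog.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def summarize_table1(fixture: pd.DataFrame | None = None) -> dict:
    """Column totals and rounded percentages of the cell-accounting table.

    Validates each row (group counts sum to the passing count, passing
    count does not exceed the sequenced count) and returns totals for
    sequenced/passed cells, the overall pass percentage, and per-group
    counts and percentages (percent of passing cells, rounded to the
    nearest integer)."""
    df = load_table1() if fixture is None else fixture
    if len(df) == 0:
        return {
            "n_sequenced": 0,
            "n_passed": 0,
            "pass_pct": 0,
            "group_counts": {g: 0 for g in GROUP_COLUMNS},
            "group_pct": {g: 0 for g in GROUP_COLUMNS},
        }
    for _, row in df.iterrows():
        group_sum = int(sum(row[g] for g in GROUP_COLUMNS))
        if group_sum != int(row["n_passed"]):
            raise ValueError(
                f"row {row['sample_id']!r}: group counts sum to {group_sum}, "
                f"expected n_passed = {int(row['n_passed'])}"
            )
        if int(row["n_passed"]) > int(row["n_sequenced"]):
            raise ValueError(f"row {row['sample_id']!r}: n_passed exceeds n_sequenced")

    n_seq = int(df["n_sequenced"].sum())
    n_pass = int(df["n_passed"].sum())
    group_counts = {g: int(df[g].sum()) for g in GROUP_COLUMNS}
    return {
        "n_sequenced": n_seq,
        "n_passed": n_pass,
        "pass_pct": int(round(100.0 * n_pass / n_seq)) if n_seq else 0,
        "group_counts": group_counts,
        "group_pct": {
            g: int(round(100.0 * c / n_pass)) if n_pass else 0
            for g, c in group_counts.items()
        },
    }


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All stage inputs and thresholds for :func:`run_all`.

    When ``counts_path`` is None a synthetic dataset is generated from
    ``sim`` (making the pipeline runnable without external data) and
    planted-truth recovery metrics are added to the report."""

    # inputs (None -> simulate)
    counts_path: str | None = None
    lengths_path: str | None = None
    qc_path: str | None = None
    housekeeping_path: str | None = None
    gmt_path: str | None = None
    cohort_expression_path: str | None = None
    cohort_probe_map_path: str | None = None
    cohort_survival_path: str | None = None

    # stage thresholds
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    cv_min: float = 0.5
    mean_log_min: float = 3.0
    cv_scale: str = "log"
    k: int = 4
    fc_min: float = 2.0
    p_max: float = 0.05
    kmeans_restarts: int = 25

    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)
    survival_sim: synthetic.SurvivalSimConfig | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "qc_thresholds" in raw:
            raw["qc_thresholds"] = qc.QCThresholds(**raw["qc_thresholds"])
        if "sim" in raw:
            sim = dict(raw["sim"])
            for key in ("cells_per_patient", "baseline_log2_mean_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["sim"] = synthetic.SimConfig(**sim)
        if raw.get("survival_sim") is not None:
            raw["survival_sim"] = synthetic.SurvivalSimConfig(**raw["survival_sim"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, float_format="%.10g", **kwargs)


def run_all(config: PipelineConfig, outdir) -> dict:
    """Execute every stage, write artifacts under ``outdir``, and return a
    run report with parameters, per-stage summaries, recovery metrics on
    simulated inputs, and output checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    # -- inputs --------------------------------------------------------
    truth = None
    if config.counts_path is None:
        sim_cfg = config.sim
        truth = synthetic.simulate_expression(sim_cfg)
        counts, lengths = truth.counts, truth.cds_lengths
        patient = truth.patient
        qc_table = synthetic.simulate_qc_metrics(
            counts.shape[1], 0, 0, 0, seed=config.seed
        )
        qc_table["cell_id"] = list(counts.columns)
        qc_table["patient_id"] = patient.values
        hk = set(truth.true_housekeeping_genes)
        logger.info("simulated %d genes x %d cells (seed=%d)", *counts.shape, sim_cfg.seed)
    else:
        counts = sio.read_matrix(config.counts_path)
        lengths = sio.read_gene_lengths(config.lengths_path)
        qc_table = qc.read_qc_table(config.qc_path)
        patient = pd.Series(
            qc_table.set_index("cell_id")["patient_id"], name="patient"
        ).reindex(counts.columns)
        hk = set(sio.read_gene_list(config.housekeeping_path)) if config.housekeeping_path else set()

    # -- qc ------------------------------------------------------------
    qc_result = qc.filter_cells(qc_table, config.qc_thresholds)
    kept = [c for c in counts.columns if c in set(qc_result.pass_ids)]
    counts = counts[kept]
    report["stages"]["qc"] = {
        "n_pass": qc_result.n_pass,
        "n_fail": qc_result.n_fail,
        "thresholds": asdict(config.qc_thresholds),
    }
    reasons = pd.DataFrame(
        [(c, ";".join(r)) for c, r in sorted(qc_result.fail_records.items())],
        columns=["cell_id", "failed_criteria"],
    )
    _write_csv(reasons, outdir / "qc_fail_reasons.csv", index=False)

    # -- normalize -----------------------------------------------------
    expr = expression.tpm_from_counts(counts, lengths, patient_of_cell=patient[kept])
    _write_csv(expr.log2_tpm1, outdir / "log2_tpm1.tsv", sep="\t")
    report["stages"]["normalize"] = {"n_genes": expr.n_genes, "n_cells": expr.n_cells}

    # -- select --------------------------------------------------------
    stats = features.compute_gene_stats(expr, hk_list=hk, cv_scale=config.cv_scale)
    selection = features.select_variable_genes(
        stats, cv_min=config.cv_min, mean_log_min=config.mean_log_min
    )
    selected = sorted(selection.selected_ids)
    _write_csv(stats, outdir / "gene_stats.tsv", sep="\t")
    sio.write_gene_list(selected, outdir / "selected_genes.txt")
    report["stages"]["select"] = {
        "n_selected": selection.n_selected,
        "hk_fraction_selected": selection.hk_fraction_selected,
        "hk_fraction_stable": selection.hk_fraction_stable,
        "criteria": selection.criteria,
    }
    if not selected:
        raise RuntimeError("stage 'select' failed: no genes passed selection")

    # -- cluster -------------------------------------------------------
    sub = expr.log2_tpm1.loc[selected]
    dist = clustering.pearson_distance(sub)
    Z = clustering.ward_linkage(dist)
    labels = clustering.cut_tree(Z, config.k)
    groups = clustering.order_groups(labels, sub)
    assign = pd.DataFrame(
        {
            "cell_id": groups.label_of_cell.index,
            "patient_id": patient[groups.label_of_cell.index].values,
            "group": groups.label_of_cell.values,
        }
    )
    _write_csv(assign, outdir / "group_assignment.csv", index=False)
    (outdir / "dendrogram.nwk").write_text(
        clustering.linkage_to_newick(Z, dist.index)
    )
    _write_csv(
        pd.DataFrame(Z, columns=["left", "right", "height", "size"]),
        outdir / "merges.tsv",
        sep="\t",
    )
    report["stages"]["cluster"] = {
        "k": groups.k,
        "group_sizes": {
            lab: int((groups.label_of_cell == lab).sum()) for lab in groups.labels
        },
        "ordering_statistic": groups.ordering_statistic,
    }

    # -- signature -----------------------------------------------------
    de = signature.anova_per_gene(expr.log2_tpm1, groups)
    sig = signature.adjacent_monotone_signature(
        expr.log2_tpm1, groups, fc_min=config.fc_min, p_max=config.p_max
    )
    _write_csv(de, outdir / "de_table.tsv", sep="\t")
    sio.write_gene_list(sig.common_up, outdir / "common_up_genes.txt")
    sio.write_gene_list(sig.adjacent_monotone, outdir / "signature_genes.txt")
    report["stages"]["signature"] = {
        "n_common_up": len(sig.common_up),
        "n_adjacent_monotone": len(sig.adjacent_monotone),
        "thresholds": sig.thresholds,
    }
    if config.gmt_path:
        collection = sio.read_gmt(config.gmt_path)
        overlap = signature.geneset_overlap(
            sig.adjacent_monotone, collection, universe_size=expr.n_genes
        )
        _write_csv(overlap, outdir / "geneset_overlap.tsv", sep="\t", index=False)

    # -- recovery metrics on simulated input ---------------------------
    if truth is not None:
        planted = set(truth.true_progression_genes)
        found = set(sig.adjacent_monotone)
        true_groups = truth.true_group[groups.label_of_cell.index]
        report["recovery"] = {
            "ari": _adjusted_rand_index(
                true_groups.values, groups.label_of_cell.values
            ),
            "signature_recall": len(found & planted) / len(planted) if planted else 0.0,
            "signature_contamination": (
                len(found - planted) / len(found) if found else 0.0
            ),
            "selection_recall": (
                len(selection.selected_ids & planted) / len(planted) if planted else 0.0
            ),
        }

    # -- survive (optional) -------------------------------------------
    if config.survival_sim is not None or config.cohort_expression_path:
        if config.survival_sim is not None:
            cohort_expr, cohort_surv = synthetic.simulate_survival_cohort(config.survival_sim)
            probe_map = {g: g for g in cohort_expr.columns}
            sig_genes = list(cohort_expr.columns)
        else:
            cohort_expr = pd.read_csv(config.cohort_expression_path, index_col=0)
            probe_map = sio.read_gene_lengths(
                config.cohort_probe_map_path, gene_col="probe_id", length_col="gene_id"
            ).to_dict()
            cohort_surv = pd.read_csv(config.cohort_survival_path)
            sig_genes = sorted(sig.adjacent_monotone)
        res = survival.analyze_cohort(
            cohort_expr,
            probe_map,
            cohort_surv,
            sig_genes,
            seed=config.seed,
            n_restarts=config.kmeans_restarts,
        )
        report["stages"]["survive"] = {
            "n_samples": res["n_samples"],
            "n_high": int((res["risk_groups"].label_of_sample == "high").sum()),
            "logrank_chi2": res["logrank"].chi_square,
            "logrank_p": res["logrank"].p,
            "hr": res["cox"].hr,
            "hr_ci": [res["cox"].ci_low, res["cox"].ci_high],
        }
    else:
        report["stages"]["survive"] = {"skipped": True}

    # -- checksums -----------------------------------------------------
    report["checksums"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.is_file() and p.name != "report.json"
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def _adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index between two labelings (contingency formula)."""
    a = pd.Categorical(a).codes
    b = pd.Categorical(b).codes
    n = len(a)
    contingency = np.zeros((a.max() + 1, b.max() + 1))
    for i, j in zip(a, b):
        contingency[i, j] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
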