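"""Synthetic data generators with planted ground truth.

Three generators cover the pipeline's inputs:

- :func:`simulate_expression` — a gene x cell negative-binomial count matrix
  with a planted monotone gene program across ordered latent groups,
  low-dispersion housekeeping genes, and per-gene CDS lengths.
- :func:`simulate_qc_metrics` — a per-cell QC-metric table with an exact,
  non-overlapping number of planted violations per criterion.
- :func:`simulate_survival_cohort` — a sample x signature-gene expression
  matrix tied to a latent score, with exponential event and censoring times
  and a planted hazard ratio between score halves.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "SurvivalSimConfig",
    "simulate_expression",
    "simulate_qc_metrics",
    "simulate_survival_cohort",
    "selection_benchmark_config",
    "signature_benchmark_config",
]


@dataclass
class SimConfig:
    """Configuration for :func:`simulate_expression`.

    Parameters
    ----------
    n_patients : int
        Number of patients; cells are split across them.
    cells_per_patient : tuple of int
        Inclusive ``(low, high)`` range for cells per patient.
    n_genes : int
        Total genes (housekeeping + progression + background).
    n_housekeeping : int
        Genes planted with a shared high baseline and low dispersion.
    n_progression_genes : int
        Genes planted with a monotone group effect.
    n_groups : int
        Number of ordered latent groups.
    delta_log2 : float
        Per-adjacent-group log2 expression step of progression genes.
    baseline_log2_mean_range : tuple of float
        Uniform range of per-gene baseline log2 mean (relative abundance).
    progression_baseline_log2_range : tuple of float or None
        Baseline range for the planted progression genes; defaults to
        ``baseline_log2_mean_range``.  Low baselines put planted genes in
        the CV-selectable regime; moderate baselines give them wide
        fold-change margins.
    dispersion : float
        Negative-binomial size parameter for non-housekeeping genes
        (variance = mu + mu**2 / dispersion).
    hk_dispersion : float
        Size parameter for housekeeping genes (large => low noise).
    hk_log2_mean : float
        Shared baseline log2 mean for housekeeping genes.
    library_size : float
        Expected total counts of a baseline (group-1) cell.
    group_mixture : ``"balanced"``, ``"dominant"`` or array
        ``"balanced"`` assigns cells round-robin to groups (equal sizes);
        ``"dominant"`` gives each patient one dominant group plus minor
        fractions of the others; an ``(n_patients, n_groups)`` array gives
        explicit per-patient group probabilities (rows sum to 1).
    size_factor_sd : float
        SD (log scale, base e) of per-cell log-normal size factors.
    seed : int
        Random seed.
    """

    n_patients: int = 15
    cells_per_patient: tuple[int, int] = (7, 77)
    n_genes: int = 2000
    n_housekeeping: int = 200
    n_progression_genes: int = 200
    n_groups: int = 4
    delta_log2: float = 1.5
    baseline_log2_mean_range: tuple[float, float] = (-3.5, -0.5)
    progression_baseline_log2_range: tuple[float, float] | None = (-4.2, -3.8)
    dispersion: float = 1.0
    hk_dispersion: float = 60.0
    hk_log2_mean: float = 6.0
    library_size: float = 400_000.0
    group_mixture: object = "dominant"
    size_factor_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_genes", "n_groups"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_housekeeping < 0 or self.n_progression_genes < 0:
            raise ValueError("planted gene counts must be non-negative")
        if self.n_housekeeping + self.n_progression_genes > self.n_genes:
            raise ValueError(
                "n_housekeeping + n_progression_genes exceeds n_genes "
                f"({self.n_housekeeping} + {self.n_progression_genes} > {self.n_genes})"
            )
        lo, hi = self.cells_per_patient
        if lo <= 0 or hi < lo:
            raise ValueError("cells_per_patient must be a positive (low, high) range")
        if self.delta_log2 < 0:
            raise ValueError("delta_log2 must be >= 0")
        if self.dispersion <= 0 or self.hk_dispersion <= 0:
            raise ValueError("dispersion parameters must be > 0")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        if isinstance(self.group_mixture, str):
            if self.group_mixture not in ("balanced", "dominant"):
                raise ValueError("group_mixture must be 'balanced', 'dominant' or a matrix")
        else:
            mix = np.asarray(self.group_mixture, dtype=float)
            if mix.shape != (self.n_patients, self.n_groups):
                raise ValueError("group_mixture matrix must be (n_patients, n_groups)")
            if (mix < 0).any() or not np.allclose(mix.sum(axis=1), 1.0):
                raise ValueError("group_mixture rows must be non-negative and sum to 1")


@dataclass
class SimulatedDataset:
    """Output of :func:`simulate_expression` with planted truth attached."""

    counts: pd.DataFrame  # gene x cell, non-negative ints
    cds_lengths: pd.Series  # gene -> bp
    true_group: pd.Series  # cell -> 1..n_groups
    patient: pd.Series  # cell -> patient id
    true_progression_genes: frozenset
    true_housekeeping_genes: frozenset
    config: SimConfig = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.true_group.index):
            raise ValueError("cell ids of counts and true_group disagree")
        if list(self.counts.columns) != list(self.patient.index):
            raise ValueError("cell ids of counts and patient disagree")
        if not self.counts.index.equals(self.cds_lengths.index):
            raise ValueError("gene ids of counts and cds_lengths disagree")
        if self.true_progression_genes & self.true_housekeeping_genes:
            raise ValueError("planted gene sets must be disjoint")


def _group_mixture_matrix(config: SimConfig) -> np.ndarray:
    """Per-patient group probabilities for the 'dominant' scheme."""
    k = config.n_groups
    mix = np.full((config.n_patients, k), 0.3 / max(k - 1, 1))
    for p in range(config.n_patients):
        mix[p, p % k] = 0.7
    if k == 1:
        mix[:] = 1.0
    return mix / mix.sum(axis=1, keepdims=True)


def simulate_expression(config: SimConfig) -> SimulatedDataset:
    """Draw a negative-binomial count matrix with a planted monotone program.

    Per gene ``g`` and cell ``c`` in group ``k`` (1-based), the expected
    count is ``2**(b_g + delta_log2 * (k - 1) * [g planted]) * s_c * scale``
    where ``b_g`` is the gene's baseline log2 mean, ``s_c`` a log-normal
    cell size factor, and ``scale`` fixed so a baseline cell's expected
    total equals ``library_size``.  Counts are NB with per-gene size
    parameter (housekeeping genes get ``hk_dispersion``, i.e. low noise).
    The adjacent-group geometric-mean ratio of planted genes is therefore
    ``2**delta_log2`` by construction.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_groups

    # -- cells ---------------------------------------------------------
    lo, hi = config.cells_per_patient
    n_cells_per_patient = rng.integers(lo, hi + 1, size=config.n_patients)
    patient_ids = [f"P{p + 1:02d}" for p in range(config.n_patients)]
    patient_of_cell = np.repeat(np.arange(config.n_patients), n_cells_per_patient)
    n_cells = int(n_cells_per_patient.sum())
    cell_ids = [
        f"{patient_ids[p]}_C{i + 1:03d}"
        for p, i in zip(
            patient_of_cell,
            np.concatenate([np.arange(n) for n in n_cells_per_patient]),
        )
    ]

    if isinstance(config.group_mixture, str) and config.group_mixture == "balanced":
        groups = (np.arange(n_cells) % k) + 1
    else:
        if isinstance(config.group_mixture, str):
            mix = _group_mixture_matrix(config)
        else:
            mix = np.asarray(config.group_mixture, dtype=float)
        groups = np.empty(n_cells, dtype=int)
        for c in range(n_cells):
            groups[c] = rng.choice(k, p=mix[patient_of_cell[c]]) + 1

    # -- genes ---------------------------------------------------------
    n_hk = config.n_housekeeping
    n_pg = config.n_progression_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    hk_idx = np.arange(n_hk)
    pg_idx = np.arange(n_hk, n_hk + n_pg)

    b_lo, b_hi = config.baseline_log2_mean_range
    baseline = rng.uniform(b_lo, b_hi, size=config.n_genes)
    p_lo, p_hi = config.progression_baseline_log2_range or (b_lo, b_hi)
    baseline[pg_idx] = rng.uniform(p_lo, p_hi, size=n_pg)
    baseline[hk_idx] = config.hk_log2_mean
    theta = np.full(config.n_genes, config.dispersion)
    theta[hk_idx] = config.hk_dispersion

    cds_lengths = rng.integers(300, 5001, size=config.n_genes)

    # -- expected counts ----------------------------------------------
    log2mu = np.tile(baseline[:, None], (1, n_cells))
    log2mu[np.ix_(pg_idx, np.arange(n_cells))] += config.delta_log2 * (groups - 1)

    # reads accumulate in proportion to molar abundance x CDS length, so
    # TPM recovers the planted abundance 2**log2mu regardless of length
    len_kb = cds_lengths / 1000.0
    size_factors = np.exp(rng.normal(0.0, config.size_factor_sd, size=n_cells))
    scale = config.library_size / (np.power(2.0, baseline) * len_kb).sum()
    mu = np.power(2.0, log2mu) * len_kb[:, None] * size_factors[None, :] * scale

    th = theta[:, None]
    counts = rng.negative_binomial(th, th / (th + mu))

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=cell_ids)
    return SimulatedDataset(
        counts=counts_df,
        cds_lengths=pd.Series(cds_lengths, index=gene_ids, name="cds_length_bp"),
        true_group=pd.Series(groups, index=cell_ids, name="true_group"),
        patient=pd.Series(
            [patient_ids[p] for p in patient_of_cell], index=cell_ids, name="patient"
        ),
        true_progression_genes=frozenset(gene_ids[i] for i in pg_idx),
        true_housekeeping_genes=frozenset(gene_ids[i] for i in hk_idx),
        config=config,
    )


# Default QC thresholds the planted violations are placed around; must stay
# in sync with scprog.qc.QCThresholds defaults.
_QC_READS = 1_000_000
_QC_MAPPED = 55.0
_QC_TIN = 45.0


def simulate_qc_metrics(
    n_cells: int,
    n_fail_reads: int,
    n_fail_mapped: int,
    n_fail_tin: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell QC metrics with exact planted violations.

    Exactly ``n_fail_reads`` cells fall strictly below the read-count
    threshold, ``n_fail_mapped`` below the mapped-percentage threshold and
    ``n_fail_tin`` below the TIN threshold; the three planted sets are
    disjoint and every other cell strictly satisfies all thresholds.
    Truth columns ``planted_fail_*`` accompany the metric columns.
    """
    for name, v in (
        ("n_cells", n_cells),
        ("n_fail_reads", n_fail_reads),
        ("n_fail_mapped", n_fail_mapped),
        ("n_fail_tin", n_fail_tin),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    n_fail = n_fail_reads + n_fail_mapped + n_fail_tin
    if n_fail > n_cells:
        raise ValueError("planted failure counts exceed n_cells")

    rng = np.random.default_rng(seed)
    reads = rng.integers(_QC_READS, 6_000_000, size=n_cells).astype(float)
    mapped = rng.uniform(_QC_MAPPED, 99.0, size=n_cells)
    tin = rng.uniform(_QC_TIN, 95.0, size=n_cells)

    order = rng.permutation(n_cells)
    fail_reads = order[:n_fail_reads]
    fail_mapped = order[n_fail_reads : n_fail_reads + n_fail_mapped]
    fail_tin = order[n_fail_reads + n_fail_mapped : n_fail]

    reads[fail_reads] = rng.integers(10_000, _QC_READS, size=n_fail_reads)
    mapped[fail_mapped] = rng.uniform(5.0, _QC_MAPPED - 0.1, size=n_fail_mapped)
    tin[fail_tin] = rng.uniform(5.0, _QC_TIN - 0.1, size=n_fail_tin)

    df = pd.DataFrame(
        {
            "cell_id": [f"CELL{i + 1:04d}" for i in range(n_cells)],
            "patient_id": ["P01"] * n_cells,
            "total_reads": reads,
            "pct_mapped": mapped,
            "median_tin": tin,
            "planted_fail_reads": False,
            "planted_fail_mapped": False,
            "planted_fail_tin": False,
        }
    )
    df.loc[fail_reads, "planted_fail_reads"] = True
    df.loc[fail_mapped, "planted_fail_mapped"] = True
    df.loc[fail_tin, "planted_fail_tin"] = True
    return df


@dataclass
class SurvivalSimConfig:
    """Configuration for :func:`simulate_survival_cohort`.

    ``true_hr`` multiplies the event hazard of the high-score half of
    samples; ``censor_rate`` is an independent exponential censoring
    hazard (0 disables censoring).
    """

    n_samples: int = 300
    n_signature_genes: int = 44
    true_hr: float = 2.0
    baseline_hazard: float = 1.0 / 1000.0
    censor_rate: float = 1.0 / 3000.0
    noise_sd: float = 1.0
    arms: tuple[tuple[str, float], ...] = (("bortezomib", 0.5), ("dexamethasone", 0.5))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_signature_genes <= 0:
            raise ValueError("n_samples and n_signature_genes must be positive")
        if self.true_hr <= 0:
            raise ValueError("true_hr must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        props = [p for _, p in self.arms]
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("arm proportions must be non-negative and sum to 1")


def simulate_survival_cohort(
    config: SurvivalSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample x signature-gene expression plus a survival table.

    Each sample gets a latent score ``z ~ N(0, 1)``; each signature gene is
    ``z`` plus independent Gaussian noise.  Event times are exponential
    with hazard ``baseline_hazard`` for the low-score half and
    ``baseline_hazard * true_hr`` for the high-score half (split at the
    median score); censoring times are exponential with ``censor_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    z = rng.normal(0.0, 1.0, size=n)
    expr = z[:, None] + rng.normal(
        0.0, config.noise_sd, size=(n, config.n_signature_genes)
    )
    gene_ids = [f"SG{i + 1:03d}" for i in range(config.n_signature_genes)]
    expr_df = pd.DataFrame(expr, index=sample_ids, columns=gene_ids)

    high = z > np.median(z)
    hazard = config.baseline_hazard * np.where(high, config.true_hr, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        t_censor = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_censor = np.full(n, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    labels, props = zip(*config.arms)
    arm = rng.choice(len(labels), size=n, p=np.asarray(props))
    surv_df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time_days": time,
            "event": event,
            "arm": [labels[a] for a in arm],
            "true_high": high,
        }
    )
    return expr_df, surv_df


def selection_benchmark_config(seed: int = 0, delta_log2: float = 1.5) -> SimConfig:
    """Balanced 4 x 40-cell benchmark with planted genes in the
    CV-selectable regime (low abundance, so the monotone program dominates
    their variability at mean log2(TPM+1) just above 3)."""
    return SimConfig(
        n_patients=4,
        cells_per_patient=(40, 40),
        n_genes=2000,
        n_housekeeping=200,
        n_progression_genes=200,
        delta_log2=delta_log2,
        baseline_log2_mean_range=(-3.5, -0.5),
        progression_baseline_log2_range=(-4.2, -3.8),
        dispersion=1.0,
        library_size=400_000.0,
        group_mixture="balanced",
        seed=seed,
    )


def signature_benchmark_config(seed: int = 0, delta_log2: float = 1.5) -> SimConfig:
    """Balanced 4 x 40-cell benchmark with planted genes in the
    wide-fold-change regime (moderate abundance, low noise, and a broad
    static background that anchors the correlation distance), tuned so
    clustering recovers the planted groups and the per-gene adjacent
    fold-change margins are comfortably above 2."""
    return SimConfig(
        n_patients=4,
        cells_per_patient=(40, 40),
        n_genes=2000,
        n_housekeeping=200,
        n_progression_genes=200,
        delta_log2=delta_log2,
        baseline_log2_mean_range=(-6.0, 2.0),
        progression_baseline_log2_range=(-3.4, -2.6),
        dispersion=3.0,
        library_size=2_000_000.0,
        group_mixture="balanced",
        seed=seed,
    )
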