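"""Survival stratification of an expression cohort by a gene signature.

Probe intensities are collapsed to genes by averaging, standardized
per gene, and the signature-gene submatrix is split into "high" and "low"
score groups by K-means (Hartigan-Wong single-point improvement, best of
several restarts).  Groups are then compared with the Kaplan-Meier
product-limit estimator, the Mantel-Cox log-rank test, and hazard ratios:
a Cox proportional-hazards fit on the binary group indicator (Efron ties,
via lifelines) alongside a Mantel-Haenszel O/E-based ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RiskGroups",
    "LogRankResult",
    "CoxResult",
    "collapse_probes",
    "standardize",
    "kmeans_dichotomize",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
    "analyze_cohort",
]


# ---------------------------------------------------------------------------
# expression preprocessing
# ---------------------------------------------------------------------------

def collapse_probes(intensities: pd.DataFrame, probe_to_gene) -> pd.DataFrame:
    """Collapse a sample x probe matrix to sample x gene by averaging the
    probes of each gene.  Probes without a gene mapping are dropped with a
    warning."""
    probe_map = pd.Series(probe_to_gene)
    mapped = [p for p in intensities.columns if p in probe_map.index and pd.notna(probe_map[p])]
    unmapped = [p for p in intensities.columns if p not in mapped]
    if unmapped:
        warnings.warn(f"dropping {len(unmapped)} unmapped probe(s): {unmapped[:5]}", stacklevel=2)
    if not mapped:
        raise ValueError("no probes could be mapped to genes")
    sub = intensities[mapped]
    return sub.T.groupby(probe_map[mapped]).mean().T


def standardize(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Mean-center and scale each gene column to SD 1 (sample SD).
    Zero-variance columns become all-zero with a warning."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardize")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=ddof)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance gene(s) set to zero: "
            f"{list(matrix.columns[zero][:5])}",
            stacklevel=2,
        )
    out = (matrix - mean) / sd.replace(0, np.nan)
    return out.fillna(0.0)


# ---------------------------------------------------------------------------
# K-means dichotomization
# ---------------------------------------------------------------------------

@dataclass
class RiskGroups:
    label_of_sample: pd.Series  # sample_id -> "high" / "low"
    cluster_means: dict = field(default_factory=dict)  # label -> mean score

    def samples_in(self, label: str) -> pd.Index:
        return self.label_of_sample.index[self.label_of_sample == label]


def _kmeans_once(X: np.ndarray, k: int, rng: np.random.Generator):
    """One K-means run: Lloyd to convergence, then Hartigan-Wong
    single-point moves (size-corrected cost change) until locally optimal."""
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.zeros(n, dtype=int)
    for it in range(100):  # Lloyd
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        if it > 0 and (new_labels == labels).all():
            break
        labels = new_labels
        for c in range(k):
            mask = labels == c
            if mask.any():
                centers[c] = X[mask].mean(axis=0)
            else:  # re-seed an empty cluster at the farthest point
                centers[c] = X[d2.min(axis=1).argmax()]

    sizes = np.bincount(labels, minlength=k).astype(float)
    for c in range(k):
        centers[c] = X[labels == c].mean(axis=0)

    improved = True
    sweeps = 0
    while improved and sweeps < 50:  # Hartigan-Wong improvement passes
        improved = False
        sweeps += 1
        for i in range(n):
            a = labels[i]
            if sizes[a] <= 1:
                continue
            cost_out = sizes[a] / (sizes[a] - 1) * ((X[i] - centers[a]) ** 2).sum()
            best_gain, best_b = 0.0, a
            for b in range(k):
                if b == a:
                    continue
                cost_in = sizes[b] / (sizes[b] + 1) * ((X[i] - centers[b]) ** 2).sum()
                gain = cost_out - cost_in
                if gain > best_gain + 1e-12:
                    best_gain, best_b = gain, b
            if best_b != a:
                centers[a] = (centers[a] * sizes[a] - X[i]) / (sizes[a] - 1)
                centers[best_b] = (centers[best_b] * sizes[best_b] + X[i]) / (sizes[best_b] + 1)
                sizes[a] -= 1
                sizes[best_b] += 1
                labels[i] = best_b
                improved = True

    wcss = sum(
        ((X[labels == c] - centers[c]) ** 2).sum() for c in range(k) if (labels == c).any()
    )
    return labels, float(wcss)


def kmeans_dichotomize(
    scores: pd.DataFrame,
    k: int = 2,
    n_restarts: int = 25,
    seed: int = 0,
) -> RiskGroups:
    """Split samples into "high"/"low" signature-expression groups.

    K-means (k = 2) on the sample x signature-gene matrix, best of
    ``n_restarts`` by within-cluster sum of squares; the cluster with the
    larger mean signature score (row mean) is labeled "high", so labels do
    not depend on cluster indices or the seed."""
    if k != 2:
        raise ValueError("dichotomization requires k = 2")
    X = scores.values.astype(float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k = {k} exceeds number of samples ({n})")
    rng = np.random.default_rng(seed)

    best_labels, best_wcss = None, np.inf
    for _ in range(max(1, n_restarts)):
        labels, wcss = _kmeans_once(X, k, rng)
        if wcss < best_wcss - 1e-12:
            best_labels, best_wcss = labels, wcss

    score = X.mean(axis=1)
    means = [score[best_labels == c].mean() for c in range(k)]
    high_cluster = int(np.argmax(means))
    label_of_sample = pd.Series(
        np.where(best_labels == high_cluster, "high", "low"),
        index=scores.index,
        name="risk_group",
    )
    if label_of_sample.nunique() < 2:
        raise ValueError("dichotomization produced an empty group")
    return RiskGroups(
        label_of_sample=label_of_sample,
        cluster_means={"high": float(max(means)), "low": float(min(means))},
    )


# ---------------------------------------------------------------------------
# survival comparison
# ---------------------------------------------------------------------------

def _aligned(records: pd.DataFrame, groups) -> pd.DataFrame:
    """Join survival records with group labels; validate coverage."""
    labels = groups.label_of_sample if isinstance(groups, RiskGroups) else pd.Series(groups)
    df = records.set_index("sample_id") if "sample_id" in records.columns else records.copy()
    missing = labels.index.difference(df.index)
    if len(missing) > 0:
        raise KeyError(f"sample(s) missing survival records: {list(missing[:5])}")
    out = df.loc[labels.index, ["time_days", "event"]].copy()
    out["group"] = labels.values
    if (out["time_days"] < 0).any():
        raise ValueError("negative survival times")
    if not out["event"].isin((0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    return out


def km_estimate(records: pd.DataFrame, groups) -> dict:
    """Kaplan-Meier product-limit curve per group.

    Returns ``{group: frame(time, at_risk, events, censored, survival)}``;
    each curve starts at S(0) = 1 and steps only at event times."""
    df = _aligned(records, groups)
    curves = {}
    for lab, sub in df.groupby("group"):
        times = np.sort(sub["time_days"].unique())
        rows = [(0.0, len(sub), 0, 0, 1.0)]
        s = 1.0
        for t in times:
            at_risk = int((sub["time_days"] >= t).sum())
            d = int(((sub["time_days"] == t) & (sub["event"] == 1)).sum())
            c = int(((sub["time_days"] == t) & (sub["event"] == 0)).sum())
            if d > 0:
                s *= 1.0 - d / at_risk
            rows.append((float(t), at_risk, d, c, s))
        curves[lab] = pd.DataFrame(
            rows, columns=["time", "at_risk", "events", "censored", "survival"]
        )
    return curves


@dataclass
class LogRankResult:
    chi_square: float
    p: float
    observed: dict
    expected: dict


def logrank_test(records: pd.DataFrame, groups) -> LogRankResult:
    """Two-group Mantel-Cox log-rank test.

    At each distinct event time the observed events in group 1 are
    compared with the hypergeometric expectation given the risk sets;
    ``chi2 = (sum(O - E))^2 / sum(V)`` with 1 df."""
    df = _aligned(records, groups)
    labs = sorted(df["group"].unique())
    if len(labs) != 2:
        raise ValueError(f"log-rank test requires exactly 2 non-empty groups, got {labs}")
    g1 = (df["group"] == labs[0]).values
    time = df["time_days"].values
    event = df["event"].values.astype(int)
    if event.sum() == 0:
        raise ValueError("no events observed")

    event_times = np.sort(np.unique(time[event == 1]))
    o1 = e1 = v = 0.0
    obs = {labs[0]: 0.0, labs[1]: 0.0}
    exp = {labs[0]: 0.0, labs[1]: 0.0}
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        e1_t = d * n1 / n
        o1 += d1
        e1 += e1_t
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        obs[labs[0]] += d1
        obs[labs[1]] += d - d1
        exp[labs[0]] += e1_t
        exp[labs[1]] += d - e1_t

    if v <= 0:
        return LogRankResult(chi_square=0.0, p=1.0, observed=obs, expected=exp)
    chi2 = (o1 - e1) ** 2 / v
    return LogRankResult(
        chi_square=float(chi2),
        p=float(sps.chi2.sf(chi2, df=1)),
        observed=obs,
        expected=exp,
    )


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    log_hr_se: float
    p: float
    hr_mantel_haenszel: float


def hazard_ratio(records: pd.DataFrame, groups, reference: str = "low") -> CoxResult:
    """Hazard ratio of the non-reference group vs ``reference``.

    Cox proportional-hazards fit on the single binary indicator (Efron
    tie handling, Newton maximization via lifelines); HR = exp(coef) with
    a 95% Wald CI.  A Mantel-Haenszel O/E ratio from the log-rank
    tabulation is reported alongside."""
    from lifelines import CoxPHFitter

    df = _aligned(records, groups)
    labs = sorted(df["group"].unique())
    if len(labs) != 2:
        raise ValueError("hazard ratio requires exactly 2 groups")
    if reference not in labs:
        raise KeyError(f"reference group {reference!r} not present")
    other = labs[0] if labs[1] == reference else labs[1]
    for lab in labs:
        if df.loc[df["group"] == lab, "event"].sum() == 0:
            raise ValueError(f"group {lab!r} has no events (monotone likelihood)")

    fit_df = pd.DataFrame(
        {
            "time": df["time_days"].values,
            "event": df["event"].values,
            "x": (df["group"] == other).astype(float).values,
        }
    )
    cph = CoxPHFitter()
    cph.fit(fit_df, duration_col="time", event_col="event")
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])

    lr = logrank_test(records, groups)
    mh = (lr.observed[other] / lr.expected[other]) / (
        lr.observed[reference] / lr.expected[reference]
    )
    return CoxResult(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.96 * se)),
        ci_high=float(np.exp(coef + 1.96 * se)),
        log_hr_se=se,
        p=float(cph.summary.loc["x", "p"]),
        hr_mantel_haenszel=float(mh),
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def analyze_cohort(
    intensities: pd.DataFrame,
    probe_to_gene,
    records: pd.DataFrame,
    signature_genes,
    arm: str | None = None,
    seed: int = 0,
    n_restarts: int = 25,
    max_missing_fraction: float = 0.2,
) -> dict:
    """Full cohort analysis: collapse, standardize, restrict to the
    signature, dichotomize, then KM / log-rank / hazard ratio.

    ``arm`` restricts records (and samples) to one treatment arm.  Samples
    missing more than ``max_missing_fraction`` of signature genes are
    dropped with a warning."""
    by_gene = collapse_probes(intensities, probe_to_gene)
    present = [g for g in signature_genes if g in by_gene.columns]
    if not present:
        raise ValueError("no signature genes present after probe collapse")
    if len(present) < len(list(signature_genes)):
        warnings.warn(
            f"{len(list(signature_genes)) - len(present)} signature gene(s) absent from cohort",
            stacklevel=2,
        )
    sub = by_gene[present]
    frac_missing = sub.isna().mean(axis=1)
    keep = frac_missing <= max_missing_fraction
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} sample(s) with excess missing genes", stacklevel=2)
    sub = sub.loc[keep].fillna(sub.mean())

    rec = records.set_index("sample_id") if "sample_id" in records.columns else records
    if arm is not None:
        rec = rec[rec["arm"] == arm]
    samples = sub.index.intersection(rec.index)
    sub = sub.loc[samples]
    rec = rec.loc[samples].reset_index().rename(columns={"index": "sample_id"})

    z = standardize(sub)
    risk = kmeans_dichotomize(z, n_restarts=n_restarts, seed=seed)
    return {
        "arm": arm,
        "n_samples": len(samples),
        "risk_groups": risk,
        "km": km_estimate(rec, risk),
        "logrank": logrank_test(rec, risk),
        "cox": hazard_ratio(rec, risk),
    }
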