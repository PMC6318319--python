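"""Group-wise differential expression and progression-signature derivation.

Per-gene one-way fixed-effects ANOVA across the ordered cell groups, with
pairwise log2 fold changes and two-group p-values (pooled-variance, i.e.
two-group ANOVA); fold change is the geometric-mean ratio
``2**(mean_log_b - mean_log_a)`` since all statistics run on the log2
scale.  From these:

- the *common up-regulated* set: genes passing ``FC >= fc_min`` (i.e.
  log2 FC >= log2(fc_min), inclusive) and ``p < p_max`` (strict) in every
  comparison of a non-reference group against the reference L1; and
- the *adjacent-monotone signature*: genes passing the same thresholds in
  every adjacent comparison (L1 vs L2, L2 vs L3, ...), intersected with
  the common up-regulated set.

Raw per-comparison p-values gate both sets by default; Benjamini-Hochberg
adjustment is available but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clustering import GroupAssignment

__all__ = [
    "SignatureResult",
    "anova_per_gene",
    "pairwise_fc",
    "common_upregulated",
    "adjacent_monotone_signature",
    "geneset_overlap",
    "geneset_group_report",
    "bh_adjust",
]


@dataclass
class SignatureResult:
    common_up: frozenset
    adjacent_monotone: frozenset
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.adjacent_monotone <= self.common_up:
            raise ValueError("adjacent_monotone must be a subset of common_up")


def _group_series(groups) -> pd.Series:
    if isinstance(groups, GroupAssignment):
        return groups.label_of_cell
    return pd.Series(groups)


def _ordered_labels(g: pd.Series) -> list:
    return sorted(g.unique(), key=lambda s: (len(str(s)), str(s)))


def anova_per_gene(expr_log: pd.DataFrame, groups) -> pd.DataFrame:
    """One-way ANOVA per gene on log2 values across groups.

    Returns a frame indexed by gene with per-group means plus ``anova_F``
    and ``anova_p`` from the F(k-1, n-k) distribution.  A gene with zero
    between-group variation gets F = 0, p = 1.
    """
    g = _group_series(groups)
    labels = _ordered_labels(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    X = expr_log[g.index].values
    n = X.shape[1]
    k = len(labels)

    means, ssw_parts, sizes = {}, [], []
    for lab in labels:
        cols = np.flatnonzero((g == lab).values)
        if len(cols) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 cells")
        sub = X[:, cols]
        m = sub.mean(axis=1)
        means[lab] = m
        ssw_parts.append(((sub - m[:, None]) ** 2).sum(axis=1))
        sizes.append(len(cols))

    grand = X.mean(axis=1)
    ssb = sum(
        sz * (means[lab] - grand) ** 2 for lab, sz in zip(labels, sizes)
    )
    ssw = sum(ssw_parts)

    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ssb <= 0, 0.0, (ssb / df_b) / np.where(ssw > 0, ssw / df_w, np.nan))
    F = np.where((ssb > 0) & (ssw <= 0), np.inf, F)
    p = np.where(np.isinf(F), 0.0, sps.f.sf(np.where(np.isfinite(F), F, 0.0), df_b, df_w))
    p = np.where(F == 0, 1.0, p)

    out = pd.DataFrame(
        {f"mean_{lab}": means[lab] for lab in labels}, index=expr_log.index
    )
    out["anova_F"] = F
    out["anova_p"] = p
    return out


def _two_group_stats(a: np.ndarray, b: np.ndarray):
    """Per-gene (log2 FC, p) for two groups of columns; pooled-variance F test."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    log2_fc = mb - ma
    ssw = ((a - ma[:, None]) ** 2).sum(axis=1) + ((b - mb[:, None]) ** 2).sum(axis=1)
    df_w = na + nb - 2
    ssb = (na * nb / (na + nb)) * (mb - ma) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ssb <= 0, 0.0, ssb / np.where(ssw > 0, ssw / df_w, np.nan))
    F = np.where((ssb > 0) & (ssw <= 0), np.inf, F)
    p = np.where(np.isinf(F), 0.0, sps.f.sf(np.where(np.isfinite(F), F, 0.0), 1, df_w))
    p = np.where(F == 0, 1.0, p)
    return log2_fc, p


def pairwise_fc(
    expr_log: pd.DataFrame, groups, comparisons: list[tuple]
) -> dict:
    """Per-gene log2 fold change and p-value for each ``(group_a, group_b)``.

    ``log2_fc = mean_log(b) - mean_log(a)``; p from the pooled two-group
    test on log2 values.  Returns ``{(a, b): frame(log2_fc, p)}``.
    """
    g = _group_series(groups)
    known = set(g.unique())
    X = expr_log[g.index].values
    out = {}
    for a, b in comparisons:
        if a not in known or b not in known:
            unknown = a if a not in known else b
            raise KeyError(f"unknown group {unknown!r}")
        ca = np.flatnonzero((g == a).values)
        cb = np.flatnonzero((g == b).values)
        log2_fc, p = _two_group_stats(X[:, ca], X[:, cb])
        out[(a, b)] = pd.DataFrame(
            {"log2_fc": log2_fc, "p": p}, index=expr_log.index
        )
    return out


def _passing(frame: pd.DataFrame, fc_min: float, p_max: float) -> frozenset:
    keep = (frame["log2_fc"] >= np.log2(fc_min)) & (frame["p"] < p_max)
    return frozenset(frame.index[keep])


def common_upregulated(
    expr_log: pd.DataFrame,
    groups,
    reference: str = "L1",
    fc_min: float = 2.0,
    p_max: float = 0.05,
) -> frozenset:
    """Genes up-regulated vs the reference in every non-reference group:
    the intersection over groups g != reference of
    {log2 FC(g vs ref) >= log2(fc_min) and p < p_max}."""
    g = _group_series(groups)
    labels = _ordered_labels(g)
    if reference not in labels:
        raise KeyError(f"reference group {reference!r} not present")
    others = [lab for lab in labels if lab != reference]
    if not others:
        raise ValueError("need at least one non-reference group")
    pw = pairwise_fc(expr_log, g, [(reference, lab) for lab in others])
    sets = [_passing(pw[(reference, lab)], fc_min, p_max) for lab in others]
    return frozenset.intersection(*sets)


def adjacent_monotone_signature(
    expr_log: pd.DataFrame,
    groups,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    reference: str | None = None,
) -> SignatureResult:
    """Genes passing FC/p in every adjacent comparison, within common_up.

    Requires at least 2 ordered groups (the adjacent chain L1-L2, L2-L3,
    ... must exist).  The result's ``adjacent_monotone`` is intersected
    with ``common_up`` so the nesting invariant holds by construction.
    """
    g = _group_series(groups)
    labels = _ordered_labels(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    reference = reference or labels[0]
    common = common_upregulated(expr_log, g, reference, fc_min, p_max)

    adjacent = list(zip(labels[:-1], labels[1:]))
    pw = pairwise_fc(expr_log, g, adjacent)
    sets = [_passing(pw[comp], fc_min, p_max) for comp in adjacent]
    monotone = frozenset.intersection(*sets) & common
    return SignatureResult(
        common_up=common,
        adjacent_monotone=monotone,
        thresholds={"fc_min": fc_min, "p_max": p_max, "reference": reference},
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return p
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def geneset_overlap(
    query: set,
    collection: dict,
    universe_size: int,
    query_name: str = "query",
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    For each set, ``p = P(X >= overlap)`` with
    ``X ~ Hypergeom(universe_size, |set|, |query|)``; q-values are BH
    across the collection.  Set and query sizes exceeding the universe
    indicate an inconsistent universe and raise.
    """
    query = set(query)
    if len(query) > universe_size:
        raise ValueError("query larger than universe")
    rows = []
    for name, members in collection.items():
        members = set(members)
        if len(members) > universe_size:
            raise ValueError(f"gene set {name!r} larger than universe")
        overlap = len(query & members)
        p = float(sps.hypergeom.sf(overlap - 1, universe_size, len(members), len(query)))
        rows.append(
            {
                "query": query_name,
                "gene_set": name,
                "set_size": len(members),
                "query_size": len(query),
                "overlap": overlap,
                "universe_size": universe_size,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].values)
    return out


def geneset_group_report(
    expr_log: pd.DataFrame, groups, gene_list, reference: str | None = None
) -> pd.DataFrame:
    """Reporting view for a supplied gene list: per-group means, global
    ANOVA F/p, and log2 FC / p for reference and adjacent comparisons.
    Unknown genes are warned about and dropped."""
    gene_list = list(gene_list)
    known = [g for g in gene_list if g in expr_log.index]
    unknown = [g for g in gene_list if g not in expr_log.index]
    if unknown:
        warnings.warn(f"dropping {len(unknown)} unknown gene(s): {unknown[:5]}", stacklevel=2)
    if not known:
        return pd.DataFrame()

    sub = expr_log.loc[known]
    g = _group_series(groups)
    labels = _ordered_labels(g)
    reference = reference or labels[0]
    report = anova_per_gene(sub, g)

    comps = [(reference, lab) for lab in labels if lab != reference]
    comps += [c for c in zip(labels[:-1], labels[1:]) if c not in comps]
    pw = pairwise_fc(sub, g, comps)
    for (a, b), frame in pw.items():
        report[f"log2_fc_{b}_vs_{a}"] = frame["log2_fc"]
        report[f"p_{b}_vs_{a}"] = frame["p"]
    return report
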