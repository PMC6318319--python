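"""Cell clustering: 1-Pearson distance, Ward.D2 linkage, tree cutting, and
expression-ordered group labels.

``ward_linkage`` implements the squared-dissimilarity Lance-Williams
recurrence with square-root merge heights (the formulation R calls
"ward.D2"), written here rather than delegated so that the agglomeration
tie rule is explicit: at equal merge cost the pair earliest in the current
cluster ordering is merged, which makes the tree deterministic across
platforms.  The returned linkage array uses the same layout as
``scipy.cluster.hierarchy`` so standard tooling can consume it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GroupAssignment",
    "pearson_distance",
    "ward_linkage",
    "cut_tree",
    "order_groups",
    "linkage_to_newick",
]


def pearson_distance(expr_log: pd.DataFrame) -> pd.DataFrame:
    """Cell x cell distance ``1 - r`` with ``r`` the Pearson correlation of
    the cells' gene-expression vectors (columns of ``expr_log``)."""
    if expr_log.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    values = expr_log.values.astype(float)
    sd = values.std(axis=0)
    if (sd == 0).any():
        bad = expr_log.columns[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero variance across the selected genes")
    r = np.corrcoef(values, rowvar=False)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=expr_log.columns, columns=expr_log.columns)


def ward_linkage(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Agglomerate under the Ward.D2 criterion.

    Runs the Lance-Williams update on squared dissimilarities,
    ``d2(k, i+j) = ((n_i + n_k) d2(k,i) + (n_j + n_k) d2(k,j)
    - n_k d2(i,j)) / (n_i + n_j + n_k)``, and records ``sqrt(d2(i,j))``
    as the merge height.  Returns an ``(n-1, 4)`` array of
    ``[id_left, id_right, height, size]`` rows with new clusters numbered
    ``n, n+1, ...`` (scipy linkage layout).
    """
    D = dist.values if isinstance(dist, pd.DataFrame) else np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 observations")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("distance matrix must have a zero diagonal")

    S = D.astype(float) ** 2  # squared dissimilarities, Lance-Williams state
    ids = list(range(n))
    sizes = np.ones(n)
    Z = np.empty((n - 1, 4))

    for step in range(n - 1):
        m = S.shape[0]
        iu, ju = np.triu_indices(m, k=1)
        flat = S[iu, ju]
        # first occurrence in row-major upper-triangle order = earliest
        # (i, j) pair in the current cluster ordering -> deterministic ties
        best = int(np.argmin(flat))
        i, j = int(iu[best]), int(ju[best])

        height = float(np.sqrt(max(S[i, j], 0.0)))
        ni, nj = sizes[i], sizes[j]
        Z[step] = (ids[i], ids[j], height, ni + nj)

        keep = np.array([t for t in range(m) if t not in (i, j)], dtype=int)
        nk = sizes[keep]
        new_row = (
            (ni + nk) * S[i, keep] + (nj + nk) * S[j, keep] - nk * S[i, j]
        ) / (ni + nj + nk)

        S = S[np.ix_(keep, keep)]
        S = np.pad(S, ((0, 1), (0, 1)))
        S[-1, :-1] = new_row
        S[:-1, -1] = new_row
        S[-1, -1] = 0.0

        ids = [ids[t] for t in keep] + [n + step]
        sizes = np.append(sizes[keep], ni + nj)

    return Z


def cut_tree(Z: np.ndarray, k: int) -> np.ndarray:
    """Partition leaves into ``k`` clusters by dropping the ``k-1`` highest
    (final) merges.  Returns integer labels aligned with leaf order,
    numbered 0..k-1 by first appearance."""
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b = int(Z[step, 0]), int(Z[step, 1])
        parent[find(a)] = parent[find(b)] = n + step

    roots: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for leaf in range(n):
        r = find(leaf)
        labels[leaf] = roots.setdefault(r, len(roots))
    return labels


@dataclass
class GroupAssignment:
    """Ordered cluster labels: L1 has the lowest ordering statistic."""

    label_of_cell: pd.Series  # cell_id -> "L1".."Lk"
    k: int
    ordering_statistic: dict  # label -> per-group mean expression

    @property
    def labels(self) -> list:
        return [f"L{i + 1}" for i in range(self.k)]

    def cells_in(self, label: str) -> pd.Index:
        return self.label_of_cell.index[self.label_of_cell == label]


def order_groups(
    partition: np.ndarray | pd.Series,
    expr_log: pd.DataFrame,
    ordering_genes=None,
) -> GroupAssignment:
    """Relabel a raw partition L1..Lk in ascending per-group mean expression.

    The ordering statistic is the mean over a group's cells of the
    per-cell mean log2 expression across ``ordering_genes`` (default: all
    genes of ``expr_log``, i.e. the selected genes).  Ties break by group
    size descending, then by lexicographically smallest member cell id.
    """
    cells = expr_log.columns
    part = pd.Series(np.asarray(partition), index=cells)
    if part.isna().any():
        raise ValueError("partition does not cover all cells")

    genes = list(ordering_genes) if ordering_genes is not None else list(expr_log.index)
    if not genes:
        raise ValueError("ordering_genes must be non-empty")
    missing = set(genes) - set(expr_log.index)
    if missing:
        raise KeyError(f"ordering gene(s) absent from matrix: {sorted(missing)[:5]}")

    cell_score = expr_log.loc[genes].mean(axis=0)
    keys = []
    for g, members in part.groupby(part).groups.items():
        if len(members) == 0:
            raise ValueError(f"group {g!r} is empty")
        keys.append(
            (float(cell_score[members].mean()), -len(members), min(map(str, members)), g)
        )
    keys.sort()

    relabel = {old: f"L{rank + 1}" for rank, (_, _, _, old) in enumerate(keys)}
    label_of_cell = part.map(relabel).rename("group")
    ordering_statistic = {relabel[old]: stat for stat, _, _, old in keys}
    return GroupAssignment(
        label_of_cell=label_of_cell, k=len(keys), ordering_statistic=ordering_statistic
    )


def linkage_to_newick(Z: np.ndarray, leaf_ids) -> str:
    """Render a linkage array as a Newick string (branch lengths from merge
    heights, leaves labeled by ``leaf_ids``)."""
    n = Z.shape[0] + 1
    leaf_ids = list(leaf_ids)
    height = {i: 0.0 for i in range(n)}
    node = {i: str(leaf_ids[i]) for i in range(n)}
    for step in range(n - 1):
        a, b, h = int(Z[step, 0]), int(Z[step, 1]), float(Z[step, 2])
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        node[n + step] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[n + step] = h
    return node[2 * n - 2] + ";"
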