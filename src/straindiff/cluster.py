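"""Hierarchical clustering of arrays to identify homologous tissue data sets
across strains.

Arrays are clustered on centered Pearson correlation distances over a set of
similarly-expressed genes, with Ward linkage applied directly to the
unsquared dissimilarities (the classical "ward.D" Lance-Williams update,
the historical default of the clustering routine this analysis style comes
from). A config switch selects the squared-distance "ward.D2" variant
instead. Cutting the dendrogram at a fixed height yields the array clusters;
a tissue is homologous across strains when every required strain's arrays
for that tissue land in one common cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SampleSheet


@dataclass
class Dendrogram:
    """Agglomeration history in scipy linkage layout.

    ``merges`` has one row per merge: (node_i, node_j, height, size); leaf
    nodes are 0..n-1 and merge k creates node n+k. ``leaves`` are the array
    ids in input order.
    """
    merges: np.ndarray
    leaves: list[str]


def correlation_distance(m: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson r between rows (arrays) over columns (genes)."""
    if m.shape[1] < 2:
        raise ValueError("correlation_distance needs >= 2 genes per array")
    v = m.to_numpy(dtype=float)
    sd = v.std(axis=1)
    if (sd == 0).any():
        bad = m.index[int(np.argmax(sd == 0))]
        raise ValueError(f"array {bad!r} has constant values; correlation undefined")
    d = 1.0 - np.corrcoef(v)
    d = (d + d.T) / 2.0  # corrcoef is symmetric only up to rounding
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=m.index, columns=m.index)


def ward_cluster(d: pd.DataFrame, squared: bool = False) -> Dendrogram:
    """Agglomerative Ward clustering via the Lance-Williams update.

    With ``squared=False`` (default) the recurrence is applied to the given
    dissimilarities as-is (ward.D); with ``squared=True`` it is applied to
    squared dissimilarities and merge heights are square-rooted (ward.D2).
    Merge-height ties break on the smallest leaf index for determinism.
    """
    dm = d.to_numpy(dtype=float).copy()
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = dm.shape[0]
    dm = (dm + dm.T) / 2.0  # exact symmetry so the pair search is well defined
    leaves = [str(x) for x in d.index]
    if squared:
        dm = dm ** 2
    work = dm.copy()
    np.fill_diagonal(work, np.inf)
    node_of = np.arange(n)                  # row index -> current node id
    sizes = np.ones(n)
    min_leaf = np.arange(n)
    alive = np.ones(n, dtype=bool)
    merges = np.zeros((n - 1, 4))
    next_node = n
    for step in range(n - 1):
        masked = np.where(alive[:, None] & alive[None, :], work, np.inf)
        height = masked.min()
        # candidate pairs at the minimum; tie-break on smallest leaf indices
        cand = np.argwhere(np.triu(masked <= height + 0.0, k=1))
        pa, pb = min(
            ((i, j) for i, j in cand),
            key=lambda ij: tuple(sorted((min_leaf[ij[0]], min_leaf[ij[1]]))),
        )
        a, b = node_of[pa], node_of[pb]
        na, nb = sizes[pa], sizes[pb]
        # Lance-Williams Ward update against every other active cluster
        others = alive.copy()
        others[[pa, pb]] = False
        nc = sizes[others]
        new = ((na + nc) * work[pa, others] + (nb + nc) * work[pb, others]
               - nc * height) / (na + nb + nc)
        work[pa, others] = new
        work[others, pa] = new
        merges[step] = (min(a, b), max(a, b),
                        np.sqrt(height) if squared else height, na + nb)
        # merged cluster reuses row pa
        node_of[pa] = next_node
        sizes[pa] = na + nb
        min_leaf[pa] = min(min_leaf[pa], min_leaf[pb])
        alive[pb] = False
        next_node += 1
    return Dendrogram(merges=merges, leaves=leaves)


def cut(dend: Dendrogram, height: float) -> pd.Series:
    """Partition induced by keeping merges with height <= ``height``.

    Returns array_id -> cluster id (1-based, ordered by first leaf).
    """
    n = len(dend.leaves)
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (i, j, h, _) in enumerate(dend.merges):
        if h <= height:
            node = n + k
            parent[find(int(i))] = node
            parent[find(int(j))] = node
    roots: dict[int, int] = {}
    labels = []
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels.append(roots[r])
    return pd.Series(labels, index=dend.leaves, name="cluster")


def select_homologous(assignment: pd.Series, sheet: SampleSheet,
                      required_strains: set[str]) -> list[tuple[str, int]]:
    """Tissues whose arrays from every required strain share one cluster."""
    f = sheet.frame
    out: list[tuple[str, int]] = []
    for tissue in dict.fromkeys(f["tissue"]):
        rows = f[(f["tissue"] == tissue) & (f["strain"].isin(required_strains))]
        if set(rows["strain"]) != set(required_strains):
            continue
        clusters = set(assignment.loc[rows["array_id"]])
        if len(clusters) == 1:
            out.append((tissue, int(clusters.pop())))
    return out
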