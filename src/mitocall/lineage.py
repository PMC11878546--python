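"""Cell-type summaries of mutation calls and heatmap ordering.

Given per-cell type labels, mutant-cell counts are normalized per
mutation (F_ij = N_ij / T_j, columns summing to one) and cell types are
clustered by complete-linkage hierarchical clustering on the Euclidean
distances between their normalized frequency profiles.  ``memo_sort``
orders a binary mutation x cell matrix into the staircase layout used
for clonal heatmaps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def celltype_frequency(calls, type_labels: dict | pd.Series) -> pd.DataFrame:
    """Normalized mutant-cell frequency per cell type (rows) x mutation (cols).

    N_ij counts cells of type i carrying mutation j; T_j = sum_i N_ij;
    F_ij = N_ij / T_j so each mutation column sums to one.  Mutations with
    no mutant cells are dropped; a called cell without a label is an error.
    """
    labels = pd.Series(type_labels)
    tensor = calls.results.tensor
    lab = labels.reindex(tensor.cells)
    flagged_any = calls.mutant_flags.any(axis=1)
    missing = [c for c, f, l in zip(tensor.cells, flagged_any, lab.isna()) if f and l]
    if missing:
        raise ValueError(f"called cells without a type label: {missing}")

    types = sorted(labels.dropna().unique())
    cols = {}
    for j in calls.reported_loci:
        flags = calls.mutant_flags[:, j]
        counts = lab[flags].value_counts()
        total = counts.sum()
        if total == 0:
            continue
        cols[tensor.locus_names[j]] = [counts.get(t, 0) / total for t in types]
    return pd.DataFrame(cols, index=types)


def cluster_celltypes(freq: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Complete-linkage hierarchical clustering of cell types.

    Rows of ``freq`` (cell types) are clustered on Euclidean distance;
    returns ``(linkage matrix, leaf order as type labels)``.  Deterministic:
    scipy's tie handling is stable for a fixed input order.
    """
    if freq.shape[0] < 2:
        raise ValueError("need at least 2 cell types to cluster")
    if freq.shape[1] < 1:
        raise ValueError("need at least 1 mutation")
    dist = pdist(freq.to_numpy(), metric="euclidean")
    linkage = hierarchy.linkage(dist, method="complete")
    order = hierarchy.leaves_list(linkage)
    return linkage, [freq.index[k] for k in order]


def memo_sort(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Staircase ordering of a binary mutation x cell matrix.

    Rows (mutations) are ordered by decreasing mutant-cell count; columns
    (cells) are ordered by reading each cell's membership vector in the new
    row order as a binary number, descending.  Ties keep the original
    index order, which makes the sort idempotent and leaves all-zero
    columns rightmost in input order.

    Returns ``(row_order, col_order)`` as integer index arrays.
    """
    mat = np.asarray(matrix, dtype=bool).astype(np.int8)
    if mat.ndim != 2:
        raise ValueError("matrix must be 2-D")
    n_rows, _ = mat.shape
    row_counts = mat.sum(axis=1)
    row_order = np.argsort(-row_counts, kind="stable")
    ordered = mat[row_order]
    # lexsort's last key is most significant -> feed rows bottom-up, negate
    # for descending order; lexsort is stable so ties keep input order
    col_order = np.lexsort(-ordered[::-1])
    return row_order, col_order


def apply_memo_sort(matrix: pd.DataFrame) -> pd.DataFrame:
    """Return the matrix reordered by :func:`memo_sort`."""
    row_order, col_order = memo_sort(matrix)
    return matrix.iloc[row_order, :].iloc[:, col_order]
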