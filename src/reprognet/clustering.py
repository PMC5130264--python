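"""Hierarchical clustering of expression profiles with uncentered correlation.

The similarity between two profiles is the normalized dot product
s = Σxᵢyᵢ / (‖x‖·‖y‖) — "uncentered correlation", i.e. cosine similarity
without mean-centering, the metric of the classic gene-expression
clustering tools.  Agglomerative merging runs on the distance 1 − s.
Missing entries (NaN) are handled pairwise-complete.  Output formats
(CDT plus GTR/ATR) are compatible with common dendrogram viewers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

__all__ = [
    "uncentered_correlation",
    "similarity_matrix",
    "hierarchical_cluster",
    "ClusterTree",
]

_LINKAGES = {"single", "complete", "average", "centroid"}


def uncentered_correlation(x, y) -> float:
    """Normalized dot product of two profiles, pairwise-complete on NaN.

    Raises on zero-norm (constant-zero) input — the similarity is
    undefined there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("profiles must be 1-D, equal length, non-empty")
    ok = np.isfinite(x) & np.isfinite(y)
    if not ok.any():
        raise ValueError("no pairwise-complete entries")
    x, y = x[ok], y[ok]
    nx_, ny_ = np.sqrt((x * x).sum()), np.sqrt((y * y).sum())
    if nx_ == 0.0 or ny_ == 0.0:
        raise ValueError("zero-norm profile: uncentered correlation undefined")
    return float((x * y).sum() / (nx_ * ny_))


def similarity_matrix(matrix: pd.DataFrame, axis: str = "genes") -> pd.DataFrame:
    """All-pairs uncentered correlation over rows (genes) or columns (arrays)."""
    if axis not in {"genes", "arrays"}:
        raise ValueError("axis must be 'genes' or 'arrays'")
    data = matrix if axis == "genes" else matrix.T
    x = data.to_numpy(dtype=float)
    bad = [
        str(data.index[i])
        for i in range(x.shape[0])
        if np.nansum(np.square(x[i])) == 0.0
    ]
    if bad:
        raise ValueError(f"zero-norm profiles on axis {axis!r}: {bad}")
    finite = np.isfinite(x)
    if finite.all():
        norms = np.sqrt((x * x).sum(axis=1))
        s = (x @ x.T) / np.outer(norms, norms)
    else:
        n = x.shape[0]
        s = np.empty((n, n))
        for i in range(n):
            s[i, i] = 1.0
            for j in range(i + 1, n):
                s[i, j] = s[j, i] = uncentered_correlation(x[i], x[j])
    np.clip(s, -1.0, 1.0, out=s)
    return pd.DataFrame(s, index=data.index, columns=data.index)


@dataclass
class ClusterTree:
    """Merge history of an agglomerative clustering run.

    ``linkage_matrix`` is the standard 4-column (left, right, distance,
    size) encoding; ``merges`` re-expresses it with the similarity at
    each merge (1 − distance), matching tree-viewer conventions.
    """

    labels: list[str]
    linkage_matrix: np.ndarray
    axis: str
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merges(self) -> pd.DataFrame:
        z = self.linkage_matrix
        return pd.DataFrame(
            {
                "left": z[:, 0].astype(int),
                "right": z[:, 1].astype(int),
                "similarity": 1.0 - z[:, 2],
                "size": z[:, 3].astype(int),
            }
        )

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in sch.leaves_list(self.linkage_matrix)]

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster ids (1..n_clusters) per leaf label."""
        assign = sch.fcluster(
            self.linkage_matrix, t=n_clusters, criterion="maxclust"
        )
        return pd.Series(assign, index=self.labels, name="cluster")

    def write_merge_table(self, path: Path) -> None:
        self.merges.to_csv(path, sep="\t", index_label="step", float_format="%.6f")


def hierarchical_cluster(
    matrix: pd.DataFrame, axis: str = "genes", linkage: str = "average"
) -> ClusterTree:
    """Agglomerative clustering on 1 − uncentered-correlation distance."""
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGES)}")
    s = similarity_matrix(matrix, axis=axis)
    if len(s) < 2:
        raise ValueError("need >= 2 items on the clustered axis")
    d = 1.0 - s.to_numpy()
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, None, out=d)
    z = sch.linkage(squareform(d, checks=False), method=linkage)
    return ClusterTree(
        labels=[str(i) for i in s.index],
        linkage_matrix=z,
        axis=axis,
        method=linkage,
    )


# ---------------------------------------------------------------------------
# tree-viewer output (CDT + GTR/ATR)


def _node_names(tree: ClusterTree, prefix: str) -> list[str]:
    return [f"NODE{i+1}X" for i in range(tree.n_leaves - 1)]


def write_cdt(
    matrix: pd.DataFrame,
    path: Path,
    gene_tree: ClusterTree | None = None,
    array_tree: ClusterTree | None = None,
) -> None:
    """Clustered data table with leaves in dendrogram order."""
    gene_order = gene_tree.leaf_order() if gene_tree else [str(i) for i in matrix.index]
    array_order = (
        array_tree.leaf_order() if array_tree else [str(c) for c in matrix.columns]
    )
    m = matrix.loc[gene_order, array_order]
    with open(path, "w") as fh:
        fh.write("GID\tNAME\tGWEIGHT\t" + "\t".join(array_order) + "\n")
        if array_tree is not None:
            aid = {lab: f"ARRY{i}X" for i, lab in enumerate(array_tree.labels)}
            fh.write("AID\t\t\t" + "\t".join(aid[a] for a in array_order) + "\n")
        fh.write("EWEIGHT\t\t\t" + "\t".join(["1"] * len(array_order)) + "\n")
        for g in gene_order:
            vals = "\t".join(
                "" if not np.isfinite(v) else f"{v:.4f}" for v in m.loc[g]
            )
            gid = f"GENE{gene_order.index(g)}X" if gene_tree else g
            fh.write(f"{gid}\t{g}\t1\t{vals}\n")


def _write_tree_file(tree: ClusterTree, path: Path, leaf_prefix: str) -> None:
    names = _node_names(tree, leaf_prefix)
    with open(path, "w") as fh:
        for i, row in tree.merges.iterrows():
            def ref(idx: int) -> str:
                if idx < tree.n_leaves:
                    return f"{leaf_prefix}{idx}X"
                return names[idx - tree.n_leaves]
            fh.write(
                f"{names[i]}\t{ref(int(row.left))}\t{ref(int(row.right))}"
                f"\t{row.similarity:.6f}\n"
            )


def write_gtr(tree: ClusterTree, path: Path) -> None:
    _write_tree_file(tree, path, "GENE")


def write_atr(tree: ClusterTree, path: Path) -> None:
    _write_tree_file(tree, path, "ARRY")
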