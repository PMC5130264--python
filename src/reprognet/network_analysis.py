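"""Degree-centrality analysis of the directed GRN and the TF-TF core.

Out-degree ranks the master regulators (how many genes a TF's binding
evidence plus expression response supports it as driving); in-degree
ranks the most-regulated genes.  The core network is the induced TF→TF
subgraph over the differentially expressed TFs.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import networkx as nx
import pandas as pd

__all__ = ["degree_centrality", "core_tf_network", "top_regulators"]


def degree_centrality(grn: nx.DiGraph) -> pd.DataFrame:
    """Per-node in/out degree with deterministic dense ranks.

    Ties are broken lexicographically by node id, so ``rank_out`` = 1 is
    the highest out-degree node (first alphabetically among equals).
    """
    nodes = sorted(grn.nodes)
    df = pd.DataFrame(
        {
            "node": nodes,
            "in_degree": [grn.in_degree(n) for n in nodes],
            "out_degree": [grn.out_degree(n) for n in nodes],
        }
    )
    for col, rank_col in (("in_degree", "rank_in"), ("out_degree", "rank_out")):
        order = df.sort_values([col, "node"], ascending=[False, True])
        df[rank_col] = pd.Series(
            range(1, len(df) + 1), index=order.index
        )
    return df.set_index("node")


def core_tf_network(grn: nx.DiGraph, detf_set: Iterable[str]) -> nx.DiGraph:
    """Induced subgraph on the DE-TFs, keeping only TF→TF edges.

    DE-TFs absent from the GRN are reported with a warning, not fatal
    (a TF may be differentially expressed yet lack regulon evidence).
    """
    detfs = set(detf_set)
    missing = sorted(detfs - set(grn.nodes))
    if missing:
        warnings.warn(f"DE-TFs absent from the GRN: {missing}", stacklevel=2)
    return grn.subgraph(detfs & set(grn.nodes)).copy()


def top_regulators(report: pd.DataFrame, k: int) -> list[str]:
    """Top-k nodes by out-degree (lexicographic tie-break)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(report):
        warnings.warn(
            f"k={k} exceeds the {len(report)} nodes; returning all",
            stacklevel=2,
        )
        k = len(report)
    ranked = report.sort_values("rank_out")
    return list(ranked.index[:k])


def write_centrality_tsv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index_label="node")
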