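"""Confidence-filtered protein-interaction graphs and MCODE complexes.

The PPI side of the analysis: load a STRING/BioGRID-style edge table,
keep high-confidence interactions (default score >= 0.7), optionally
keep only experimentally validated evidence, restrict to the
differentially expressed proteins, and detect densely connected
complexes with MCODE (molecular complex detection):

1. *Vertex weighting* — each vertex v gets weight k·d, where k is the
   order of the highest k-core of v's closed neighborhood and d is the
   density of that core ("core-clustering coefficient").
2. *Complex prediction* — complexes are seeded from the highest-weight
   unvisited vertex and grown breadth-first over neighbors whose weight
   is within ``vwp`` (vertex weight percentage) of the seed weight; a
   vertex joins at most one complex.
3. *Post-processing* — complexes without a 2-core are discarded;
   *haircut* prunes singly connected members; *fluff* (off by default)
   adds high-density neighbor shells.

A complex scores density × size; published practice keeps score > 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "load_ppi",
    "restrict_to_de",
    "mcode",
    "filter_complexes",
    "ComplexResult",
]

_EVIDENCE = {"validated", "predicted"}


def load_ppi(
    table: pd.DataFrame | Path | str,
    min_confidence: float = 0.7,
    evidence_filter: str = "all",
) -> nx.Graph:
    """Build an undirected confidence-weighted graph from an edge table.

    ``table`` has columns (a, b, confidence, evidence).  Edges below
    ``min_confidence`` are dropped; ``evidence_filter`` is ``all`` or
    ``validated_only``.  Self-edges are dropped; duplicate (b, a) of
    (a, b) collapses to one edge keeping the maximum confidence.
    """
    if evidence_filter not in {"all", "validated_only"}:
        raise ValueError("evidence_filter must be 'all' or 'validated_only'")
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    g = nx.Graph()
    for i, row in enumerate(table.itertuples(index=False), start=1):
        try:
            a, b, conf, ev = str(row.a), str(row.b), float(row.confidence), str(row.evidence)
        except (AttributeError, ValueError) as exc:
            raise ValueError(f"malformed PPI row {i}: {row}") from exc
        if not 0.0 <= conf <= 1.0:
            raise ValueError(f"row {i}: confidence {conf} outside [0, 1]")
        if ev not in _EVIDENCE:
            raise ValueError(f"row {i}: unknown evidence class {ev!r}")
        if a == b:
            continue
        if conf < min_confidence:
            continue
        if evidence_filter == "validated_only" and ev != "validated":
            continue
        u, v = sorted((a, b))
        if g.has_edge(u, v):
            g[u][v]["confidence"] = max(g[u][v]["confidence"], conf)
        else:
            g.add_edge(u, v, confidence=conf, evidence=ev)
    return g


def restrict_to_de(graph: nx.Graph, de_set: Iterable[str]) -> nx.Graph:
    """Induced subgraph on the differentially expressed proteins."""
    return graph.subgraph(set(de_set) & set(graph.nodes)).copy()


@dataclass(frozen=True)
class ComplexResult:
    """A detected complex: member set, its density and density×size score."""

    members: frozenset[str]
    density: float
    score: float
    seed: str

    @property
    def size(self) -> int:
        return len(self.members)

    @staticmethod
    def from_members(graph: nx.Graph, members: Iterable[str], seed: str) -> "ComplexResult":
        members = frozenset(members)
        sub = graph.subgraph(members)
        d = nx.density(sub) if len(members) > 1 else 0.0
        return ComplexResult(members=members, density=d, score=d * len(members), seed=seed)


def _vertex_weights(graph: nx.Graph) -> dict[str, float]:
    """k-core-based weighting of every vertex's closed neighborhood."""
    w = {}
    for v in graph.nodes:
        nbhd = graph.subgraph(set(graph[v]) | {v})
        if nbhd.number_of_edges() == 0:
            w[v] = 0.0
            continue
        core = nx.core_number(nbhd)
        kmax = max(core.values())
        top = nbhd.subgraph([u for u, c in core.items() if c >= kmax])
        w[v] = kmax * nx.density(top)
    return w


def mcode(
    graph: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.2,
) -> list[ComplexResult]:
    """Detect dense complexes; returns results sorted by score descending.

    ``vwp`` (vertex weight percentage, in [0, 1)) controls how far a
    grown member's weight may fall below the seed's: members require
    weight >= (1 - vwp) × seed weight.  Ties in seed order and growth
    order are broken lexicographically by node id for determinism.
    """
    if not 0.0 <= vwp < 1.0:
        raise ValueError(f"vwp must be in [0, 1), got {vwp}")
    weights = _vertex_weights(graph)
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    visited: set[str] = set()
    results: list[ComplexResult] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0.0:
            continue
        threshold = (1.0 - vwp) * weights[seed]
        members = {seed}
        frontier = [seed]
        visited.add(seed)
        while frontier:
            nxt = []
            for v in frontier:
                for u in sorted(graph[v], key=str):
                    if u in visited or u in members:
                        continue
                    if weights[u] >= threshold:
                        members.add(u)
                        visited.add(u)
                        nxt.append(u)
            frontier = nxt
        sub = graph.subgraph(members)
        two_core = nx.k_core(sub, 2)
        if two_core.number_of_nodes() == 0:
            continue
        final = set(two_core.nodes) if haircut else set(members)
        if fluff:
            shell = set()
            for v in sorted(final, key=str):
                for u in sorted(graph[v], key=str):
                    if u in final or u in shell:
                        continue
                    cand = graph.subgraph(final | shell | {u})
                    if nx.density(cand) >= fluff_density:
                        shell.add(u)
            final |= shell
        results.append(ComplexResult.from_members(graph, final, seed))
    results.sort(key=lambda c: (-c.score, -c.size, min(map(str, c.members))))
    return results


def filter_complexes(
    results: Sequence[ComplexResult], min_score: float = 2.0
) -> list[ComplexResult]:
    """Keep complexes with score strictly greater than ``min_score``."""
    return [c for c in results if c.score > min_score]


def write_complexes_tsv(results: Sequence[ComplexResult], path) -> None:
    rows = [
        {
            "complex": i + 1,
            "score": round(c.score, 6),
            "density": round(c.density, 6),
            "size": c.size,
            "members": ",".join(sorted(c.members)),
        }
        for i, c in enumerate(results)
    ]
    pd.DataFrame(
        rows, columns=["complex", "score", "density", "size", "members"]
    ).to_csv(path, sep="\t", index=False)
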