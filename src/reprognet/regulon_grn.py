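"""TF→target regulatory-network construction from a binding-site regulon DB.

A regulon database (ChEA-style GMT: one regulator per line followed by the
genes whose promoters/enhancers it binds) is combined with a consensus
differential-expression table: regulators over-represented among the DEGs
(one-sided hypergeometric, p < 0.05) are kept, their edges are restricted
to expression-responsive targets (|linear FC| >= 1.5 somewhere), and the
result is a directed graph whose nodes carry expression direction.
Composition statistics (up/down percentages of a target set vs the DEG
background) and cross-species direction concordance are computed on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .deg_consensus import ConsensusTable

__all__ = [
    "RegulonDB",
    "read_gmt",
    "write_gmt",
    "regulator_enrichment",
    "filter_edges_by_expression",
    "build_grn",
    "common_targets",
    "direction_composition",
    "DirectionComposition",
    "cross_species_concordance",
    "write_sif",
]


@dataclass
class RegulonDB:
    """Regulator → target-gene-set mapping with per-source provenance.

    The same TF may appear under several sources (different ChIP
    experiments); ``targets_of`` returns the merged union view.
    """

    _sources: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    _meta: dict[tuple[str, str], dict] = field(default_factory=dict)

    def add(
        self, tf: str, targets: Iterable[str], species: str = "", source: str = ""
    ) -> None:
        targets = {t for t in targets if t}
        if not targets:
            raise ValueError(f"regulon for {tf!r} is empty")
        key = (tf, source)
        if key in self._sources:
            raise ValueError(f"duplicate regulon source {key}")
        self._sources[key] = targets
        self._meta[key] = {"species": species, "source": source}

    @property
    def regulators(self) -> list[str]:
        return sorted({tf for tf, _ in self._sources})

    def targets_of(self, tf: str) -> set[str]:
        out: set[str] = set()
        found = False
        for (name, _), targets in self._sources.items():
            if name == tf:
                out |= targets
                found = True
        if not found:
            raise KeyError(f"unknown regulator: {tf}")
        return out

    def __contains__(self, tf: str) -> bool:
        return any(name == tf for name, _ in self._sources)

    def __len__(self) -> int:
        return len(self.regulators)

    def merged(self) -> dict[str, set[str]]:
        return {tf: self.targets_of(tf) for tf in self.regulators}

    def gene_space(self) -> set[str]:
        out: set[str] = set()
        for targets in self._sources.values():
            out |= targets
        return out

    def write_gmt(self, path: Path) -> None:
        """Merged view, one regulator per line, members sorted."""
        with open(path, "w") as fh:
            for tf in self.regulators:
                sources = sorted(
                    {self._meta[k]["source"] for k in self._sources if k[0] == tf}
                )
                desc = ";".join(s for s in sources if s) or "na"
                members = "\t".join(sorted(self.targets_of(tf)))
                fh.write(f"{tf}\t{desc}\t{members}\n")


def read_gmt(path: Path, species: str = "") -> RegulonDB:
    """Parse a GMT file (name, description, members...) into a RegulonDB.

    Duplicate member genes within a line are deduplicated; a line with
    fewer than three fields is a parse error naming the line number.
    """
    db = RegulonDB()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, members...)"
                )
            name, desc = fields[0], fields[1]
            members = [f.strip() for f in fields[2:] if f.strip()]
            db.add(name, members, species=species, source=desc)
    return db


def write_gmt(sets: Mapping[str, Iterable[str]], path: Path, desc: str = "na") -> None:
    """Write a plain name → members mapping as GMT."""
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write(f"{name}\t{desc}\t" + "\t".join(sorted(set(sets[name]))) + "\n")


# ---------------------------------------------------------------------------
# enrichment of regulators among the DEGs


def regulator_enrichment(
    db: RegulonDB,
    deg_set: Iterable[str],
    universe: Iterable[str],
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per regulator.

    For each TF the regulon is first intersected with ``universe``;
    the p-value is P(X >= k) for k = |regulon ∩ deg_set| drawn from a
    hypergeometric(N=|universe|, m=|regulon ∩ universe|, n=|deg_set|).
    Benjamini–Hochberg q-values are reported alongside, but the default
    decision column ``enriched`` uses raw p < ``p_threshold`` (the
    standard regulon-screen convention).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    deg = set(deg_set) & universe
    n = len(deg)
    N = len(universe)
    rows = []
    for tf in db.regulators:
        regulon = db.targets_of(tf) & universe
        m = len(regulon)
        k = len(regulon & deg)
        p = float(sps.hypergeom.sf(k - 1, N, m, n)) if m else 1.0
        rows.append((tf, m, k, p))
    out = pd.DataFrame(rows, columns=["tf", "regulon_size", "overlap", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    out["enriched"] = out["p"] < p_threshold
    return out.sort_values(["p", "tf"]).reset_index(drop=True)


def filter_edges_by_expression(
    db: RegulonDB,
    consensus: ConsensusTable,
    fc_threshold: float = 1.5,
    regulators: Iterable[str] | None = None,
) -> list[tuple[str, str]]:
    """Keep TF→target edges whose target is an expression-responsive DEG.

    An edge survives iff the target's consensus direction is up or down
    and its max |linear FC| across comparisons is >= ``fc_threshold``.
    """
    lfc = np.log2(fc_threshold) if np.isfinite(fc_threshold) else np.inf
    directions = consensus.directions()
    maxfc = consensus.max_abs_log2fc()
    responsive = set(
        directions.index[(directions != "none") & (maxfc >= lfc)]
    )
    tfs = sorted(regulators) if regulators is not None else db.regulators
    edges = []
    for tf in tfs:
        for g in sorted(db.targets_of(tf) & responsive):
            edges.append((tf, g))
    return edges


def build_grn(
    enriched_tfs: Iterable[str],
    edges: Iterable[tuple[str, str]],
    consensus: ConsensusTable,
) -> nx.DiGraph:
    """Assemble the directed GRN from enriched regulators and kept edges.

    Nodes are the enriched TFs plus their surviving targets; every node
    carries ``direction`` (up/down/none, from the consensus table) and an
    ``is_tf`` flag; only edges whose source is an enriched TF are kept.
    """
    enriched = set(enriched_tfs)
    directions = consensus.directions()
    g = nx.DiGraph()
    for tf in sorted(enriched):
        g.add_node(tf, is_tf=True, direction=directions.get(tf, "none"))
    for tf, target in edges:
        if tf not in enriched:
            continue
        if target not in g:
            g.add_node(
                target,
                is_tf=target in enriched,
                direction=directions.get(target, "none"),
            )
        g.add_edge(tf, target)
    return g


def common_targets(
    tf_names: Sequence[str], db: RegulonDB, gene_set: Iterable[str] | None = None
) -> set[str]:
    """Intersection of the named TFs' regulons, restricted to ``gene_set``.

    Typically used with the DEG list to reproduce shared-target counts of
    co-operating regulators (e.g. the common Hnf4a/Foxa2 targets, or the
    common targets of the four PRC2 members).
    """
    unknown = [tf for tf in tf_names if tf not in db]
    if unknown:
        raise KeyError(f"unknown regulators: {unknown}")
    if not tf_names:
        return set()
    out = db.targets_of(tf_names[0])
    for tf in tf_names[1:]:
        out &= db.targets_of(tf)
    if gene_set is not None:
        out &= set(gene_set)
    return out


@dataclass(frozen=True)
class DirectionComposition:
    n_up: int
    n_down: int
    pct_up: float
    pct_down: float
    p_enrichment: float


def direction_composition(
    gene_set: Iterable[str], consensus: ConsensusTable
) -> DirectionComposition:
    """Up/down composition of a called gene set vs the DEG background.

    Percentages are over the called (up+down) members of ``gene_set``.
    The enrichment p is a one-sided Fisher exact test for the set being
    more up-skewed than the remaining DEG background (2x2: in-set /
    out-of-set × up / down).
    """
    gene_set = set(gene_set)
    directions = consensus.directions()
    in_up = int(((directions == "up") & directions.index.isin(gene_set)).sum())
    in_down = int(((directions == "down") & directions.index.isin(gene_set)).sum())
    if in_up + in_down == 0:
        raise ValueError("gene_set contains no called DEGs; composition undefined")
    bg_up, bg_down, _ = consensus.counts()
    out_up, out_down = bg_up - in_up, bg_down - in_down
    _, p = sps.fisher_exact(
        [[in_up, in_down], [out_up, out_down]], alternative="greater"
    )
    total = in_up + in_down
    return DirectionComposition(
        n_up=in_up,
        n_down=in_down,
        pct_up=100.0 * in_up / total,
        pct_down=100.0 * in_down / total,
        p_enrichment=float(p),
    )


def cross_species_concordance(
    tf: str | None,
    db: RegulonDB,
    consensus_a: ConsensusTable,
    consensus_b: ConsensusTable,
    ortholog_map: Mapping[str, str],
    targets: Iterable[str] | None = None,
) -> tuple[float, int]:
    """Fraction of a TF's targets with the same DE direction in two species.

    Evaluated over targets that are called (up or down) in *both* species
    after mapping through ``ortholog_map`` (species-A symbol → species-B
    symbol).  Pass ``targets`` explicitly to evaluate an arbitrary gene
    set instead of a regulon.  Returns (fraction, evaluated-set size).
    """
    if targets is None:
        if tf is None:
            raise ValueError("need a regulator name or an explicit target set")
        targets = db.targets_of(tf)
    dir_a = consensus_a.directions()
    dir_b = consensus_b.directions()
    n_same = n_eval = 0
    for g in targets:
        h = ortholog_map.get(g)
        if h is None:
            continue
        da = dir_a.get(g, "none")
        db_ = dir_b.get(h, "none")
        if da == "none" or db_ == "none":
            continue
        n_eval += 1
        n_same += int(da == db_)
    if n_eval == 0:
        raise ValueError("no targets are called in both species")
    return n_same / n_eval, n_eval


def write_sif(graph: nx.DiGraph, path: Path, interaction: str = "regulates") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(graph.edges):
            fh.write(f"{a}\t{interaction}\t{b}\n")
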