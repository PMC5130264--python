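"""End-to-end orchestration: consensus DEGs → GRN → centrality → complexes.

``run_pipeline`` executes the full analysis from a plain config, writes
every intermediate table under the output directory, and records a
manifest (parameters, seed, checksums) so a rerun with the same inputs
is byte-identical.  ``summary_report`` prints the headline composition
statistics of any consensus table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, network_analysis, ppi_modules, regulon_grn
from .deg_consensus import ConsensusTable, call_detfs, consensus_from_datasets
from .synthetic_data import read_expression_dataset

log = logging.getLogger("reprognet")

__all__ = ["RunConfig", "run_pipeline", "summary_report", "enrichment_universe"]


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    input_dir: str
    output_dir: str
    regulon_gmt: str = "regulons.gmt"
    ppi_tsv: str = "ppi.tsv"
    genesets_gmt: str | None = None
    p_threshold: float = 0.05
    fc_threshold: float = 1.5
    min_present: int = 4
    min_agree: int = 4
    detf_fc_threshold: float = 1.5
    detf_min_agree: int = 3
    enrichment_p: float = 0.05
    ppi_confidence: float = 0.7
    vwp: float = 0.2
    min_complex_score: float = 2.0
    include_regulators: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("p_threshold", "enrichment_p"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.fc_threshold < 1 or self.detf_fc_threshold < 1:
            raise ValueError("fold-change thresholds must be >= 1 (linear scale)")
        if not 0 <= self.vwp < 1:
            raise ValueError("vwp must be in [0, 1)")
        if not 0 <= self.ppi_confidence <= 1:
            raise ValueError("ppi_confidence must be in [0, 1]")
        indir = Path(self.input_dir)
        if not indir.is_dir():
            raise FileNotFoundError(f"input_dir not found: {indir}")
        for name in (self.regulon_gmt, self.ppi_tsv):
            if name and not (indir / name).is_file():
                raise FileNotFoundError(f"missing input file: {indir / name}")
        if self.genesets_gmt and not (indir / self.genesets_gmt).is_file():
            raise FileNotFoundError(f"missing input file: {indir / self.genesets_gmt}")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def enrichment_universe(
    consensus: ConsensusTable, db: regulon_grn.RegulonDB, min_present: int
) -> set[str]:
    """Genes assayed in enough comparisons and known to the regulon DB.

    Restricting the background to genes that *could* have been both
    measured and annotated avoids inflating enrichment with genes the
    binding-site database never covers.
    """
    measured = set(
        consensus.table.index[consensus.table["n_present"] >= min_present]
    )
    return measured & (db.gene_space() | set(db.regulators))


def summary_report(
    consensus: ConsensusTable,
    detf_table: pd.DataFrame | None = None,
    core_network=None,
    complexes=None,
    compositions: dict[str, regulon_grn.DirectionComposition] | None = None,
) -> tuple[str, dict]:
    """Headline composition statistics as text plus a machine-readable dict.

    Percentages are rounded half-up to integers; exact counts are always
    printed so independent rounding of up%/down% is auditable.
    """
    n_up, n_down, total = consensus.counts()
    stats: dict = {
        "deg_total": total,
        "deg_up": n_up,
        "deg_down": n_down,
        "deg_pct_up": _round_half_up(100.0 * n_up / total) if total else 0,
        "deg_pct_down": _round_half_up(100.0 * n_down / total) if total else 0,
    }
    lines = [
        f"{total} DEGs; {stats['deg_pct_up']}% up, {stats['deg_pct_down']}% down "
        f"({n_up} up / {n_down} down)"
    ]
    if detf_table is not None:
        d_up = int((detf_table["detf_call"] == "DETF_up").sum())
        d_down = int((detf_table["detf_call"] == "DETF_down").sum())
        stats.update(detf_total=d_up + d_down, detf_up=d_up, detf_down=d_down)
        lines.append(f"{d_up + d_down} DE-TFs ({d_up} up / {d_down} down)")
    if core_network is not None:
        stats.update(
            core_nodes=core_network.number_of_nodes(),
            core_edges=core_network.number_of_edges(),
        )
        lines.append(
            f"core TF-TF network: {stats['core_nodes']} nodes, "
            f"{stats['core_edges']} edges"
        )
    if complexes is not None:
        stats["n_significant_complexes"] = len(complexes)
        lines.append(f"{len(complexes)} protein complexes above the score filter")
    if compositions:
        for name, comp in compositions.items():
            lines.append(
                f"{name}: {comp.n_up + comp.n_down} called targets, "
                f"{_round_half_up(comp.pct_up)}% up / "
                f"{_round_half_up(comp.pct_down)}% down "
                f"(enrichment p = {comp.p_enrichment:.3g})"
            )
            stats[f"composition:{name}"] = asdict(comp)
    return "\n".join(lines) + "\n", stats


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the artifacts under ``output_dir``.

    Returns the in-memory results keyed by stage name.
    """
    config.validate()
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- stage 1: per-comparison stats + consensus vote -------------------
    matrices = sorted(indir.glob("*_expression.tsv"))
    if not matrices:
        raise FileNotFoundError(f"no *_expression.tsv matrices in {indir}")
    datasets = []
    for m in matrices:
        cfg = m.with_name(m.name.replace("_expression.tsv", "_comparison.cfg"))
        if not cfg.is_file():
            raise FileNotFoundError(f"missing comparison config for {m}")
        datasets.append(read_expression_dataset(m, cfg))
    primary = [d for d in datasets if d.species != "human"] or datasets
    log.info("deg_consensus: %d comparisons in", len(primary))
    consensus = consensus_from_datasets(
        primary,
        p_threshold=config.p_threshold,
        fc_threshold=config.fc_threshold,
        min_present=config.min_present,
        min_agree=config.min_agree,
    )
    consensus.to_tsv(outdir / "consensus.tsv")
    n_up, n_down, total = consensus.counts()
    log.info("deg_consensus: %d DEGs out (%d up / %d down)", total, n_up, n_down)

    # --- stage 2: DE-TF calls + regulator enrichment + GRN ----------------
    db = regulon_grn.read_gmt(indir / config.regulon_gmt)
    detf = call_detfs(
        consensus,
        db.regulators,
        fc_threshold=config.detf_fc_threshold,
        min_agree=config.detf_min_agree,
    )
    detf.to_csv(outdir / "detf.tsv", sep="\t")
    detf_set = set(detf.index[detf["detf_call"] != "none"])
    universe = enrichment_universe(consensus, db, config.min_present)
    enrichment = regulon_grn.regulator_enrichment(
        db, consensus.deg_genes(), universe, p_threshold=config.enrichment_p
    )
    enrichment.to_csv(outdir / "regulator_enrichment.tsv", sep="\t", index=False)
    enriched = set(enrichment.loc[enrichment["enriched"], "tf"])
    enriched |= set(config.include_regulators) & set(db.regulators)
    log.info(
        "regulon_grn: %d/%d regulators enriched (p < %g)",
        len(enriched), len(db), config.enrichment_p,
    )
    edges = regulon_grn.filter_edges_by_expression(
        db, consensus, fc_threshold=config.fc_threshold, regulators=sorted(enriched)
    )
    grn = regulon_grn.build_grn(enriched, edges, consensus)
    regulon_grn.write_sif(grn, outdir / "grn_edges.sif")
    pd.DataFrame(
        [
            {"node": n, "is_tf": a["is_tf"], "direction": a["direction"]}
            for n, a in sorted(grn.nodes(data=True))
        ]
    ).to_csv(outdir / "grn_nodes.tsv", sep="\t", index=False)
    log.info("regulon_grn: GRN with %d nodes / %d edges", grn.number_of_nodes(), grn.number_of_edges())

    # --- stage 3: centrality + core TF-TF network -------------------------
    centrality = network_analysis.degree_centrality(grn)
    network_analysis.write_centrality_tsv(centrality, outdir / "centrality.tsv")
    core = network_analysis.core_tf_network(grn, detf_set & set(grn.nodes))
    regulon_grn.write_sif(core, outdir / "core_network.sif")

    # --- stage 4: PPI networks + complexes --------------------------------
    ppi_table = pd.read_csv(indir / config.ppi_tsv, sep="\t")
    complexes_by_evidence = {}
    for evidence in ("validated_only", "all"):
        g = ppi_modules.load_ppi(
            ppi_table,
            min_confidence=config.ppi_confidence,
            evidence_filter=evidence,
        )
        found = ppi_modules.mcode(g, vwp=config.vwp)
        kept = ppi_modules.filter_complexes(found, config.min_complex_score)
        ppi_modules.write_complexes_tsv(
            kept, outdir / f"complexes_{evidence}.tsv"
        )
        complexes_by_evidence[evidence] = kept
        log.info(
            "ppi_modules[%s]: %d-node graph, %d complexes (%d above score %g)",
            evidence, g.number_of_nodes(), len(found), len(kept),
            config.min_complex_score,
        )

    # --- stage 5: clustering of DEG fold-change profiles ------------------
    deg_genes = sorted(consensus.deg_genes())
    gene_tree = None
    if len(deg_genes) >= 2:
        profile = consensus.log2fc_matrix().loc[deg_genes]
        gene_tree = clustering.hierarchical_cluster(profile, axis="genes")
        gene_tree.write_merge_table(outdir / "gene_tree_merges.tsv")
        clustering.write_cdt(profile, outdir / "deg_profiles.cdt", gene_tree=gene_tree)
        clustering.write_gtr(gene_tree, outdir / "gene_tree.gtr")

    # --- stage 6: optional gene-set enrichment of the DEGs ----------------
    ora_table = None
    if config.genesets_gmt:
        from .enrichment_stats import ora

        collection = regulon_grn.read_gmt(indir / config.genesets_gmt).merged()
        ora_universe = set(consensus.table.index[consensus.table["n_present"] >= config.min_present])
        query = consensus.deg_genes() & ora_universe
        ora_table = ora(query, collection, ora_universe)
        ora_table.to_csv(outdir / "ora.tsv", sep="\t", index=False)

    # --- report + manifest ------------------------------------------------
    text, stats = summary_report(
        consensus,
        detf_table=detf,
        core_network=core,
        complexes=complexes_by_evidence["validated_only"],
    )
    (outdir / "summary.txt").write_text(text)
    artifacts = sorted(p for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "parameters": asdict(config),
        "stats": stats,
        "checksums": {p.name: _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "consensus": consensus,
        "detf": detf,
        "enrichment": enrichment,
        "grn": grn,
        "centrality": centrality,
        "core": core,
        "complexes": complexes_by_evidence,
        "gene_tree": gene_tree,
        "ora": ora_table,
        "manifest": manifest,
        "summary": text,
    }
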