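"""Per-comparison differential expression and cross-dataset consensus calls.

Several independent expression comparisons of the same cellular transition
(e.g. fibroblast vs induced hepatocyte, assayed on different platforms by
different labs) are tested one at a time — log2 fold change plus a two-sample
two-sample t-test — and a gene is accepted as a consensus differentially
expressed gene (DEG) only when a minimum number of comparisons agree on a
significant change in the same direction.  Transcription factors get a
separate, fold-change-only rule (DE-TFs), because modest expression shifts
in a regulator can still rewire its downstream program.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ExpressionDataset",
    "ConsensusTable",
    "compute_gene_stats",
    "call_per_comparison",
    "consensus_call",
    "consensus_from_datasets",
    "call_detfs",
]

#: smallest representable positive double; used for the degenerate
#: zero-variance, unequal-means case so the gene still sorts to the top.
_P_FLOOR = float(np.nextafter(0.0, 1.0))


@dataclass
class ExpressionDataset:
    """One dataset's log2 expression matrix plus its comparison definition.

    Parameters
    ----------
    values
        Genes x samples matrix of log2 expression.  Duplicate gene ids are
        tolerated (probe-level leftovers); they are collapsed to the row
        with the largest ``|log2fc|`` when statistics are computed.
    test_samples, control_samples
        Disjoint sample-id groups, each of size >= 2 (a variance estimate
        is needed for the p-value stage).
    """

    values: pd.DataFrame
    test_samples: tuple[str, ...]
    control_samples: tuple[str, ...]
    dataset_id: str
    species: str = "mouse"

    def __post_init__(self) -> None:
        self.test_samples = tuple(self.test_samples)
        self.control_samples = tuple(self.control_samples)
        if set(self.test_samples) & set(self.control_samples):
            raise ValueError("test and control sample sets must be disjoint")
        if len(self.test_samples) < 2 or len(self.control_samples) < 2:
            raise ValueError(
                "each group needs >= 2 replicates for the p-value stage"
            )
        missing = [
            s
            for s in self.test_samples + self.control_samples
            if s not in self.values.columns
        ]
        if missing:
            raise ValueError(f"samples not in matrix: {missing}")
        sub = self.values[list(self.test_samples + self.control_samples)]
        if not np.isfinite(sub.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.values.index.unique()


def compute_gene_stats(
    dataset: ExpressionDataset, method: str = "student"
) -> pd.DataFrame:
    """Two-sample t-test and log2 fold change per gene of one comparison.

    Returns a frame indexed by gene with columns ``log2fc`` and ``p_value``.
    ``log2fc = mean(test) - mean(control)`` (the data are log2, so the
    difference of means *is* the log2 fold change).

    ``method`` is ``student`` (pooled variance, the default: exact and
    well calibrated at 2–4 replicates when group variances are
    comparable) or ``welch`` (unequal variances; noticeably conservative
    at these group sizes because of the Satterthwaite df estimate).

    Degenerate rows (zero variance in both groups) get p = 1 when the
    means are equal and the smallest positive double otherwise.
    """
    if method not in {"student", "welch"}:
        raise ValueError("method must be 'student' or 'welch'")
    a = dataset.values[list(dataset.test_samples)].to_numpy(dtype=float)
    b = dataset.values[list(dataset.control_samples)].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    import warnings as _warnings

    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        # near-constant rows trigger precision warnings; their p-values
        # are overwritten by the degenerate-case handling below
        _warnings.simplefilter("ignore", RuntimeWarning)
        p = sps.ttest_ind(a, b, axis=1, equal_var=(method == "student")).pvalue
    p = np.asarray(p, dtype=float)
    both_flat = (a.var(axis=1, ddof=1) == 0.0) & (b.var(axis=1, ddof=1) == 0.0)
    p[both_flat & (log2fc == 0.0)] = 1.0
    p[both_flat & (log2fc != 0.0)] = _P_FLOOR
    out = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p}, index=dataset.values.index
    )
    if out.index.has_duplicates:
        # collapse duplicated ids to the most responsive row
        out = (
            out.assign(_a=out["log2fc"].abs())
            .sort_values("_a", ascending=False, kind="stable")
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_a")
        )
    return out.reindex(dataset.values.index.unique())


def call_per_comparison(
    stats: pd.DataFrame,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.Series:
    """Classify each gene of one comparison as ``up``/``down``/``none``.

    ``fc_threshold`` is on the linear scale: *up* requires
    ``p < p_threshold`` and linear FC >= fc_threshold, *down* requires
    linear FC <= 1/fc_threshold.
    """
    if p_threshold <= 0 or fc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    lfc = np.log2(fc_threshold)
    sig = stats["p_value"] < p_threshold
    call = pd.Series("none", index=stats.index, dtype=object)
    call[sig & (stats["log2fc"] >= lfc)] = "up"
    call[sig & (stats["log2fc"] <= -lfc)] = "down"
    return call


@dataclass
class ConsensusTable:
    """Cross-comparison record per gene with the final consensus calls.

    ``table`` is indexed by gene and carries, per comparison ``c``, the
    columns ``log2fc:c``, ``p:c`` and ``call:c`` (NaN / ``absent`` where
    the gene was not measured on that platform), plus the vote summaries
    ``n_present``, ``n_sig_up``, ``n_sig_down``, the DEG ``call`` and the
    ``detf_call`` (filled by :func:`call_detfs`).
    """

    table: pd.DataFrame
    comparisons: tuple[str, ...]
    params: dict = field(default_factory=dict)

    # -- views -------------------------------------------------------------
    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def deg_genes(self) -> set[str]:
        return set(self.table.index[self.table["call"] != "none"])

    def directions(self) -> pd.Series:
        """Per-gene direction: ``up``/``down`` for called DEGs else ``none``."""
        return self.calls.map(
            {"DEG_up": "up", "DEG_down": "down"}
        ).fillna("none")

    def counts(self) -> tuple[int, int, int]:
        """(n_up, n_down, total called)."""
        n_up = int((self.table["call"] == "DEG_up").sum())
        n_down = int((self.table["call"] == "DEG_down").sum())
        return n_up, n_down, n_up + n_down

    def log2fc_matrix(self) -> pd.DataFrame:
        """Genes x comparisons log2FC matrix (NaN where absent)."""
        cols = [f"log2fc:{c}" for c in self.comparisons]
        m = self.table[cols].copy()
        m.columns = list(self.comparisons)
        return m

    def max_abs_log2fc(self) -> pd.Series:
        return self.log2fc_matrix().abs().max(axis=1)

    # -- io ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "ConsensusTable":
        table = pd.read_csv(path, sep="\t", index_col="gene")
        comparisons = tuple(
            c.split(":", 1)[1] for c in table.columns if c.startswith("log2fc:")
        )
        return cls(table=table, comparisons=comparisons)


def consensus_call(
    per_comparison: Mapping[str, pd.DataFrame],
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    min_present: int = 4,
    min_agree: int = 4,
) -> ConsensusTable:
    """Combine per-comparison statistics into consensus DEG calls.

    Two separate vote counts decide a call.  A gene is ``DEG_up`` iff

    * it is measured in >= ``min_present`` comparisons,
    * at least ``min_agree`` comparisons call it significant (either
      direction) — the gene responds reproducibly,
    * at least ``min_agree`` of its measured comparisons show a positive
      fold change, with positives strictly outnumbering negatives — the
      same pattern recurs, and
    * significant up-calls strictly outnumber significant down-calls —
      the significance evidence does not contradict the direction
      (exact ties yield no call).

    Symmetric for down.  Counting the "same pattern" votes over the
    direction of change (fold-change sign) rather than only over
    significant calls keeps genes whose effect is consistent but
    narrowly misses significance on a platform or two — the behaviour a
    meta-analysis of underpowered 2–4-replicate comparisons needs.
    """
    comparisons = tuple(per_comparison)
    if min_agree > len(comparisons):
        raise ValueError(
            f"min_agree={min_agree} exceeds the {len(comparisons)} comparisons"
        )
    genes = sorted(set().union(*(set(s.index) for s in per_comparison.values())))
    blocks = {}
    n_present = pd.Series(0, index=genes)
    n_up = pd.Series(0, index=genes)
    n_down = pd.Series(0, index=genes)
    n_pat_up = pd.Series(0, index=genes)
    n_pat_down = pd.Series(0, index=genes)
    for cid, stats in per_comparison.items():
        s = stats.reindex(genes)
        call = pd.Series("absent", index=genes, dtype=object)
        present = s["p_value"].notna()
        call[present] = call_per_comparison(
            s[present], p_threshold=p_threshold, fc_threshold=fc_threshold
        )
        blocks[f"log2fc:{cid}"] = s["log2fc"]
        blocks[f"p:{cid}"] = s["p_value"]
        blocks[f"call:{cid}"] = call
        n_present += present.astype(int)
        n_up += (call == "up").astype(int)
        n_down += (call == "down").astype(int)
        n_pat_up += (present & (s["log2fc"] > 0)).astype(int)
        n_pat_down += (present & (s["log2fc"] < 0)).astype(int)
    table = pd.DataFrame(blocks, index=genes)
    table["n_present"] = n_present
    table["n_sig_up"] = n_up
    table["n_sig_down"] = n_down
    table["n_pattern_up"] = n_pat_up
    table["n_pattern_down"] = n_pat_down
    n_sig = n_up + n_down
    eligible = (n_present >= min_present) & (n_sig >= min_agree)
    call = pd.Series("none", index=genes, dtype=object)
    call[
        eligible
        & (n_pat_up >= min_agree) & (n_pat_up > n_pat_down)
        & (n_up > n_down)
    ] = "DEG_up"
    call[
        eligible
        & (n_pat_down >= min_agree) & (n_pat_down > n_pat_up)
        & (n_down > n_up)
    ] = "DEG_down"
    table["call"] = call
    table["detf_call"] = "none"
    return ConsensusTable(
        table=table,
        comparisons=comparisons,
        params=dict(
            p_threshold=p_threshold,
            fc_threshold=fc_threshold,
            min_present=min_present,
            min_agree=min_agree,
        ),
    )


def consensus_from_datasets(
    datasets: Sequence[ExpressionDataset], method: str = "student", **kwargs
) -> ConsensusTable:
    """Convenience: compute per-comparison stats then the consensus vote."""
    per = {d.dataset_id: compute_gene_stats(d, method=method) for d in datasets}
    return consensus_call(per, **kwargs)


def call_detfs(
    consensus: ConsensusTable,
    tf_list: Iterable[str],
    fc_threshold: float = 1.5,
    min_agree: int = 3,
) -> pd.DataFrame:
    """Differentially expressed transcription factor (DE-TF) calls.

    A TF is ``DETF_up`` iff in >= ``min_agree`` comparisons its linear
    fold change is >= ``fc_threshold`` in the same direction (strict
    majority over the opposite direction).  No p-value filter is applied:
    small expression shifts in a regulator are biologically consequential,
    so the rule is fold-change-only by design.

    Side effect: fills the ``detf_call`` column of ``consensus.table``.

    Returns a frame indexed by TF with ``n_fc_up``, ``n_fc_down`` and
    ``detf_call``.
    """
    tfs = sorted(set(tf_list))
    lfc = np.log2(fc_threshold)
    m = consensus.log2fc_matrix()
    rows = []
    for tf in tfs:
        if tf in m.index:
            v = m.loc[tf]
            nu = int((v >= lfc).sum())
            nd = int((v <= -lfc).sum())
        else:
            nu = nd = 0
        call = "none"
        if nu >= min_agree and nu > nd:
            call = "DETF_up"
        elif nd >= min_agree and nd > nu:
            call = "DETF_down"
        rows.append((tf, nu, nd, call))
    out = pd.DataFrame(
        rows, columns=["tf", "n_fc_up", "n_fc_down", "detf_call"]
    ).set_index("tf")
    hits = out.index[out["detf_call"] != "none"]
    present = [t for t in hits if t in consensus.table.index]
    consensus.table.loc[present, "detf_call"] = out.loc[present, "detf_call"]
    return out
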