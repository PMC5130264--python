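import numpy as np
import pandas as pd
import pytest

import reprognet as rn
from reprognet.deg_consensus import ConsensusTable


@pytest.fixture(scope="session")
def default_world():
    """Default synthetic study: regulons, ground truth, datasets, consensus."""
    cfg = rn.SimulationConfig()
    db, truth = rn.generate_regulon_db(cfg)
    datasets = rn.generate_datasets(cfg, truth)
    consensus = rn.consensus_from_datasets(datasets)
    return {
        "config": cfg,
        "db": db,
        "truth": truth,
        "datasets": datasets,
        "consensus": consensus,
    }


def make_stats(gene_to_lfc_p):
    """Build a per-comparison statistics frame from {gene: (log2fc, p)}."""
    genes = sorted(gene_to_lfc_p)
    return pd.DataFrame(
        {
            "log2fc": [gene_to_lfc_p[g][0] for g in genes],
            "p_value": [gene_to_lfc_p[g][1] for g in genes],
        },
        index=genes,
    )


def make_consensus(n_up, n_down, n_none=0, lfc=2.0):
    """Minimal consensus table with the given final call counts."""
    genes, calls, lfcs = [], [], []
    for i in range(n_up):
        genes.append(f"u{i:04d}"); calls.append("DEG_up"); lfcs.append(lfc)
    for i in range(n_down):
        genes.append(f"d{i:04d}"); calls.append("DEG_down"); lfcs.append(-lfc)
    for i in range(n_none):
        genes.append(f"n{i:04d}"); calls.append("none"); lfcs.append(0.0)
    table = pd.DataFrame(
        {
            "log2fc:c1": lfcs,
            "p:c1": 1e-4,
            "call:c1": ["up" if c == "DEG_up" else "down" if c == "DEG_down" else "none" for c in calls],
            "n_present": 7,
            "n_sig_up": [4 if c == "DEG_up" else 0 for c in calls],
            "n_sig_down": [4 if c == "DEG_down" else 0 for c in calls],
            "call": calls,
            "detf_call": "none",
        },
        index=genes,
    )
    return ConsensusTable(table=table, comparisons=("c1",))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
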