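"""Per-comparison statistics and the cross-dataset consensus vote."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import reprognet as rn
from reprognet.deg_consensus import ExpressionDataset

from conftest import make_stats


def _dataset(test_rows, control_rows, gene_ids=None):
    test_rows = np.atleast_2d(test_rows)
    control_rows = np.atleast_2d(control_rows)
    genes = gene_ids or [f"g{i}" for i in range(test_rows.shape[0])]
    t_cols = [f"t{i}" for i in range(test_rows.shape[1])]
    c_cols = [f"c{i}" for i in range(control_rows.shape[1])]
    values = pd.DataFrame(
        np.hstack([test_rows, control_rows]), index=genes, columns=t_cols + c_cols
    )
    return ExpressionDataset(values, tuple(t_cols), tuple(c_cols), "D1")


class TestGeneStats:
    def test_identical_groups_give_null_result(self):
        s = rn.compute_gene_stats(_dataset([5, 5, 5], [5, 5, 5]))
        assert s.loc["g0", "log2fc"] == 0.0
        assert s.loc["g0", "p_value"] == 1.0

    def test_log2fc_is_difference_of_log_means(self):
        s = rn.compute_gene_stats(_dataset([6, 6], [5, 5]))
        assert s.loc["g0", "log2fc"] == pytest.approx(1.0)  # linear FC = 2
        assert 0.0 < s.loc["g0", "p_value"] < 1e-200  # degenerate: flagged minimal

    def test_matches_scipy_on_random_data(self, rng):
        a = rng.normal(8, 1, (50, 3))
        b = rng.normal(8, 1, (50, 3))
        ds = _dataset(a, b)
        s = rn.compute_gene_stats(ds, method="welch")
        expected = sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        np.testing.assert_allclose(s["p_value"], expected)

    def test_duplicate_gene_ids_keep_strongest_response(self):
        ds = _dataset(
            [[9, 9, 9], [5.5, 5.5, 5.5]], [[5, 5, 5], [5, 5, 5]],
            gene_ids=["gx", "gx"],
        )
        s = rn.compute_gene_stats(ds)
        assert len(s) == 1
        assert s.loc["gx", "log2fc"] == pytest.approx(4.0)

    def test_invalid_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            rn.compute_gene_stats(_dataset([5, 5], [5, 5]), method="wilcoxon")

    @pytest.mark.parametrize(
        "test,control,err",
        [
            ((["t0"], ["t0", "c0"]), None, "disjoint"),
            ((["t0"], ["c0", "c1"]), None, ">= 2 replicates"),
        ],
    )
    def test_dataset_validation(self, test, control, err):
        values = pd.DataFrame(
            [[5.0, 5.0, 5.0, 5.0]], index=["g0"], columns=["t0", "t1", "c0", "c1"]
        )
        with pytest.raises(ValueError, match=err):
            ExpressionDataset(values, tuple(test[0]), tuple(test[1]), "D")

    def test_nonfinite_values_rejected(self):
        values = pd.DataFrame(
            [[5.0, np.nan, 5.0, 5.0]], index=["g0"], columns=["t0", "t1", "c0", "c1"]
        )
        with pytest.raises(ValueError, match="finite"):
            ExpressionDataset(values, ("t0", "t1"), ("c0", "c1"), "D")


class TestPerComparisonCall:
    @pytest.mark.parametrize(
        "log2fc,p,expected",
        [
            (1.0, 0.001, "up"),        # 2-fold increase, significant
            (1.0, 0.2, "none"),        # fails the p filter
            (np.log2(1 / 1.6), 0.01, "down"),  # 1.6-fold decrease
            (0.3, 0.001, "none"),      # significant but below 1.5-fold
        ],
    )
    def test_rule(self, log2fc, p, expected):
        calls = rn.call_per_comparison(make_stats({"g": (log2fc, p)}))
        assert calls["g"] == expected

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            rn.call_per_comparison(make_stats({"g": (1, 0.01)}), p_threshold=0)


def _seven_comparisons(gene_rows):
    """gene_rows: {gene: [(lfc, p) or None per comparison]}"""
    out = {}
    for ci in range(7):
        d = {}
        for g, row in gene_rows.items():
            if row[ci] is not None:
                d[g] = row[ci]
        out[f"c{ci}"] = make_stats(d)
    return out


SIG_UP = (2.0, 0.001)
SIG_DOWN = (-2.0, 0.001)
FLAT = (0.05, 0.9)
FLAT_NEG = (-0.05, 0.9)


class TestConsensusVote:
    def test_up_in_four_of_seven_is_deg(self):
        per = _seven_comparisons({"g": [SIG_UP] * 4 + [FLAT_NEG] * 3})
        assert rn.consensus_call(per).calls["g"] == "DEG_up"

    def test_split_vote_gives_no_call(self):
        per = _seven_comparisons({"g": [SIG_UP] * 3 + [SIG_DOWN] * 3 + [FLAT]})
        assert rn.consensus_call(per).calls["g"] == "none"

    def test_gene_on_too_few_platforms_never_called(self):
        per = _seven_comparisons({"g": [SIG_UP] * 3 + [None] * 4,
                                  "anchor": [FLAT] * 7})
        cons = rn.consensus_call(per)
        assert cons.calls["g"] == "none"
        assert cons.table.loc["g", "n_present"] == 3

    def test_consistent_pattern_rescues_marginal_significance(self):
        # 4 significant + 3 same-direction sub-threshold comparisons
        per = _seven_comparisons({"g": [SIG_UP] * 4 + [(0.4, 0.3)] * 3})
        assert rn.consensus_call(per).calls["g"] == "DEG_up"

    def test_min_agree_exceeding_comparisons_is_error(self):
        per = _seven_comparisons({"g": [SIG_UP] * 7})
        with pytest.raises(ValueError, match="min_agree"):
            rn.consensus_call(per, min_agree=8)

    def test_vote_is_permutation_invariant(self):
        rows = {"g1": [SIG_UP] * 4 + [FLAT] * 3,
                "g2": [SIG_DOWN] * 5 + [SIG_UP] * 2}
        per = _seven_comparisons(rows)
        shuffled = dict(reversed(list(per.items())))
        a = rn.consensus_call(per).calls
        b = rn.consensus_call(shuffled).calls
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_lowering_min_agree_never_removes_a_call(self, rng):
        # random single-direction effect profiles
        per = {}
        genes = [f"g{i}" for i in range(60)]
        signs = {g: rng.choice([-1.0, 1.0]) for g in genes}
        for ci in range(7):
            per[f"c{ci}"] = make_stats(
                {
                    g: (signs[g] * abs(rng.normal(1.5, 0.8)), float(rng.uniform(0, 0.4)))
                    for g in genes
                }
            )
        strict = rn.consensus_call(per, min_agree=5).calls
        loose = rn.consensus_call(per, min_agree=4).calls
        for g in genes:
            if strict[g] != "none":
                assert loose[g] == strict[g]

    def test_counts_sum_to_total(self):
        per = _seven_comparisons({"g1": [SIG_UP] * 5 + [FLAT] * 2,
                                  "g2": [SIG_DOWN] * 6 + [FLAT]})
        n_up, n_down, total = rn.consensus_call(per).counts()
        assert (n_up, n_down, total) == (1, 1, 2)


class TestDetfCall:
    def test_fold_change_only_rule(self):
        # 1.5-fold in three comparisons, no p filter
        rows = {"tf": [(np.log2(1.6), 0.4), (np.log2(1.7), 0.5), (np.log2(1.9), 0.6)]
                + [FLAT] * 4}
        cons = rn.consensus_call(_seven_comparisons(rows))
        detf = rn.call_detfs(cons, ["tf"])
        assert detf.loc["tf", "detf_call"] == "DETF_up"

    def test_below_threshold_everywhere_is_none(self):
        rows = {"tf": [(np.log2(1.4), 0.001)] * 7}
        cons = rn.consensus_call(_seven_comparisons(rows))
        detf = rn.call_detfs(cons, ["tf"])
        assert detf.loc["tf", "detf_call"] == "none"

    def test_empty_tf_list(self):
        cons = rn.consensus_call(_seven_comparisons({"g": [SIG_UP] * 7}))
        assert rn.call_detfs(cons, []).empty

    def test_conflicting_directions_need_strict_majority(self):
        rows = {"tf": [(1.0, 0.5)] * 3 + [(-1.0, 0.5)] * 3 + [FLAT]}
        cons = rn.consensus_call(_seven_comparisons(rows))
        assert rn.call_detfs(cons, ["tf"]).loc["tf", "detf_call"] == "none"


def test_null_simulation_gives_uniform_pvalues():
    """With no true effect the per-comparison p-values are U(0, 1)."""
    rng = np.random.default_rng(5)
    a = rng.normal(8, 0.5, (1000, 3))
    b = rng.normal(8, 0.5, (1000, 3))
    s = rn.compute_gene_stats(_dataset(a, b))
    assert sps.kstest(s["p_value"], "uniform").pvalue > 0.01
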