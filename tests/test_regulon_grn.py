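"""Regulon database handling, enrichment statistics and GRN assembly."""

import math

import networkx as nx
import numpy as np
import pytest

import reprognet as rn
from reprognet.regulon_grn import write_gmt

from conftest import make_consensus


class TestGmtIO:
    def test_duplicate_members_deduplicated(self, tmp_path):
        p = tmp_path / "r.gmt"
        p.write_text("HNF4A\tsrc\tA\tB\tA\n")
        db = rn.read_gmt(p)
        assert db.targets_of("HNF4A") == {"A", "B"}

    def test_empty_file(self, tmp_path):
        p = tmp_path / "r.gmt"
        p.write_text("")
        assert len(rn.read_gmt(p)) == 0

    def test_short_line_is_parse_error_with_line_number(self, tmp_path):
        p = tmp_path / "r.gmt"
        p.write_text("OK\tsrc\tA\nBAD\tonlydesc\n")
        with pytest.raises(ValueError, match=":2"):
            rn.read_gmt(p)

    def test_roundtrip_is_identity_on_merged_view(self, tmp_path, default_world):
        db = default_world["db"]
        p = tmp_path / "r.gmt"
        db.write_gmt(p)
        assert rn.read_gmt(p).merged() == db.merged()

    def test_multiple_sources_merge_per_tf(self):
        db = rn.RegulonDB()
        db.add("FOXA2", {"A", "B"}, source="chip1")
        db.add("FOXA2", {"B", "C"}, source="chip2")
        assert db.targets_of("FOXA2") == {"A", "B", "C"}
        assert len(db) == 1


def _tiny_db(universe10):
    db = rn.RegulonDB()
    db.add("TF1", set(universe10[:5]))
    return db


class TestRegulatorEnrichment:
    def test_worked_example_five_over_210(self):
        # |universe|=10, regulon 5, query 4, overlap 4:
        # p = C(5,4)*C(5,0)/C(10,4) = 5/210
        universe = [f"g{i}" for i in range(10)]
        db = _tiny_db(universe)
        res = rn.regulator_enrichment(db, set(universe[:4]), universe)
        assert res.loc[0, "p"] == pytest.approx(5 / 210)

    def test_full_overlap_of_universe_regulon_is_one(self):
        universe = [f"g{i}" for i in range(6)]
        db = rn.RegulonDB()
        db.add("TF1", set(universe))
        res = rn.regulator_enrichment(db, set(universe[:3]), universe)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self, rng):
        # exhaustive tail mass over all overlap values, N <= 20
        for _ in range(25):
            N = int(rng.integers(5, 21))
            m = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"g{i}" for i in range(N)]
            regulon = set(rng.choice(universe, m, replace=False))
            query = set(rng.choice(universe, n, replace=False))
            k = len(regulon & query)
            expected = sum(
                math.comb(m, j) * math.comb(N - m, n - j)
                for j in range(k, min(m, n) + 1)
            ) / math.comb(N, n)
            db = rn.RegulonDB()
            db.add("TF1", regulon)
            res = rn.regulator_enrichment(db, query, universe)
            assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_true_overlap(self):
        universe = [f"g{i}" for i in range(20)]
        db = _tiny_db(universe)
        p_small = rn.regulator_enrichment(db, set(universe[:2]), universe).loc[0, "p"]
        p_large = rn.regulator_enrichment(db, set(universe[:3]), universe).loc[0, "p"]
        assert p_large <= p_small

    def test_empty_universe_is_error(self):
        db = rn.RegulonDB()
        db.add("TF1", {"A"})
        with pytest.raises(ValueError, match="universe"):
            rn.regulator_enrichment(db, set(), [])


class TestEdgeFilterAndAssembly:
    def _setup(self):
        cons = make_consensus(2, 1, n_none=1)  # u0000,u0001 up; d0000 down; n0000 none
        db = rn.RegulonDB()
        db.add("TF1", {"u0000", "d0000", "n0000"})
        db.add("TF2", {"u0001"})
        return cons, db

    def test_uncalled_targets_dropped(self):
        cons, db = self._setup()
        edges = rn.filter_edges_by_expression(db, cons)
        assert ("TF1", "n0000") not in edges
        assert ("TF1", "u0000") in edges and ("TF1", "d0000") in edges

    def test_infinite_threshold_empties_the_network(self):
        cons, db = self._setup()
        assert rn.filter_edges_by_expression(db, cons, fc_threshold=np.inf) == []

    def test_edges_only_from_enriched_tfs(self):
        cons, db = self._setup()
        edges = rn.filter_edges_by_expression(db, cons)
        grn = rn.build_grn({"TF1"}, edges, cons)
        assert all(grn.nodes[a]["is_tf"] for a, _ in grn.edges)
        assert set(grn.successors("TF1")) == {"u0000", "d0000"}
        assert "TF2" not in grn

    def test_no_enriched_tfs_gives_empty_network(self):
        cons, db = self._setup()
        grn = rn.build_grn(set(), rn.filter_edges_by_expression(db, cons), cons)
        assert grn.number_of_nodes() == 0

    def test_node_directions_from_consensus(self):
        cons, db = self._setup()
        grn = rn.build_grn({"TF1"}, rn.filter_edges_by_expression(db, cons), cons)
        assert grn.nodes["u0000"]["direction"] == "up"
        assert grn.nodes["d0000"]["direction"] == "down"


class TestCommonTargets:
    def _db(self):
        db = rn.RegulonDB()
        db.add("A", {"g1", "g2", "g3"})
        db.add("B", {"g2", "g3", "g4"})
        db.add("C", {"g9"})
        return db

    def test_intersection_restricted_to_gene_set(self):
        db = self._db()
        assert rn.common_targets(["A", "B"], db, {"g2", "g9"}) == {"g2"}

    def test_disjoint_regulons_give_empty_set(self):
        assert rn.common_targets(["A", "C"], self._db()) == set()

    def test_single_tf_is_its_regulon(self):
        assert rn.common_targets(["C"], self._db()) == {"g9"}

    def test_order_invariant_and_subset(self):
        db = self._db()
        ab = rn.common_targets(["A", "B"], db)
        assert ab == rn.common_targets(["B", "A"], db)
        assert ab <= db.targets_of("A") and ab <= db.targets_of("B")

    def test_unknown_tf_is_error(self):
        with pytest.raises(KeyError, match="ZZZ"):
            rn.common_targets(["A", "ZZZ"], self._db())


class TestDirectionComposition:
    def test_repressor_module_style_counts(self):
        # 10 up / 58 down -> 14.7% / 85.3%
        cons = make_consensus(10, 58)
        comp = rn.direction_composition(set(cons.table.index), cons)
        assert comp.pct_up == pytest.approx(14.7, abs=0.05)
        assert comp.pct_down == pytest.approx(85.3, abs=0.05)

    def test_deg_background_style_counts(self):
        # 247 up / 424 down -> 36.8% / 63.2% (rounds to the familiar 37/63)
        cons = make_consensus(247, 424)
        comp = rn.direction_composition(set(cons.table.index), cons)
        assert comp.pct_up == pytest.approx(36.8, abs=0.05)
        assert comp.pct_down == pytest.approx(63.2, abs=0.05)
        assert comp.pct_up + comp.pct_down == pytest.approx(100.0)

    def test_set_equal_to_background_is_not_enriched(self):
        cons = make_consensus(30, 50)
        comp = rn.direction_composition(set(cons.table.index), cons)
        assert comp.p_enrichment >= 0.5

    def test_empty_set_is_error(self):
        cons = make_consensus(5, 5)
        with pytest.raises(ValueError, match="composition undefined"):
            rn.direction_composition({"missing"}, cons)


class TestCrossSpeciesConcordance:
    def _pair(self, invert=False):
        cons_a = make_consensus(5, 5)
        cons_b = make_consensus(5, 5)
        # mirror species: same genes upper-cased
        table = cons_b.table.copy()
        table.index = [g.upper() for g in table.index]
        if invert:
            table["call"] = table["call"].map(
                {"DEG_up": "DEG_down", "DEG_down": "DEG_up"}
            )
        cons_b.table = table
        orth = {g: g.upper() for g in cons_a.table.index}
        return cons_a, cons_b, orth

    def test_copied_directions_give_one(self):
        cons_a, cons_b, orth = self._pair()
        frac, n = rn.cross_species_concordance(
            None, rn.RegulonDB(), cons_a, cons_b, orth,
            targets=set(cons_a.table.index),
        )
        assert (frac, n) == (1.0, 10)

    def test_inverted_directions_give_zero(self):
        cons_a, cons_b, orth = self._pair(invert=True)
        frac, _ = rn.cross_species_concordance(
            None, rn.RegulonDB(), cons_a, cons_b, orth,
            targets=set(cons_a.table.index),
        )
        assert frac == 0.0

    def test_zero_evaluable_targets_is_error(self):
        cons_a, cons_b, orth = self._pair()
        with pytest.raises(ValueError, match="called in both"):
            rn.cross_species_concordance(
                None, rn.RegulonDB(), cons_a, cons_b, orth, targets={"absent"}
            )


def test_write_gmt_plain_mapping(tmp_path):
    p = tmp_path / "sets.gmt"
    write_gmt({"s1": {"b", "a"}}, p)
    assert p.read_text() == "s1\tna\ta\tb\n"
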