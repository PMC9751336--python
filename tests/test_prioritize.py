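"""Prioritization cascade: set algebra, filtering, expansion, ranking."""
import numpy as np
import pandas as pd
import pytest

from fibroscore.prioritize import (
    annotate_drugs, build_panel, expand_network, filter_disease_associated,
    intersect_sources, venn_to_json,
)


def gda(rows):
    return pd.DataFrame(rows, columns=["gene_id", "disease", "score"])


def net(rows):
    return pd.DataFrame(rows, columns=["node_a", "node_b", "combined_score"])


class TestIntersectSources:
    def test_worked_three_set_example(self):
        regions = intersect_sources({"A": {"g1", "g2", "g3"}, "B": {"g2", "g3"}, "C": {"g3"}})
        assert regions[("A", "B", "C")] == {"g3"}
        assert regions[("A",)] == {"g1"}
        assert regions[("A", "B")] == {"g2"}
        assert regions[("B",)] == set() and regions[("C",)] == set()

    def test_disjoint_and_identical(self):
        d = intersect_sources({"A": {"x"}, "B": {"y"}})
        assert d[("A", "B")] == set()
        i = intersect_sources({"A": {"x", "y"}, "B": {"x", "y"}})
        assert i[("A", "B")] == {"x", "y"} and i[("A",)] == set()

    def test_region_sizes_sum_to_union(self, rng):
        genes = [f"g{i}" for i in range(40)]
        for _ in range(200):
            sets = {s: set(rng.choice(genes, rng.integers(0, 25), replace=False))
                    for s in ("A", "B", "C")}
            regions = intersect_sources(sets)
            assert sum(len(v) for v in regions.values()) == len(set().union(*sets.values()))

    def test_de_table_input_and_direction_validation(self):
        de = pd.DataFrame({"feature_id": ["a", "b"], "call": ["up", "down"]})
        regions = intersect_sources({}, direction="up", de_by_source={"A": de, "B": de})
        assert regions[("A", "B")] == {"a"}
        with pytest.raises(ValueError, match="direction"):
            intersect_sources({}, direction="sideways", de_by_source={"A": de, "B": de})


class TestDiseaseFilter:
    def test_empty_table(self):
        out = filter_disease_associated({"g1"}, gda([]))
        assert out.genes == []

    def test_non_fibrosis_disease_excluded(self):
        out = filter_disease_associated({"g1"}, gda([("g1", "carcinoma", 0.9)]))
        assert out.genes == []

    def test_min_score_filter_arithmetic(self):
        table = gda([
            ("g1", "cardiac fibrosis", 0.3),
            ("g2", "renal fibrosis", 0.01),
            ("g3", "carcinoma", 0.8),
        ])
        out = filter_disease_associated({"g1", "g2", "g3", "g4", "g5"}, table, min_score=0.05)
        assert out.genes == ["g1"]
        assert out.detail["score"].tolist() == [0.3]


class TestExpandNetwork:
    def test_threshold_is_inclusive_at_070(self):
        network = net([("C", "A", 0.69), ("D", "A", 0.70)])
        out = expand_network({"A"}, {"C", "D"}, network)
        assert out.added == ["D"]

    def test_no_edges_no_expansion(self):
        assert expand_network({"A"}, {"C"}, net([])).added == []

    def test_worked_example_with_outside_node(self):
        network = net([("C", "A", 0.9), ("D", "B", 0.6), ("E", "F", 0.95)])
        out = expand_network({"A", "B"}, {"C", "D", "E"}, network)
        assert out.added == ["C"]
        assert out.partners == {"C": ["A"]}

    def test_candidates_only_ever_added(self):
        network = net([("X", "A", 0.99)])
        assert expand_network({"A"}, {"C"}, network).added == []

    def test_equals_exhaustive_scan_and_monotone(self, rng):
        nodes = [f"n{i}" for i in range(120)]
        for _ in range(20):
            k = int(rng.integers(50, 300))
            a = rng.choice(nodes, k)
            b = rng.choice(nodes, k)
            pairs = sorted({(min(x, y), max(x, y)) for x, y in zip(a, b) if x != y})
            edges = net([(x, y, s) for (x, y), s in
                         zip(pairs, rng.uniform(0, 1, len(pairs)))])
            seeds = set(rng.choice(nodes, 10, replace=False))
            cands = set(rng.choice(nodes, 40, replace=False))
            prev = None
            for thr in (0.3, 0.5, 0.7, 0.9):
                out = set(expand_network(seeds, cands, edges, thr).added)
                brute = set()
                for _, e in edges.iterrows():
                    if e["combined_score"] < thr:
                        continue
                    x, y = e["node_a"], e["node_b"]
                    if x in cands and x not in seeds and y in seeds:
                        brute.add(x)
                    if y in cands and y not in seeds and x in seeds:
                        brute.add(y)
                assert out == brute
                if prev is not None:
                    assert out <= prev
                prev = out
            assert expand_network(seeds, cands, edges, 1.0).added == sorted(
                {g for g in expand_network(seeds, cands, edges, 1.0).added}
            )


class TestDrugsAndPanel:
    def drugs(self):
        return pd.DataFrame(
            [("g1", "drugA", "approved"), ("g1", "drugB", "phase2")],
            columns=["gene_id", "drug_name", "status"],
        )

    def test_empty_drug_table_all_unavailable(self):
        out = annotate_drugs(["g1", "g2"], pd.DataFrame(columns=["gene_id", "drug_name", "status"]))
        assert not out["drug_available"].any()

    def test_multiple_rows_listed(self):
        out = annotate_drugs(["g1"], self.drugs()).set_index("gene_id")
        assert bool(out.loc["g1", "drug_available"])
        assert out.loc["g1", "drugs"].count(";") == 1

    def test_join_arithmetic(self):
        members = [f"g{i}" for i in range(33)]
        table = pd.DataFrame({"gene_id": members[:9], "drug_name": "d", "status": "approved"})
        out = annotate_drugs(members, table)
        assert int(out["drug_available"].sum()) == 9

    def make_panel(self, order=("A", "B", "C")):
        assoc = filter_disease_associated(
            {"g1", "g2"},
            gda([("g1", "cardiac fibrosis", 0.5), ("g2", "renal fibrosis", 0.7)]),
        )
        expansion = expand_network({"g1", "g2"}, {"g1", "g2", "g3"},
                                   net([("g3", "g1", 0.9)]))
        up = {"A": {"g1", "g2", "g3"}, "B": {"g2"}, "C": {"g2", "g3"}}
        up = {k: up[k] for k in order}
        return build_panel(assoc, expansion, up, self.drugs(), net([("g3", "g1", 0.9)]))

    def test_rank_key_order(self):
        panel = self.make_panel().set_index("gene_id")
        # g2 up in 3 sources beats g3 (2) beats g1 (1)
        assert panel.loc["g2", "rank"] == 1
        assert panel.loc["g3", "rank"] == 2
        assert panel.loc["g1", "rank"] == 3
        assert panel.loc["g3", "provenance"] == "network-added"
        assert panel.loc["g3", "fibrosis_partners"] == "g1"
        assert bool(panel.loc["g1", "drug_available"])

    def test_permutation_invariance_and_idempotence(self):
        p1 = self.make_panel(("A", "B", "C"))
        p2 = self.make_panel(("C", "A", "B"))
        pd.testing.assert_frame_equal(p1, p2)

    def test_lexical_tiebreak(self):
        assoc = filter_disease_associated(
            {"ga", "gb"},
            gda([("ga", "cardiac fibrosis", 0.5), ("gb", "cardiac fibrosis", 0.5)]),
        )
        expansion = expand_network(set(assoc.genes), {"ga", "gb"}, net([]))
        panel = build_panel(assoc, expansion, {"A": {"ga", "gb"}},
                            pd.DataFrame(columns=["gene_id", "drug_name", "status"]),
                            net([]))
        assert panel["gene_id"].tolist() == ["ga", "gb"]

    def test_network_added_have_associated_partner(self, fixture_study):
        truth = fixture_study.truth
        for g in truth.expected_added:
            assert g not in truth.expected_associated

    def test_venn_json_shape(self):
        regions = intersect_sources({"A": {"x"}, "B": {"x", "y"}})
        js = venn_to_json(regions)
        assert js["A&B"]["n"] == 1 and js["B"]["members"] == ["y"]
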