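"""Antisense classification, lncRNA-mRNA pairing, PPI extension."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ceranet import (
    FeatureSet,
    GeneAnnotation,
    AnnotationSet,
    TypedNetwork,
    build_lnc_mrna_network,
    classify_antisense_pair,
    first_neighbor_extension,
)
from ceranet.networks import NetworkError


def gene(gid, strand, start, end, exons, biotype):
    return GeneAnnotation(gid, "chr1", strand, start, end, tuple(exons), biotype)


MRNA_TWO_EXON = gene("G1", "+", 500, 2400, [(500, 900), (2000, 2400)], "mRNA")


class TestClassifyAntisensePair:
    def test_exon_overlap_opposite_strand_is_natural(self):
        mrna = gene("G1", "+", 100, 200, [(100, 200)], "mRNA")
        lnc = gene("L1", "-", 150, 250, [(150, 250)], "lncRNA")
        assert classify_antisense_pair(lnc, mrna, 10_000) == "antisense_natural"

    def test_intron_contained_opposite_strand_is_intronic(self):
        lnc = gene("L1", "-", 1000, 1500, [(1000, 1500)], "lncRNA")
        assert classify_antisense_pair(lnc, MRNA_TWO_EXON, 10_000) == "antisense_intronic"

    def test_same_strand_containment_is_proximity(self):
        lnc = gene("L1", "+", 1000, 1500, [(1000, 1500)], "lncRNA")
        assert classify_antisense_pair(lnc, MRNA_TWO_EXON, 10_000) == "proximity"

    def test_natural_takes_priority_over_intronic(self):
        # overlaps exon 1 AND would sit near the intron: exon overlap wins
        lnc = gene("L1", "-", 800, 1200, [(800, 1200)], "lncRNA")
        assert classify_antisense_pair(lnc, MRNA_TWO_EXON, 10_000) == "antisense_natural"

    def test_beyond_window_is_none(self):
        lnc = gene("L1", "-", 50_000, 50_500, [(50_000, 50_500)], "lncRNA")
        assert classify_antisense_pair(lnc, MRNA_TWO_EXON, 10_000) is None

    def test_gap_within_window_is_proximity(self):
        lnc = gene("L1", "-", 7000, 7500, [(7000, 7500)], "lncRNA")
        assert classify_antisense_pair(lnc, MRNA_TWO_EXON, 10_000) == "proximity"

    def test_different_chromosome_is_none(self):
        lnc = GeneAnnotation("L1", "chr2", "-", 500, 900, ((500, 900),), "lncRNA")
        assert classify_antisense_pair(lnc, MRNA_TWO_EXON, 10_000) is None

    @given(shift=st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariant_under_uniform_coordinate_shift(self, shift):
        for lnc in (
            gene("L1", "-", 700, 1100, [(700, 1100)], "lncRNA"),
            gene("L2", "-", 1000, 1500, [(1000, 1500)], "lncRNA"),
            gene("L3", "+", 7000, 7500, [(7000, 7500)], "lncRNA"),
        ):
            before = classify_antisense_pair(lnc, MRNA_TWO_EXON, 10_000)
            after = classify_antisense_pair(
                lnc.shifted(shift), MRNA_TWO_EXON.shifted(shift), 10_000
            )
            assert before == after


class TestBuildLncMrnaNetwork:
    def make_annotation(self):
        ann = AnnotationSet()
        ann.add(gene("G1", "+", 100, 200, [(100, 200)], "mRNA"))
        ann.add(gene("L1", "-", 150, 250, [(150, 250)], "lncRNA"))
        ann.add(gene("G2", "+", 100_000, 100_200, [(100_000, 100_200)], "mRNA"))
        ann.add(gene("L2", "-", 500_000, 500_300, [(500_000, 500_300)], "lncRNA"))
        return ann

    def test_single_planted_pair(self):
        ann = self.make_annotation()
        net = build_lnc_mrna_network(
            FeatureSet("l", {"L1": "down"}), FeatureSet("m", {"G1": "up"}), ann, 10_000
        )
        assert net.n_nodes == 2 and net.n_edges == 1
        assert net.graph.edges["L1", "G1"]["type"] == "antisense_natural"

    def test_no_classified_pairs_gives_empty_network(self):
        ann = self.make_annotation()
        net = build_lnc_mrna_network(
            FeatureSet("l", {"L2": "down"}), FeatureSet("m", {"G1": "up"}), ann, 10_000
        )
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_unresolvable_id_skipped_with_warning(self, caplog):
        ann = self.make_annotation()
        with caplog.at_level("WARNING"):
            net = build_lnc_mrna_network(
                FeatureSet("l", {"L1": "down", "MISSING": "up"}),
                FeatureSet("m", {"G1": "up"}),
                ann,
                10_000,
            )
        assert net.n_edges == 1
        assert any("MISSING" in rec.message for rec in caplog.records)

    def test_planted_pairs_recovered_exactly(self, default_dataset):
        # ground-truth round trip: DE sets taken straight from the truth
        truth = default_dataset.truth
        lnc = FeatureSet("l", {l: "down" for l, _, _ in truth.antisense_pairs})
        mrna = FeatureSet("m", {g: "down" for _, g, _ in truth.antisense_pairs})
        net = build_lnc_mrna_network(
            lnc, mrna, default_dataset.annotation,
            default_dataset.config.proximity_window_bp,
        )
        got = {
            (a, b) if a.startswith("L") else (b, a)
            for a, b in net.graph.edges()
        }
        expected = {(l, g) for l, g, _ in truth.antisense_pairs}
        assert got == expected
        for l, g, cls in truth.antisense_pairs:
            assert net.graph.edges[l, g]["type"] == cls


class TestFirstNeighborExtension:
    def base_net(self):
        net = TypedNetwork()
        net.add_node("L1", "lncRNA")
        net.add_node("G1", "mRNA")
        net.add_edge("L1", "G1", "antisense_natural")
        return net

    def test_first_but_not_second_neighbors_added(self):
        out = first_neighbor_extension(self.base_net(), [("G1", "P1"), ("P1", "P2")])
        assert set(out.graph.nodes) == {"L1", "G1", "P1"}
        assert out.graph.has_edge("G1", "P1")
        assert not out.graph.has_edge("P1", "P2")

    def test_no_seed_edges_returns_input_unchanged(self):
        net = self.base_net()
        out = first_neighbor_extension(net, [("X1", "X2")])
        assert set(out.graph.nodes) == set(net.graph.nodes)
        assert out.n_edges == net.n_edges

    def test_neighbor_neighbor_edges_kept(self):
        out = first_neighbor_extension(
            self.base_net(), [("G1", "P1"), ("G1", "P2"), ("P1", "P2")]
        )
        assert out.graph.has_edge("P1", "P2")

    def test_node_set_matches_brute_force_neighborhood(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            g = nx.gnp_random_graph(25, 0.15, seed=int(rng.integers(2**31)))
            ppi = [(f"n{a}", f"n{b}") for a, b in g.edges()]
            net = TypedNetwork()
            seeds = [f"n{i}" for i in rng.choice(25, size=4, replace=False)]
            for s in seeds:
                net.add_node(s, "mRNA")
            out = first_neighbor_extension(net, ppi)
            expected = set(seeds)
            for a, b in ppi:
                if a in seeds:
                    expected.add(b)
                if b in seeds:
                    expected.add(a)
            assert set(out.graph.nodes) == expected

    def test_idempotent_on_own_output(self):
        ppi = [("G1", "P1"), ("P1", "P2"), ("G1", "P3"), ("P3", "P4")]
        once = first_neighbor_extension(self.base_net(), ppi)
        twice = first_neighbor_extension(once, ppi)
        assert set(twice.graph.nodes) == set(once.graph.nodes)
        assert set(twice.graph.edges) == set(once.graph.edges)

    def test_antisense_edge_counts_conserved(self):
        net = self.base_net()
        before = net.edge_type_counts()
        out = first_neighbor_extension(net, [("G1", "P1"), ("P1", "P2")])
        after = out.edge_type_counts()
        for etype in ("antisense_natural", "antisense_intronic", "proximity"):
            assert after.get(etype, 0) == before.get(etype, 0)


class TestTypedNetworkInvariants:
    def test_self_loop_rejected(self):
        net = TypedNetwork()
        net.add_node("A", "protein")
        with pytest.raises(NetworkError):
            net.add_edge("A", "A", "ppi")

    def test_conflicting_duplicate_edge_rejected(self):
        net = TypedNetwork()
        net.add_node("A", "protein")
        net.add_node("B", "protein")
        net.add_edge("A", "B", "ppi")
        with pytest.raises(NetworkError):
            net.add_edge("B", "A", "proximity")

    def test_unknown_types_rejected(self):
        net = TypedNetwork()
        with pytest.raises(NetworkError):
            net.add_node("A", "gene")
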