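"""Synthetic-data generator: planted truths, determinism, distributions."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ceranet import (
    SimulationConfig,
    classify_antisense_pair,
    seed_match,
    simulate_all,
    simulate_annotation,
    simulate_counts,
    simulate_ppi,
    simulate_sequences,
)
from ceranet.simulate import SimulationError, PlacementError

SMALL = SimulationConfig(
    n_mrna=20, n_lncrna=8, n_mirna=12, n_protein_extra=10,
    n_planted_de=10, n_planted_triads=2, seed=1,
)


class TestConfigValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(n_mrna=-1)

    def test_planted_de_bounded_by_features(self):
        with pytest.raises(SimulationError):
            SimulationConfig(n_mrna=2, n_lncrna=1, n_planted_de=4, n_planted_triads=0)

    def test_triads_bounded_by_available_features(self):
        with pytest.raises(SimulationError):
            SimulationConfig(n_mrna=5, n_lncrna=1, n_mirna=2, n_planted_triads=3)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(dispersion=-0.1)


class TestSimulateAnnotation:
    def test_forced_antisense_fraction_plants_one_pair(self):
        cfg = SimulationConfig(
            n_mrna=2, n_lncrna=1, n_mirna=1, n_planted_de=1,
            n_planted_triads=0, antisense_fraction=1.0, seed=1,
        )
        _, truth = simulate_annotation(cfg)
        assert len(truth.antisense_pairs) == 1

    def test_zero_antisense_fraction_plants_none(self):
        cfg = dataclasses.replace(SMALL, antisense_fraction=0.0)
        _, truth = simulate_annotation(cfg)
        assert truth.antisense_pairs == set()

    def test_classifier_reproduces_every_planted_class(self):
        ann, truth = simulate_annotation(SimulationConfig())
        assert truth.antisense_pairs
        window = SimulationConfig().proximity_window_bp
        for lnc_id, mrna_id, cls in truth.antisense_pairs:
            assert classify_antisense_pair(ann[lnc_id], ann[mrna_id], window) == cls

    def test_distal_lncrnas_not_classified_with_any_mrna(self):
        cfg = SimulationConfig()
        ann, truth = simulate_annotation(cfg)
        paired = {l for l, _, _ in truth.antisense_pairs}
        distal = [g for g in ann.by_biotype("lncRNA") if g.gene_id not in paired]
        assert distal
        for lnc in distal:
            for mrna in ann.by_biotype("mRNA"):
                assert classify_antisense_pair(lnc, mrna, cfg.proximity_window_bp) is None

    def test_short_chromosome_raises_placement_error(self):
        with pytest.raises(PlacementError):
            simulate_annotation(dataclasses.replace(SMALL, chrom_length=10_000))


class TestSimulateCounts:
    def test_planted_fold_changes_shift_means(self):
        # average realized counts across planted-up features in the knockdown
        # samples sit near 2**log2fc times the reference, within NB noise
        cfg = dataclasses.replace(
            SMALL, n_mrna=400, n_planted_de=200, n_lncrna=0, n_mirna=0,
            n_planted_triads=0, antisense_fraction=0.0,
            nonspecific_fraction=0.0, nonspecific_overlap=0, dispersion=0.01,
        )
        ann, truth = simulate_annotation(cfg)
        matrix, truth = simulate_counts(ann, cfg, truth)
        up = [f for f, d, c in truth.de_features if d == "up" and c == "knockdown"]
        assert len(up) > 50
        ratio = (matrix.counts.loc[up, "S1"] + 1) / (matrix.counts.loc[up, "S0"] + 1)
        assert np.median(ratio) == pytest.approx(2**cfg.planted_log2fc, rel=0.2)

    def test_same_seed_gives_bit_identical_matrices(self):
        ann, truth = simulate_annotation(SMALL)
        m1, _ = simulate_counts(ann, SMALL, dataclasses.replace(truth))
        ann2, truth2 = simulate_annotation(SMALL)
        m2, _ = simulate_counts(ann2, SMALL, truth2)
        pd.testing.assert_frame_equal(m1.counts, m2.counts)

    def test_target_lncrna_down_and_triads_down_up_down(self):
        ann, truth = simulate_annotation(SMALL)
        _, truth = simulate_counts(ann, SMALL, truth)
        kd = dict(truth.knockdown_de())
        assert kd[truth.target_lncrna] == "down"
        for lnc, mir, gene in truth.triads:
            assert kd[mir] == "up" and kd[gene] == "down" and lnc == truth.target_lncrna

    def test_nonspecific_set_overlaps_planted_by_configured_count(self):
        ann, truth = simulate_annotation(SMALL)
        _, truth = simulate_counts(ann, SMALL, truth)
        kd_ids = {f for f, _ in truth.knockdown_de()}
        ns_ids = {f for f, _ in truth.nonspecific_de()}
        assert len(kd_ids & ns_ids) == SMALL.nonspecific_overlap


class TestSimulatePPI:
    def test_m1_attachment_gives_tree(self):
        cfg = dataclasses.replace(
            SMALL, n_mrna=8, n_protein_extra=2, n_planted_de=5, n_planted_triads=2
        )
        ann, _ = simulate_annotation(cfg)
        edges = simulate_ppi(ann, cfg, m=1)
        assert len(edges) == 9  # 10 nodes, tree

    def test_hub_degree_at_least_mean(self, default_dataset):
        import networkx as nx

        g = nx.Graph(default_dataset.ppi)
        degrees = [d for _, d in g.degree()]
        assert max(degrees) >= np.mean(degrees)
        assert nx.is_connected(g)

    def test_simple_graph_no_self_loops_or_duplicates(self, default_dataset):
        edges = default_dataset.ppi
        assert all(a != b for a, b in edges)
        keys = [tuple(sorted(e)) for e in edges]
        assert len(keys) == len(set(keys))

    def test_fixed_seed_reproducible(self):
        ann, _ = simulate_annotation(SMALL)
        assert simulate_ppi(ann, SMALL) == simulate_ppi(ann, SMALL)

    def test_too_few_nodes_rejected(self):
        cfg = SimulationConfig(
            n_mrna=1, n_lncrna=0, n_mirna=0, n_protein_extra=0,
            n_planted_de=0, n_planted_triads=0,
        )
        ann, _ = simulate_annotation(cfg)
        with pytest.raises(SimulationError):
            simulate_ppi(ann, cfg)


class TestSimulateSequences:
    def test_planted_triads_have_8mer_sites_at_recorded_positions(self, default_dataset):
        truth = default_dataset.truth
        for lnc, mir, gene in truth.triads:
            mir_seq = default_dataset.mirna_sequences[mir]
            for target_id, seqs in ((gene, default_dataset.utr_sequences),
                                    (lnc, default_dataset.lncrna_sequences)):
                hits = seed_match(mir_seq, seqs[target_id])
                planted_pos = truth.planted_sites[(mir, target_id)]
                assert any(
                    h.site_type == "8mer" and h.position == planted_pos for h in hits
                )

    def test_collision_screening_leaves_only_planted_sites(self, default_dataset):
        # a miRNA outside any triad must have zero sites in validated UTRs
        truth = default_dataset.truth
        triad_mirs = {m for _, m, _ in truth.triads}
        other = sorted(set(default_dataset.mirna_sequences) - triad_mirs)[:20]
        for mir in other:
            for gene in truth.validated_mrnas:
                assert seed_match(
                    default_dataset.mirna_sequences[mir],
                    default_dataset.utr_sequences[gene],
                ) == []

    def test_zero_triads_plants_no_sites(self):
        cfg = dataclasses.replace(SMALL, n_planted_triads=0)
        ann, truth = simulate_annotation(cfg)
        _, truth = simulate_counts(ann, cfg, truth)
        _, _, _, truth = simulate_sequences(ann, cfg, truth)
        assert truth.planted_sites == {}

    def test_all_mirnas_are_21nt(self, default_dataset):
        assert all(len(s) == 21 for s in default_dataset.mirna_sequences.values())

    def test_too_short_sequences_rejected(self):
        cfg = dataclasses.replace(SMALL, utr_length=6)
        ann, truth = simulate_annotation(cfg)
        with pytest.raises(SimulationError):
            simulate_sequences(ann, cfg, truth)


class TestDeterminism:
    def test_same_seed_end_to_end_identical(self):
        d1 = simulate_all(SMALL)
        d2 = simulate_all(SMALL)
        pd.testing.assert_frame_equal(d1.counts.counts, d2.counts.counts)
        assert d1.mirna_sequences == d2.mirna_sequences
        assert d1.utr_sequences == d2.utr_sequences
        assert d1.ppi == d2.ppi
        assert d1.truth.de_features == d2.truth.de_features

    def test_different_seeds_differ(self):
        d1 = simulate_all(SMALL)
        d2 = simulate_all(dataclasses.replace(SMALL, seed=2))
        assert not d1.counts.counts.equals(d2.counts.counts)
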