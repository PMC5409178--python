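"""Genotype graph construction, clustering, effect calls and paths."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dupfit import presets
from dupfit.fitness import SelectionEstimate
from dupfit.landscape import (
    ELEMENT_UNIVERSE,
    AlleleSpec,
    GenotypeSpec,
    build_landscape,
    classify_edges,
    classify_step,
    cluster_fitness_classes,
    find_neutral_paths,
    is_absorbing,
)
from dupfit.pipeline import estimates_map, fit_screen, s_matrix


def scp(promoter="BUB1pr", minus=()):
    return AlleleSpec(ELEMENT_UNIVERSE - set(minus), promoter, "SCP")


class TestAlleleSpec:
    def test_extant_layout_enforced(self):
        with pytest.raises(ValueError):
            AlleleSpec(ELEMENT_UNIVERSE, "BUB1pr", "extant_Bub1")  # has KEN1
        with pytest.raises(ValueError):
            AlleleSpec(ELEMENT_UNIVERSE, "MAD3pr", "extant_Mad3")  # has kinase
        AlleleSpec(ELEMENT_UNIVERSE - {"KEN1"}, "BUB1pr", "extant_Bub1")
        AlleleSpec(ELEMENT_UNIVERSE - {"KINASE"}, "MAD3pr", "extant_Mad3")

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            AlleleSpec({"NOT_A_MOTIF"})


class TestClassifyStep:
    def test_duplication_fills_empty_locus(self):
        parent = GenotypeSpec("p", locus_bub1=scp())
        child = GenotypeSpec("c", locus_bub1=scp(), locus_mad3=scp("MAD3pr"))
        assert classify_step(parent, child) == "duplication"

    def test_single_element_loss(self):
        parent = GenotypeSpec("p", locus_bub1=scp())
        child = GenotypeSpec("c", locus_bub1=scp(minus={"KEN1"}))
        assert classify_step(parent, child) == "element_loss"

    def test_two_element_difference_is_not_a_step(self):
        parent = GenotypeSpec("p", locus_bub1=scp())
        child = GenotypeSpec("c", locus_bub1=scp(minus={"KEN1", "KEN2"}))
        assert classify_step(parent, child) is None

    def test_gene_loss(self):
        parent = GenotypeSpec("p", locus_bub1=scp(minus={"KEN1"}), locus_mad3=scp("MAD3pr"))
        child = GenotypeSpec("c", locus_mad3=scp("MAD3pr"))
        assert classify_step(parent, child) == "gene_loss"

    def test_losing_identical_duplicate_is_a_reversion(self):
        parent = GenotypeSpec("p", locus_bub1=scp(), locus_mad3=scp("MAD3pr"))
        child = GenotypeSpec("c", locus_bub1=scp())
        assert classify_step(parent, child) is None

    def test_no_edge_adds_an_element(self):
        parent = GenotypeSpec("p", locus_bub1=scp(minus={"KEN1"}))
        child = GenotypeSpec("c", locus_bub1=scp())
        assert classify_step(parent, child) is None


class TestBuildLandscape:
    def test_matches_brute_force_event_relation(self):
        genos = presets.reconstructed_genotypes()
        scape = build_landscape(genos)
        expected = {
            (p.label, c.label)
            for p, c in itertools.permutations(genos, 2)
            if classify_step(p, c) is not None
        }
        assert set(scape.graph.edges) == expected

    def test_landscape_is_a_dag(self):
        scape = build_landscape(presets.reconstructed_genotypes())
        assert nx.is_directed_acyclic_graph(scape.graph)

    def test_element_loss_edges_decrease_count_by_one(self):
        scape = build_landscape(presets.reconstructed_genotypes())
        genos = scape.genotypes
        for u, v, d in scape.graph.edges(data=True):
            if d["event"] == "element_loss":
                assert genos[u].element_count() - genos[v].element_count() == 1

    def test_duplicate_labels_rejected(self):
        g = GenotypeSpec("x", locus_bub1=scp())
        with pytest.raises(ValueError):
            build_landscape([g, g])


class TestClustering:
    def test_three_synthetic_classes_recovered(self, screen_fixture):
        genos, counts, truth = screen_fixture
        mat = s_matrix(fit_screen(counts))
        res = cluster_fitness_classes(mat, wildtype=presets.EXTANT_LABEL)
        assert res.n_classes == 3
        # class labels must agree with the generative truth
        mapping = {}
        for geno, cl in res.labels.items():
            mapping.setdefault(cl, set()).add(truth[geno])
        assert all(len(v) == 1 for v in mapping.values())

    def test_class_means_match_truth_scale(self, screen_fixture):
        genos, counts, truth = screen_fixture
        mat = s_matrix(fit_screen(counts))
        res = cluster_fitness_classes(mat, wildtype=presets.EXTANT_LABEL)
        means = sorted(res.class_mean_s)
        assert means[0] == pytest.approx(-0.3, abs=0.02)   # censored bound
        assert means[1] == pytest.approx(-0.015, abs=0.005)
        assert abs(means[2]) < 0.005

    def test_all_zero_matrix_is_one_class(self):
        z = pd.DataFrame(np.zeros((5, 5)), index=list("abcde"), columns=list("abcde"))
        assert cluster_fitness_classes(z).n_classes == 1

    def test_permutation_invariance(self, screen_fixture):
        genos, counts, _ = screen_fixture
        mat = s_matrix(fit_screen(counts))
        res1 = cluster_fitness_classes(mat)
        shuffled = mat.sample(frac=1, random_state=1)
        res2 = cluster_fitness_classes(shuffled)
        part1 = res1.labels.groupby(res1.labels).groups
        assert {frozenset(v) for v in part1.values()} == {
            frozenset(v) for v in res2.labels.groupby(res2.labels).groups.values()
        }

    def test_shift_invariance(self, screen_fixture):
        genos, counts, _ = screen_fixture
        mat = s_matrix(fit_screen(counts))
        res1 = cluster_fitness_classes(mat)
        res2 = cluster_fitness_classes(mat + 0.42)
        assert (res1.labels == res2.labels).all()

    def test_row_without_observations_rejected(self):
        mat = pd.DataFrame(
            [[0.0, 0.1], [np.nan, np.nan]], index=["a", "b"], columns=["a", "b"]
        )
        with pytest.raises(ValueError, match="no observed"):
            cluster_fitness_classes(mat)


def _classified_fixture(screen_fixture):
    genos, counts, _ = screen_fixture
    scape = build_landscape(genos)
    est = fit_screen(counts)
    classify_edges(scape, estimates_map(est), reference=presets.EXTANT_LABEL)
    return scape


class TestClassifyEdges:
    def test_wt_to_wt_edges_are_neutral(self, screen_fixture):
        scape = _classified_fixture(screen_fixture)
        d = scape.graph.edges["SCP", "SCPx2"]
        assert d["call"] == "no_detectable_effect"
        assert len(d["s_reps"]) == 2

    def test_exit_edges_from_extant_pair_are_deleterious(self, screen_fixture):
        scape = _classified_fixture(screen_fixture)
        for child in ("bub1_locus_only", "mad3_locus_only"):
            assert scape.graph.edges[presets.EXTANT_LABEL, child]["call"] == "deleterious"

    def test_missing_contrast_marked_unknown(self, screen_fixture):
        genos, counts, _ = screen_fixture
        scape = build_landscape(genos)
        classify_edges(scape, {}, reference=None)
        assert all(
            d["call"] == "unknown" for _, _, d in scape.graph.edges(data=True)
        )


class TestPaths:
    def test_neutral_path_with_four_degenerations(self, screen_fixture):
        scape = _classified_fixture(screen_fixture)
        paths = find_neutral_paths(scape, presets.SOURCE_LABEL, presets.EXTANT_LABEL)
        assert len(paths) >= 1
        assert max(p.degenerations for p in paths) >= 3
        assert not any(p.indeterminate for p in paths)

    def test_matches_brute_force_enumeration(self, screen_fixture):
        scape = _classified_fixture(screen_fixture)
        non_del = nx.DiGraph(
            (u, v)
            for u, v, d in scape.graph.edges(data=True)
            if d["call"] != "deleterious"
        )
        non_del.add_nodes_from(scape.graph.nodes)
        expected = {
            tuple(p)
            for p in nx.all_simple_paths(
                non_del, presets.SOURCE_LABEL, presets.EXTANT_LABEL
            )
        }
        got = {
            p.nodes
            for p in find_neutral_paths(scape, presets.SOURCE_LABEL, presets.EXTANT_LABEL)
        }
        assert got == expected

    def test_all_deleterious_means_no_paths(self, screen_fixture):
        genos, _, _ = screen_fixture
        scape = build_landscape(genos)
        for _, _, d in scape.graph.edges(data=True):
            d["call"] = "deleterious"
        assert find_neutral_paths(scape, presets.SOURCE_LABEL, presets.EXTANT_LABEL) == []

    def test_source_equals_target_gives_zero_length_path(self, screen_fixture):
        scape = _classified_fixture(screen_fixture)
        (p,) = find_neutral_paths(scape, "SCP", "SCP")
        assert p.nodes == ("SCP",) and p.degenerations == 0

    def test_unknown_edge_marks_path_indeterminate(self, screen_fixture):
        genos, counts, _ = screen_fixture
        scape = build_landscape(genos)
        est = fit_screen(counts)
        classify_edges(scape, estimates_map(est), reference=presets.EXTANT_LABEL)
        scape.graph.edges["SCP", "SCPx2"]["call"] = "unknown"
        paths = find_neutral_paths(scape, "SCP", presets.EXTANT_LABEL)
        assert paths and all(p.indeterminate for p in paths)


class TestAbsorbing:
    def test_extant_pair_is_absorbing(self, screen_fixture):
        scape = _classified_fixture(screen_fixture)
        assert is_absorbing(scape, presets.EXTANT_LABEL)

    def test_node_with_neutral_exit_is_not_absorbing(self, screen_fixture):
        scape = _classified_fixture(screen_fixture)
        assert not is_absorbing(scape, "SCP")

    def test_sink_is_vacuously_absorbing(self, screen_fixture):
        scape = _classified_fixture(screen_fixture)
        assert is_absorbing(scape, "mad3_locus_only")

    def test_unclassified_exit_raises(self, screen_fixture):
        scape = _classified_fixture(screen_fixture)
        scape.graph.edges[presets.EXTANT_LABEL, "mad3_locus_only"]["call"] = "unknown"
        with pytest.raises(ValueError):
            is_absorbing(scape, presets.EXTANT_LABEL)
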