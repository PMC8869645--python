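import numpy as np
import pytest

from dadascan.align import revcomp
from dadascan.phylo import (
    Clade,
    PhyloTree,
    TransposaseProtein,
    check_catalytic_motifs,
    extract_transposase,
    group_lineages,
    midpoint_root,
    neighbor_joining,
    protein_distance_matrix,
)
from dadascan.simulate import build_element

from _oracles import random_additive_matrix


@pytest.fixture(scope="module")
def ref_element():
    return build_element(1, 1900, 520)


class TestExtractTransposase:
    def test_generator_round_trip(self, ref_element):
        tp = extract_transposase(ref_element.seq, "f")
        assert tp is not None and tp.sequence == ref_element.protein

    def test_reverse_complement_same_protein(self, ref_element):
        tp = extract_transposase(revcomp(ref_element.seq), "f")
        assert tp.sequence == ref_element.protein and tp.strand == "-"

    def test_non_coding_sequence_gives_none(self):
        assert extract_transposase("TAATAGTGA" * 200, "f") is None

    def test_short_orf_below_threshold_gives_none(self):
        e = build_element(2, 900, 150)
        assert extract_transposase(e.seq, "f", min_orf_codons=300) is None


class TestMotifCheck:
    def test_reference_against_itself_intact(self, ref_element):
        mc = check_catalytic_motifs(ref_element.protein, ref_element.protein,
                                    ref_element.motif_positions)
        assert mc.dde_intact and mc.dxxh_intact

    def test_h_to_q_flips_dxxh(self, ref_element):
        p = list(ref_element.protein)
        p[ref_element.motif_positions["h"] - 1] = "Q"
        mc = check_catalytic_motifs("".join(p), ref_element.protein,
                                    ref_element.motif_positions)
        assert mc.dde_intact and not mc.dxxh_intact
        assert mc.observed["h"] == "Q"

    @pytest.mark.parametrize("key", ["d1", "d2"])
    def test_d_to_n_flips_dde(self, ref_element, key):
        p = list(ref_element.protein)
        p[ref_element.motif_positions[key] - 1] = "N"
        mc = check_catalytic_motifs("".join(p), ref_element.protein,
                                    ref_element.motif_positions)
        assert not mc.dde_intact

    def test_ddd_variant_counts_as_intact(self, ref_element):
        p = list(ref_element.protein)
        p[ref_element.motif_positions["e"] - 1] = "D"
        mc = check_catalytic_motifs("".join(p), ref_element.protein,
                                    ref_element.motif_positions)
        assert mc.dde_intact


class TestDistanceMatrix:
    def test_identical_zero_and_single_substitution(self):
        base = "M" + "ACDEFGHIKL" * 10
        one_sub = base[:50] + ("A" if base[50] != "A" else "C") + base[51:]
        prots = [TransposaseProtein("a", base, 1, "+"),
                 TransposaseProtein("b", base, 1, "+"),
                 TransposaseProtein("c", one_sub, 1, "+")]
        D, labels = protein_distance_matrix(prots)
        assert D[0, 1] == 0
        assert D[0, 2] == pytest.approx(1 / 101)
        assert np.allclose(D, D.T, atol=1e-12)

    def test_fewer_than_three_is_error(self):
        p = TransposaseProtein("a", "MAAAA", 1, "+")
        with pytest.raises(ValueError):
            protein_distance_matrix([p, p])


class TestNeighborJoining:
    def test_reconstructs_additive_matrices_exactly(self):
        rng = np.random.default_rng(0)
        for n in (4, 5, 6, 8):
            for _ in range(3):
                D, labels = random_additive_matrix(rng, n)
                tree = neighbor_joining(D, labels)
                pl = tree.path_lengths()
                err = max(abs(pl[(a, b)] - D[i, j])
                          for i, a in enumerate(labels)
                          for j, b in enumerate(labels) if a != b)
                assert err < 1e-9

    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 3, 5], [3, 0, 6], [5, 6, 0]])
        tree = neighbor_joining(D, ["a", "b", "c"])
        pl = tree.path_lengths()
        assert pl[("a", "b")] == pytest.approx(3)
        assert pl[("a", "c")] == pytest.approx(5)
        assert pl[("b", "c")] == pytest.approx(6)

    def test_leaf_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(1)
        D, labels = random_additive_matrix(rng, 6)
        t1 = neighbor_joining(D, labels)
        perm = rng.permutation(6)
        D2 = D[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        t2 = neighbor_joining(D2, labels2)
        pl1, pl2 = t1.path_lengths(), t2.path_lengths()
        for pair, d in pl1.items():
            assert pl2[pair] == pytest.approx(d, abs=1e-9)

    def test_newick_parses_with_dendropy(self):
        import dendropy

        rng = np.random.default_rng(2)
        D, labels = random_additive_matrix(rng, 5)
        tree = neighbor_joining(D, labels)
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == sorted(labels)


class TestMidpointRoot:
    def test_two_leaves_equidistant(self):
        root = Clade(children=[Clade(name="a", branch_length=0.5),
                               Clade(name="b", branch_length=1.5)])
        rooted = midpoint_root(PhyloTree(root))
        a, b = {l.name: l for l in rooted.root.leaves()}["a"], None
        depths = {}
        def walk(n, d):
            if n.is_leaf:
                depths[n.name] = d + n.branch_length
            for c in n.children:
                walk(c, d + (n.branch_length if n is not rooted.root else 0))
        walk(rooted.root, 0)
        assert depths["a"] == pytest.approx(1.0) and depths["b"] == pytest.approx(1.0)

    def test_farthest_pair_equidistant_on_random_trees(self):
        rng = np.random.default_rng(3)
        D, labels = random_additive_matrix(rng, 7)
        tree = neighbor_joining(D, labels)
        rooted = midpoint_root(tree)
        depths = {}
        def walk(n, d):
            if n.is_leaf:
                depths[n.name] = d + n.branch_length
            for c in n.children:
                walk(c, d + (n.branch_length if n is not rooted.root else 0))
        walk(rooted.root, 0)
        diam = max(D[i, j] for i in range(7) for j in range(7))
        assert max(depths.values()) == pytest.approx(diam / 2, abs=1e-9)

    def test_rerooting_is_idempotent(self):
        rng = np.random.default_rng(4)
        D, labels = random_additive_matrix(rng, 6)
        r1 = midpoint_root(neighbor_joining(D, labels))
        r2 = midpoint_root(r1)
        assert r1.newick() == r2.newick()


def _leaf(name):
    return Clade(name=name, branch_length=1.0)


def _node(*children):
    n = Clade(children=list(children), branch_length=1.0)
    return n


class TestGroupLineages:
    def test_clean_clades_give_separate_lineages(self):
        tree = PhyloTree(_node(_node(_leaf("a1"), _leaf("a2")),
                               _node(_leaf("u1"), _leaf("u2"))), rooted=True)
        groups = group_lineages(tree, {"a1": "tA", "a2": "tA",
                                       "u1": "U6", "u2": "U6"})
        assert sorted(g.name for g in groups) == ["U6", "tA"]

    def test_interleaved_labels_merge_with_slash_name(self):
        # tV leaves nested inside the tD clade
        tree = PhyloTree(
            _node(_node(_leaf("d1"), _node(_leaf("v1"),
                                           _node(_leaf("v2"), _leaf("d2")))),
                  _node(_leaf("a1"), _leaf("a2"))), rooted=True)
        groups = group_lineages(tree, {"d1": "tD", "d2": "tD", "v1": "tV",
                                       "v2": "tV", "a1": "tA", "a2": "tA"})
        names = sorted(g.name for g in groups)
        assert names == ["tA", "tD/tV"]
        merged = [g for g in groups if g.name == "tD/tV"][0]
        assert sorted(merged.families) == ["d1", "d2", "v1", "v2"]

    def test_unconfirmed_leaf_inside_clade_inherits_label(self):
        tree = PhyloTree(
            _node(_node(_leaf("a1"), _node(_leaf("x"), _leaf("a2"))),
                  _node(_leaf("u1"), _leaf("u2"))), rooted=True)
        groups = group_lineages(tree, {"a1": "tA", "a2": "tA", "x": "unconfirmed",
                                       "u1": "U6", "u2": "U6"})
        ta = [g for g in groups if g.name == "tA"][0]
        assert "x" in ta.families and ta.provisional == ["x"]

    def test_scenario_families_land_in_distinct_lineages(self, pipeline_run):
        import json
        from dadascan.pipeline import _p

        cfg, summary = pipeline_run
        data = json.loads(_p(cfg, "lineages.json").read_text())
        names = sorted(g["name"] for g in data["lineages"])
        assert names == ["5S", "tA", "tV", "tY"]
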