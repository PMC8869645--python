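import numpy as np
import pytest

from dadascan.align import Hit, align_global
from dadascan.families import (
    build_msa,
    cluster_hits,
    extend_consensus,
    low_copy_fallback,
    majority_consensus,
)
from dadascan.simulate import mutate_seq

from _oracles import naive_majority


class TestClusterHits:
    def test_identical_sequences_one_cluster(self):
        seqs = [("a", "ACGTACGTACGT"), ("b", "ACGTACGTACGT"), ("c", "ACGTACGTACGT")]
        clusters = cluster_hits(seqs)
        assert len(clusters) == 1 and len(clusters[0]) == 3

    def test_half_identical_pair_stays_apart(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACGT"), 60))
        b = mutate_seq(a, rng, 0.5)
        ident = align_global(a, b).identity
        assert ident < 0.75  # confirmed with the alignment oracle
        clusters = cluster_hits([("a", a), ("b", b)])
        assert len(clusters) == 2

    def test_linked_within_family_divergence(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), 300))
        members = [(f"m{i}", mutate_seq(a, rng, 0.02)) for i in range(4)]
        assert len(cluster_hits(members)) == 1

    def test_partition_invariant_under_permutation(self):
        rng = np.random.default_rng(2)
        base1 = "".join(rng.choice(list("ACGT"), 120))
        base2 = "".join(rng.choice(list("ACGT"), 120))
        seqs = [(f"a{i}", mutate_seq(base1, rng, 0.05)) for i in range(3)] + \
               [(f"b{i}", mutate_seq(base2, rng, 0.05)) for i in range(3)]
        ref = None
        for perm_seed in range(4):
            prng = np.random.default_rng(perm_seed)
            order = prng.permutation(len(seqs))
            shuffled = [seqs[i] for i in order]
            clusters = cluster_hits(shuffled)
            partition = sorted(tuple(sorted(c.member_ids)) for c in clusters)
            if ref is None:
                ref = partition
            assert partition == ref

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            cluster_hits([])


class TestBuildMsa:
    def test_identical_sequences_gap_free(self):
        rows = build_msa(["ACGTACGT"] * 3)
        assert rows == ["ACGTACGT"] * 3

    def test_substitutions_only_keep_center_length(self):
        center = "ACGTACGTACGTACGT"
        m1 = "ACGTACGAACGTACGT"
        m2 = "ACGTACGTACGTACGA"
        rows = build_msa([center, m1, m2])
        assert all(len(r) == len(center) for r in rows)

    def test_ungapping_reproduces_inputs(self):
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACGT"), 80))
        seqs = [mutate_seq(base, rng, 0.1) for _ in range(4)]
        seqs[1] = seqs[1][:30] + seqs[1][40:]  # introduce a deletion
        rows = build_msa(seqs)
        assert [r.replace("-", "") for r in rows] == seqs

    def test_single_sequence_passthrough(self):
        assert build_msa(["ACGT"]) == ["ACGT"]


class TestMajorityConsensus:
    def test_two_thirds_majority_called(self):
        cons = majority_consensus(["A", "A", "G"])
        assert cons.seq == "A" and cons.support[0] == pytest.approx(2 / 3)

    def test_tie_gives_n(self):
        assert majority_consensus(["A", "A", "G", "G"]).seq == "N"

    def test_gap_majority_column_dropped(self):
        assert majority_consensus(["AT", "-T", "-T", "-T"]).seq == "T"

    def test_agrees_with_naive_counter_on_random_msas(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            nrows = int(rng.integers(1, 7))
            ncols = int(rng.integers(1, 15))
            rows = ["".join(rng.choice(list("ACGT-"), ncols)) for _ in range(nrows)]
            assert majority_consensus(rows).seq == naive_majority(rows)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            majority_consensus([])


def _cluster_for_family(scenario, fam):
    truth = [t for t in scenario.truth if t.family_id == fam]
    hits = [Hit("q", scenario.genome.id, t.start, t.end, t.element_strand, 100.0, 0.98)
            for t in truth]
    seqs = []
    from dadascan.align import revcomp

    for h in hits:
        s = scenario.genome.seq[h.start : h.end]
        seqs.append(s if h.strand == "+" else revcomp(s))
    from dadascan.families import HitCluster

    return HitCluster([f"m{i}" for i in range(len(hits))], seqs, "m0", seqs[0], hits)


class TestExtendConsensus:
    def test_scenario_family_confirmed_in_first_round(self, scenario):
        cluster = _cluster_for_family(scenario, "tY")
        ext = extend_consensus(cluster, scenario.genome, scenario.templates,
                               flank=600, max_rounds=3)
        assert ext.confirmed and ext.rounds == 1
        assert ext.left_match is not None and ext.right_match is not None
        assert ext.left_match.template == "tRNA-Tyr-GTA"

    def test_non_gene_context_is_unconfirmed(self, scenario, element):
        # plant the element in plain background: no genes to reach
        rng = np.random.default_rng(9)
        bg = "".join(rng.choice(list("ACGT"), 40_000))
        from dadascan.io import GenomeRecord
        from dadascan.families import HitCluster

        g = GenomeRecord("g", "", bg[:10_000] + element.seq + bg[10_000:])
        hits = [Hit("q", "g", 10_000, 10_000 + len(element.seq), "+", 50.0, 1.0)] * 3
        cluster = HitCluster(["a", "b", "c"], [element.seq] * 3, "a", element.seq,
                             hits)
        ext = extend_consensus(cluster, g, scenario.templates, flank=400, max_rounds=2)
        assert not ext.confirmed

    def test_member_cap_of_ten_loci(self, scenario):
        cluster = _cluster_for_family(scenario, "tY")
        # inflate the cluster beyond ten members
        cluster.hits = cluster.hits * 4
        cluster.member_seqs = cluster.member_seqs * 4
        cluster.member_ids = [f"m{i}" for i in range(len(cluster.hits))]
        ext = extend_consensus(cluster, scenario.genome, scenario.templates,
                               flank=600, max_rounds=1, max_members=10)
        assert ext.consensus.member_count == 10


class TestLowCopyFallback:
    def test_two_copy_family_recovered(self, scenario):
        truth = [t for t in scenario.truth if t.family_id == "tV"]
        t = truth[0]
        hit = Hit("q", scenario.genome.id, t.start, t.end, t.element_strand, 50.0, 1.0)
        fb = low_copy_fallback(hit, scenario.genome, scenario.templates, flank=4000)
        assert fb is not None and fb["left_template"] == "tRNA-Val-TAC"

    def test_random_background_gives_none(self, scenario, element):
        rng = np.random.default_rng(10)
        from dadascan.io import GenomeRecord

        bg = "".join(rng.choice(list("ACGT"), 30_000))
        g = GenomeRecord("g", "", bg[:8000] + element.seq + bg[8000:])
        hit = Hit("q", "g", 8000, 8000 + len(element.seq), "+", 50.0, 1.0)
        assert low_copy_fallback(hit, g, scenario.templates, flank=4000) is None
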