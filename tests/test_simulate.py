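import numpy as np
import pytest
from Bio.Seq import Seq

from dadascan.align import align_protein_global, revcomp
from dadascan.simulate import (
    PlantSpec,
    build_element,
    default_scenario,
    default_templates,
    mutate_element,
    plant_genome,
)


class TestBuildElement:
    def test_length_and_orf_contract(self):
        e = build_element(1, 3000, 600)
        assert len(e.seq) == 3000
        orf = e.seq[e.orf_start : e.orf_start + e.orf_len_nt]
        assert len(orf) == 3 * 600
        tr = str(Seq(orf).translate())
        assert tr[0] == "M" and tr[-1] == "*" and "*" not in tr[:-1]

    def test_motif_residues_at_recorded_positions(self):
        e = build_element(1, 3000, 600)
        p = e.motif_positions
        assert e.protein[p["d1"] - 1] == "D"
        assert e.protein[p["d2"] - 1] == "D"
        assert e.protein[p["e"] - 1] == "E"
        assert e.protein[p["dxxh_d"] - 1] == "D"
        assert p["h"] == p["dxxh_d"] + 3 and e.protein[p["h"] - 1] == "H"

    def test_same_seed_identical(self):
        assert build_element(9, 2000, 500).seq == build_element(9, 2000, 500).seq

    def test_too_small_is_error(self):
        with pytest.raises(ValueError):
            build_element(1, 100, 600)


class TestMutateElement:
    def test_motifs_preserved_and_divergence_in_range(self):
        e = build_element(3, 1900, 520)
        m = mutate_element(e, 10)
        p = m.motif_positions
        assert m.protein[p["d1"] - 1] == "D" and m.protein[p["h"] - 1] == "H"
        ident = align_protein_global(e.protein, m.protein).identity
        assert 0.5 < ident < 0.8  # aa divergence around the 0.35 default

    def test_orf_stays_clean(self):
        e = build_element(3, 1900, 520)
        m = mutate_element(e, 11)
        orf = m.seq[m.orf_start : m.orf_start + m.orf_len_nt]
        tr = str(Seq(orf).translate())
        assert tr[:-1] == m.protein and "*" not in tr[:-1]


@pytest.fixture()
def ala(templates):
    return templates[0]


class TestPlantGenome:
    def test_tsd_construction_single_copy(self, templates, ala, element):
        spec = PlantSpec("f", element.seq, ala, insertion_offset=33, tsd_len=6,
                         n_copies=1)
        genome, truth, _ = plant_genome(templates, [spec], 20_000, seed=4)
        (t,) = truth
        left = genome.seq[t.start - 6 : t.start]
        right = genome.seq[t.end : t.end + 6]
        assert left == right and len(t.tsd_left) == 6

    def test_replacement_on_both_flanks(self, templates, ala, element):
        spec = PlantSpec("f", element.seq, ala, insertion_offset=33, tsd_len=6,
                         replacement=("TAGCAT", "GCGCAA", "both"), n_copies=1)
        genome, truth, _ = plant_genome(templates, [spec], 20_000, seed=4)
        (t,) = truth
        assert genome.seq[t.start - 6 : t.start] == "GCGCAA"
        assert genome.seq[t.end : t.end + 6] == "GCGCAA"
        assert ala.seq[32:38] == "TAGCAT"

    def test_replacement_must_match_template(self, templates, ala, element):
        with pytest.raises(ValueError):
            PlantSpec("f", element.seq, ala, insertion_offset=33, tsd_len=6,
                      replacement=("AAAAAA", "GCGCAA", "both"))

    def test_slice_and_compare_oracle(self, templates, element):
        # every divergence-0 untruncated truth interval reconstructs its
        # element exactly, across many random specs
        rng = np.random.default_rng(5)
        specs = []
        for i in range(60):
            t = templates[rng.integers(0, len(templates))]
            off = int(rng.integers(10, len(t.seq) - 8))
            specs.append(PlantSpec(
                f"f{i}", element.seq, t, insertion_offset=off,
                tsd_len=int(rng.choice([6, 7])),
                orientation_rule=str(rng.choice(["same", "opposite"])),
                n_copies=1))
        genome, truth, _ = plant_genome(templates, specs, 300_000, seed=6)
        assert len(truth) == 60
        for t in truth:
            body = genome.seq[t.start : t.end]
            if t.element_strand == "-":
                body = revcomp(body)
            assert body == element.seq

    def test_conservation_of_copy_counts(self, templates, ala, element):
        specs = [PlantSpec("a", element.seq, ala, 33, n_copies=3),
                 PlantSpec("b", element.seq, ala, 20, n_copies=2)]
        _, truth, _ = plant_genome(templates, specs, 60_000, seed=8)
        assert len(truth) == 5

    def test_determinism(self, templates, ala, element):
        spec = PlantSpec("f", element.seq, ala, 33, n_copies=2)
        g1, t1, _ = plant_genome(templates, [spec], 30_000, seed=12)
        g2, t2, _ = plant_genome(templates, [spec], 30_000, seed=12)
        assert g1.seq == g2.seq
        assert [vars(a) for a in t1] == [vars(b) for b in t2]

    def test_placement_failure_is_error(self, templates, ala, element):
        spec = PlantSpec("f", element.seq, ala, 33, n_copies=50)
        with pytest.raises(RuntimeError):
            plant_genome(templates, [spec], 5_000, seed=1)


class TestDefaultScenario:
    def test_family_and_copy_contract(self, scenario):
        fams = {t.family_id for t in scenario.truth}
        assert len(fams) >= 4
        counts = {f: sum(1 for t in scenario.truth if t.family_id == f) for f in fams}
        low = [f for f, c in counts.items() if c < 3]
        assert low == ["tV"]  # exactly one low-copy family
        assert all(c >= 3 for f, c in counts.items() if f != "tV")

    def test_acceptor_d_arm_family_at_positions_8_13(self, scenario):
        ty = [t for t in scenario.truth if t.family_id == "tY"]
        assert ty and all(t.insertion_offset == 8 and t.tsd_len == 6 for t in ty)

    def test_all_tsd_lengths_are_6_or_7(self, scenario):
        assert all(t.tsd_len in (6, 7) for t in scenario.truth)

    def test_anticodon_families_opposite_orientation(self, scenario):
        for fam in ("tA", "tV"):
            assert all(t.orientation == "opposite"
                       for t in scenario.truth if t.family_id == fam)

    def test_byte_identical_across_calls(self):
        a = default_scenario(2, background_length=120_000)
        b = default_scenario(2, background_length=120_000)
        assert a.genome.seq == b.genome.seq and a.truth_json() == b.truth_json()

    def test_default_templates_have_valid_anatomy(self, templates):
        for t in templates:
            if t.gene_class == "tRNA":
                lo, hi = t.spans["a_box"]
                assert lo <= 8 and hi >= 13
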