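import numpy as np
import pytest

from dadascan.simulate import PlantSpec, plant_genome
from dadascan.targets import (
    build_target_profile,
    characterize_hit,
    classify_target,
    define_boundaries,
    detect_tsd,
    name_family,
    assign_specificity,
)


def _plant_one(templates, element, *, template_idx=0, offset=33, tsd_len=6,
               orientation="same", replacement=None, seed=4, divergence=0.0):
    spec = PlantSpec("fam", element.seq, templates[template_idx],
                     insertion_offset=offset, tsd_len=tsd_len,
                     orientation_rule=orientation, replacement=replacement,
                     n_copies=1, divergence=divergence)
    genome, truth, _ = plant_genome(
        templates, [spec], 40_000, seed=seed,
        intact_copies={templates[template_idx].name: (4, 0.02)})
    return genome, truth[0]


def _characterize(templates, genome, tr, element):
    copy = characterize_hit(genome, (tr.start, tr.end), templates, "fam",
                            element_seq=element.seq)
    byname = {t.name: t for t in templates}
    t = byname[copy.template_name]
    tsd = detect_tsd(copy, t, element.seq)
    return copy, tsd, t


class TestDefineBoundaries:
    def test_exact_interval_on_planted_copy(self, templates, element):
        genome, tr = _plant_one(templates, element)
        copy, tsd, _ = _characterize(templates, genome, tr, element)
        gs, ge = copy.genome_interval(copy.j1 + tsd.trim_left, copy.j2 - tsd.trim_right)
        assert (gs, ge) == (tr.start, tr.end)

    def test_strand_flip_gives_same_gene_local_call(self, templates, element):
        # find a copy whose array landed on the minus strand and check the
        # gene-local result matches a plus-strand plant
        for seed in range(4, 30):
            genome, tr = _plant_one(templates, element, seed=seed)
            if tr.gene_strand == "-":
                break
        assert tr.gene_strand == "-"
        copy, tsd, t = _characterize(templates, genome, tr, element)
        ann = classify_target(copy, tsd, t)
        assert ann.insertion_offset == 33 and tsd.length == 6

    def test_locus_without_insertion_is_error(self, templates):
        t = templates[0]
        rng = np.random.default_rng(5)
        bg = "".join(rng.choice(list("ACGT"), 400))
        locus = bg[:150] + t.seq + bg[150:]
        with pytest.raises(ValueError, match="no element insert"):
            define_boundaries(locus, t, hint=(150, 150 + len(t.seq)))


class TestDetectTsd:
    def test_planted_6bp_duplication(self, templates, element):
        genome, tr = _plant_one(templates, element, tsd_len=6)
        _, tsd, _ = _characterize(templates, genome, tr, element)
        assert tsd.kind == "duplication" and tsd.length == 6
        assert tsd.left_seq == tsd.right_seq == tr.tsd_left

    def test_planted_7bp_never_reported_as_6(self, templates, element):
        genome, tr = _plant_one(templates, element, template_idx=3, offset=60,
                                tsd_len=7)
        _, tsd, _ = _characterize(templates, genome, tr, element)
        assert tsd.kind == "duplication" and tsd.length == 7

    @pytest.mark.parametrize("side", ["left", "right", "both"])
    def test_replacement_called_with_replacing_sequence(self, templates, element, side):
        genome, tr = _plant_one(templates, element,
                                replacement=("TAGCAT", "GCGCAA", side))
        _, tsd, _ = _characterize(templates, genome, tr, element)
        assert tsd.kind == f"replacement_{side}"
        assert tsd.replaced_with == "GCGCAA"
        assert tsd.insertion_offset == 33


class TestClassifyTarget:
    def test_acceptor_d_boundary_at_offset_8(self, templates, element):
        genome, tr = _plant_one(templates, element, template_idx=1, offset=8)
        copy, tsd, t = _characterize(templates, genome, tr, element)
        ann = classify_target(copy, tsd, t)
        assert ann.insertion_offset == 8
        assert ann.region == "acceptor_d_boundary"

    def test_anticodon_arm_opposite_orientation(self, templates, element):
        genome, tr = _plant_one(templates, element, offset=33,
                                orientation="opposite")
        copy, tsd, t = _characterize(templates, genome, tr, element)
        ann = classify_target(copy, tsd, t)
        assert ann.orientation == "opposite"
        assert ann.region == "anticodon_arm"

    def test_5s_target_maps_to_other_region(self, templates, element):
        genome, tr = _plant_one(templates, element, template_idx=3, offset=60,
                                tsd_len=7)
        copy, tsd, t = _characterize(templates, genome, tr, element)
        ann = classify_target(copy, tsd, t)
        assert ann.region == "other" and ann.insertion_offset == 60


class TestAssignSpecificity:
    def _member(self, template_name, flanked=True):
        from dadascan.targets import ElementCopy, TsdCall, TargetAnnotation

        copy = ElementCopy("f", template_name, "A" * 200, 50, 150, 10, 4,
                           20 if flanked else 0, 20 if flanked else 0)
        tsd = TsdCall(6, "AAAAAA", "AAAAAA", "duplication")
        ann = TargetAnnotation(template_name, "tRNA", 33, "same",
                               "anticodon_arm", flanked)
        return copy, tsd, ann

    def test_modal_target_wins_with_secondary_counts(self, templates):
        byname = {t.name: t for t in templates}
        members = [self._member("tRNA-Val-TAC"), self._member("tRNA-Val-TAC"),
                   self._member("tRNA-Ala-AGC")]
        label, secondary = assign_specificity(members, byname)
        assert label == "tV" and secondary == {"tRNA-Ala-AGC": 1}

    def test_all_5s_members(self, templates):
        byname = {t.name: t for t in templates}
        m = self._member("5S-rRNA")
        m[2].gene_class = "rRNA5S"
        label, secondary = assign_specificity([m], byname)
        assert label == "5S" and secondary == {}

    def test_no_flanked_member_is_unconfirmed(self, templates):
        byname = {t.name: t for t in templates}
        members = [self._member("tRNA-Val-TAC", flanked=False)]
        assert assign_specificity(members, byname)[0] == "unconfirmed"


class TestTargetProfile:
    def test_single_window_equals_profile(self, templates, element):
        genome, tr = _plant_one(templates, element)
        copy, tsd, _ = _characterize(templates, genome, tr, element)
        prof = build_target_profile([(copy, tsd)])
        assert prof.windows[0] == prof.consensus
        assert prof.counts.sum() == len(prof.consensus)

    def test_counts_conserve_window_number(self, templates, element):
        pairs = []
        for seed in (4, 5, 6):
            genome, tr = _plant_one(templates, element, seed=seed)
            copy, tsd, _ = _characterize(templates, genome, tr, element)
            pairs.append((copy, tsd))
        prof = build_target_profile(pairs)
        assert (prof.counts.sum(axis=1) == len(prof.windows)).all()

    def test_argmax_over_stacked_windows(self):
        # hand-built windows: three TAGCTC-site copies vs one TGGCGC
        from dadascan.targets import TargetSiteProfile, _BASE_IDX
        import numpy as np

        windows = ["TAGCTC"] * 3 + ["TGGCGC"]
        counts = np.zeros((6, 4), dtype=int)
        for w in windows:
            for i, c in enumerate(w):
                counts[i, _BASE_IDX[c]] += 1
        cons = "".join("ACGT"[int(counts[i].argmax())] if
                       (counts[i] == counts[i].max()).sum() == 1 else "N"
                       for i in range(6))
        assert cons == "TAGCTC"


class TestNameFamily:
    def test_first_name(self):
        assert name_family("tA", "CaAu", set()) == "Dada-tA_CaAu"

    def test_collision_appends_number(self):
        assert name_family("tA", "CaAu", {"Dada-tA_CaAu"}) == "Dada-tA2_CaAu"

    def test_collision_on_5s(self):
        assert name_family("5S", "CaAu", {"Dada-5S_CaAu"}) == "Dada-5S2_CaAu"

    def test_unconfirmed_is_numbered_x(self):
        assert name_family("unconfirmed", "CaAu", set()) == "Dada-X1_CaAu"
        assert name_family("unconfirmed", "CaAu", {"Dada-X1_CaAu"}) == "Dada-X2_CaAu"

    def test_bad_species_code_is_error(self):
        with pytest.raises(ValueError):
            name_family("tA", "", set())
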