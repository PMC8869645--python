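"""Synthetic genomes with multicopy small-RNA gene arrays and planted
transposon insertions, with complete ground truth.

The generator emulates the substrate that a target-specific DNA
transposon survey assumes: a genome carrying tandem arrays of diverged
tRNA/5S gene copies (with a conserved per-template intergenic spacer, as
real pol-III gene arrays have), a subset of which are interrupted by
planted element insertions. Each insertion duplicates a 6- or 7-bp
target site on both flanks, or replaces it with a family-specific
sequence on one or both sides; elements may be inserted in either
orientation relative to the gene and may be 5'-truncated. Divergence is
i.i.d. substitution only (no indels), so consensus recovery is exact at
zero divergence.

Every planted copy is described by a :class:`TruthRecord`; slicing the
emitted genome at a truth interval reconstructs the planted element
(untruncated, divergence 0). A single PRNG stream seeded from one
integer governs all randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .align import revcomp
from .io import AnnotationRow, GenomeRecord, RnaGeneTemplate

_BASES = np.array(list("ACGT"))

# codon table: aa -> sorted list of codons (no stops)
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)
_STOPS = sorted(standard_dna_table.stop_codons)
_AA20 = sorted(_CODONS_FOR)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def mutate_seq(seq: str, rng: np.random.Generator, p: float) -> str:
    """Apply i.i.d. substitutions (never to the same base) at rate p."""
    if p <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < p)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# transposon elements

@dataclass
class Element:
    """A synthetic transposon element: nucleotide sequence carrying one
    transposase-like ORF with annotated catalytic-motif positions.

    ``motif_positions`` holds 1-based residue positions on ``protein``
    for the DDE triad (d1, d2, e) and the DxxH signature (dxxh_d, h).
    """

    seq: str
    orf_start: int  # 0-based, on the + strand of seq
    orf_len_nt: int
    protein: str  # translation, including initial M, excluding stop
    motif_positions: dict[str, int]

    def __len__(self) -> int:
        return len(self.seq)


def build_element(seed: int, length: int = 1900, orf_length: int = 520) -> Element:
    """Build a random element containing one ORF of exactly ``orf_length``
    codons (start codon, no internal stop, stop codon) whose protein
    carries D, D, E catalytic residues and a DxxH block at recorded
    positions. The remainder of the element is random sequence.
    """
    if orf_length * 3 + 6 > length:
        raise ValueError(
            f"length {length} too small for a {orf_length}-codon ORF plus margins"
        )
    rng = np.random.default_rng(seed)
    n_aa = orf_length - 1  # protein residues incl. initial M; stop codon excluded
    protein = ["M"] + [_AA20[i] for i in rng.integers(0, 20, n_aa - 1)]
    pos = {
        "d1": int(round(0.25 * n_aa)),
        "d2": int(round(0.45 * n_aa)),
        "dxxh_d": int(round(0.60 * n_aa)),
        "e": int(round(0.80 * n_aa)),
    }
    pos["h"] = pos["dxxh_d"] + 3
    protein[pos["d1"] - 1] = "D"
    protein[pos["d2"] - 1] = "D"
    protein[pos["dxxh_d"] - 1] = "D"
    protein[pos["h"] - 1] = "H"
    protein[pos["e"] - 1] = "E"
    prot = "".join(protein)
    codons = ["ATG"]
    for aa in prot[1:]:
        opts = _CODONS_FOR[aa]
        codons.append(opts[rng.integers(0, len(opts))])
    codons.append(_STOPS[rng.integers(0, len(_STOPS))])
    orf = "".join(codons)
    orf_start = int(rng.integers(3, length - len(orf) - 2))
    # an in-frame stop just upstream keeps the planted ORF the longest one
    left = _random_dna(rng, orf_start - 3) + "TAA"
    right = _random_dna(rng, length - orf_start - len(orf))
    return Element(
        seq=left + orf + right,
        orf_start=orf_start,
        orf_len_nt=len(orf),
        protein=prot,
        motif_positions=pos,
    )


def mutate_element(
    element: Element,
    seed: int,
    aa_divergence: float = 0.35,
    synonymous_rate: float = 0.15,
    noncoding_divergence: float = 0.25,
) -> Element:
    """Derive a diverged element: codon-level substitutions in the ORF
    (catalytic-motif residues and start/stop preserved, no stops
    introduced), free substitution elsewhere. Used to create related
    families descending from a common ancestral element.
    """
    rng = np.random.default_rng(seed)
    keep = {p - 1 for p in element.motif_positions.values()} | {0}
    prot = list(element.protein)
    codons = [
        element.seq[element.orf_start + 3 * i : element.orf_start + 3 * i + 3]
        for i in range(len(element.protein))
    ]
    for i in range(len(prot)):
        if i in keep:
            continue
        if rng.random() < aa_divergence:
            new_aa = prot[i]
            while new_aa == prot[i]:
                new_aa = _AA20[rng.integers(0, 20)]
            prot[i] = new_aa
            opts = _CODONS_FOR[new_aa]
            codons[i] = opts[rng.integers(0, len(opts))]
        elif rng.random() < synonymous_rate:
            opts = _CODONS_FOR[prot[i]]
            codons[i] = opts[rng.integers(0, len(opts))]
    stop = _STOPS[rng.integers(0, len(_STOPS))]
    # preserve the in-frame stop guarding the ORF start
    left = (
        mutate_seq(element.seq[: element.orf_start - 3], rng, noncoding_divergence)
        + element.seq[element.orf_start - 3 : element.orf_start]
    )
    right = mutate_seq(
        element.seq[element.orf_start + element.orf_len_nt :], rng, noncoding_divergence
    )
    return Element(
        seq=left + "".join(codons) + stop + right,
        orf_start=len(left),
        orf_len_nt=element.orf_len_nt,
        protein="".join(prot),
        motif_positions=dict(element.motif_positions),
    )


# ---------------------------------------------------------------------------
# plant specifications and truth

@dataclass
class PlantSpec:
    """How to plant one family's copies into target-gene copies."""

    family_id: str
    element_seq: str
    target_template: RnaGeneTemplate
    insertion_offset: int  # 1-based gene position of the first duplicated base
    tsd_len: int = 6
    orientation_rule: str = "same"  # element ORF sense vs gene sense
    replacement: Optional[tuple[str, str, str]] = None  # (replaced, replacement, sidedness)
    n_copies: int = 1
    truncation_prob: float = 0.0
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.tsd_len not in (6, 7):
            raise ValueError(f"tsd_len must be 6 or 7, got {self.tsd_len}")
        if self.orientation_rule not in ("same", "opposite"):
            raise ValueError(f"orientation_rule must be same/opposite")
        t = self.target_template
        if self.insertion_offset + self.tsd_len - 1 > len(t.seq):
            raise ValueError(
                f"insertion_offset {self.insertion_offset} + tsd_len {self.tsd_len} "
                f"exceeds template {t.name!r} length {len(t.seq)}"
            )
        if self.replacement is not None:
            replaced, replacement, side = self.replacement
            if side not in ("left", "right", "both"):
                raise ValueError(f"replacement sidedness must be left/right/both")
            if len(replaced) != self.tsd_len:
                raise ValueError("replaced_seq length must equal tsd_len")
            o = self.insertion_offset - 1
            if t.seq[o : o + self.tsd_len] != replaced:
                raise ValueError(
                    f"replaced_seq {replaced!r} does not match template "
                    f"{t.name!r} at offset {self.insertion_offset}"
                )
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth for one planted copy. Coordinates are 0-based
    half-open on the + strand of the emitted genome; the element body
    interval excludes both TSD copies. TSD sequences are reported in
    gene orientation (left = upstream of the element on the gene sense
    strand)."""

    copy_id: str
    family_id: str
    genome_id: str
    start: int
    end: int
    element_strand: str  # genome strand on which the element seq reads forward
    gene_strand: str
    target_gene: str
    insertion_offset: int  # 1-based, gene-local
    tsd_len: int
    tsd_left: str
    tsd_right: str
    orientation: str  # same / opposite (element ORF vs gene)
    truncated: bool
    replacement_sidedness: str  # none / left / right / both

    def to_dict(self) -> dict:
        return dict(vars(self))


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


@dataclass
class _Unit:
    seq: str
    features: list  # (kind, start, end, strand, payload)


def _build_inserted_unit(spec: PlantSpec, rng: np.random.Generator, copy_id: str) -> _Unit:
    t = spec.target_template
    g = mutate_seq(t.seq, rng, spec.divergence)
    o = spec.insertion_offset - 1
    L = spec.tsd_len
    elem = mutate_seq(spec.element_seq, rng, spec.divergence)
    truncated = False
    if spec.truncation_prob > 0 and rng.random() < spec.truncation_prob:
        cut = int(rng.integers(int(0.1 * len(elem)), int(0.7 * len(elem))))
        elem = elem[cut:]
        truncated = True
    e_ins = elem if spec.orientation_rule == "same" else revcomp(elem)
    tsd = g[o : o + L]
    x_left, x_right = tsd, tsd
    side = "none"
    if spec.replacement is not None:
        _, replacement, side = spec.replacement
        if side in ("left", "both"):
            x_left = replacement
        if side in ("right", "both"):
            x_right = replacement
    seq = g[:o] + x_left + e_ins + x_right + g[o + L :]
    body_start = o + len(x_left)
    body_end = body_start + len(e_ins)
    payload = dict(
        copy_id=copy_id,
        family_id=spec.family_id,
        target_gene=t.name,
        insertion_offset=spec.insertion_offset,
        tsd_len=L,
        tsd_left=x_left,
        tsd_right=x_right,
        orientation=spec.orientation_rule,
        truncated=truncated,
        replacement_sidedness=side,
        element_strand_in_unit="+" if spec.orientation_rule == "same" else "-",
    )
    return _Unit(seq, [("element", body_start, body_end, "+", payload),
                       ("gene", 0, len(seq), "+", dict(target_gene=t.name, inserted=True))])


def plant_genome(
    templates: Sequence[RnaGeneTemplate],
    plant_specs: Sequence[PlantSpec],
    background_length: int,
    seed: int,
    intact_copies: dict[str, tuple[int, float]] | None = None,
    genome_id: str = "synth_chr1",
    array_units: tuple[int, int] = (4, 7),
    spacer_length: tuple[int, int] = (190, 250),
    max_retries: int = 1000,
) -> tuple[GenomeRecord, list[TruthRecord], list[AnnotationRow]]:
    """Emit a genome with planted insertions and complete ground truth.

    Gene copies (intact ones per ``intact_copies``: template name ->
    (count, divergence), plus every inserted copy) are organised into
    tandem arrays with a conserved per-template spacer and placed at
    random non-overlapping loci on a uniform-random background, on either
    strand with probability 0.5. Returns the genome, one TruthRecord per
    planted copy, and annotation rows for all planted features.
    """
    rng = np.random.default_rng(seed)
    by_name = {t.name: t for t in templates}
    for spec in plant_specs:
        if spec.target_template.name not in by_name:
            raise ValueError(f"spec {spec.family_id} references unknown template")
    spacers = {t.name: _random_dna(rng, int(rng.integers(*spacer_length))) for t in templates}

    # compose units per template
    units_by_template: dict[str, list[_Unit]] = {t.name: [] for t in templates}
    counter = 0
    for spec in plant_specs:
        for _ in range(spec.n_copies):
            cid = f"{spec.family_id}.{counter}"
            counter += 1
            units_by_template[spec.target_template.name].append(
                _build_inserted_unit(spec, rng, cid)
            )
    for name, (count, div) in (intact_copies or {}).items():
        t = by_name[name]
        for _ in range(count):
            g = mutate_seq(t.seq, rng, div)
            units_by_template[name].append(
                _Unit(g, [("gene", 0, len(g), "+", dict(target_gene=name, inserted=False))])
            )

    # assemble arrays joined by diverged copies of the spacer; inserted
    # units go to interior array positions when intact copies allow it,
    # emulating the low edge probability of real multi-hundred-copy
    # tandem arrays
    arrays: list[_Unit] = []
    for name, units in units_by_template.items():
        if not units:
            continue
        inserted = [u for u in units if u.features[0][0] == "element"]
        plain = [u for u in units if u.features[0][0] != "element"]
        inserted = [inserted[i] for i in rng.permutation(len(inserted))] if inserted else []
        plain = [plain[i] for i in rng.permutation(len(plain))] if plain else []
        chunks: list[list[_Unit]] = []
        while inserted or plain:
            size = int(rng.integers(array_units[0], array_units[1] + 1))
            take_ins = min(len(inserted), 2, max(0, size - 2))
            take_plain = min(len(plain), size - take_ins)
            if take_ins == 0 and take_plain == 0:
                take_ins = min(len(inserted), size)
            chunk_ins = [inserted.pop() for _ in range(take_ins)]
            chunk_plain = [plain.pop() for _ in range(take_plain)]
            if len(chunk_plain) >= 2 and chunk_ins:
                interior = chunk_plain[1:-1] + chunk_ins
                interior = [interior[i] for i in rng.permutation(len(interior))]
                chunks.append([chunk_plain[0]] + interior + [chunk_plain[-1]])
            else:
                merged = chunk_plain + chunk_ins
                chunks.append([merged[i] for i in rng.permutation(len(merged))])
        for chunk in chunks:
            seq_parts: list[str] = []
            feats = []
            off = 0
            for j, u in enumerate(chunk):
                seq_parts.append(u.seq)
                for kind, s, e, st, payload in u.features:
                    feats.append((kind, s + off, e + off, st, payload))
                off += len(u.seq)
                if j < len(chunk) - 1:
                    sp = mutate_seq(spacers[name], rng, 0.05)
                    seq_parts.append(sp)
                    off += len(sp)
            arrays.append(_Unit("".join(seq_parts), feats))

    # orient each array and place it on the background without overlap
    genome = np.array(list(_random_dna(rng, background_length)))
    placed: list[tuple[int, int]] = []
    truths: list[TruthRecord] = []
    annotations: list[AnnotationRow] = []
    for arr in arrays:
        arr_strand = "+" if rng.random() < 0.5 else "-"
        seq = arr.seq
        feats = arr.features
        if arr_strand == "-":
            n = len(seq)
            seq = revcomp(seq)
            feats = [(k, n - e, n - s, _flip(st), p) for k, s, e, st, p in feats]
        if len(seq) + 40 >= background_length:
            raise RuntimeError(
                "could not place a gene array without overlap; "
                "increase background_length"
            )
        pos = None
        for _ in range(max_retries):
            cand = int(rng.integers(0, background_length - len(seq)))
            if all(cand + len(seq) + 20 <= s or cand >= e + 20 for s, e in placed):
                pos = cand
                break
        if pos is None:
            raise RuntimeError(
                "could not place a gene array without overlap; "
                "increase background_length"
            )
        placed.append((pos, pos + len(seq)))
        genome[pos : pos + len(seq)] = list(seq)
        for kind, s, e, st, payload in feats:
            gs, ge = pos + s, pos + e
            if kind == "element":
                p = payload
                gene_strand = arr_strand
                elem_strand = (
                    p["element_strand_in_unit"] if arr_strand == "+"
                    else _flip(p["element_strand_in_unit"])
                )
                truths.append(
                    TruthRecord(
                        copy_id=p["copy_id"],
                        family_id=p["family_id"],
                        genome_id=genome_id,
                        start=gs,
                        end=ge,
                        element_strand=elem_strand,
                        gene_strand=gene_strand,
                        target_gene=p["target_gene"],
                        insertion_offset=p["insertion_offset"],
                        tsd_len=p["tsd_len"],
                        tsd_left=p["tsd_left"],
                        tsd_right=p["tsd_right"],
                        orientation=p["orientation"],
                        truncated=p["truncated"],
                        replacement_sidedness=p["replacement_sidedness"],
                    )
                )
                annotations.append(
                    AnnotationRow(genome_id, gs, ge, elem_strand, f"element:{p['copy_id']}")
                )
            else:
                label = "gene_inserted" if payload.get("inserted") else "gene"
                annotations.append(
                    AnnotationRow(genome_id, gs, ge, st if arr_strand == "+" else st,
                                  f"{label}:{payload['target_gene']}")
                )
    record = GenomeRecord(genome_id, "synthetic genome with planted insertions",
                          "".join(genome))
    return record, truths, annotations


# ---------------------------------------------------------------------------
# gene templates

# shared tRNA scaffold pieces (73 nt total); the A-box hexamer (positions
# 8-13) and the anticodon loop (31-39) vary per template, plus a 10-nt
# variable arm so templates are distinguishable by alignment
_ACCEPTOR = "GCCGGGA"  # 1-7
_DLOOP = "AGCTCAGTTGGT"  # 14-25
_STEM2 = "AGAGC"  # 26-30
_TAIL_FIXED = "GGTTCGATTCCCAGTCCGGGCACC"  # 50-73, contains the B box


def make_trna_template(
    name: str, isotype: str, anticodon: str, abox_hexamer: str, loop9: str, var10: str
) -> RnaGeneTemplate:
    """Assemble a 73-nt tRNA-like gene template with annotated spans:
    acceptor_stem [1,7], a_box [8,19] (hexamer at 8-13), d_arm [14,25],
    anticodon_loop [31,39] (anticodon at 34-36)."""
    if len(abox_hexamer) != 6 or len(loop9) != 9 or len(var10) != 10:
        raise ValueError("abox_hexamer must be 6 nt, loop 9 nt, variable arm 10 nt")
    seq = _ACCEPTOR + abox_hexamer + _DLOOP + _STEM2 + loop9 + var10 + _TAIL_FIXED
    return RnaGeneTemplate(
        name=name,
        gene_class="tRNA",
        isotype=isotype,
        anticodon=anticodon,
        seq=seq,
        spans={
            "acceptor_stem": (1, 7),
            "a_box": (8, 19),
            "d_arm": (14, 25),
            "anticodon_loop": (31, 39),
        },
    )


def make_5s_template(name: str = "5S-rRNA", seed: int = 505) -> RnaGeneTemplate:
    """A 119-nt 5S rRNA-like gene template (fixed sequence)."""
    rng = np.random.default_rng(seed)
    return RnaGeneTemplate(name=name, gene_class="rRNA5S", seq=_random_dna(rng, 119))


def default_templates() -> list[RnaGeneTemplate]:
    """The template library used by the packaged scenario."""
    return [
        # anticodon-arm target: positions 33-38 read TAGCAT (anticodon AGC)
        make_trna_template("tRNA-Ala-AGC", "Ala", "AGC", "TGGTAT", "CTTAGCATA", "ACGTTGACTA"),
        # acceptor/D-arm boundary target: A-box hexamer TAGCTC at 8-13
        make_trna_template("tRNA-Tyr-GTA", "Tyr", "GTA", "TAGCTC", "CTTGTAAAT", "GATCCATGGA"),
        # anticodon-arm target for the low-copy family
        make_trna_template("tRNA-Val-TAC", "Val", "TAC", "TGGTGA", "CTTTACAAT", "TTCAGGCTAC"),
        make_5s_template(),
    ]


# ---------------------------------------------------------------------------
# packaged scenario

@dataclass
class Scenario:
    """A complete synthetic study: genome, template library, planted
    truth, the ancestral transposase used as the survey query, and the
    per-family planted specificity labels."""

    genome: GenomeRecord
    templates: list[RnaGeneTemplate]
    truth: list[TruthRecord]
    annotations: list[AnnotationRow]
    specs: list[PlantSpec]
    elements: dict[str, Element]
    ancestor: Element
    planted_labels: dict[str, str]
    seed: int

    def truth_json(self) -> str:
        return json.dumps(
            {
                "genome_id": self.genome.id,
                "seed": self.seed,
                "planted_labels": self.planted_labels,
                "records": [t.to_dict() for t in self.truth],
            },
            indent=1,
        )


def default_scenario(seed: int = 1, background_length: int = 260_000) -> Scenario:
    """The packaged synthetic survey: four families covering
    anticodon-arm targeting in opposite orientation, acceptor/D-arm
    boundary targeting at gene positions 8-13 (with both-sided target
    replacement in part of one family), a 5S-targeting family with 7-bp
    TSDs, and a 2-copy family exercising the low-copy fallback.
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(1, 2**31 - 1, 8)]
    templates = default_templates()
    t_ala, t_tyr, t_val, t_5s = templates
    ancestor = build_element(sub[0], length=1900, orf_length=520)
    elements = {
        "tA": mutate_element(ancestor, sub[1]),
        "tY": mutate_element(ancestor, sub[2]),
        "5S": mutate_element(ancestor, sub[3]),
        "tV": mutate_element(ancestor, sub[4]),
    }
    specs = [
        # anticodon arm, opposite orientation, 6-bp TSD
        PlantSpec("tA", elements["tA"].seq, t_ala, insertion_offset=33, tsd_len=6,
                  orientation_rule="opposite", n_copies=4, divergence=0.02),
        # part of the same family with both-sided target replacement
        PlantSpec("tA", elements["tA"].seq, t_ala, insertion_offset=33, tsd_len=6,
                  orientation_rule="opposite", n_copies=2, divergence=0.0,
                  replacement=("TAGCAT", "GCGCAA", "both")),
        # acceptor-stem/D-arm boundary (gene positions 8-13), 6-bp TSD
        PlantSpec("tY", elements["tY"].seq, t_tyr, insertion_offset=8, tsd_len=6,
                  orientation_rule="same", n_copies=5, divergence=0.02),
        # 5S rRNA target, 7-bp TSD
        PlantSpec("5S", elements["5S"].seq, t_5s, insertion_offset=60, tsd_len=7,
                  orientation_rule="same", n_copies=4, divergence=0.01),
        # low-copy family (2 copies) for the fallback path
        PlantSpec("tV", elements["tV"].seq, t_val, insertion_offset=33, tsd_len=6,
                  orientation_rule="opposite", n_copies=2, divergence=0.0),
    ]
    intact = {
        "tRNA-Ala-AGC": (14, 0.02),
        "tRNA-Tyr-GTA": (12, 0.02),
        "tRNA-Val-TAC": (8, 0.02),
        "5S-rRNA": (10, 0.02),
    }
    genome, truth, annotations = plant_genome(
        templates, specs, background_length, seed=sub[5], intact_copies=intact
    )
    return Scenario(
        genome=genome,
        templates=templates,
        truth=truth,
        annotations=annotations,
        specs=specs,
        elements=elements,
        ancestor=ancestor,
        planted_labels={"tA": "tA", "tY": "tY", "5S": "5S", "tV": "tV"},
        seed=seed,
    )
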