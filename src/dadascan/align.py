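"""Alignment kernels and homology search.

This module provides the exact affine-gap aligners used throughout the
pipeline (global Needleman-Wunsch-Gotoh and local Smith-Waterman-Gotoh),
a k-mer seeded nucleotide search used to locate element copies in a
genome, and a six-frame translated search used to survey a genome with a
transposase protein query.

Identity is counted over alignment columns where both rows are non-gap;
coverage of a sequence is the aligned (non-terminal-gap) span divided by
its full length.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._kernels import gotoh_align

# ---------------------------------------------------------------------------
# scoring

_DNA_ORDER = "ACGTN"
_DNA_CODE = {c: i for i, c in enumerate(_DNA_ORDER)}

_B62 = substitution_matrices.load("BLOSUM62")
PROTEIN_ALPHABET = str(_B62.alphabet)  # includes B, Z, X, *
_AA_CODE = {c: i for i, c in enumerate(PROTEIN_ALPHABET)}
_B62_MATRIX = np.array(_B62, dtype=np.int64)


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring. Defaults are conventional for diverged
    repeat-family DNA: match +2, mismatch -3, gap open -5, gap extend -2.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def matrix(self) -> np.ndarray:
        S = np.full((5, 5), self.mismatch, dtype=np.int64)
        for i in range(4):
            S[i, i] = self.match
        S[4, :] = self.mismatch  # N never matches
        S[:, 4] = self.mismatch
        return S


@dataclass(frozen=True)
class ProteinScoring:
    """BLOSUM62 with conventional gap penalties."""

    gap_open: int = -11
    gap_extend: int = -1

    def matrix(self) -> np.ndarray:
        return _B62_MATRIX


DEFAULT_DNA_SCORING = Scoring()
DEFAULT_PROTEIN_SCORING = ProteinScoring()


def _encode_dna(s: str) -> np.ndarray:
    return np.array([_DNA_CODE.get(c, 4) for c in s], dtype=np.int64)


def _encode_protein(s: str) -> np.ndarray:
    x = _AA_CODE["X"]
    return np.array([_AA_CODE.get(c, x) for c in s], dtype=np.int64)


def revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


# ---------------------------------------------------------------------------
# pairwise alignment

@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    coverage_a: float
    coverage_b: float
    mode: str
    a_interval: tuple[int, int] = (0, 0)  # 0-based half-open span aligned on a
    b_interval: tuple[int, int] = (0, 0)

    def __len__(self) -> int:
        return len(self.aligned_a)


def _build_alignment(a, b, score, ai, bi, mode) -> PairwiseAlignment:
    cols_a = []
    cols_b = []
    matches = 0
    both = 0
    for x, y in zip(ai, bi):
        ca = a[x] if x >= 0 else "-"
        cb = b[y] if y >= 0 else "-"
        cols_a.append(ca)
        cols_b.append(cb)
        if x >= 0 and y >= 0:
            both += 1
            if ca == cb and ca != "N":
                matches += 1
    a_pos = [x for x in ai if x >= 0]
    b_pos = [y for y in bi if y >= 0]
    a_iv = (a_pos[0], a_pos[-1] + 1) if a_pos else (0, 0)
    b_iv = (b_pos[0], b_pos[-1] + 1) if b_pos else (0, 0)
    cov_a = (a_iv[1] - a_iv[0]) / len(a) if a else 0.0
    cov_b = (b_iv[1] - b_iv[0]) / len(b) if b else 0.0
    return PairwiseAlignment(
        aligned_a="".join(cols_a),
        aligned_b="".join(cols_b),
        score=score,
        identity=matches / both if both else 0.0,
        coverage_a=cov_a,
        coverage_b=cov_b,
        mode=mode,
        a_interval=a_iv,
        b_interval=b_iv,
    )


def align_global(a: str, b: str, scoring: Scoring = DEFAULT_DNA_SCORING) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two DNA sequences."""
    if not a or not b:
        raise ValueError("align_global requires non-empty sequences")
    score, ai, bi = gotoh_align(
        _encode_dna(a), _encode_dna(b), scoring.matrix(), scoring.gap_open, scoring.gap_extend, False
    )
    return _build_alignment(a, b, score, ai, bi, "global")


def align_local(a: str, b: str, scoring: Scoring = DEFAULT_DNA_SCORING) -> PairwiseAlignment:
    """Optimal affine-gap local alignment; the empty alignment (score 0)
    is returned when nothing scores positive."""
    if not a or not b:
        raise ValueError("align_local requires non-empty sequences")
    score, ai, bi = gotoh_align(
        _encode_dna(a), _encode_dna(b), scoring.matrix(), scoring.gap_open, scoring.gap_extend, True
    )
    return _build_alignment(a, b, score, ai, bi, "local")


def align_protein_global(a: str, b: str, scoring: ProteinScoring = DEFAULT_PROTEIN_SCORING) -> PairwiseAlignment:
    if not a or not b:
        raise ValueError("alignment requires non-empty sequences")
    score, ai, bi = gotoh_align(
        _encode_protein(a), _encode_protein(b), scoring.matrix(), scoring.gap_open, scoring.gap_extend, False
    )
    return _build_alignment(a, b, score, ai, bi, "global")


def align_protein_local(a: str, b: str, scoring: ProteinScoring = DEFAULT_PROTEIN_SCORING) -> PairwiseAlignment:
    if not a or not b:
        raise ValueError("alignment requires non-empty sequences")
    score, ai, bi = gotoh_align(
        _encode_protein(a), _encode_protein(b), scoring.matrix(), scoring.gap_open, scoring.gap_extend, True
    )
    return _build_alignment(a, b, score, ai, bi, "local")


# ---------------------------------------------------------------------------
# hits

@dataclass
class Hit:
    """One homology hit on a subject sequence (0-based half-open)."""

    query_id: str
    subject_id: str
    start: int
    end: int
    strand: str
    score: float
    identity: float
    frame: int = 0  # 0 for nucleotide hits; 1..3 / -1..-3 for translated hits

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_hits(hits: list[Hit], max_gap: int = 50) -> list[Hit]:
    """Merge overlapping or nearby hits on the same strand (chaining)."""
    out: list[Hit] = []
    for strand in "+-":
        sh = sorted((h for h in hits if h.strand == strand), key=lambda h: (h.start, h.end))
        cur: Hit | None = None
        for h in sh:
            if cur is not None and h.start <= cur.end + max_gap:
                w1, w2 = cur.length, h.length
                cur.identity = (cur.identity * w1 + h.identity * w2) / (w1 + w2)
                cur.end = max(cur.end, h.end)
                cur.score = cur.score + h.score
            else:
                if cur is not None:
                    out.append(cur)
                cur = Hit(**vars(h))
        if cur is not None:
            out.append(cur)
    out.sort(key=lambda h: (h.start, h.end, h.strand))
    return out


def seed_extend_search(
    query_dna: str,
    genome,
    k: int = 12,
    min_identity: float = 0.75,
    min_length: int = 100,
    scoring: Scoring = DEFAULT_DNA_SCORING,
    query_id: str = "query",
    merge_gap: int = 50,
) -> list[Hit]:
    """Exact k-mer seeded search of ``query_dna`` against a genome record,
    on both strands, with local-alignment extension of seed clusters.

    Any region sharing an exact k-mer with the query is examined; hits
    are reported when the local alignment reaches ``min_identity`` and
    spans at least ``min_length`` on the subject. Overlapping hits on the
    same strand are merged.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if len(query_dna) < k:
        raise ValueError("query shorter than k")
    gseq = genome.seq if hasattr(genome, "seq") else str(genome)
    gid = getattr(genome, "id", "subject")
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(gseq) - k + 1):
        kmer = gseq[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)

    hits: list[Hit] = []
    for strand in "+-":
        q = query_dna if strand == "+" else revcomp(query_dna)
        seeds: list[tuple[int, int]] = []  # (genome pos, query pos)
        for qpos in range(len(q) - k + 1):
            for gpos in index.get(q[qpos : qpos + k], ()):
                seeds.append((gpos, qpos))
        if not seeds:
            continue
        # project each seed to a candidate genomic window for the full query
        windows: list[tuple[int, int]] = []
        for gpos, qpos in seeds:
            s = max(0, gpos - qpos - merge_gap)
            e = min(len(gseq), gpos + (len(q) - qpos) + merge_gap)
            windows.append((s, e))
        windows.sort()
        merged: list[list[int]] = []
        for s, e in windows:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            aln = align_local(q, gseq[s:e], scoring)
            sub_len = aln.b_interval[1] - aln.b_interval[0]
            if sub_len >= min_length and aln.identity >= min_identity:
                hits.append(
                    Hit(
                        query_id=query_id,
                        subject_id=gid,
                        start=int(s + aln.b_interval[0]),
                        end=int(s + aln.b_interval[1]),
                        strand=strand,
                        score=float(aln.score),
                        identity=aln.identity,
                    )
                )
    return _merge_hits(hits, merge_gap)


# ---------------------------------------------------------------------------
# translated search

def six_frame_translations(seq: str) -> list[tuple[int, str, str]]:
    """Return [(frame, strand, protein)] for frames 1..3 on each strand.

    Frame f on strand + starts at nucleotide f-1; on strand - it starts
    at f-1 of the reverse complement. Ambiguous codons translate to X.
    """
    out = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for f in range(3):
            sub = s[f : len(s) - ((len(s) - f) % 3)]
            prot = str(Seq(sub).translate()) if sub else ""
            out.append((f + 1, strand, prot))
    return out


def translated_search(
    protein_query: str,
    genome,
    scoring_aa: ProteinScoring = DEFAULT_PROTEIN_SCORING,
    min_score: int = 100,
    seed_k: int = 4,
    query_id: str = "query",
    merge_gap_nt: int = 150,
) -> list[Hit]:
    """Search a genome with a protein query across all six reading frames.

    Each frame translation is split at stop codons into segments;
    segments sharing an exact ``seed_k``-mer with the query are locally
    aligned against it with BLOSUM62. Hits are reported in DNA
    coordinates with the frame recorded (positive for + strand, negative
    for -). Nearby hits on one strand are merged, which joins ORF
    fragments separated by isolated stop codons in diverged copies.
    """
    gseq = genome.seq if hasattr(genome, "seq") else str(genome)
    gid = getattr(genome, "id", "subject")
    qkmers = {protein_query[i : i + seed_k] for i in range(len(protein_query) - seed_k + 1)}
    glen = len(gseq)
    hits: list[Hit] = []
    for frame, strand, prot in six_frame_translations(gseq):
        # split into inter-stop segments, keeping coordinates
        start = 0
        segments: list[tuple[int, str]] = []
        for part in prot.split("*"):
            if part:
                segments.append((start, part))
            start += len(part) + 1
        for aa_off, seg in segments:
            if len(seg) < 20:
                continue
            if not any(seg[i : i + seed_k] in qkmers for i in range(len(seg) - seed_k + 1)):
                continue
            aln = align_protein_local(protein_query, seg, scoring_aa)
            if aln.score < min_score:
                continue
            aa_s = aa_off + aln.b_interval[0]
            aa_e = aa_off + aln.b_interval[1]
            nt_s = (frame - 1) + 3 * aa_s
            nt_e = (frame - 1) + 3 * aa_e
            if strand == "-":
                nt_s, nt_e = glen - nt_e, glen - nt_s
            hits.append(
                Hit(
                    query_id=query_id,
                    subject_id=gid,
                    start=nt_s,
                    end=nt_e,
                    strand=strand,
                    score=aln.score,
                    identity=aln.identity,
                    frame=frame if strand == "+" else -frame,
                )
            )
    return _merge_hits(hits, merge_gap_nt)
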