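"""Family building: single-linkage clustering of homology hits,
majority-rule consensus construction, and consensus elongation with
genomic flanks until the targeted small-RNA gene is reached on both
sides, with a fallback path for low-copy families.

Clustering follows BLASTCLUST-style semantics: two sequences are linked
when their global identity and mutual length coverage both reach the
thresholds (defaults 0.75/0.75), and clusters are the connected
components of that link graph. Consensus calling applies the 50%
majority rule per column; columns where gaps hold a strict majority are
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import (
    DEFAULT_DNA_SCORING,
    Hit,
    PairwiseAlignment,
    Scoring,
    align_global,
    align_local,
    revcomp,
)
from .io import RnaGeneTemplate

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# clustering

@dataclass
class HitCluster:
    """A connected component of linked hits. ``member_seqs`` are oriented
    to the + strand of the cluster (the representative's strand);
    ``hits`` are kept when clustering genomic hits so members can be
    re-extracted with flanks."""

    member_ids: list[str]
    member_seqs: list[str]
    representative_id: str
    representative_seq: str
    hits: list[Hit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.member_ids)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_hits(
    sequences: Sequence[tuple[str, str]],
    id_thr: float = 0.75,
    cov_thr: float = 0.75,
    scoring: Scoring = DEFAULT_DNA_SCORING,
    hits: Optional[Sequence[Hit]] = None,
) -> list[HitCluster]:
    """Single-linkage clustering of (id, sequence) pairs under the
    predicate: global identity >= id_thr AND coverage of both sequences
    >= cov_thr. Output order is deterministic: clusters by descending
    size, then by the representative sequence lexicographically.
    """
    if not sequences:
        raise ValueError("cluster_hits requires at least one sequence")
    n = len(sequences)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sequences[i][1], sequences[j][1]
            aln = align_global(a, b, scoring)
            if (
                aln.identity >= id_thr
                and aln.coverage_a >= cov_thr
                and aln.coverage_b >= cov_thr
            ):
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    clusters = []
    for members in groups.values():
        # representative: longest member, ties by lexicographic sequence
        rep = min(members, key=lambda i: (-len(sequences[i][1]), sequences[i][1]))
        member_seqs = []
        for i in members:
            seq = sequences[i][1]
            member_seqs.append(seq)
        clusters.append(
            HitCluster(
                member_ids=[sequences[i][0] for i in members],
                member_seqs=member_seqs,
                representative_id=sequences[rep][0],
                representative_seq=sequences[rep][1],
                hits=[hits[i] for i in members] if hits is not None else [],
            )
        )
    clusters.sort(key=lambda c: (-len(c), c.representative_seq))
    return clusters


# ---------------------------------------------------------------------------
# multiple alignment and consensus

def build_msa(member_sequences: Sequence[str], scoring: Scoring = DEFAULT_DNA_SCORING) -> list[str]:
    """Center-star multiple alignment around the longest member (ties by
    lexicographic order). Rows come back in input order; columns follow
    center coordinates, with insertion blocks right-padded. Ungapping any
    row reproduces its input sequence.
    """
    if not member_sequences:
        raise ValueError("build_msa requires at least one sequence")
    if len(member_sequences) == 1:
        return [member_sequences[0]]
    order = sorted(range(len(member_sequences)),
                   key=lambda i: (-len(member_sequences[i]), member_sequences[i]))
    c = order[0]
    center = member_sequences[c]
    n = len(center)
    # pairwise alignments of center vs every other member
    pair: dict[int, PairwiseAlignment] = {}
    ins = [0] * (n + 1)  # max insertion length after k center characters
    for i, seq in enumerate(member_sequences):
        if i == c:
            continue
        aln = align_global(center, seq, scoring)
        pair[i] = aln
        k = 0
        run = 0
        for ca in aln.aligned_a:
            if ca == "-":
                run += 1
            else:
                if run:
                    ins[k] = max(ins[k], run)
                    run = 0
                k += 1
        if run:
            ins[k] = max(ins[k], run)
    rows = []
    for i, seq in enumerate(member_sequences):
        if i == c:
            parts = ["-" * ins[0]]
            for k in range(n):
                parts.append(center[k])
                parts.append("-" * ins[k + 1])
            rows.append("".join(parts))
            continue
        aln = pair[i]
        parts = []
        k = 0
        slot = []  # member chars aligned into the insertion slot after k center chars
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if ca == "-":
                slot.append(cb)
            else:
                parts.append("".join(slot) + "-" * (ins[k] - len(slot)))
                slot = []
                parts.append(cb)
                k += 1
        parts.append("".join(slot) + "-" * (ins[k] - len(slot)))
        rows.append("".join(parts))
    assert len({len(r) for r in rows}) == 1
    return rows


@dataclass
class ConsensusSequence:
    """A majority-rule consensus: per-column support is the fraction of
    non-gap members voting for the called base (1.0 for N calls kept for
    bookkeeping)."""

    seq: str
    support: list[float]
    member_count: int

    def __len__(self) -> int:
        return len(self.seq)


def majority_consensus(msa: Sequence[str], threshold: float = 0.5) -> ConsensusSequence:
    """Call the majority-rule consensus of an alignment.

    Per column: columns where gaps hold a strict majority are dropped;
    otherwise the most frequent non-gap base is called when it reaches
    ``threshold`` of the non-gap entries and non-gap entries are at least
    half the rows; ties and insufficient support give N.
    """
    if not msa:
        raise ValueError("majority_consensus requires at least one row")
    nrows = len(msa)
    out = []
    support = []
    for col in zip(*msa):
        nongap = [c for c in col if c != "-"]
        if len(nongap) * 2 < nrows:
            # gaps are a strict majority
            continue
        counts: dict[str, int] = {}
        for c in nongap:
            counts[c] = counts.get(c, 0) + 1
        best = max(counts.values())
        top = [b for b, k in counts.items() if k == best]
        f = best / len(nongap)
        if len(top) == 1 and f >= threshold and 2 * len(nongap) >= nrows:
            out.append(top[0])
            support.append(f)
        else:
            out.append("N")
            support.append(0.0)
    return ConsensusSequence("".join(out), support, nrows)


# ---------------------------------------------------------------------------
# consensus elongation

@dataclass
class TemplateMatch:
    template: str
    start: int  # interval on the consensus, 0-based half-open
    end: int
    identity: float
    coverage: float


@dataclass
class ExtendedConsensus:
    """Result of the elongation loop: the flank-extended consensus, the
    element region within it, and the small-RNA gene matches detected on
    each side. ``confirmed`` is False when the loop exhausted its rounds
    without genes on both sides."""

    consensus: ConsensusSequence
    element_region: tuple[int, int]
    left_match: Optional[TemplateMatch]
    right_match: Optional[TemplateMatch]
    confirmed: bool
    rounds: int


def _best_template_match(
    region: str,
    templates: Sequence[RnaGeneTemplate],
    offset: int,
    min_identity: float,
    min_coverage: float,
    scoring: Scoring,
) -> Optional[TemplateMatch]:
    best: Optional[TemplateMatch] = None
    if len(region) < 20:
        return None
    for t in templates:
        for seq in (t.seq, revcomp(t.seq)):
            aln = align_local(seq, region, scoring)
            if aln.identity >= min_identity and aln.coverage_a >= min_coverage:
                m = TemplateMatch(
                    t.name,
                    offset + aln.b_interval[0],
                    offset + aln.b_interval[1],
                    aln.identity,
                    aln.coverage_a,
                )
                if best is None or m.coverage * m.identity > best.coverage * best.identity:
                    best = m
    return best


def extend_consensus(
    cluster: HitCluster,
    genome,
    templates: Sequence[RnaGeneTemplate],
    flank: int = 10000,
    max_rounds: int = 5,
    max_members: int = 10,
    consensus_threshold: float = 0.5,
    template_min_identity: float = 0.8,
    template_min_coverage: float = 0.6,
    scoring: Scoring = DEFAULT_DNA_SCORING,
) -> ExtendedConsensus:
    """Elongate a cluster consensus with genomic flanks until small-RNA
    gene sequences are reached on both sides.

    Each round re-extracts up to ``max_members`` member loci with
    ``round * flank`` bp of flank on each side (oriented to the member
    hit strand), rebuilds the majority consensus, and checks for a
    template match (identity >= 0.8 over >= 60% of a template) on both
    sides of the element region. Exhausting ``max_rounds`` returns the
    last consensus flagged unconfirmed.
    """
    if not cluster.hits:
        raise ValueError("extend_consensus needs clusters with genomic hits")
    gseq = genome.seq if hasattr(genome, "seq") else str(genome)
    base = majority_consensus(build_msa(cluster.member_seqs, scoring), consensus_threshold)
    members = sorted(cluster.hits, key=lambda h: (-(h.end - h.start), h.start))[:max_members]
    cons = base
    region = (0, len(base.seq))
    left = right = None
    for r in range(1, max_rounds + 1):
        ext = flank * r
        loci = []
        for h in members:
            s = max(0, h.start - ext)
            e = min(len(gseq), h.end + ext)
            seq = gseq[s:e]
            if h.strand == "-":
                seq = revcomp(seq)
            loci.append(seq)
        cons = majority_consensus(build_msa(loci, scoring), consensus_threshold)
        anchor = align_local(base.seq, cons.seq, scoring)
        region = anchor.b_interval
        left = _best_template_match(
            cons.seq[: region[0]], templates, 0,
            template_min_identity, template_min_coverage, scoring,
        )
        right = _best_template_match(
            cons.seq[region[1] :], templates, region[1],
            template_min_identity, template_min_coverage, scoring,
        )
        if left is not None and right is not None:
            return ExtendedConsensus(cons, region, left, right, True, r)
    logger.info("elongation unconfirmed after %d rounds", max_rounds)
    return ExtendedConsensus(cons, region, left, right, False, max_rounds)


def low_copy_fallback(
    hit: Hit,
    genome,
    templates: Sequence[RnaGeneTemplate],
    flank: int = 10000,
    template_min_identity: float = 0.8,
    template_min_coverage: float = 0.6,
    scoring: Scoring = DEFAULT_DNA_SCORING,
) -> Optional[dict]:
    """Low-copy path: when clustering produced no cluster of three or
    more members, test whether multicopy genes flank the hit within
    ``flank`` bp on both sides. Returns the flanking template names (for
    delegation to boundary calling) or None.
    """
    gseq = genome.seq if hasattr(genome, "seq") else str(genome)
    left_ctx = gseq[max(0, hit.start - flank) : hit.start]
    right_ctx = gseq[hit.end : hit.end + flank]
    left = _best_template_match(
        left_ctx, templates, 0, template_min_identity, template_min_coverage, scoring
    )
    right = _best_template_match(
        right_ctx, templates, 0, template_min_identity, template_min_coverage, scoring
    )
    if left is None or right is None:
        return None
    return {"hit": hit, "left_template": left.template, "right_template": right.template}
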