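# Methods

This note documents the models, algorithms, parameter choices, and known
limits of `dadascan`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The problem

*Dada*-like DNA transposons integrate inside multicopy small-RNA genes
(tRNA, 5S rRNA, U1/U6 snRNA), generating 6- or 7-bp target site
duplications (TSDs), sometimes replacing the target sequence with a
family-specific sequence on one or both sides, and — for the
anticodon-arm-targeting lineages — inserting in the opposite
orientation relative to the gene. Characterizing such a family from a
genome means (i) finding the copies, (ii) reconstructing the element
consensus, (iii) reading the element/gene junctions precisely enough to
call the TSD and the insertion position inside the gene, and (iv)
placing the family in a lineage by transposase phylogeny.

## Synthetic survey substrate

The generator builds the conditions the survey assumes rather than a
general genome simulator:

- **Gene arrays.** Gene copies are organized into tandem arrays of 4–7
  units joined by a per-template conserved spacer (190–250 bp, 5%
  diverged per occurrence), mirroring pol-III gene cluster structure.
  Inserted units are placed at interior array positions when intact
  copies allow it: real arrays have hundreds of copies, so edge
  insertions are rare, and the consensus-elongation step ("reach gene
  sequence on both sides") presumes interior context. Arrays land on
  either genome strand with probability 0.5, on a uniform-random
  background, non-overlapping (bounded retries, then an error — copies
  are never silently dropped).
- **Elements.** `build_element` emits a random element carrying one ORF
  (default 520 codons, inside a 1900-bp element; published transposases
  run 530–668 residues) with the catalytic D, D, E residues and a DxxH
  block planted at recorded positions, and an in-frame stop immediately
  upstream of the start codon so the planted ORF is exactly the longest
  ORF. Families descend from a common ancestral element via
  `mutate_element` (default 0.35 amino-acid divergence, synonymous rate
  0.15, 0.25 non-coding divergence, motifs and ORF integrity
  preserved): this keeps all families detectable with one ancestral
  protein query while separating them at the 75% clustering threshold
  and by ≥30% protein divergence on the tree.
- **Insertions.** The gene copy is diverged first, then split at the
  insertion offset; the TSD is the diverged copy's own bases, so
  duplications are exact at every divergence level (as in reality,
  where duplication happens at integration time). Replacement plants
  substitute the template-validated target window with the replacing
  sequence on the requested side(s). Truncation removes a random 10–70%
  of the element 5′ end only. Divergence is i.i.d. substitution, no
  indels — a deliberate v1 restriction that keeps consensus-recovery
  checks exact; indel divergence is a listed extension.
- **Determinism.** One `numpy` PRNG stream seeded from a single integer
  drives everything; identical seeds give byte-identical genomes and
  truth JSON.

The packaged scenario (`default_scenario`) plants four families on a
260 kb genome: 6 anticodon-arm copies in tRNA-Ala (opposite
orientation; two of them with both-sided TAGCAT→GCGCAA replacement,
divergence 0, the rest at 0.02), 5 A-box copies in tRNA-Tyr at gene
position 8 (divergence 0.02), 4 copies in 5S with 7-bp TSDs (0.01), and
a 2-copy tRNA-Val family (divergence 0) that exercises the low-copy
fallback. Problem sizes (genome length, copy numbers, element length)
are desk-scale choices that preserve the survey's structure: arrays,
within-family divergence, both strands, all four target modes.

What the generator does **not** emulate: indel divergence, nested
insertions of one family into another, element internal deletions other
than 5′ truncation, tRNA introns, and genome-scale repeat landscapes
beyond the planted arrays. Passing tests therefore demonstrate the
pipeline's correctness on clean substitution-diverged copies in array
context, not robustness to assembly artifacts or deep decay.

## Alignment kernels

Global (Needleman–Wunsch–Gotoh) and local (Smith–Waterman–Gotoh)
affine-gap aligners are implemented as numba kernels with deterministic
traceback (diagonal before up before left; predecessor preference M, X,
Y; the local traceback ends at the first maximal cell in row-major
order). Opening a gap costs `gap_open + gap_extend`, extension
`gap_extend`. Defaults: match +2, mismatch −3, open −5, extend −2 for
DNA (conventional for diverged repeat families; no scoring is
prescribed by the survey design), BLOSUM62 with −11/−1 for protein.
Identity is counted over columns non-gap in both rows; coverage of a
sequence is its aligned (non-terminal-gap) span over its length. Both
aligners are checked against an independent brute-force recursion over
alignment moves (exhaustive small-instance equivalence plus seeded
random pairs).

`seed_extend_search` indexes exact k-mers (default k=12) on both
strands, projects each seed to a candidate window, merges windows, and
extends by local alignment; hits pass at ≥`min_identity` over
≥`min_length` subject span, and same-strand hits within 50 bp merge.
`translated_search` scans all six frames, splits translations at stop
codons, pre-filters segments by shared protein 4-mers, aligns candidates
with BLOSUM62, and reports hits in DNA coordinates with the frame;
same-strand hits within 150 bp merge, which rejoins ORFs fragmented by
isolated stops in diverged copies.

## Clustering, consensus, elongation

Clustering is single linkage under the predicate
`identity ≥ 0.75 AND coverage_a ≥ 0.75 AND coverage_b ≥ 0.75` on global
alignments, with deterministic output order. The multiple alignment is
center-star around the longest member; the consensus applies the 50%
majority rule per column (ties and insufficient support call N; columns
with a strict gap majority are dropped).

Elongation re-extracts up to 10 member loci (the survey's cap) with
`round × flank` bp on each side, rebuilds the consensus, and stops when
a template match (identity ≥0.8 over ≥60% of a template — our contract,
none is prescribed) lies on both sides of the element region, up to 5
rounds; exhaustion returns the consensus flagged unconfirmed. Clusters
with fewer than three members ("more than two genomic coordinates" read
literally) go to the fallback: a single hit whose ±flank context holds
template matches on both sides becomes a representative (not consensus)
family. The default flank is the survey's 10,000 bp; the packaged
scenario runs with 600 bp because its arrays space genes a few hundred
bp apart (the fallback keeps a 4,000 bp flank, which costs little).

## Boundary and TSD calling

Boundaries come from comparing the interrupted gene copy with the
intact template. A semiglobal DP (template prefix free to end anywhere;
its mirror for suffixes) yields two junction anchors near the homology
hit; the insert between them is the element candidate. The pipeline
then locates the family element sequence inside the insert (local
alignment, either orientation) and reads the junctions off the element
extent — this is the load-bearing step, because junction anchors
alone are unreliable whenever an element terminus resembles the
template continuation.

With junctions pinned at the element edges `[es, ee)`, every target-site
geometry places the two copies element-adjacent: left `L[es−w:es]`,
right `L[ee:ee+w]`. Candidates over w ∈ {7, 6} and a small junction
jitter (±4 bp, absorbing element-edge bases lost to per-copy
divergence) are tested in order of jitter budget, then total jitter,
then longest w, so exact junctions outrank any jittered reading:

- equal copies matching the template window at the re-anchored offset
  (≤1 mismatch) → **duplication** of length w;
- equal copies mismatching it (≥2 mismatches, the threshold separating
  replacement from point divergence) whose outer neighbourhoods
  re-anchor to the template exactly w apart → **both-sided
  replacement**, with the replacing sequence reported;
- one side intact (≤1 mismatch to the expected window) and the other
  mismatching (≥2) → **one-sided replacement** (tested 6 before 7: with
  no duplication to fix w, the known replacement lengths are 6 bp).

Template re-anchoring slides a 12-bp template window over the junction;
it is exact in every geometry because the gene-derived flank is
template-contiguous across the junction (the TSD itself is a template
window). Without an element sequence (the bare `detect_tsd` contract) a
shift search around the semiglobal anchors covers the clean cases.

The insertion offset is the 1-based gene position of the first
target-site base on the mature-gene sense strand, regardless of element
orientation. Region classification: acceptor-stem/D-arm boundary when
the target site lies inside the A box (default span [8,19] for
unannotated tRNAs, containing nucleotides 8–13), anticodon arm when it
overlaps the anticodon loop, otherwise other. Orientation compares the
family ORF sense with the gene sense. Specificity is the modal target
among copies flanked by gene sequence on both sides (ties toward more
flanked members, then lexicographic; three-letter isotypes map to
standard one-letter codes); other observed targets are reported as
secondary with counts. Family names follow
`Dada-<specificity>_<speciesCode>` with numeric collision suffixes
(2, 3, …); a lettered-suffix convention exists in the literature but is
not formalized, so numeric was chosen. Target-site profiles stack
fixed-width windows (default 20 bp, 7 bp of lead) aligned on the first
target-site base, replacement copies contributing their replacing
sequence, and report per-site counts and the most frequent base (ties
as N).

### Known identifiability limit

When an element-edge base equals the corresponding template base
adjacent to the target site (probability 1/4 per edge), the locus
genuinely admits two consistent readings — e.g. a 6-bp duplication with
element `X…`, or a 7-bp duplication with element `…` one base shorter.
With the exact element sequence in hand the extent pins the true
junctions and the zero-jitter reading wins; when the element itself is
*estimated* from the genome (the pipeline's provisional-element walk),
a coincidence at the estimate's edge can shift the whole family to the
alternative reading, changing called TSD lengths and offsets by one.
The same ambiguity affects 5′-truncated copies, whose truncation point
is a random sequence edge. These are properties of the sequence, not
resolvable errors; the per-family majority-length vote over several
members minimizes but cannot eliminate them.

## Pipeline mechanics

Stages persist all artifacts to a run directory (genome, truth, hits,
cluster consensus, per-copy table, family JSON/FASTA, GFF3, trees,
lineages, motif screen, evaluation) with a SHA-256 manifest; stages can
be re-run individually and a rerun with the same seed reproduces every
hash. Member sets per family combine the clustered hits with a
nucleotide re-search using the cluster consensus; re-search claims are
arbitrated globally (a claim overlapping another cluster's members or a
higher-identity claim is dropped) because local-alignment islands
between related families would otherwise leak across clusters. The
provisional full-length element is estimated by walking from the
ORF-hit edges outward to the nearest gene-template content — the
interrupted gene's own split part is always nearest — with
edge-anchored short windows (≥10 bp, one mismatch tolerated from 12 bp,
junction-adjacent 3 bp exact) so boundary-proximal insertions with
split parts shorter than a full window are found; the majority length
group over several members wins, since junction overshoot adds a whole
spacer+gene block while spurious early stops are rare.

Evaluation matches reported copies to truth by ≥50% reciprocal interval
overlap and reports per-family recall, precision, TSD-length accuracy
(over matched untruncated duplication copies), insertion-offset
accuracy (over flanked copies), and specificity-label accuracy, all
with denominators.

## Phylogeny

Transposases are the longest Met-to-stop ORF over six frames (default
minimum 300 codons — below the 530–668-residue working range, tolerant
of partially truncated consensus); families without one are flagged
non-coding and excluded from the tree. Distances are p-distances from
global BLOSUM62 alignments. The tree is standard neighbor joining with
deterministic tie-breaking (smallest Q, then smallest index pair) and
negative branch lengths clamped to zero with a log entry, then
midpoint-rooted (root halfway along the longest leaf-to-leaf path;
idempotent; degree-2 nodes suppressed). Likelihood methods with
bootstrap support are intentionally out of scope: the package's claim
is lineage *grouping*, which distance trees support, not branch
support values.

Lineages are maximal clades whose confirmed labels agree; unconfirmed
leaves inside a lineage clade inherit its label flagged provisional;
two labels whose leaves interleave (the minimal clade containing one
label's leaves contains the other's) merge into a slash-named lineage,
reproducing the tD/tV-style merge. The catalytic-motif screen projects
annotated reference positions through a global alignment and reads the
residues: the DDE triad is intact for (D,D,E) or (D,D,D) — the DDD
variant is accepted, with residues reported so callers can distinguish
— and the DxxH histidine read as Q is the domestication signature.

## Numerical and degenerate-input choices

Ties in consensus columns call N; ties in local-alignment end cells take
the first maximum in row-major order; zero-length trees root at an
arbitrary node with a log entry; N never matches in DNA scoring;
annotation spans are validated against template length; a locus without
an insert of ≥50 bp raises rather than returning a degenerate copy.
All report coordinates are 1-based inclusive; internal coordinates are
0-based half-open on the stored strand.

## Distribution table

The packaged TSV transcribes a published presence/absence table of
confirmed target-specificity lineages across actinopterygian fish
families (29 rows, 12 lineage columns). The column label `th` is
preserved verbatim from the source table even though it plainly denotes
the tD lineage (its marks match every textual statement about tD); the
lineage count after the tD/tV merge therefore merges the `th` and `tV`
columns. The loader validates the column set and the 0/1 flags and
reports malformed rows by number.
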