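"""Reading and writing of external formats: FASTA genomes, small-RNA gene
template libraries, interval annotations (BED/GFF3/TSV), and the packaged
lineage-distribution fixture.

No science lives here. Internal coordinates are 0-based half-open on the
plus strand of the stored sequence; every human-facing report uses 1-based
inclusive coordinates. BED output is 0-based half-open, GFF3 1-based
inclusive, as those formats require.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")

#: region labels recognised in template annotations
REGION_LABELS = ("acceptor_stem", "d_arm", "anticodon_loop", "a_box")

GENE_CLASSES = ("tRNA", "rRNA5S", "snU1", "snU6", "other")


@dataclass
class GenomeRecord:
    """One nucleotide sequence (chromosome, scaffold, or synthetic genome)."""

    id: str
    description: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"record {self.id!r} has non-DNA characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class RnaGeneTemplate:
    """An intact multicopy small-RNA gene with structural annotation.

    ``spans`` maps region labels (``acceptor_stem``, ``d_arm``,
    ``anticodon_loop``, ``a_box``) to 1-based inclusive intervals on the
    sense strand of ``seq``. For tRNA templates the A box is the internal
    RNA-polymerase-III promoter element; when unannotated it defaults to
    [8, 19], which contains the mature-tRNA nucleotides 8-13 that matter
    for positional classification.
    """

    name: str
    gene_class: str
    isotype: str = ""
    anticodon: str = ""
    seq: str = ""
    spans: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene_class {self.gene_class!r}")
        if not self.seq:
            raise ValueError(f"template {self.name!r} has empty sequence")
        for label, (lo, hi) in self.spans.items():
            if label not in REGION_LABELS:
                raise ValueError(f"unknown region label {label!r} in {self.name!r}")
            if not (1 <= lo <= hi <= len(self.seq)):
                raise ValueError(
                    f"span {label}=[{lo},{hi}] outside template {self.name!r} "
                    f"(length {len(self.seq)})"
                )
        if self.gene_class == "tRNA":
            if "a_box" not in self.spans:
                self.spans["a_box"] = (8, min(19, len(self.seq)))
            lo, hi = self.spans["a_box"]
            if not (lo <= 8 and hi >= 13):
                raise ValueError(
                    f"a_box span [{lo},{hi}] of {self.name!r} must contain positions 8-13"
                )
            if self.anticodon:
                if "anticodon_loop" not in self.spans:
                    raise ValueError(f"tRNA template {self.name!r} lacks anticodon_loop span")
                lo, hi = self.spans["anticodon_loop"]
                if self.anticodon not in self.seq[lo - 1 : hi]:
                    raise ValueError(
                        f"anticodon {self.anticodon} of {self.name!r} not found inside "
                        f"anticodon_loop span [{lo},{hi}]"
                    )


@dataclass
class AnnotationRow:
    """A genomic feature interval, stored 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str
    label: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval start {self.start} must be < end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Lowercase input is uppercased; characters outside {A,C,G,T,N} are
    mapped to N with a logged count. An empty file or duplicate record
    ids are errors.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    n_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        cleaned = "".join(c if c in DNA_ALPHABET else "N" for c in seq)
        n_mapped += sum(1 for a, b in zip(seq, cleaned) if a != b)
        records.append(GenomeRecord(rec.id, rec.description, cleaned))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if n_mapped:
        logger.warning("mapped %d non-ACGTN characters to N while reading %s", n_mapped, path)
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def _parse_span(text: str) -> tuple[int, int] | None:
    text = text.strip()
    if not text or text in (".", "-"):
        return None
    lo, hi = text.split("-") if "-" in text else text.split(":")
    return int(lo), int(hi)


def read_template_library(
    fasta_path: str | Path, annotation_path: str | Path
) -> list[RnaGeneTemplate]:
    """Read a small-RNA gene template library.

    The FASTA holds the gene-body sequences (sense strand); the TSV
    sidecar carries one row per template: name, gene_class, isotype,
    anticodon, and span columns (``acceptor_stem``, ``d_arm``,
    ``anticodon_loop``, ``a_box``) as ``start-end`` 1-based inclusive,
    empty when unannotated.
    """
    seqs = {r.id: r.seq for r in read_fasta(fasta_path)}
    table = pd.read_csv(annotation_path, sep="\t", dtype=str).fillna("")
    templates = []
    for _, row in table.iterrows():
        name = row["name"]
        if name not in seqs:
            raise ValueError(f"annotation row {name!r} has no matching FASTA record")
        spans = {}
        for label in REGION_LABELS:
            if label in row.index:
                span = _parse_span(row[label])
                if span is not None:
                    spans[label] = span
        templates.append(
            RnaGeneTemplate(
                name=name,
                gene_class=row["gene_class"],
                isotype=row.get("isotype", ""),
                anticodon=row.get("anticodon", ""),
                seq=seqs[name],
                spans=spans,
            )
        )
    return templates


def write_template_library(
    templates: Iterable[RnaGeneTemplate], fasta_path: str | Path, annotation_path: str | Path
) -> None:
    templates = list(templates)
    write_fasta(
        [GenomeRecord(t.name, t.gene_class, t.seq) for t in templates], fasta_path
    )
    rows = []
    for t in templates:
        row = {
            "name": t.name,
            "gene_class": t.gene_class,
            "isotype": t.isotype,
            "anticodon": t.anticodon,
        }
        for label in REGION_LABELS:
            span = t.spans.get(label)
            row[label] = f"{span[0]}-{span[1]}" if span else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


def write_annotations(rows: Iterable[AnnotationRow], path: str | Path, dialect: str) -> None:
    """Write feature intervals as BED (0-based half-open), GFF3 (1-based
    inclusive) or plain TSV (internal 0-based half-open coordinates)."""
    rows = list(rows)
    dialect = dialect.upper()
    with open(path, "w") as fh:
        if dialect == "BED":
            for r in rows:
                fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.label}\t{r.score:g}\t{r.strand}\n")
        elif dialect == "GFF3":
            fh.write("##gff-version 3\n")
            for r in rows:
                fh.write(
                    f"{r.seq_id}\tdadascan\t{r.label}\t{r.start + 1}\t{r.end}\t"
                    f"{r.score:g}\t{r.strand}\t.\t.\n"
                )
        elif dialect == "TSV":
            fh.write("seq_id\tstart\tend\tstrand\tlabel\tscore\n")
            for r in rows:
                fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.strand}\t{r.label}\t{r.score:g}\n")
        else:
            raise ValueError(f"unknown annotation dialect {dialect!r}")


def read_annotations(path: str | Path, dialect: str) -> list[AnnotationRow]:
    """Inverse of :func:`write_annotations`; returns internal coordinates."""
    dialect = dialect.upper()
    rows: list[AnnotationRow] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("seq_id\t"):
                continue
            f = line.split("\t")
            if dialect == "BED":
                rows.append(AnnotationRow(f[0], int(f[1]), int(f[2]), f[5], f[3], float(f[4])))
            elif dialect == "GFF3":
                rows.append(AnnotationRow(f[0], int(f[3]) - 1, int(f[4]), f[6], f[2], float(f[5])))
            elif dialect == "TSV":
                rows.append(AnnotationRow(f[0], int(f[1]), int(f[2]), f[3], f[4], float(f[5])))
            else:
                raise ValueError(f"unknown annotation dialect {dialect!r}")
    return rows


#: the 12 target-specificity lineage columns of the packaged distribution table
LINEAGE_COLUMNS = ["U6", "tA", "tY", "tL", "tN", "tK", "tR", "tS", "U1", "5S", "th", "tV"]


def load_distribution_fixture(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged presence/absence table of target-specific
    transposon lineages across actinopterygian fish families.

    Columns: ``order``, ``family``, ``n_species`` plus one boolean column
    per lineage (:data:`LINEAGE_COLUMNS`). The column label ``th`` is
    preserved verbatim from the transcribed source table.
    """
    if path is None:
        ref = resources.files("dadascan.data") / "dada_distribution_actinopterygii.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    expected = ["order", "family", "n_species"] + LINEAGE_COLUMNS
    if list(df.columns) != expected:
        raise ValueError(f"distribution fixture has unexpected columns {list(df.columns)}")
    for i, row in df.iterrows():
        for c in LINEAGE_COLUMNS:
            if row[c] not in (0, 1):
                raise ValueError(f"malformed presence flag in fixture row {i + 2}: {c}={row[c]!r}")
    df[LINEAGE_COLUMNS] = df[LINEAGE_COLUMNS].astype(bool)
    return df
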