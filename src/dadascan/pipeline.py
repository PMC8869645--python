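"""End-to-end orchestration: simulate -> search -> cluster/consensus ->
characterize -> tree -> evaluate, with per-stage artifacts persisted in a
run directory and a hash manifest for reproducibility.

Every stage reads its inputs from files written by the previous stage,
so stages can be re-run individually from the command line. All
thresholds are echoed to the log at stage start.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import families as fam_mod
from . import io as io_mod
from . import phylo as phylo_mod
from . import simulate as sim_mod
from . import targets as tgt_mod
from .align import Hit, Scoring, align_local, revcomp, seed_extend_search, translated_search

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """All pipeline knobs. The clustering thresholds (75% identity, 75%
    coverage), the 50% consensus majority rule, the 10,000 bp flank and
    the 10-locus cap per elongation round are the survey's constants;
    the packaged synthetic scenario runs with a smaller flank because
    its gene arrays are tighter than real genomic tRNA clusters."""

    run_dir: str = "run"
    seed: int = 1
    species_code: str = "SynG"
    simulate: bool = True
    background_length: int = 260_000

    # external inputs (used when simulate=False)
    genome_fasta: Optional[str] = None
    templates_fasta: Optional[str] = None
    templates_tsv: Optional[str] = None
    query_protein: Optional[str] = None
    truth_json: Optional[str] = None

    # survey constants
    id_thr: float = 0.75
    cov_thr: float = 0.75
    consensus_threshold: float = 0.5
    flank: int = 10_000
    fallback_flank: Optional[int] = None  # defaults to flank
    max_hits_per_round: int = 10
    max_rounds: int = 5

    # search
    k: int = 12
    min_identity: float = 0.75
    min_hit_length: int = 100
    min_protein_score: int = 100

    # characterization / phylogeny
    template_min_identity: float = 0.8
    template_min_coverage: float = 0.6
    min_orf_codons: int = 300

    # scoring
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def scoring(self) -> Scoring:
        return Scoring(self.match, self.mismatch, self.gap_open, self.gap_extend)

    def validate(self) -> None:
        for name in ("id_thr", "cov_thr", "consensus_threshold",
                     "min_identity", "template_min_identity", "template_min_coverage"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.flank <= 0:
            raise ValueError("flank must be positive")
        if self.k < 8:
            raise ValueError("k must be >= 8")
        if self.max_hits_per_round < 1 or self.max_rounds < 1:
            raise ValueError("max_hits_per_round and max_rounds must be >= 1")
        if not self.simulate:
            for name in ("genome_fasta", "templates_fasta", "templates_tsv", "query_protein"):
                if getattr(self, name) is None:
                    raise ValueError(f"{name} is required when simulate=False")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def scenario_config(run_dir: str, seed: int = 1, **overrides) -> PipelineConfig:
    """Configuration for the packaged synthetic scenario: desk-scale
    flank (the generator's gene arrays are a few hundred bp apart, so a
    600 bp flank reaches flanking genes in one elongation round)."""
    defaults = dict(run_dir=run_dir, seed=seed, simulate=True, flank=600,
                    fallback_flank=4000)
    defaults.update(overrides)
    return PipelineConfig(**defaults)


# ---------------------------------------------------------------------------
# helpers

def _p(cfg: PipelineConfig, name: str) -> Path:
    return Path(cfg.run_dir) / name


def _write_hits(hits: list[Hit], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tsubject_id\tstart\tend\tstrand\tscore\tidentity\tframe\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.subject_id}\t{h.start}\t{h.end}\t{h.strand}\t"
                     f"{h.score:g}\t{h.identity:.4f}\t{h.frame}\n")


def _read_hits(path: Path) -> list[Hit]:
    hits = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hits.append(Hit(f[0], f[1], int(f[2]), int(f[3]), f[4],
                            float(f[5]), float(f[6]), int(f[7])))
    return hits


def _load_genome(cfg: PipelineConfig) -> io_mod.GenomeRecord:
    return io_mod.read_fasta(_p(cfg, "genome.fa"))[0]


def _load_templates(cfg: PipelineConfig) -> list[io_mod.RnaGeneTemplate]:
    return io_mod.read_template_library(_p(cfg, "templates.fa"), _p(cfg, "templates.tsv"))


def _gene_here(tseqs: list[str], L: str, j: int, direction: int,
               k: int = 16, tol: int = 2) -> bool:
    """Is the locus adjacent to position j (ending at j for direction<0,
    starting at j for direction>0) gene-template sequence? Besides full
    k-windows, exact template-edge windows of >= 8 bp are accepted, so
    short split-gene parts next to boundary-proximal insertions are
    found."""
    side = "left" if direction < 0 else "right"
    for t in tseqs:
        if direction < 0 and j - k >= 0:
            p = tgt_mod._scan_at(t, L, j, side, k=k, tol=tol)
            # the junction-adjacent bases must match exactly, or the
            # window tolerance would absorb element bases
            if p is not None and t[max(0, p - 3) : p] == L[j - min(3, p) : j]:
                return True
        if direction > 0 and j + k <= len(L):
            p = tgt_mod._scan_at(t, L, j, side, k=k, tol=tol)
            if p is not None and t[p : p + 3] == L[j : j + 3]:
                return True
        # template-edge anchored short windows: exact for >=10 bp, one
        # mismatch tolerated from 12 bp (junction-adjacent 3 bp exact),
        # so short split-gene parts survive a diverged base
        for p in range(10, k):
            if direction < 0 and j - p >= 0:
                win = L[j - p : j]
                mism = sum(a != b for a, b in zip(t[:p], win))
                if mism == 0 or (p >= 12 and mism == 1 and t[p - 3 : p] == win[-3:]):
                    return True
            if direction > 0 and j + p <= len(L):
                win = L[j : j + p]
                mism = sum(a != b for a, b in zip(t[-p:], win))
                if mism == 0 or (p >= 12 and mism == 1 and t[-p : -p + 3] == win[:3]):
                    return True
    return False


def _walk_to_gene(
    tseqs: list[str], L: str, start: int, direction: int, max_walk: int = 800,
) -> Optional[int]:
    """Walk from inside the element toward a flank until the locus
    matches gene-template sequence again; returns the junction position.
    The nearest gene content outward of an insertion is the interrupted
    gene's own split part, so the first match is the element junction."""
    for step in range(0, max_walk, 3):
        j = start - step if direction < 0 else start + step
        if (direction < 0 and j < 8) or (direction > 0 and j > len(L) - 8):
            return None
        if _gene_here(tseqs, L, j, direction):
            best = j
            for dj in range(1, 4):
                jj = j + dj if direction < 0 else j - dj
                if _gene_here(tseqs, L, jj, direction):
                    best = jj
                else:
                    break
            return best
    return None


def _provisional_element(
    genome_seq: str, hits: list[Hit], templates, margin: int = 900
) -> Optional[str]:
    """Estimate the full element sequence by walking from ORF-region hit
    edges outward to the nearest gene junctions. Several members are
    tried and the majority length-group wins: junction overshoot
    (walking past a diverged split part to a neighbouring gene) adds a
    whole spacer+gene block, while spurious early stops are rare, so
    the modal length is the element length."""
    tseqs = [t.seq for t in templates] + [revcomp(t.seq) for t in templates]
    candidates = []
    for hit in sorted(hits, key=lambda h: -(h.end - h.start))[:5]:
        ws = max(0, hit.start - margin)
        we = min(len(genome_seq), hit.end + margin)
        window = genome_seq[ws:we]
        j1 = _walk_to_gene(tseqs, window, hit.start - ws, -1)
        j2 = _walk_to_gene(tseqs, window, hit.end - ws, +1)
        if j1 is None or j2 is None or j2 - j1 < 50:
            continue
        body = window[j1:j2]
        if hit.strand == "-":
            body = revcomp(body)
        candidates.append(body)
    if not candidates:
        return None
    # group candidates whose lengths agree within 10 bp; take the
    # largest group, shortest member within it
    candidates.sort(key=len)
    groups: list[list[str]] = []
    for c in candidates:
        if groups and len(c) - len(groups[-1][0]) <= 10:
            groups[-1].append(c)
        else:
            groups.append([c])
    best = max(groups, key=len)
    return best[0]


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: PipelineConfig) -> None:
    """Emit the synthetic genome, template library, ground truth, the
    transposase survey query, and a BED of planted features."""
    run = Path(cfg.run_dir)
    run.mkdir(parents=True, exist_ok=True)
    if cfg.simulate:
        sc = sim_mod.default_scenario(cfg.seed, cfg.background_length)
        io_mod.write_fasta([sc.genome], _p(cfg, "genome.fa"))
        io_mod.write_template_library(sc.templates, _p(cfg, "templates.fa"),
                                      _p(cfg, "templates.tsv"))
        _p(cfg, "truth.json").write_text(sc.truth_json())
        io_mod.write_annotations(sc.annotations, _p(cfg, "planted.bed"), "BED")
        io_mod.write_fasta(
            [io_mod.GenomeRecord("query", "ancestral transposase", sc.ancestor.seq)],
            _p(cfg, "query_element.fa"),
        )
        _p(cfg, "query.faa").write_text(f">query\n{sc.ancestor.protein}\n")
        _p(cfg, "reference.json").write_text(json.dumps({
            "protein": sc.ancestor.protein,
            "motif_positions": sc.ancestor.motif_positions,
            "planted_labels": sc.planted_labels,
        }, indent=1))
    else:
        # stage inputs supplied by the user: copy into the run directory
        import shutil

        shutil.copy(cfg.genome_fasta, _p(cfg, "genome.fa"))
        shutil.copy(cfg.templates_fasta, _p(cfg, "templates.fa"))
        shutil.copy(cfg.templates_tsv, _p(cfg, "templates.tsv"))
        shutil.copy(cfg.query_protein, _p(cfg, "query.faa"))
        if cfg.truth_json:
            shutil.copy(cfg.truth_json, _p(cfg, "truth.json"))
    cfg.to_yaml(_p(cfg, "config.yaml"))


def stage_search(cfg: PipelineConfig) -> list[Hit]:
    """Translated (six-frame) survey of the genome with the transposase
    protein query."""
    logger.info("search: min_protein_score=%d", cfg.min_protein_score)
    genome = _load_genome(cfg)
    with open(_p(cfg, "query.faa")) as fh:
        lines = [l.strip() for l in fh if not l.startswith(">")]
    protein = "".join(lines)
    hits = translated_search(protein, genome, min_score=cfg.min_protein_score)
    _write_hits(hits, _p(cfg, "hits.tsv"))
    return hits


def stage_build(cfg: PipelineConfig) -> dict:
    """Cluster hits (75%/75% single linkage), build majority consensus
    per cluster, and elongate with genomic flanks until gene sequences
    flank the element on both sides; low-copy clusters go through the
    gene-flanked fallback."""
    logger.info("build: id_thr=%.2f cov_thr=%.2f consensus=%.2f flank=%d max_hits=%d",
                cfg.id_thr, cfg.cov_thr, cfg.consensus_threshold, cfg.flank,
                cfg.max_hits_per_round)
    genome = _load_genome(cfg)
    templates = _load_templates(cfg)
    hits = _read_hits(_p(cfg, "hits.tsv"))
    scoring = cfg.scoring()
    seqs = []
    for i, h in enumerate(hits):
        s = genome.seq[h.start : h.end]
        if h.strand == "-":
            s = revcomp(s)
        seqs.append((f"hit{i}", s))
    clusters = fam_mod.cluster_hits(seqs, cfg.id_thr, cfg.cov_thr, scoring, hits=hits)
    candidates = []
    for ci, cluster in enumerate(clusters):
        key = f"cluster{ci}"
        if len(cluster) >= 3:
            ext = fam_mod.extend_consensus(
                cluster, genome, templates, flank=cfg.flank,
                max_rounds=cfg.max_rounds, max_members=cfg.max_hits_per_round,
                consensus_threshold=cfg.consensus_threshold,
                template_min_identity=cfg.template_min_identity,
                template_min_coverage=cfg.template_min_coverage, scoring=scoring,
            )
            base = fam_mod.majority_consensus(
                fam_mod.build_msa(cluster.member_seqs, scoring), cfg.consensus_threshold
            )
            candidates.append(dict(
                key=key, confirmed=ext.confirmed, is_representative=False,
                base_consensus=base.seq, rounds=ext.rounds,
                members=[dataclasses.asdict(h) for h in cluster.hits],
                left_template=ext.left_match.template if ext.left_match else None,
                right_template=ext.right_match.template if ext.right_match else None,
            ))
        else:
            rep_hit = max(cluster.hits, key=lambda h: h.end - h.start)
            fb = fam_mod.low_copy_fallback(
                rep_hit, genome, templates,
                flank=cfg.fallback_flank or cfg.flank,
                template_min_identity=cfg.template_min_identity,
                template_min_coverage=cfg.template_min_coverage, scoring=scoring,
            )
            candidates.append(dict(
                key=key, confirmed=fb is not None, is_representative=True,
                base_consensus=cluster.representative_seq, rounds=0,
                members=[dataclasses.asdict(h) for h in cluster.hits],
                left_template=fb["left_template"] if fb else None,
                right_template=fb["right_template"] if fb else None,
            ))
    out = {"clusters": candidates}
    _p(cfg, "families.json").write_text(json.dumps(out, indent=1))
    io_mod.write_fasta(
        [io_mod.GenomeRecord(c["key"], "cluster consensus", c["base_consensus"])
         for c in candidates],
        _p(cfg, "consensus_base.fa"),
    )
    return out


def _resolve_members(cfg: PipelineConfig, genome, cands: list[dict]) -> list[list[Hit]]:
    """Member sets per confirmed cluster: the clustered hits plus a
    nucleotide re-search with the cluster consensus (which catches
    copies whose ORF the protein search fragmented). Re-search claims
    are resolved globally: a claim overlapping another cluster's
    clustered members, or a higher-identity claim from another cluster,
    is dropped — local-alignment islands between related families would
    otherwise leak across clusters."""
    scoring = cfg.scoring()
    base_members = [[Hit(**m) for m in c["members"]] for c in cands]
    claims: list[list[Hit]] = []
    for c in cands:
        claims.append(seed_extend_search(
            c["base_consensus"], genome, k=cfg.k, min_identity=cfg.min_identity,
            min_length=cfg.min_hit_length, scoring=scoring, query_id=c["key"],
        ))
    resolved: list[list[Hit]] = []
    for i, c in enumerate(cands):
        members = list(base_members[i])
        for h in claims[i]:
            if any(h.start < m.end and h.end > m.start for m in members):
                continue
            foreign = False
            for j in range(len(cands)):
                if j == i:
                    continue
                if any(h.start < m.end and h.end > m.start for m in base_members[j]):
                    foreign = True
                    break
                if any(h.start < o.end and h.end > o.start and o.identity > h.identity
                       for o in claims[j]):
                    foreign = True
                    break
            if not foreign:
                members.append(h)
        members.sort(key=lambda h: (h.start, h.end))
        resolved.append(members)
    return resolved


def _characterize_family(
    cfg: PipelineConfig, genome, templates, cand: dict, members: list[Hit]
) -> Optional[tgt_mod.FamilyRecord]:
    scoring = cfg.scoring()
    by_name = {t.name: t for t in templates}
    # provisional full-length element (majority over several members)
    element_seq = _provisional_element(genome.seq, members, templates)
    # locate the cluster consensus inside the element: the ORF sits
    # asymmetrically, so hit intervals extend by different amounts on
    # each side
    dL = dR = None
    if element_seq is not None:
        loc = align_local(cand["base_consensus"], element_seq, cfg.scoring())
        if loc.score > 0:
            dL = loc.b_interval[0]
            dR = len(element_seq) - loc.b_interval[1]
    copies: list[tuple[tgt_mod.ElementCopy, tgt_mod.TsdCall, Optional[tgt_mod.TargetAnnotation]]] = []
    for h in members:
        # project the element extent around the ORF-region hit
        if dL is not None:
            padL, padR = (dL, dR) if h.strand == "+" else (dR, dL)
        else:
            padL = padR = 30
        interval = (max(0, h.start - padL - 10),
                    min(len(genome.seq), h.end + padR + 10))
        try:
            copy = tgt_mod.characterize_hit(
                genome, interval, templates, cand["key"],
                element_seq=element_seq, scoring=scoring,
            )
        except ValueError:
            continue
        t = by_name[copy.template_name]
        tsd = tgt_mod.detect_tsd(copy, t, element_seq)
        ann = tgt_mod.classify_target(copy, tsd, t) if tsd.kind != "none" else (
            tgt_mod.classify_target(copy, tsd, t)
        )
        copies.append((copy, tsd, ann))
    if not copies:
        return None
    # refined element sequence: majority consensus over full-length
    # called bodies, in element orientation
    bodies = []
    for copy, tsd, _ann in copies:
        body = copy.locus[copy.j1 + tsd.trim_left : copy.j2 - tsd.trim_right]
        if copy.element_strand == "-":
            body = revcomp(body)
        bodies.append(body)
    full = [b for b in bodies if len(b) >= 0.95 * max(len(x) for x in bodies)]
    if len(full) >= 2:
        refined = fam_mod.majority_consensus(
            fam_mod.build_msa(full, scoring), cfg.consensus_threshold
        ).seq
    else:
        refined = max(bodies, key=len)
    # orient the family sequence to its ORF sense
    prot = phylo_mod.extract_transposase(refined, cand["key"], cfg.min_orf_codons)
    if prot is not None and prot.strand == "-":
        refined = revcomp(refined)
        prot = phylo_mod.extract_transposase(refined, cand["key"], cfg.min_orf_codons)
    label, secondary = tgt_mod.assign_specificity(
        [c for c in copies if c[2] is not None], by_name
    )
    rec = tgt_mod.FamilyRecord(
        name="",  # assigned by the caller (needs the global name set)
        family_key=cand["key"],
        seq=refined,
        is_representative=bool(cand["is_representative"]),
        specificity=label,
        secondary_targets=secondary,
        members=copies,
        confirmed=bool(cand["confirmed"]),
        protein=prot.sequence if prot else None,
    )
    return rec


def stage_characterize(cfg: PipelineConfig) -> list[tgt_mod.FamilyRecord]:
    """Boundary + TSD calling for every member copy of every confirmed
    family, specificity assignment, family naming, and target-site
    profiles."""
    logger.info("characterize: template_min_identity=%.2f min_coverage=%.2f",
                cfg.template_min_identity, cfg.template_min_coverage)
    genome = _load_genome(cfg)
    templates = _load_templates(cfg)
    data = json.loads(_p(cfg, "families.json").read_text())
    records: list[tgt_mod.FamilyRecord] = []
    names: set[str] = set()
    for cand in data["clusters"]:
        if not cand["confirmed"]:
            logger.info("cluster %s unconfirmed; skipped", cand["key"])
    confirmed = [c for c in data["clusters"] if c["confirmed"]]
    member_sets = _resolve_members(cfg, genome, confirmed)
    for cand, members in zip(confirmed, member_sets):
        rec = _characterize_family(cfg, genome, templates, cand, members)
        if rec is None:
            continue
        rec.name = tgt_mod.name_family(rec.specificity, cfg.species_code, names)
        names.add(rec.name)
        records.append(rec)
    # persist: per-copy table, family JSON, consensus FASTA, GFF3, profiles
    rows = []
    gff = []
    fam_json = []
    for rec in records:
        prof = None
        with_sites = [(c, t) for c, t, a in rec.members if t.kind != "none"]
        if with_sites:
            try:
                prof = tgt_mod.build_target_profile(with_sites)
            except ValueError:
                prof = None
        fam_json.append(dict(
            name=rec.name, key=rec.family_key, specificity=rec.specificity,
            secondary_targets=rec.secondary_targets,
            representative=rec.is_representative, confirmed=rec.confirmed,
            n_members=len(rec.members), seq=rec.seq,
            protein=rec.protein,
            profile=None if prof is None else dict(
                windows=prof.windows, lead=prof.lead, consensus=prof.consensus),
        ))
        for i, (copy, tsd, ann) in enumerate(rec.members):
            gs, ge = copy.genome_interval(copy.j1 + tsd.trim_left,
                                          copy.j2 - tsd.trim_right)
            strand = copy.gene_strand if copy.element_strand == "+" else (
                "-" if copy.gene_strand == "+" else "+")
            rows.append(dict(
                family=rec.name, copy=f"{rec.name}.{i}", genome_id=copy.genome_id,
                start=gs, end=ge, element_strand=strand,
                target=copy.template_name, gene_strand=copy.gene_strand,
                tsd_kind=tsd.kind, tsd_len=tsd.length if tsd.length else "",
                tsd_left=tsd.left_seq, tsd_right=tsd.right_seq,
                replaced_with=tsd.replaced_with,
                insertion_offset=ann.insertion_offset if ann else "",
                orientation=ann.orientation if ann else "",
                region=ann.region if ann else "",
                flanked_both_sides=ann.flanked_both_sides if ann else False,
            ))
            gff.append(io_mod.AnnotationRow(copy.genome_id, gs, ge, strand,
                                            f"{rec.name}", 0.0))
    import pandas as pd

    pd.DataFrame(rows).to_csv(_p(cfg, "copies.tsv"), sep="\t", index=False)
    _p(cfg, "families_final.json").write_text(json.dumps(fam_json, indent=1))
    io_mod.write_fasta(
        [io_mod.GenomeRecord(r.name, "family sequence", r.seq) for r in records],
        _p(cfg, "families.fa"),
    )
    if gff:
        io_mod.write_annotations(gff, _p(cfg, "elements.gff3"), "GFF3")
    return records


def stage_tree(cfg: PipelineConfig) -> dict:
    """Transposase tree (NJ on p-distances, midpoint-rooted), lineage
    grouping, and the catalytic-motif screen against the reference."""
    logger.info("tree: min_orf_codons=%d", cfg.min_orf_codons)
    fams = json.loads(_p(cfg, "families_final.json").read_text())
    proteins = []
    labels = {}
    for f in fams:
        labels[f["name"]] = f["specificity"]
        if f["protein"]:
            proteins.append(phylo_mod.TransposaseProtein(f["name"], f["protein"], 1, "+"))
        else:
            logger.info("family %s non-coding; excluded from tree", f["name"])
    out: dict = {"lineages": [], "motifs": {}}
    if len(proteins) >= 3:
        D, names = phylo_mod.protein_distance_matrix(proteins)
        tree = phylo_mod.neighbor_joining(D, names)
        _p(cfg, "tree_unrooted.nwk").write_text(tree.newick() + "\n")
        rooted = phylo_mod.midpoint_root(tree)
        _p(cfg, "tree.nwk").write_text(rooted.newick() + "\n")
        groups = phylo_mod.group_lineages(rooted, labels)
        out["lineages"] = [dataclasses.asdict(g) for g in groups]
    ref_path = _p(cfg, "reference.json")
    if ref_path.exists():
        ref = json.loads(ref_path.read_text())
        rows = []
        for p in proteins:
            mc = phylo_mod.check_catalytic_motifs(
                p.sequence, ref["protein"], ref["motif_positions"])
            out["motifs"][p.family_id] = dataclasses.asdict(mc)
            rows.append(f"{p.family_id}\t{mc.dde_intact}\t{mc.dxxh_intact}\t"
                        + ",".join(f"{k}={v}" for k, v in sorted(mc.observed.items())))
        _p(cfg, "motifs.tsv").write_text(
            "family\tdde_intact\tdxxh_intact\tobserved\n" + "\n".join(rows) + "\n")
    _p(cfg, "lineages.json").write_text(json.dumps(out, indent=1))
    return out


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvaluationReport:
    """Copy-detection precision/recall per planted family (matching by
    >=50% reciprocal interval overlap) plus TSD-length, specificity and
    insertion-offset accuracies, with denominators."""

    per_family: dict
    overall: dict

    def to_json(self) -> str:
        return json.dumps({"per_family": self.per_family, "overall": self.overall},
                          indent=1)


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if ov == 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def evaluate_against_truth(copies_rows: list[dict], truth: dict) -> EvaluationReport:
    """Compare the characterized copies with generator ground truth."""
    records = truth["records"]
    planted_labels = truth.get("planted_labels", {})
    genome_ids = {r["genome_id"] for r in records}
    for row in copies_rows:
        if row["genome_id"] not in genome_ids:
            raise ValueError(
                f"report genome id {row['genome_id']!r} not present in truth")
    per_family: dict[str, dict] = {}
    matches = []  # (truth record, report row)
    used = set()
    for tr in records:
        best = None
        for i, row in enumerate(copies_rows):
            if i in used:
                continue
            ro = _reciprocal_overlap((tr["start"], tr["end"]),
                                     (int(row["start"]), int(row["end"])))
            if ro >= 0.5 and (best is None or ro > best[0]):
                best = (ro, i)
        if best is not None:
            used.add(best[1])
            matches.append((tr, copies_rows[best[1]]))
    fam_ids = sorted({r["family_id"] for r in records})
    overall_counts = dict(matched=0, planted=len(records), reported=len(copies_rows),
                          tsd_correct=0, tsd_eval=0, offset_correct=0, offset_eval=0)
    report_family_of = {}  # planted family -> modal recovered family name
    for fid in fam_ids:
        fam_truth = [r for r in records if r["family_id"] == fid]
        fam_matches = [(tr, row) for tr, row in matches if tr["family_id"] == fid]
        names = {}
        for _tr, row in fam_matches:
            names[row["family"]] = names.get(row["family"], 0) + 1
        modal = max(names.items(), key=lambda kv: (kv[1], kv[0]))[0] if names else None
        report_family_of[fid] = modal
        tsd_eval = [(tr, row) for tr, row in fam_matches
                    if not tr["truncated"] and tr["replacement_sidedness"] == "none"]
        def _as_int(v):
            try:
                return int(float(v))
            except (TypeError, ValueError):
                return None

        tsd_ok = sum(1 for tr, row in tsd_eval
                     if _as_int(row["tsd_len"]) == int(tr["tsd_len"]))
        off_eval = [(tr, row) for tr, row in fam_matches if row["flanked_both_sides"]]
        off_ok = sum(1 for tr, row in off_eval
                     if int(row["insertion_offset"]) == int(tr["insertion_offset"]))
        n_reported = sum(1 for row in copies_rows if row["family"] == modal) if modal else 0
        n_matched_modal = sum(1 for _t, row in fam_matches if row["family"] == modal)
        planted_label = planted_labels.get(fid, fid)
        reported_label = None
        if modal is not None:
            # family name pattern Dada-<label><idx?>_<code>
            mid = modal.split("-", 1)[1].rsplit("_", 1)[0]
            reported_label = mid.rstrip("0123456789")
        per_family[fid] = dict(
            planted=len(fam_truth),
            matched=len(fam_matches),
            recall=len(fam_matches) / len(fam_truth) if fam_truth else 1.0,
            reported=n_reported,
            precision=(n_matched_modal / n_reported) if n_reported else 0.0,
            recovered_family=modal,
            planted_label=planted_label,
            reported_label=reported_label,
            label_correct=reported_label == planted_label,
            tsd_eval=len(tsd_eval), tsd_correct=tsd_ok,
            tsd_accuracy=tsd_ok / len(tsd_eval) if tsd_eval else None,
            offset_eval=len(off_eval), offset_correct=off_ok,
            offset_accuracy=off_ok / len(off_eval) if off_eval else None,
        )
        overall_counts["matched"] += len(fam_matches)
        overall_counts["tsd_correct"] += tsd_ok
        overall_counts["tsd_eval"] += len(tsd_eval)
        overall_counts["offset_correct"] += off_ok
        overall_counts["offset_eval"] += len(off_eval)
    overall = dict(
        recall=overall_counts["matched"] / overall_counts["planted"],
        precision=(overall_counts["matched"] / overall_counts["reported"]
                   if overall_counts["reported"] else 0.0),
        tsd_accuracy=(overall_counts["tsd_correct"] / overall_counts["tsd_eval"]
                      if overall_counts["tsd_eval"] else None),
        offset_accuracy=(overall_counts["offset_correct"] / overall_counts["offset_eval"]
                         if overall_counts["offset_eval"] else None),
        label_accuracy=(sum(1 for f in per_family.values() if f["label_correct"])
                        / len(per_family) if per_family else None),
        **overall_counts,
    )
    return EvaluationReport(per_family=per_family, overall=overall)


def stage_evaluate(cfg: PipelineConfig) -> EvaluationReport:
    import pandas as pd

    truth = json.loads(_p(cfg, "truth.json").read_text())
    df = pd.read_csv(_p(cfg, "copies.tsv"), sep="\t")
    rows = df.to_dict("records")
    rep = evaluate_against_truth(rows, truth)
    _p(cfg, "evaluation.json").write_text(rep.to_json())
    return rep


def write_manifest(cfg: PipelineConfig) -> dict:
    run = Path(cfg.run_dir)
    manifest = {}
    for p in sorted(run.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    _p(cfg, "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order; returns a summary dictionary."""
    cfg.validate()
    logging.basicConfig(level=logging.INFO)
    stage_simulate(cfg)
    stage_search(cfg)
    stage_build(cfg)
    records = stage_characterize(cfg)
    tree = stage_tree(cfg)
    summary: dict = {
        "families": [r.name for r in records],
        "lineages": [g["name"] for g in tree.get("lineages", [])],
    }
    if _p(cfg, "truth.json").exists():
        rep = stage_evaluate(cfg)
        summary["evaluation"] = rep.overall
    write_manifest(cfg)
    return summary
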