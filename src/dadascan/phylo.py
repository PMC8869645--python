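"""Transposase extraction, catalytic-motif screening, neighbor-joining
trees with midpoint rooting, and grouping of families into
target-specificity lineages.

The tree is a distance tree over transposase p-distances: the package's
claim is the grouping of families by lineage, not branch support, so a
deterministic NJ + midpoint rooting stands in for likelihood methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .align import align_protein_global, revcomp

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ORF extraction

@dataclass
class TransposaseProtein:
    family_id: str
    sequence: str  # residues, no stop
    frame: int  # 1..3
    strand: str
    length: int = 0

    def __post_init__(self) -> None:
        self.length = len(self.sequence)


def extract_transposase(
    consensus: str, family_id: str = "", min_orf_codons: int = 300
) -> Optional[TransposaseProtein]:
    """Longest ORF (Met to stop) over six frames, translated.

    Returns None (family non-coding) when no ORF reaches
    ``min_orf_codons`` codons. The default threshold sits below known
    transposase lengths while tolerating partially truncated consensus
    sequences.
    """
    best: Optional[TransposaseProtein] = None
    for strand in "+-":
        s = consensus if strand == "+" else revcomp(consensus)
        for f in range(3):
            sub = s[f : len(s) - ((len(s) - f) % 3)]
            if len(sub) < 3:
                continue
            prot = str(Seq(sub).translate())
            pos = 0
            for segment in prot.split("*"):
                m = segment.find("M")
                if m >= 0:
                    orf = segment[m:]
                    if len(orf) >= min_orf_codons and (
                        best is None or len(orf) > best.length
                    ):
                        best = TransposaseProtein(family_id, orf, f + 1, strand)
                pos += len(segment) + 1
    return best


# ---------------------------------------------------------------------------
# motif screen

@dataclass
class MotifCheck:
    """Intactness of the DDE catalytic triad and the DxxH signature,
    with the residues observed at the annotated reference positions."""

    dde_intact: bool
    dxxh_intact: bool
    observed: dict[str, str]


def check_catalytic_motifs(
    protein: str,
    reference_protein: str,
    reference_positions: dict[str, int],
) -> MotifCheck:
    """Project annotated catalytic positions of a reference transposase
    onto a protein through a global alignment and read the residues.

    ``reference_positions`` carries 1-based positions on the reference
    for keys ``d1``, ``d2``, ``e`` (catalytic triad) and ``h`` (the DxxH
    histidine). The triad is intact when the residues are (D, D, E) or
    (D, D, D); a position projected into a gap reads "-" and is not
    intact. A histidine-to-glutamine change (DxxQ) is the classic
    domestication signature.
    """
    aln = align_protein_global(protein, reference_protein)
    # map reference position -> protein residue through alignment columns
    proj: dict[int, str] = {}
    pi = ri = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if cb != "-":
            ri += 1
            proj[ri] = ca if ca != "-" else "-"
        if ca != "-":
            pi += 1
    observed = {k: proj.get(p, "-") for k, p in reference_positions.items()}
    dde = (
        observed.get("d1") == "D"
        and observed.get("d2") == "D"
        and observed.get("e") in ("E", "D")
    )
    dxxh = observed.get("h") == "H"
    return MotifCheck(dde_intact=dde, dxxh_intact=dxxh, observed=observed)


# ---------------------------------------------------------------------------
# distances

def protein_distance_matrix(
    proteins: Sequence[TransposaseProtein],
) -> tuple[np.ndarray, list[str]]:
    """Pairwise p-distances (mismatches / aligned non-gap columns) from
    global alignments. Requires at least three proteins."""
    if len(proteins) < 3:
        raise ValueError("need at least 3 proteins for a distance matrix")
    n = len(proteins)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = align_protein_global(proteins[i].sequence, proteins[j].sequence)
            D[i, j] = D[j, i] = 1.0 - aln.identity
    return D, [p.family_id for p in proteins]


# ---------------------------------------------------------------------------
# trees

@dataclass
class Clade:
    name: Optional[str] = None
    branch_length: float = 0.0
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.branch_length:.6g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.branch_length:.6g}"


@dataclass
class PhyloTree:
    root: Clade
    rooted: bool = False

    def newick(self) -> str:
        inner = ",".join(c.newick() for c in self.root.children)
        return f"({inner});"

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    # -- undirected edge view, for path lengths and re-rooting
    def edges(self) -> list[tuple[Clade, Clade, float]]:
        out = []

        def walk(node: Clade):
            for c in node.children:
                out.append((node, c, c.branch_length))
                walk(c)

        walk(self.root)
        return out

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """All leaf-pair path lengths (undirected)."""
        adj: dict[int, list[tuple[Clade, float]]] = {}
        for a, b, w in self.edges():
            adj.setdefault(id(a), []).append((b, w))
            adj.setdefault(id(b), []).append((a, w))
        leaves = self.root.leaves()
        out: dict[tuple[str, str], float] = {}
        for src in leaves:
            dist = {id(src): 0.0}
            stack = [src]
            while stack:
                node = stack.pop()
                for nxt, w in adj.get(id(node), []):
                    if id(nxt) not in dist:
                        dist[id(nxt)] = dist[id(node)] + w
                        stack.append(nxt)
            for dst in leaves:
                if dst is not src:
                    out[(src.name, dst.name)] = dist[id(dst)]
        return out


def neighbor_joining(matrix: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Standard neighbor-joining agglomeration with deterministic
    tie-breaking (smallest index pair). Negative branch lengths are
    clamped to zero with a log entry. The result is unrooted,
    represented with a trifurcating root."""
    D = np.array(matrix, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs n >= 3")
    if not np.allclose(D, D.T, atol=1e-9) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    nodes: list[Clade] = [Clade(name=l) for l in labels]
    active = list(range(n))
    Dw = {(i, j): D[i, j] for i in range(n) for j in range(n)}

    def clamp(x: float) -> float:
        if x < 0:
            logger.info("clamped negative NJ branch length %.4g to 0", x)
            return 0.0
        return x

    while len(active) > 2:
        m = len(active)
        r = {i: sum(Dw[(i, k)] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * Dw[(i, j)] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * Dw[(i, j)] + (r[i] - r[j]) / (2 * (m - 2))
        lj = Dw[(i, j)] - li
        parent = Clade()
        ci, cj = nodes[i], nodes[j]
        ci.branch_length = clamp(li)
        cj.branch_length = clamp(lj)
        parent.children = [ci, cj]
        new = len(nodes)
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)]
        for k in active:
            Dw[(new, k)] = Dw[(k, new)] = 0.5 * (
                Dw[(i, k)] + Dw[(j, k)] - Dw[(i, j)]
            )
        Dw[(new, new)] = 0.0
        active.append(new)
    i, j = active
    # join the last two: place the remaining edge on a trifurcating root
    # when one side is internal, else a simple two-leaf tree
    a, b = nodes[i], nodes[j]
    d = clamp(Dw[(i, j)])
    if not a.is_leaf:
        b.branch_length = d
        a.children.append(b)
        root = a
    elif not b.is_leaf:
        a.branch_length = d
        b.children.append(a)
        root = b
    else:
        a.branch_length = d / 2
        b.branch_length = d / 2
        root = Clade(children=[a, b])
    return PhyloTree(root=root, rooted=False)


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root the tree halfway along the longest leaf-to-leaf path.

    The two farthest leaves end up equidistant from the root (to within
    numerical precision). Re-rooting an already midpoint-rooted tree is
    idempotent. A tree with all-zero branch lengths keeps its topology
    with the root at an arbitrary node (logged).
    """
    # undirected adjacency
    adj: dict[int, list[tuple[Clade, float]]] = {}
    index: dict[int, Clade] = {}
    for a, b, w in tree.edges():
        adj.setdefault(id(a), []).append((b, w))
        adj.setdefault(id(b), []).append((a, w))
        index[id(a)] = a
        index[id(b)] = b
    leaves = sorted(tree.root.leaves(), key=lambda l: l.name)
    if len(leaves) < 2:
        return PhyloTree(root=tree.root, rooted=True)

    def farthest(src: Clade):
        dist = {id(src): 0.0}
        prev: dict[int, Clade] = {}
        stack = [src]
        while stack:
            node = stack.pop()
            for nxt, w in adj.get(id(node), []):
                if id(nxt) not in dist:
                    dist[id(nxt)] = dist[id(node)] + w
                    prev[id(nxt)] = node
                    stack.append(nxt)
        best = max(
            (l for l in leaves if l is not src),
            key=lambda l: (dist[id(l)], l.name),
        )
        return best, dist, prev

    u, _, _ = farthest(leaves[0])
    v, dist, prev = farthest(u)
    diameter = dist[id(v)]
    if diameter <= 0:
        logger.info("zero-length tree; midpoint root placed at an arbitrary node")
        return PhyloTree(root=tree.root, rooted=True)
    # walk back from v to u, find the edge containing the midpoint
    path = [v]
    while path[-1] is not u:
        path.append(prev[id(path[-1])])
    half = diameter / 2
    acc = 0.0
    edge_w = {}
    for a, b, w in tree.edges():
        edge_w[(id(a), id(b))] = w
        edge_w[(id(b), id(a))] = w
    for k in range(len(path) - 1):
        w = edge_w[(id(path[k]), id(path[k + 1]))]
        if acc + w >= half - 1e-12:
            below, above = path[k], path[k + 1]
            t_below = half - acc  # distance from `below` to the new root
            break
        acc += w
    # re-root: new root on the edge (below, above)
    new_root = Clade()

    def rebuild(node: Clade, came_from: Clade | None) -> Clade:
        clone = Clade(name=node.name)
        for nxt, w in adj.get(id(node), []):
            if came_from is not None and nxt is came_from:
                continue
            child = rebuild(nxt, node)
            child.branch_length = w
            clone.children.append(child)
        return clone

    cb = rebuild(below, above)
    cb.branch_length = t_below
    ca = rebuild(above, below)
    ca.branch_length = edge_w[(id(below), id(above))] - t_below
    new_root.children = [cb, ca]
    # suppress degree-2 internal nodes created by removing the old root
    def suppress(node: Clade):
        for i, c in enumerate(list(node.children)):
            suppress(c)
        node.children = [
            c if c.is_leaf or len(c.children) != 1 else _merge_unary(c)
            for c in node.children
        ]

    def _merge_unary(c: Clade) -> Clade:
        child = c.children[0]
        child.branch_length += c.branch_length
        return child

    suppress(new_root)
    return PhyloTree(root=new_root, rooted=True)


# ---------------------------------------------------------------------------
# lineage grouping

@dataclass
class LineageGroup:
    name: str  # e.g. "tA" or the merged "tD/tV"
    labels: list[str]
    families: list[str]
    provisional: list[str] = field(default_factory=list)  # unconfirmed members


def group_lineages(tree: PhyloTree, family_labels: dict[str, str]) -> list[LineageGroup]:
    """Group leaves of a rooted tree into target-specificity lineages.

    Maximal clades whose confirmed labels are all identical form a
    lineage named by that label; unconfirmed leaves inside a lineage
    clade inherit its label (flagged provisional). Two labels whose
    leaves interleave — the minimal clade containing one label's leaves
    also contains the other's — are merged into a slash-named lineage.
    """
    leaves = tree.root.leaves()
    label_leaves: dict[str, set[str]] = {}
    for leaf in leaves:
        lab = family_labels.get(leaf.name, "unconfirmed")
        if lab != "unconfirmed":
            label_leaves.setdefault(lab, set()).add(leaf.name)

    # leaf sets of every clade
    clade_sets: list[tuple[Clade, frozenset[str]]] = []

    def walk(node: Clade) -> frozenset[str]:
        if node.is_leaf:
            s = frozenset([node.name])
        else:
            s = frozenset().union(*(walk(c) for c in node.children))
        clade_sets.append((node, s))
        return s

    walk(tree.root)

    def mrca_set(names: set[str]) -> frozenset[str]:
        best = None
        for _, s in clade_sets:
            if names <= s and (best is None or len(s) < len(best)):
                best = s
        return best if best is not None else frozenset(names)

    labels = sorted(label_leaves)
    parent = {l: l for l in labels}

    def find(l):
        while parent[l] != l:
            parent[l] = parent[parent[l]]
            l = parent[l]
        return l

    for a in labels:
        ma = mrca_set(label_leaves[a])
        for b in labels:
            if a == b:
                continue
            if ma & label_leaves[b]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for l in labels:
        groups.setdefault(find(l), []).append(l)

    out: list[LineageGroup] = []
    assigned: set[str] = set()
    for members in groups.values():
        labs = sorted(members)
        fams: set[str] = set().union(*(label_leaves[l] for l in labs))
        clade = mrca_set(set(fams))
        provisional = sorted(
            n for n in clade
            if family_labels.get(n, "unconfirmed") == "unconfirmed"
        )
        out.append(
            LineageGroup(
                name="/".join(labs),
                labels=labs,
                families=sorted(fams) + provisional,
                provisional=provisional,
            )
        )
        assigned |= fams | set(provisional)
    leftovers = sorted(
        l.name for l in leaves if l.name not in assigned
    )
    if leftovers:
        out.append(LineageGroup("unconfirmed", ["unconfirmed"], leftovers, leftovers))
    out.sort(key=lambda g: g.name)
    return out
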