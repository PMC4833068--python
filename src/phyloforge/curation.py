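"""Homolog-group curation: hit filtering, alignment trimming, long-branch
cutting, spurious-tip removal, and isoform masking.

The curation pipeline refines similarity-clustered gene families into clean
homolog trees.  Alignment and tree inference themselves are external
(MAFFT/SATe, FastTree/RAxML and friends); this module consumes their output
and performs the tree- and alignment-surgery steps between rounds:

1. iteratively cut branches longer than 2 substitutions/site (conserved
   domains or assembly chimeras pull unrelated clusters together),
2. repeat at the more stringent cutoff 0.5,
3. on the final tree cut at 0.6, remove spurious terminal branches
   (> 0.2 and > 10x their sister), and
4. mask assembly isoforms: monophyletic or paraphyletic same-taxon tips are
   reduced to the single tip with the most unambiguous aligned characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

from .seqs import AMBIGUOUS, Alignment, SeqRecord, TaxonMap
from .trees import Node, PhyloTree


@dataclass
class HitRecord:
    """One row of an all-vs-all protein similarity report (outfmt-6 style)."""

    query: str
    subject: str
    pident: float          # percent identity in [0, 100]
    nident: int            # identical aligned residues
    qlen: int
    slen: int
    qcov: float            # aligned query fraction in [0, 1]
    evalue: float

    @property
    def is_self(self) -> bool:
        return self.query == self.subject


@dataclass
class CurationParams:
    """Numeric knobs of the homology-inference stage."""

    evalue_cutoff: float = 1e-5
    min_ident_pct: float = 50.0
    min_qcov: float = 0.7
    mcl_evalue_cutoff: float = 1e-30     # metadata: clustering is external
    min_seq_len_aa: int = 40
    min_ingroup_taxa: int = 8
    col_occupancy_homolog: float = 0.05
    col_occupancy_ortholog: float = 0.3
    branch_cutoffs: tuple[float, ...] = (2.0, 0.5, 0.6)
    spurious_tip_abs: float = 0.2
    spurious_tip_ratio: float = 10.0

    def __post_init__(self):
        if any(c <= 0 for c in self.branch_cutoffs):
            raise ValueError("branch cutoffs must be positive")
        iterative = self.branch_cutoffs[:-1]
        if list(iterative) != sorted(set(iterative), reverse=True):
            # iterated rounds tighten; the last value applies to the final
            # tree only and may sit between them
            raise ValueError("iterative branch cutoffs must strictly decrease")


@dataclass
class HomologGroup:
    """A putative gene family: members plus (optionally) alignment and tree."""

    id: str
    members: list[SeqRecord] = field(default_factory=list)
    alignment: Alignment | None = None
    tree: PhyloTree | None = None

    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]


# ---------------------------------------------------------------------------
# tabular hit parsing / filtering
# ---------------------------------------------------------------------------

def parse_hit_table(text: str) -> list[HitRecord]:
    """Parse a 14-column tab-separated hit report.

    Column order is the standard 12-column tabular output (query, subject,
    pident, alnlen, mismatch, gapopen, qstart, qend, sstart, send, evalue,
    bitscore) extended with qlen and slen.  Query coverage is computed as
    (qend - qstart + 1) / qlen from the single reported HSP.
    """
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        try:
            if len(parts) < 14:
                raise ValueError(f"{len(parts)} columns, expected >= 14")
            q, s = parts[0], parts[1]
            pident = float(parts[2])
            alnlen = int(parts[3])
            qstart, qend = int(parts[6]), int(parts[7])
            evalue = float(parts[10])
            qlen, slen = int(parts[12]), int(parts[13])
            nident = round(pident / 100.0 * alnlen)
            qcov = (qend - qstart + 1) / qlen
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed hit row at line {lineno}: {exc}") from exc
        out.append(HitRecord(q, s, pident, nident, qlen, slen, qcov, evalue))
    return out


def filter_hits(hits: Iterable[HitRecord],
                params: CurationParams | None = None) -> list[HitRecord]:
    """Keep hits usable for homology inference.

    Retains non-self hits with E-value <= cutoff, percent identity > 50 and
    query coverage (aligned query span / query length) > 0.7.
    """
    params = params or CurationParams()
    return [h for h in hits
            if not h.is_self
            and h.evalue <= params.evalue_cutoff
            and h.pident > params.min_ident_pct
            and h.qcov > params.min_qcov]


def read_clusters(text: str) -> list[list[str]]:
    """Cluster membership, one cluster per line of whitespace-separated ids."""
    return [line.split() for line in text.splitlines() if line.strip()]


# ---------------------------------------------------------------------------
# cluster-level filters
# ---------------------------------------------------------------------------

def filter_cluster(group: HomologGroup, params: CurationParams,
                   taxa: TaxonMap) -> HomologGroup | None:
    """Drop short sequences; reject groups with too few ingroup taxa.

    Sequences shorter than ``min_seq_len_aa`` (unaligned amino acids) are
    removed; the group is rejected (``None``) when fewer than
    ``min_ingroup_taxa`` distinct ingroup taxa remain.
    """
    kept = [m for m in group.members
            if len(m.ungapped()) >= params.min_seq_len_aa]
    if taxa.n_ingroup_taxa([m.id for m in kept]) < params.min_ingroup_taxa:
        return None
    return replace(group, members=kept)


def trim_columns(aln: Alignment, min_occupancy: float) -> tuple[Alignment, list[str]]:
    """Remove low-occupancy alignment columns.

    A column is kept when the fraction of non-gap, non-ambiguous cells is at
    least ``min_occupancy``.  Returns the trimmed alignment plus the ids of
    rows left all-gap by the trimming (flagged, not dropped).
    """
    if not 0 <= min_occupancy <= 1:
        raise ValueError("min_occupancy must be in [0, 1]")
    if aln.n_rows == 0:
        raise ValueError("empty alignment")
    n = aln.n_rows
    keep = [j for j in range(aln.n_cols)
            if sum(1 for c in aln.column(j) if c not in AMBIGUOUS) / n
            >= min_occupancy or min_occupancy == 0]
    rows = [SeqRecord(r.id, "".join(r.residues[j] for j in keep), r.taxon)
            for r in aln.rows]
    trimmed = Alignment(rows, aln.alphabet)
    empty = [r.id for r in trimmed.rows if r.n_unambiguous == 0]
    return trimmed, empty


# ---------------------------------------------------------------------------
# tree surgery
# ---------------------------------------------------------------------------

def cut_long_branches(tree: PhyloTree, cutoff: float) -> list[PhyloTree]:
    """Cut every branch longer than ``cutoff``; return the resulting subtrees.

    The input may be arbitrarily rooted: a bifurcating root's two edges are
    first merged so the cut set matches the underlying unrooted tree, making
    the result invariant to the input rooting.  Each connected component of
    the cut tree is returned as one tree (single tips included); unary nodes
    are suppressed with branch lengths merged additively, so no returned tree
    retains a branch longer than the cutoff.
    """
    out: list[PhyloTree] = []
    pending = [tree.copy().root]
    while pending:
        frag = PhyloTree(pending.pop(), rooted=False)
        frag.root.length = None
        frag.suppress_unifurcations()
        if frag.root.is_tip and frag.root.label is None:
            continue  # component reduced to nothing (all children cut away)
        # a degree-2 root splits one underlying unrooted edge in two:
        # merge so the cut decision matches the unrooted tree
        if len(frag.root.children) == 2:
            a, b = frag.root.children
            if a.is_tip and b.is_tip:
                if (a.length or 0.0) + (b.length or 0.0) > cutoff:
                    pending.extend(frag.root.children)
                    continue
            else:
                frag.collapse_root_edge()
        long_edges = [n for n in frag.root.iter_preorder()
                      if n.parent is not None and n.length is not None
                      and n.length > cutoff]
        if not long_edges:
            out.append(frag)
            continue
        for n in long_edges:
            n.parent.remove_child(n)
        pending.append(frag.root)       # re-check after suppression merges
        pending.extend(long_edges)
    return out


def _stepwise_depth(node: Node) -> float:
    """Stepwise-average depth: A(tip)=0; A(n)=mean_c(length(c)+A(c))."""
    if node.is_tip:
        return 0.0
    return sum((c.length or 0.0) + _stepwise_depth(c)
               for c in node.children) / len(node.children)


def remove_spurious_tips(tree: PhyloTree, abs_cutoff: float = 0.2,
                         ratio: float = 10.0,
                         sister_mode: str = "subtree") -> PhyloTree:
    """Remove tips on suspiciously long terminal branches.

    A tip is removed when its terminal branch exceeds ``abs_cutoff``
    substitutions/site AND is more than ``ratio`` times its sister's length.
    A non-tip sister's length is its stem plus its stepwise-average depth
    (``sister_mode="subtree"``); with ``sister_mode="tip"``, only tip sisters
    are compared.  At polytomies the longest sibling measure is used, so a
    tip is only removed when it dwarfs every sibling.
    """
    work = tree.copy()

    def sister_length(sib: Node) -> float | None:
        if sib.is_tip:
            return sib.length or 0.0
        if sister_mode == "tip":
            return None
        return (sib.length or 0.0) + _stepwise_depth(sib)

    doomed = []
    for tip in work.tips():
        if tip.parent is None or tip.length is None or tip.length <= abs_cutoff:
            continue
        sibs = [sister_length(s) for s in tip.parent.children if s is not tip]
        sibs = [s for s in sibs if s is not None]
        if sibs and tip.length > ratio * max(sibs):
            doomed.append(tip)
    for tip in doomed:
        if tip.parent is not None:
            tip.parent.remove_child(tip)
    work.suppress_unifurcations()
    return work


def mask_isoform_tips(tree: PhyloTree, taxa: TaxonMap,
                      char_counts: dict[str, int]) -> PhyloTree:
    """Reduce same-taxon isoform tip groups to a single representative.

    Within every maximal monophyletic or paraphyletic (grade interrupted only
    by tips of the same taxon) set of tips belonging to one taxon, only the
    tip with the highest unambiguous-character count is kept (ties broken by
    lexicographically smallest id).  Implemented by iterating two local
    rules to a fixed point: merge sister tips of one taxon, then merge a tip
    with its parent's sister tip of the same taxon.
    """
    for tip in tree.tips():
        if tip.label not in char_counts:
            raise KeyError(f"no character count for tip {tip.label!r}")
    work = tree.copy()

    def better(a: Node, b: Node) -> Node:
        ka, kb = char_counts[a.label], char_counts[b.label]
        if ka != kb:
            return a if ka > kb else b
        return a if a.label < b.label else b

    def merge(keep: Node, drop: Node) -> None:
        drop.parent.remove_child(drop)
        work.suppress_unifurcations()

    changed = True
    while changed:
        changed = False
        # monophyletic: two sister tips of one taxon
        for tip in work.tips():
            if tip.parent is None:
                continue
            for sib in tip.parent.children:
                if sib is not tip and sib.is_tip and sib.label is not None \
                        and taxa.taxon_of(sib.label) == taxa.taxon_of(tip.label):
                    keep = better(tip, sib)
                    merge(keep, sib if keep is tip else tip)
                    changed = True
                    break
            if changed:
                break
        if changed:
            continue
        # paraphyletic: tip vs its parent's sister tip of the same taxon
        for tip in work.tips():
            parent = tip.parent
            if parent is None or parent.parent is None:
                continue
            for aunt in parent.parent.children:
                if aunt is not parent and aunt.is_tip and aunt.label is not None \
                        and taxa.taxon_of(aunt.label) == taxa.taxon_of(tip.label):
                    keep = better(tip, aunt)
                    merge(keep, aunt if keep is tip else tip)
                    changed = True
                    break
            if changed:
                break
    return work


# ---------------------------------------------------------------------------
# the full curation pipeline
# ---------------------------------------------------------------------------

@dataclass
class RemovalEvent:
    """Machine-readable log entry for one curation removal."""

    stage: str         # e.g. "cut@2.0", "spurious_tip", "isoform_mask"
    group_id: str
    detail: str


#: hook signature: (group) -> group with fresh alignment+tree; identity by default
InferenceHook = Callable[[HomologGroup], HomologGroup]


def curate_pipeline(group: HomologGroup, params: CurationParams,
                    taxa: TaxonMap,
                    infer: InferenceHook | None = None,
                    ) -> tuple[list[HomologGroup], list[RemovalEvent]]:
    """Run the full curation cascade on one putative homolog group.

    Requires ``group.tree`` (and ``group.alignment`` when character counts are
    needed for isoform masking).  ``infer`` re-estimates alignment and tree
    for the subgroups produced by each long-branch cutting round; when omitted
    the existing tree is re-used (appropriate for precomputed inputs and for
    simulation, where topology does not change between rounds).

    Returns the surviving homolog groups plus a removal log.
    """
    if group.tree is None:
        raise ValueError(f"group {group.id}: curation requires a tree")
    infer = infer or (lambda g: g)
    log: list[RemovalEvent] = []
    *iterative_cutoffs, final_cutoff = params.branch_cutoffs

    def subgroup(parent: HomologGroup, tree: PhyloTree, serial: int
                 ) -> HomologGroup:
        ids = set(tree.tip_labels())
        members = [m for m in parent.members if m.id in ids]
        aln = parent.alignment.subset(ids) if parent.alignment else None
        gid = parent.id if serial == 0 else f"{parent.id}_{serial}"
        return HomologGroup(gid, members, aln, tree)

    work = [group]
    for cutoff in iterative_cutoffs:
        nxt = []
        for g in work:
            pieces = cut_long_branches(g.tree, cutoff)
            if len(pieces) > 1:
                log.append(RemovalEvent(f"cut@{cutoff:g}", g.id,
                                        f"split into {len(pieces)} components"))
            for i, piece in enumerate(pieces):
                sub = subgroup(g, piece, i if len(pieces) > 1 else 0)
                checked = filter_cluster(sub, params, taxa)
                if checked is None:
                    log.append(RemovalEvent("min_ingroup_taxa", sub.id,
                                            f"{len(piece.tips())} tips discarded"))
                    continue
                try:
                    nxt.append(infer(checked))
                except Exception as exc:
                    raise RuntimeError(
                        f"inference hook failed at cut@{cutoff:g} for "
                        f"{sub.id}: {exc}") from exc
        work = nxt

    out: list[HomologGroup] = []
    for g in work:
        pieces = cut_long_branches(g.tree, final_cutoff)
        if len(pieces) > 1:
            log.append(RemovalEvent(f"cut@{final_cutoff:g}", g.id,
                                    f"split into {len(pieces)} components"))
        for i, piece in enumerate(pieces):
            before = set(piece.tip_labels())
            piece = remove_spurious_tips(piece, params.spurious_tip_abs,
                                         params.spurious_tip_ratio)
            for lost in sorted(before - set(piece.tip_labels())):
                log.append(RemovalEvent("spurious_tip", g.id, lost))
            counts = (g.alignment.char_counts() if g.alignment
                      else {t: 0 for t in piece.tip_labels()})
            before = set(piece.tip_labels())
            piece = mask_isoform_tips(piece, taxa, counts)
            for lost in sorted(before - set(piece.tip_labels())):
                log.append(RemovalEvent("isoform_mask", g.id, lost))
            sub = subgroup(g, piece, i if len(pieces) > 1 else 0)
            checked = filter_cluster(sub, params, taxa)
            if checked is None:
                log.append(RemovalEvent("min_ingroup_taxa", sub.id,
                                        "discarded after final round"))
                continue
            out.append(checked)
    return out, log
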