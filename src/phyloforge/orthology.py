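"""Orthology decomposition of homolog trees by rooted-clade extraction and
iterative pruning of the smaller side at each inferred duplication.

Homolog trees are unrooted.  Clades "rooted by" the designated root taxon
(the earliest-diverging taxon in the dataset) are extracted: every maximal
subtree free of root-taxon tips that sits across a single edge from a
root-taxon-containing component.  Within each extracted clade, a gene
duplication is inferred wherever the two sides of a node share one or more
taxa; the side with fewer distinct taxa is pruned, root to tips, until no
taxon appears twice.  What remains is an ortholog group: at most one
sequence per taxon, related purely by speciation under this criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

from .curation import HomologGroup, trim_columns
from .seqs import Alignment, TaxonMap
from .trees import Node, PhyloTree, extract_subtree, reroot


@dataclass
class OrthologGroup:
    """A pruned, re-trimmed single-copy gene: tree + alignment."""

    id: str
    tree: PhyloTree
    alignment: Alignment
    source_homolog: str

    @property
    def n_taxa(self) -> int:
        return len({r.taxon for r in self.alignment.rows})

    @property
    def n_cols(self) -> int:
        return self.alignment.n_cols


@dataclass
class PruneEvent:
    """One duplication-side removal during RT pruning."""

    node_tips: tuple[str, ...]      # tips of the pruned side
    shared_taxa: tuple[str, ...]


# ---------------------------------------------------------------------------

def extract_rooted_clades(tree: PhyloTree, taxa: TaxonMap) -> list[PhyloTree]:
    """Extract maximal root-taxon-free clades from an unrooted homolog tree.

    Each returned clade is a maximal subtree with no root-taxon tip that is
    adjacent (across one edge) to a component containing at least one
    root-taxon tip; it is returned rooted at that edge with the edge length
    kept as the clade's stem.  Trees without a root-taxon tip yield ``[]``.
    The result is invariant to the arbitrary rooting of the input.
    """
    if taxa.root_taxon is None:
        raise ValueError("taxon map has no root taxon")
    root_tips = sorted(t.label for t in tree.tips()
                       if taxa.taxon_of(t.label) == taxa.root_taxon)
    if not root_tips:
        return []
    # deterministic orientation: hang the tree from the first root-taxon tip
    work = reroot(tree, tree.find_tip(root_tips[0]))

    clades: list[PhyloTree] = []

    def walk(node: Node) -> None:
        for child in node.children:
            labels = child.tip_labels()
            if any(taxa.taxon_of(l) == taxa.root_taxon for l in labels):
                walk(child)
            elif not child.is_tip or taxa.taxon_of(child.label) != taxa.root_taxon:
                clades.append(extract_subtree(work, child))

    walk(work.root)
    return clades


def _taxon_set(node: Node, taxa: TaxonMap) -> set[str]:
    return {taxa.taxon_of(l) for l in node.tip_labels()}


def prune_paralogs_rt(clade: PhyloTree, taxa: TaxonMap,
                      char_counts: dict[str, int] | None = None,
                      ) -> tuple[PhyloTree, list[PruneEvent]]:
    """Rooted-tree (RT) paralog pruning.

    Traverses the rooted clade from the root toward the tips; at every node
    whose child subtrees share at least one taxon, the side with fewer
    distinct taxa is removed (tie-break: keep the side with the greater
    summed unambiguous-character count, then the lexicographically smallest
    tip id).  At polytomies all child pairs are checked and the smaller side
    pruned greedily until children are pairwise taxon-disjoint.  The result
    has at most one tip per taxon.
    """
    char_counts = char_counts or {}
    work = clade.copy()
    events: list[PruneEvent] = []

    def weight(node: Node) -> tuple:
        tips = sorted(node.tip_labels())
        chars = sum(char_counts.get(t, 0) for t in tips)
        # larger tuple wins the keep decision
        return (len(_taxon_set(node, taxa)), chars,
                # smaller id should win, so negate via reverse comparison later
                tips[0] if tips else "")

    def prune_at(node: Node) -> bool:
        """Resolve one overlapping child pair below ``node``; True if pruned."""
        kids = node.children
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                a, b = kids[i], kids[j]
                shared = _taxon_set(a, taxa) & _taxon_set(b, taxa)
                if not shared:
                    continue
                (na, ca, ta), (nb, cb, tb) = weight(a), weight(b)
                if (na, ca) > (nb, cb):
                    drop = b
                elif (nb, cb) > (na, ca):
                    drop = a
                else:
                    drop = b if ta < tb else a
                events.append(PruneEvent(tuple(sorted(drop.tip_labels())),
                                         tuple(sorted(shared))))
                node.remove_child(drop)
                return True
        return False

    # iterate to a fixed point, restarting traversal after each removal so
    # detached subtrees are never revisited
    while True:
        pruned = False
        for node in work.root.iter_preorder():
            if not node.is_tip and prune_at(node):
                pruned = True
                break
        if not pruned:
            break
        work.suppress_unifurcations()

    # postcondition asserted on every call
    labels = work.tip_labels()
    taxon_list = [taxa.taxon_of(l) for l in labels]
    assert len(taxon_list) == len(set(taxon_list)), \
        "RT pruning left a duplicated taxon"
    return work, events


def build_ortholog_group(homolog: HomologGroup, pruned: PhyloTree,
                         taxa: TaxonMap, min_taxa: int = 10,
                         min_cols: int = 0, serial: int = 0,
                         min_occupancy: float = 0.3,
                         ) -> OrthologGroup | None:
    """Assemble an ortholog group from a pruned clade.

    Alignment rows for the retained tips are extracted from the homolog
    alignment and re-trimmed at ``min_occupancy`` column occupancy; the
    group is rejected (``None``) when fewer than ``min_taxa`` taxa or
    ``min_cols`` columns remain.
    """
    if homolog.alignment is None:
        raise ValueError(f"homolog {homolog.id} has no alignment")
    ids = pruned.tip_labels()
    have = set(homolog.alignment.ids())
    missing = [i for i in ids if i not in have]
    if missing:
        raise KeyError(f"tips without alignment rows: {missing}")
    aln = homolog.alignment.subset(ids)
    aln, _ = trim_columns(aln, min_occupancy)
    group = OrthologGroup(f"{homolog.id}.o{serial}", pruned, aln, homolog.id)
    if group.n_taxa < min_taxa or group.n_cols < min_cols:
        return None
    return group


def orthologs_from_homolog(homolog: HomologGroup, taxa: TaxonMap,
                           min_taxa: int = 10, min_cols: int = 0,
                           ) -> list[OrthologGroup]:
    """Full decomposition of one homolog group into ortholog groups."""
    if homolog.tree is None:
        raise ValueError(f"homolog {homolog.id} has no tree")
    counts = homolog.alignment.char_counts() if homolog.alignment else {}
    out = []
    serial = 0
    for clade in extract_rooted_clades(homolog.tree, taxa):
        pruned, _ = prune_paralogs_rt(clade, taxa, counts)
        group = build_ortholog_group(homolog, pruned, taxa, min_taxa,
                                     min_cols, serial)
        serial += 1
        if group is not None:
            out.append(group)
    return out
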