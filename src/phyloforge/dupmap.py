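"""Mapping gene duplications from homolog trees onto a species tree.

Well-supported, taxon-rich clades are extracted from homolog trees; a gene
duplication is recorded at every clade node whose two child subtrees share
two or more taxa, and is mapped to the most recent common ancestor of the
node's taxa on the species tree.  Per extracted clade, nested duplications
mapping to the same species node are counted once.  Branch summaries report,
for each species-tree branch, the proportion of informative clades that show
a duplication there — the signature used to locate whole-genome
duplications, which appear as one branch with a far higher proportion than
the background gene-duplication rate produces elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqs import TaxonMap
from .trees import Node, PhyloTree, extract_subtree, mrca_taxa, reroot


@dataclass
class CladeExtractionRule:
    """Which clades of a homolog tree qualify for duplication mapping."""

    clade_name: str
    members: set[str]
    min_taxa_present: int
    min_mean_support: float = 80.0

    def __post_init__(self):
        if self.min_taxa_present > len(self.members):
            raise ValueError("min_taxa_present exceeds clade size")


@dataclass
class DuplicationRecord:
    homolog_id: str
    clade_serial: int
    taxa_union: frozenset[str]
    shared_taxa: frozenset[str]
    species_node_id: str


@dataclass
class BranchSummary:
    n_dup: int = 0
    n_informative: int = 0

    @property
    def proportion(self) -> float | None:
        if self.n_informative == 0:
            return None   # not investigated
        return self.n_dup / self.n_informative


# ---------------------------------------------------------------------------

def label_species_nodes(species_tree: PhyloTree) -> None:
    """Assign stable ids to internal species-tree nodes (tips keep labels)."""
    i = 0
    for node in species_tree.root.iter_preorder():
        if not node.is_tip and not getattr(node, "label", None):
            node.label = f"N{i}"
        i += 1


def species_node_id(node: Node) -> str:
    return node.label if node.label else "?"


def mean_internal_support(clade: PhyloTree) -> float:
    """Mean bootstrap over internal nodes of the clade, excluding the stem
    (the clade root carries the stem's support) and the tips."""
    values = [n.support for n in clade.internal_nodes(exclude_root=True)
              if n.support is not None]
    missing = [n for n in clade.internal_nodes(exclude_root=True)
               if n.support is None]
    if missing:
        raise ValueError("clade has internal nodes without support values")
    if not values:
        return 100.0   # cherries have no internal edges to doubt
    return sum(values) / len(values)


def extract_supported_clades(tree: PhyloTree, rule: CladeExtractionRule,
                             taxa: TaxonMap) -> list[PhyloTree]:
    """Maximal well-supported clades whose tips all belong to the rule's taxa.

    Unrooted input is first oriented on a tip outside the rule's member set
    (an outgroup to the clade must exist).  A clade qualifies when it has at
    least ``min_taxa_present`` distinct member taxa and mean internal-node
    bootstrap support of at least ``min_mean_support``.
    """
    outside = sorted(t.label for t in tree.tips()
                     if taxa.taxon_of(t.label) not in rule.members)
    if not outside:
        return []
    # deterministic, rooting-invariant orientation on an outside tip
    work = reroot(tree, tree.find_tip(outside[0]))

    clades: list[PhyloTree] = []

    def walk(node: Node) -> None:
        labels = node.tip_labels()
        node_taxa = {taxa.taxon_of(l) for l in labels}
        if node_taxa <= rule.members:
            if len(node_taxa) >= rule.min_taxa_present:
                clade = extract_subtree(work, node)
                if mean_internal_support(clade) >= rule.min_mean_support:
                    clades.append(clade)
            return  # maximal member-only clade: do not descend
        for c in node.children:
            walk(c)

    walk(work.root)
    return clades


def detect_duplications(clade: PhyloTree, taxa: TaxonMap,
                        min_shared: int = 2) -> list[Node]:
    """Nodes whose child subtrees share at least ``min_shared`` taxa.

    Requiring two shared taxa ignores within-taxon (terminal) duplications,
    which are indistinguishable from assembly isoforms after tip masking.
    """
    out = []
    for node in clade.root.iter_preorder():
        if len(node.children) < 2:
            continue
        sets = [{taxa.taxon_of(l) for l in c.tip_labels()}
                for c in node.children]
        shared = set()
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                shared |= sets[i] & sets[j]
        if len(shared) >= min_shared:
            out.append(node)
    return out


def map_duplication(clade: PhyloTree, dup_node: Node, species_tree: PhyloTree,
                    taxa: TaxonMap, homolog_id: str = "",
                    clade_serial: int = 0) -> DuplicationRecord:
    """Map one duplication node to the species tree.

    The target is the MRCA of all taxa below the duplication node; with
    missing taxa or gene/species conflict this is the containing (possibly
    deeper) species node.
    """
    union = frozenset(taxa.taxon_of(l) for l in dup_node.tip_labels())
    species_taxa = set(species_tree.tip_labels())
    unknown = union - species_taxa
    if unknown:
        raise KeyError(f"taxa absent from species tree: {sorted(unknown)}")
    sets = [{taxa.taxon_of(l) for l in c.tip_labels()}
            for c in dup_node.children]
    shared = set()
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            shared |= sets[i] & sets[j]
    target = mrca_taxa(species_tree, union, lambda lab: lab)
    return DuplicationRecord(homolog_id, clade_serial, union,
                             frozenset(shared), species_node_id(target))


def dedupe_nested(records: list[DuplicationRecord]) -> list[DuplicationRecord]:
    """At most one duplication per (extracted clade, species node)."""
    seen = set()
    out = []
    for r in records:
        key = (r.homolog_id, r.clade_serial, r.species_node_id)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# per-branch summaries
# ---------------------------------------------------------------------------

def _observable_nodes(clade_taxa: set[str], species_tree: PhyloTree
                      ) -> set[str]:
    """Species nodes at which this clade could reveal a duplication.

    A duplication at a species branch is observable only when the extracted
    clade samples at least two taxa from each child lineage of that branch
    (the shared-taxon rule needs two taxa below the duplication, and mapping
    to that node needs both sides represented).
    """
    out = set()
    for node in species_tree.root.iter_preorder():
        if node.is_tip or len(node.children) < 2:
            continue
        per_child = [len({t.label for t in c.tips()} & clade_taxa)
                     for c in node.children]
        if sorted(per_child, reverse=True)[1] >= 2 and max(per_child) >= 2:
            out.add(species_node_id(node))
    return out


def summarize_branches(records: list[DuplicationRecord],
                       clade_taxon_sets: dict[tuple[str, int], set[str]],
                       species_tree: PhyloTree,
                       ) -> dict[str, BranchSummary]:
    """Per-species-branch duplication proportions.

    ``clade_taxon_sets`` maps each extracted clade (homolog id, serial) to
    its taxon set; the denominator for a branch counts the clades for which
    a duplication at that branch would have been observable.
    """
    summary: dict[str, BranchSummary] = {
        species_node_id(n): BranchSummary()
        for n in species_tree.root.iter_preorder() if not n.is_tip}
    for clade_key, clade_taxa in clade_taxon_sets.items():
        for node_id in _observable_nodes(clade_taxa, species_tree):
            summary[node_id].n_informative += 1
    counted = {(r.homolog_id, r.clade_serial, r.species_node_id)
               for r in dedupe_nested(records)}
    for _, _, node_id in counted:
        if node_id in summary:
            summary[node_id].n_dup += 1
    return summary


def annotate_species_tree(species_tree: PhyloTree,
                          summary: dict[str, BranchSummary]) -> PhyloTree:
    """Copy of the species tree with duplication proportions as supports."""
    out = species_tree.copy()
    for node in out.root.iter_preorder():
        if node.is_tip:
            continue
        s = summary.get(species_node_id(node))
        node.support = (round(100 * s.proportion, 1)
                        if s and s.proportion is not None else None)
    return out


# ---------------------------------------------------------------------------
# gene-family expansion ranking
# ---------------------------------------------------------------------------

@dataclass
class ExpansionRow:
    clade_id: str
    n_tips: int
    n_taxa: int
    top_taxon: str
    top_count: int


def rank_expansion(clades: list[tuple[str, PhyloTree]], taxa: TaxonMap,
                   min_taxa: int = 5,
                   ) -> tuple[list[ExpansionRow], list[ExpansionRow]]:
    """Rank extracted clades by gene-family expansion.

    Returns two tables over clades with at least ``min_taxa`` taxa: table A
    sorted by the highest per-taxon tip count (lineage-specific expansion),
    table B by total tip count (family-wide expansion).
    """
    rows = []
    for clade_id, clade in clades:
        labels = clade.tip_labels()
        counts: dict[str, int] = {}
        for l in labels:
            t = taxa.taxon_of(l)
            counts[t] = counts.get(t, 0) + 1
        if len(counts) < min_taxa:
            continue
        top_taxon = max(sorted(counts), key=lambda t: counts[t])
        rows.append(ExpansionRow(clade_id, len(labels), len(counts),
                                 top_taxon, counts[top_taxon]))
    by_top = sorted(rows, key=lambda r: (-r.top_count, r.clade_id))
    by_total = sorted(rows, key=lambda r: (-r.n_tips, r.clade_id))
    return by_top, by_total


def expansion_tsv(rows: list[ExpansionRow]) -> str:
    lines = ["clade_id\tn_tips\tn_taxa\ttop_taxon\ttop_count"]
    lines += [f"{r.clade_id}\t{r.n_tips}\t{r.n_taxa}\t{r.top_taxon}\t{r.top_count}"
              for r in rows]
    return "\n".join(lines) + "\n"
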