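"""Woody-versus-herbaceous substitution-rate contrasts.

For each extracted gene clade containing a designated woody/herbaceous
sister pair, per-branch synonymous (dS) and nonsynonymous (dN) trees from an
external branch-model codon analysis are reduced to a signed contrast:

    L_W = stem_W + A(W),  L_H = stem_H + A(H),
    contrast = (max - min) / min,  positive iff L_H > L_W,

where A is the stepwise average of branch lengths from the tips to the
clade root: A(tip) = 0, A(node) = mean over children c of (len(c) + A(c)).
Contrasts beyond +/-10 in magnitude (and zero denominators) are excluded.
The per-comparison null of equal average rates is tested with an exact
two-sided sign test on the contrast signs; restricting to sister pairs with
equal tip counts controls the node-density artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .seqs import NT_UNAMBIGUOUS, Alignment, SeqRecord, TaxonMap
from .trees import Node, PhyloTree

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
STOP_CODONS = {c for c, a in GENETIC_CODE.items() if a == "*"}


@dataclass
class ContrastDefinition:
    """One woody/herbaceous sister-pair comparison."""

    label: str
    woody: set[str]
    herbaceous: set[str]

    def __post_init__(self):
        if not self.woody or not self.herbaceous:
            raise ValueError("both habit sets must be nonempty")
        if self.woody & self.herbaceous:
            raise ValueError("woody and herbaceous sets overlap")

    def validate(self, taxa: TaxonMap) -> None:
        for t in self.woody:
            if taxa.habit_of(t) != "W":
                raise ValueError(f"{t} is not flagged woody")
        for t in self.herbaceous:
            if taxa.habit_of(t) != "H":
                raise ValueError(f"{t} is not flagged herbaceous")


class RateTrees:
    """Per-branch dS and dN lengths on one shared gene-clade topology."""

    def __init__(self, ds_tree: PhyloTree, dn_tree: PhyloTree):
        if sorted(ds_tree.tip_labels()) != sorted(dn_tree.tip_labels()):
            raise ValueError("dS and dN trees have different tip sets")
        self.ds_tree = ds_tree
        self.dn_tree = dn_tree

    @classmethod
    def from_newicks(cls, ds_text: str, dn_text: str) -> "RateTrees":
        from .trees import read_newick
        return cls(read_newick(ds_text), read_newick(dn_text))

    def tree(self, metric: str) -> PhyloTree:
        return self.ds_tree if metric == "dS" else self.dn_tree


@dataclass
class SisterPairContrast:
    clade_id: str
    label: str
    ds_contrast: float | None
    dn_contrast: float | None
    woody_tips: int
    herb_tips: int
    included: bool


# ---------------------------------------------------------------------------
# codon alignment preparation
# ---------------------------------------------------------------------------

def back_translate(protein_aln: Alignment, cds: dict[str, str]) -> Alignment:
    """Thread unaligned CDS onto a protein alignment, codon per residue.

    Each amino acid is replaced by its source codon (cross-checked against
    the standard genetic code); gaps become ``---``.  A terminal stop codon
    on the CDS is tolerated and dropped.
    """
    rows = []
    for r in protein_aln.rows:
        try:
            nt = cds[r.id].upper().replace("U", "T")
        except KeyError:
            raise KeyError(f"no CDS for {r.id!r}") from None
        aa_len = sum(1 for c in r.residues if c != "-")
        if len(nt) == 3 * (aa_len + 1) and nt[-3:] in STOP_CODONS:
            nt = nt[:-3]
        if len(nt) != 3 * aa_len:
            raise ValueError(
                f"{r.id}: CDS length {len(nt)} != 3 x {aa_len} residues")
        out = []
        k = 0
        for pos, aa in enumerate(r.residues):
            if aa == "-":
                out.append("---")
                continue
            codon = nt[3 * k:3 * k + 3]
            k += 1
            translated = GENETIC_CODE.get(codon)
            if translated is not None and aa not in ("X", "*") \
                    and translated != "*" and translated != aa.upper():
                raise ValueError(
                    f"{r.id} position {pos + 1}: codon {codon} encodes "
                    f"{translated}, alignment has {aa}")
            out.append(codon)
        rows.append(SeqRecord(r.id, "".join(out), r.taxon))
    return Alignment(rows, "codon")


def trim_codon_columns(codon_aln: Alignment,
                       min_unambiguous: float = 0.2) -> Alignment:
    """Drop codon columns with too few unambiguous codons.

    A codon is unambiguous when all three positions are in {A,C,G,T}; codon
    columns where the unambiguous fraction falls below ``min_unambiguous``
    are removed whole.
    """
    if codon_aln.n_cols % 3:
        raise ValueError("alignment width not divisible by 3")
    n = codon_aln.n_rows
    keep = []
    for j in range(0, codon_aln.n_cols, 3):
        good = sum(1 for r in codon_aln.rows
                   if set(r.residues[j:j + 3]) <= NT_UNAMBIGUOUS)
        if good / n >= min_unambiguous:
            keep.append(j)
    rows = [SeqRecord(r.id, "".join(r.residues[j:j + 3] for j in keep), r.taxon)
            for r in codon_aln.rows]
    return Alignment(rows, "codon")


# ---------------------------------------------------------------------------
# branch-model labeling (input preparation for external codon analysis)
# ---------------------------------------------------------------------------

@dataclass
class BranchModelJob:
    """Labeled tree plus run configuration for a branch-model codon fit."""

    clade_id: str
    label: str
    newick: str               # woody clade marked #1, herbaceous #2
    pair_node_tips: tuple[str, ...]
    config: dict = field(default_factory=lambda: {
        "model": 2, "NSsites": 0, "CodonFreq": "F3x4"})


def find_sister_pairs(clade: PhyloTree, defn: ContrastDefinition,
                      taxa: TaxonMap) -> list[Node]:
    """Nodes whose two children split cleanly into the definition's woody
    and herbaceous taxon sets (at least one tip on each side)."""
    pairs = []
    for node in clade.root.iter_preorder():
        if len(node.children) != 2:
            continue
        a, b = node.children
        ta = {taxa.taxon_of(l) for l in a.tip_labels()}
        tb = {taxa.taxon_of(l) for l in b.tip_labels()}
        for w_side, h_side in ((ta, tb), (tb, ta)):
            if w_side and h_side and w_side <= defn.woody \
                    and h_side <= defn.herbaceous:
                pairs.append(node)
                break
    return pairs


def label_branch_model(clade: PhyloTree, defn: ContrastDefinition,
                       taxa: TaxonMap, clade_id: str = "",
                       ) -> list[BranchModelJob]:
    """Emit branch-model run stubs for every candidate sister pair.

    The woody subtree is marked ``#1``, its herbaceous sister ``#2``, and the
    rest of the clade is left as background.  Clades without a valid sister
    pair yield an empty list (skipped with reason upstream).
    """
    jobs = []
    for serial, node in enumerate(find_sister_pairs(clade, defn, taxa)):
        a, b = node.children
        ta = {taxa.taxon_of(l) for l in a.tip_labels()}
        woody_child = a if ta <= defn.woody else b
        herb_child = b if woody_child is a else a
        marked = clade.copy()
        # re-find the pair in the copy by tip sets
        text = _newick_with_marks(marked, set(woody_child.tip_labels()),
                                  set(herb_child.tip_labels()))
        jobs.append(BranchModelJob(clade_id, defn.label, text,
                                   tuple(sorted(node.tip_labels()))))
    return jobs


def _newick_with_marks(tree: PhyloTree, woody_tips: set[str],
                       herb_tips: set[str]) -> str:
    def render(node: Node) -> str:
        tips = set(node.tip_labels())
        if node.is_tip:
            out = node.label or ""
        else:
            out = "(" + ",".join(render(c) for c in node.children) + ")"
        if tips == woody_tips:
            out += "#1"
        elif tips == herb_tips:
            out += "#2"
        if node.length is not None:
            out += f":{node.length:.6g}"
        return out

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def stepwise_average(node: Node) -> float:
    """Stepwise average of branch lengths from the tips up to ``node``.

    A(tip) = 0; A(node) = mean over children c of (length(c) + A(c)).
    Unlike an arithmetic mean over tip path lengths, every child lineage
    contributes equally regardless of how many tips it carries.
    """
    if node.is_tip:
        return 0.0
    return sum((c.length or 0.0) + stepwise_average(c)
               for c in node.children) / len(node.children)


def _lineage_length(node: Node, include_stem: bool) -> float:
    stem = (node.length or 0.0) if include_stem else 0.0
    return stem + stepwise_average(node)


def compute_contrast(rate_trees: RateTrees, pair_tips: set[str],
                     defn: ContrastDefinition, taxa: TaxonMap,
                     clade_id: str = "", include_stem: bool = True,
                     exclude_abs: float = 10.0) -> SisterPairContrast:
    """Signed (max-min)/min rate contrast for one sister pair.

    ``pair_tips`` identifies the sister-pair node by its tip set.  The stem
    branch of each sister clade is included in its lineage average by
    default (``include_stem=False`` gives the alternative reading).  The
    contrast is positive when the herbaceous lineage is longer; values with
    magnitude above ``exclude_abs`` or a zero denominator are flagged
    excluded.
    """
    values: dict[str, float | None] = {}
    woody_tips = herb_tips = 0
    included = True
    for metric in ("dS", "dN"):
        tree = rate_trees.tree(metric)
        node = _node_by_tipset(tree, pair_tips)
        a, b = node.children
        ta = {taxa.taxon_of(l) for l in a.tip_labels()}
        woody_child = a if ta <= defn.woody else b
        herb_child = b if woody_child is a else a
        woody_tips = len(woody_child.tip_labels())
        herb_tips = len(herb_child.tip_labels())
        lw = _lineage_length(woody_child, include_stem)
        lh = _lineage_length(herb_child, include_stem)
        lo, hi = min(lw, lh), max(lw, lh)
        if lo == 0:
            values[metric] = None
            included = False
            continue
        c = (hi - lo) / lo
        c = c if lh > lw else -c
        values[metric] = c
        if abs(c) > exclude_abs:
            included = False
    return SisterPairContrast(clade_id, defn.label, values["dS"],
                              values["dN"], woody_tips, herb_tips, included)


def _node_by_tipset(tree: PhyloTree, tips: set[str]) -> Node:
    for node in tree.root.iter_preorder():
        if set(node.tip_labels()) == tips:
            if len(node.children) != 2:
                raise ValueError("sister-pair node is not bifurcating")
            return node
    raise KeyError(f"no node with tip set {sorted(tips)}")


def sign_test(n_pos: int, n_neg: int) -> float:
    """Exact two-sided sign test at success probability 1/2.

    p = 2 * min(tail probabilities), capped at 1; for p = 1/2 this equals
    the minimum-likelihood two-sided convention.  Ties must be excluded
    upstream.  ``n_pos + n_neg == 0`` raises (p undefined).
    """
    n = n_pos + n_neg
    if n == 0:
        raise ValueError("sign test undefined with zero informative pairs")
    lower = stats.binom.cdf(min(n_pos, n_neg), n, 0.5)
    return float(min(1.0, 2.0 * lower))


# ---------------------------------------------------------------------------
# the full study
# ---------------------------------------------------------------------------

@dataclass
class ContrastTableRow:
    label: str
    metric: str
    n_gt: int          # woody > herbaceous (negative contrasts)
    n_lt: int          # woody < herbaceous (positive contrasts)
    p_value: float | None
    median_contrast: float | None
    n_analyzed: int


@dataclass
class ContrastReport:
    seed: int
    n_sub: int
    all_pairs: list[ContrastTableRow]
    equal_tips: list[ContrastTableRow]
    contrasts: list[SisterPairContrast]


def _table(contrasts: list[SisterPairContrast], label: str,
           ) -> list[ContrastTableRow]:
    rows = []
    for metric, attr in (("dS", "ds_contrast"), ("dN", "dn_contrast")):
        vals = [getattr(c, attr) for c in contrasts
                if c.included and getattr(c, attr) is not None
                and getattr(c, attr) != 0]
        n_pos = sum(1 for v in vals if v > 0)
        n_neg = sum(1 for v in vals if v < 0)
        p = sign_test(n_pos, n_neg) if vals else None
        med = float(np.median(vals)) if vals else None
        rows.append(ContrastTableRow(label, metric, n_neg, n_pos, p, med,
                                     len(vals)))
    return rows


def run_contrast_study(clades: list[tuple[str, RateTrees]],
                       defns: list[ContrastDefinition], taxa: TaxonMap,
                       n_sub: int = 3000, seed: int = 0,
                       include_stem: bool = True,
                       exclude_abs: float = 10.0) -> ContrastReport:
    """Compute the full contrast report over a set of extracted gene clades.

    For every definition, every clade containing a valid sister pair
    contributes one contrast (the first pair, in deterministic preorder,
    when several exist); a seeded random subset of at most ``n_sub`` clades
    is analyzed per definition.  The report carries a table over all
    included contrasts and a second table restricted to pairs where the
    woody and herbaceous lineages have the same number of tips.
    """
    rng = np.random.default_rng(seed)
    all_rows, eq_rows, kept = [], [], []
    for defn in defns:
        per_defn: list[SisterPairContrast] = []
        for clade_id, rt in clades:
            pairs = find_sister_pairs(rt.ds_tree, defn, taxa)
            if not pairs:
                continue
            tipset = set(pairs[0].tip_labels())
            per_defn.append(compute_contrast(rt, tipset, defn, taxa, clade_id,
                                             include_stem, exclude_abs))
        if len(per_defn) > n_sub:
            idx = sorted(rng.choice(len(per_defn), size=n_sub, replace=False))
            per_defn = [per_defn[i] for i in idx]
        kept.extend(per_defn)
        included = [c for c in per_defn if c.included]
        all_rows.extend(_table(included, defn.label))
        eq_rows.extend(_table([c for c in included
                               if c.woody_tips == c.herb_tips], defn.label))
    return ContrastReport(seed, n_sub, all_rows, eq_rows, kept)


def report_tsv(rows: list[ContrastTableRow], seed: int | None = None) -> str:
    lines = []
    if seed is not None:
        lines.append(f"# subsampling seed: {seed}")
    lines.append("contrast\tmetric\tn_W_gt_H\tn_W_lt_H\tp_sign_test\t"
                 "median_contrast\tn")
    for r in rows:
        p = "NA" if r.p_value is None else f"{r.p_value:.3g}"
        m = "NA" if r.median_contrast is None else f"{r.median_contrast:.3f}"
        lines.append(f"{r.label}\t{r.metric}\t{r.n_gt}\t{r.n_lt}\t{p}\t{m}\t"
                     f"{r.n_analyzed}")
    return "\n".join(lines) + "\n"
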