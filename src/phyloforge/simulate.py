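"""Synthetic gene families with known ground truth.

Gene lineages evolve along a known species tree under a lineage-wise
birth-death (duplication/loss) process; whole-genome duplications are
applied instantaneously at the start of a designated species branch, with
the extra copy retained at a stated probability.  Branch rates carry
lognormal noise and a habit-linked multiplier (herbaceous lineages faster,
matching the up-to-threefold contrast the toolkit is built to measure).
Assembly isoforms (near-identical same-taxon sister tips) and spuriously
long contaminant branches can be injected, and codon sequence pairs are
sampled to match target synonymous divergences so Ks estimation is testable
end to end.  Every stochastic choice derives from a single seed; the truth
record lists every duplication with its species branch, plus injected
isoform and contaminant tips.
"""

from __future__ import annotations

import json
import math
import os
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .contrasts import GENETIC_CODE, STOP_CODONS, ContrastDefinition, RateTrees
from .dupmap import label_species_nodes
from .ks import _syn_fraction
from .seqs import SeqRecord, TaxonMap, write_clade_sets, write_fasta
from .trees import Node, PhyloTree, mrca, read_newick, write_newick

# ---------------------------------------------------------------------------
# the default study system: a desk-scale species tree
# ---------------------------------------------------------------------------

#: 16 ingroup taxa (8 woody / 8 herbaceous), 7 non-root outgroup taxa in two
#: named outgroup lineages, plus the root taxon AQC used for rooting.
#: The clade carrying the default whole-genome duplication (the "B" clade)
#: is drawn deep enough that a tip-to-duplication synonymous path is ~0.3,
#: putting within-taxon paralog pairs near Ks 0.6 in woody lineages.
DEFAULT_SPECIES_NEWICK = (
    "(AQC:0.3,"
    "((AST1:0.1,(AST2:0.08,AST3:0.08):0.05):0.12,"
    "((((ROS1:0.09,ROS2:0.09):0.05,(ROS3:0.09,ROS4:0.09):0.05):0.07,"
    "(((((CW1:0.06,CW2:0.06):0.04,CW3:0.08):0.05,"
    "((CH1:0.06,CH2:0.06):0.04,CH3:0.08):0.05):0.06,"
    "((BW1:0.08,BW2:0.08):0.07,(BH1:0.08,BH2:0.08):0.07):0.15):0.04,"
    "((SW1:0.12,SH1:0.12):0.06,"
    "((XH1:0.07,XW1:0.07):0.05,(XH2:0.07,XW2:0.07):0.05):0.06):0.04"
    "):0.06):0.04):0.05"
    "):0.05);"
)

INGROUP = {"CW1", "CW2", "CW3", "CH1", "CH2", "CH3",
           "BW1", "BW2", "BH1", "BH2", "SW1", "SH1",
           "XH1", "XW1", "XH2", "XW2"}
OUTGROUP = {"AQC", "AST1", "AST2", "AST3", "ROS1", "ROS2", "ROS3", "ROS4"}
HABIT = {t: ("W" if "W" in t else "H") for t in INGROUP}

#: clade carrying the default WGD (retention 0.3 on its stem branch)
WGD_CLADE = frozenset({"BW1", "BW2", "BH1", "BH2"})


def default_species_tree() -> tuple[PhyloTree, TaxonMap]:
    tree = read_newick(DEFAULT_SPECIES_NEWICK)
    tree.rooted = True
    label_species_nodes(tree)
    taxa = TaxonMap(
        ingroup=set(INGROUP), outgroup=set(OUTGROUP), habit=dict(HABIT),
        clades={"ingroup": set(INGROUP),
                "asterids": {"AST1", "AST2", "AST3"},
                "rosids": {"ROS1", "ROS2", "ROS3", "ROS4"}},
        root_taxon="AQC")
    return tree, taxa


def default_contrast_definitions() -> list[ContrastDefinition]:
    return [
        ContrastDefinition("A", {"CW1", "CW2", "CW3"}, {"CH1", "CH2", "CH3"}),
        ContrastDefinition("B", {"BW1", "BW2"}, {"BH1", "BH2"}),
        ContrastDefinition("C", {"SW1"}, {"SH1"}),
    ]


# ---------------------------------------------------------------------------
# configuration and truth records
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    species_tree: PhyloTree = None
    taxa: TaxonMap = None
    n_families: int = 100
    dup_rate: float = 0.05           # lambda, per unit branch length
    loss_rate: float = 0.05          # mu
    wgd_events: list[tuple[frozenset, float]] = field(
        default_factory=lambda: [(WGD_CLADE, 0.3)])
    ds_herb_multiplier: float = 3.0  # herbaceous lineages up to 3x faster
    dn_herb_multiplier: float = 3.0
    dn_ds_ratio: float = 0.3
    noise_sigma: float = 0.25        # lognormal sigma on branch rates
    isoform_rate: float = 0.0        # per-tip probability
    contaminant_rate: float = 0.0    # per-family probability
    support_range: tuple[float, float] = (90.0, 100.0)
    seed: int = 0

    def __post_init__(self):
        if self.species_tree is None or self.taxa is None:
            tree, taxa = default_species_tree()
            self.species_tree = self.species_tree or tree
            self.taxa = self.taxa or taxa
        label_species_nodes(self.species_tree)
        for rate in (self.dup_rate, self.loss_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        for _, retention in self.wgd_events:
            if not 0 <= retention <= 1:
                raise ValueError("retention must be in [0, 1]")

    def wgd_branch_ids(self) -> list[str]:
        """Species node id below each WGD branch (where duplications map)."""
        out = []
        for clade_taxa, _ in self.wgd_events:
            out.append(mrca(self.species_tree, clade_taxa).label)
        return out


@dataclass
class DuplicationTruth:
    species_branch: str     # id of the species node below the branch
    is_wgd: bool


@dataclass
class FamilyTruth:
    family_id: str
    duplications: list[DuplicationTruth] = field(default_factory=list)
    isoforms: list[str] = field(default_factory=list)
    contaminants: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {"family_id": self.family_id,
                "duplications": [{"species_branch": d.species_branch,
                                  "is_wgd": d.is_wgd}
                                 for d in self.duplications],
                "isoforms": self.isoforms,
                "contaminants": self.contaminants}


@dataclass
class Family:
    tree: PhyloTree | None      # None when the family went extinct
    truth: FamilyTruth


# ---------------------------------------------------------------------------
# gene-family simulation
# ---------------------------------------------------------------------------

def simulate_family(config: SimulationConfig, family_index: int,
                    rng: np.random.Generator) -> Family:
    """Evolve one gene family along the species tree.

    Returns the gene tree (tips named ``taxon@f<index>c<copy>``) plus the
    truth record; ``tree`` is ``None`` when every lineage was lost.
    """
    truth = FamilyTruth(f"fam{family_index}")
    counters: dict[str, int] = defaultdict(int)
    lam, mu = config.dup_rate, config.loss_rate
    total = lam + mu
    wgd_by_node: dict[str, float] = {}
    for clade_taxa, retention in config.wgd_events:
        wgd_by_node[mrca(config.species_tree, clade_taxa).label] = retention

    def at_node(sp_node: Node) -> Node | None:
        if sp_node.is_tip:
            taxon = sp_node.label
            counters[taxon] += 1
            return Node(label=f"{taxon}@f{family_index}c{counters[taxon]}",
                        length=0.0)
        kids = [enter_edge(c) for c in sp_node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node = Node(length=0.0)
        for k in kids:
            node.add_child(k)
        return node

    def enter_edge(sp_child: Node) -> Node | None:
        retention = wgd_by_node.get(sp_child.label)
        if retention and rng.random() < retention:
            a = walk(sp_child, sp_child.length or 0.0)
            b = walk(sp_child, sp_child.length or 0.0)
            if a is not None and b is not None:
                node = Node(length=0.0)
                node.add_child(a)
                node.add_child(b)
                truth.duplications.append(
                    DuplicationTruth(sp_child.label, is_wgd=True))
                return node
            return a if a is not None else b
        return walk(sp_child, sp_child.length or 0.0)

    def walk(sp_child: Node, remaining: float) -> Node | None:
        while True:
            t = rng.exponential(1.0 / total) if total > 0 else math.inf
            if t >= remaining:
                node = at_node(sp_child)
                if node is not None:
                    node.length += remaining
                return node
            if rng.random() < mu / total:
                return None                      # loss
            a = walk(sp_child, remaining - t)
            b = walk(sp_child, remaining - t)
            if a is not None and b is not None:
                node = Node(length=t)
                node.add_child(a)
                node.add_child(b)
                truth.duplications.append(
                    DuplicationTruth(sp_child.label, is_wgd=False))
                return node
            survivor = a if a is not None else b
            if survivor is None:
                return None
            survivor.length += t
            return survivor

    root = at_node(config.species_tree.root)
    if root is None or root.is_tip:
        return Family(None, truth)       # extinct or single survivor: unusable
    root.length = None
    tree = PhyloTree(root, rooted=False)

    _inject_artifacts(tree, config, family_index, rng, truth)
    lo, hi = config.support_range
    for node in tree.internal_nodes():
        node.support = float(np.round(rng.uniform(lo, hi), 1))
    tree.root.support = None
    return Family(tree, truth)


def _inject_artifacts(tree: PhyloTree, config: SimulationConfig,
                      family_index: int, rng: np.random.Generator,
                      truth: FamilyTruth) -> None:
    if config.isoform_rate > 0:
        for tip in list(tree.tips()):
            if rng.random() >= config.isoform_rate or tip.length is None:
                continue
            delta = min(0.005, tip.length / 2)
            fork = Node(length=tip.length - delta)
            parent = tip.parent
            idx = parent.children.index(tip)
            parent.children[idx] = fork
            fork.parent = parent
            tip.parent = None
            tip.length = delta
            fork.add_child(tip)
            iso = Node(label=tip.label + ".iso",
                       length=delta * rng.uniform(0.5, 1.5))
            fork.add_child(iso)
            truth.isoforms.append(iso.label)
    if config.contaminant_rate > 0 and rng.random() < config.contaminant_rate:
        internals = [n for n in tree.internal_nodes(exclude_root=True)]
        if internals:
            host = internals[rng.integers(len(internals))]
            fork = Node(length=(host.length or 0.0) / 2)
            parent = host.parent
            idx = parent.children.index(host)
            parent.children[idx] = fork
            fork.parent = parent
            host.parent = None
            host.length = (host.length or 0.0) / 2
            fork.add_child(host)
            contaminant = Node(label=f"CTM@f{family_index}c1", length=3.0)
            fork.add_child(contaminant)
            truth.contaminants.append(contaminant.label)


def assign_branch_lengths(gene_tree: PhyloTree, config: SimulationConfig,
                          rng: np.random.Generator) -> RateTrees:
    """Draw per-branch dS and dN lengths for a gene (sub)tree.

    Each branch's base length (time) is scaled by unit-mean lognormal noise;
    branches whose descendant tips are all herbaceous additionally get the
    habit multiplier.  dN uses its own noise draw and the dN/dS ratio.
    """
    ds_tree = gene_tree.copy()
    dn_tree = gene_tree.copy()
    taxa = config.taxa
    sigma = config.noise_sigma
    mean_adj = -sigma * sigma / 2.0    # unit-mean lognormal

    def all_herb(node: Node) -> bool:
        labels = node.tip_labels()
        return bool(labels) and all(
            taxa.habit_of(taxa.taxon_of(l)) == "H" for l in labels)

    for ds_node, dn_node in zip(ds_tree.root.iter_preorder(),
                                dn_tree.root.iter_preorder()):
        if ds_node.length is None:
            continue
        herb = all_herb(ds_node)
        ds_mult = config.ds_herb_multiplier if herb else 1.0
        dn_mult = config.dn_herb_multiplier if herb else 1.0
        ds_node.length = float(ds_node.length * ds_mult
                               * rng.lognormal(mean_adj, sigma))
        dn_node.length = float(dn_node.length * config.dn_ds_ratio * dn_mult
                               * rng.lognormal(mean_adj, sigma))
    return RateTrees(ds_tree, dn_tree)


def simulate_bundle(config: SimulationConfig) -> list[Family]:
    """Simulate ``config.n_families`` families from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    return [simulate_family(config, i, rng) for i in range(config.n_families)]


# ---------------------------------------------------------------------------
# codon-sequence sampling at target synonymous divergence
# ---------------------------------------------------------------------------

_SENSE_CODONS = sorted(set(GENETIC_CODE) - STOP_CODONS)


def random_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    """Uniformly random sense codons (no stops)."""
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return [_SENSE_CODONS[i] for i in idx]


def evolve_cds(codons: list[str], target_syn_div: float,
               rng: np.random.Generator) -> tuple[list[str], float]:
    """Evolve a codon sequence under independent-site, equal-rate (JC-like)
    nucleotide substitution until the accumulated synonymous divergence
    (synonymous substitutions per synonymous site, sites recounted as the
    sequence drifts) reaches ``target_syn_div``.

    Proposals are uniform over (codon, position, alternative) triples; every
    change is applied except those creating a stop codon, so nonsynonymous
    divergence accrues at the rate the site structure dictates.  Returns the
    evolved copy and the realized synonymous divergence.
    """
    work = list(codons)
    site_counts = [_syn_fraction(c) for c in work]
    total_sites = sum(site_counts)
    accumulated = 0.0
    n = len(work)
    while accumulated < target_syn_div:
        i = int(rng.integers(n))
        pos = int(rng.integers(3))
        alt = "ACGT"[rng.integers(4)]
        codon = work[i]
        if alt == codon[pos]:
            continue
        mutant = codon[:pos] + alt + codon[pos + 1:]
        if GENETIC_CODE[mutant] == "*":
            continue
        if GENETIC_CODE[mutant] == GENETIC_CODE[codon]:
            accumulated += 1.0 / total_sites
        work[i] = mutant
        total_sites += _syn_fraction(mutant) - site_counts[i]
        site_counts[i] = _syn_fraction(mutant)
    return work, accumulated


def make_paralog_pair(n_codons: int, target_ks: float,
                      rng: np.random.Generator
                      ) -> tuple[str, str, float]:
    """A CDS pair at (approximately) the requested synonymous divergence.

    Both copies descend from one random ancestor, each absorbing half the
    target; returns (cds1, cds2, realized total divergence).
    """
    ancestor = random_cds(n_codons, rng)
    c1, d1 = evolve_cds(ancestor, target_ks / 2.0, rng)
    c2, d2 = evolve_cds(ancestor, target_ks / 2.0, rng)
    return "".join(c1), "".join(c2), d1 + d2


def translate_cds(cds: str) -> str:
    return "".join(GENETIC_CODE[cds[i:i + 3]] for i in range(0, len(cds), 3))


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------

def paralog_pair_targets(family: Family, rate_trees: RateTrees,
                         taxa: TaxonMap) -> dict[str, list[tuple[str, str, float]]]:
    """Per-taxon paralog tip pairs and their dS path lengths.

    For every taxon with exactly two copies in the family, the target Ks of
    a sequence pair is the dS path length between the two tips.
    """
    tree = rate_trees.ds_tree
    by_taxon: dict[str, list[str]] = defaultdict(list)
    for label in tree.tip_labels():
        by_taxon[taxa.taxon_of(label)].append(label)
    out: dict[str, list[tuple[str, str, float]]] = defaultdict(list)
    for taxon, labels in by_taxon.items():
        if len(labels) != 2:
            continue
        a, b = sorted(labels)
        anc = mrca(tree, [a, b])
        dist = 0.0
        for lab in (a, b):
            node = tree.find_tip(lab)
            while node is not anc:
                dist += node.length or 0.0
                node = node.parent
        out[taxon].append((a, b, dist))
    return dict(out)


def emit_fixtures(config: SimulationConfig, outdir,
                  with_sequences: bool = False, n_codons: int = 300) -> dict:
    """Write a byte-reproducible fixture bundle and return its manifest.

    Contents: species tree, taxon map, clade sets, contrast definitions,
    per-family gene-tree newicks, a truth JSON, and (optionally) per-taxon
    peptide/CDS FASTA plus self-hit tables whose paralog pairs match the
    families' dS paths.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    families = [simulate_family(config, i, rng)
                for i in range(config.n_families)]

    with open(os.path.join(outdir, "species_tree.nwk"), "w") as fh:
        fh.write(write_newick(config.species_tree) + "\n")
    with open(os.path.join(outdir, "taxon_map.tsv"), "w") as fh:
        fh.write(config.taxa.to_tsv())
    with open(os.path.join(outdir, "clade_sets.tsv"), "w") as fh:
        fh.write(write_clade_sets(config.taxa.clades))
    with open(os.path.join(outdir, "contrast_defs.tsv"), "w") as fh:
        fh.write("label\twoody\therbaceous\n")
        for d in default_contrast_definitions():
            fh.write(f"{d.label}\t{','.join(sorted(d.woody))}\t"
                     f"{','.join(sorted(d.herbaceous))}\n")

    tree_dir = os.path.join(outdir, "trees")
    os.makedirs(tree_dir, exist_ok=True)
    truth = []
    n_written = 0
    for fam in families:
        truth.append(fam.truth.to_json())
        if fam.tree is None:
            continue
        with open(os.path.join(tree_dir, f"{fam.truth.family_id}.nwk"),
                  "w") as fh:
            fh.write(write_newick(fam.tree) + "\n")
        n_written += 1

    manifest = {"seed": config.seed, "n_families": config.n_families,
                "n_surviving": n_written,
                "wgd_branches": config.wgd_branch_ids()}

    if with_sequences:
        seq_rng = np.random.default_rng(config.seed + 1)
        peptides: dict[str, list[SeqRecord]] = defaultdict(list)
        cds_records: dict[str, list[SeqRecord]] = defaultdict(list)
        hit_rows: dict[str, list[str]] = defaultdict(list)
        for fam in families:
            if fam.tree is None:
                continue
            rt = assign_branch_lengths(fam.tree, config, seq_rng)
            for taxon, pairs in sorted(
                    paralog_pair_targets(fam, rt, config.taxa).items()):
                for a, b, target in pairs:
                    cds1, cds2, _ = make_paralog_pair(n_codons, target, seq_rng)
                    pep1, pep2 = translate_cds(cds1), translate_cds(cds2)
                    peptides[taxon] += [SeqRecord(a, pep1), SeqRecord(b, pep2)]
                    cds_records[taxon] += [SeqRecord(a, cds1),
                                           SeqRecord(b, cds2)]
                    ident = sum(x == y for x, y in zip(pep1, pep2))
                    pid = 100.0 * ident / n_codons
                    hit_rows[taxon].append(
                        f"{a}\t{b}\t{pid:.2f}\t{n_codons}\t"
                        f"{n_codons - ident}\t0\t1\t{n_codons}\t1\t{n_codons}"
                        f"\t1e-50\t500\t{n_codons}\t{n_codons}")
        seq_dir = os.path.join(outdir, "sequences")
        os.makedirs(seq_dir, exist_ok=True)
        for taxon in sorted(peptides):
            write_fasta(peptides[taxon],
                        os.path.join(seq_dir, f"{taxon}.pep.fa"))
            write_fasta(cds_records[taxon],
                        os.path.join(seq_dir, f"{taxon}.cds.fa"))
            with open(os.path.join(seq_dir, f"{taxon}.hits.tsv"), "w") as fh:
                fh.write("\n".join(hit_rows[taxon]) + "\n")
        manifest["sequence_taxa"] = sorted(peptides)

    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump({"manifest": manifest, "families": truth}, fh, indent=1)
    return manifest
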