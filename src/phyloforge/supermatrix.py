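"""Supermatrix construction: ortholog filtering, partitioned concatenation,
occupancy statistics, and gene-wise jackknife resampling.

Occupancy definitions (stated in output headers, since usage varies across
studies): gene occupancy is the fraction of filled (taxon x gene) cells;
character occupancy is the fraction of non-gap characters over the whole
matrix.  Missing taxa are padded with ``-``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .orthology import OrthologGroup
from .seqs import GAP, Alignment, SeqRecord


@dataclass
class Partition:
    gene_id: str
    start: int   # 1-based inclusive
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class Supermatrix:
    alignment: Alignment
    partitions: list[Partition]
    gene_occupancy: float
    character_occupancy: float
    per_taxon_gene_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def n_taxa(self) -> int:
        return self.alignment.n_rows

    @property
    def n_cols(self) -> int:
        return self.alignment.n_cols

    @property
    def n_genes(self) -> int:
        return len(self.partitions)

    def gene_alignment(self, gene_id: str) -> Alignment:
        """Recover one input gene: its columns, minus all-gap padding rows."""
        part = next(p for p in self.partitions if p.gene_id == gene_id)
        rows = []
        for r in self.alignment.rows:
            chunk = r.residues[part.start - 1:part.end]
            if any(c != GAP for c in chunk):
                rows.append(SeqRecord(r.id, chunk, r.taxon))
        return Alignment(rows, self.alignment.alphabet)


def filter_orthologs(groups: list[OrthologGroup], min_taxa: int,
                     min_cols: int) -> list[OrthologGroup]:
    """Keep groups with at least ``min_taxa`` taxa and ``min_cols`` columns."""
    return [g for g in groups if g.n_taxa >= min_taxa and g.n_cols >= min_cols]


def concatenate(groups: list[OrthologGroup]) -> Supermatrix:
    """Concatenate trimmed ortholog alignments into a partitioned supermatrix.

    Rows are keyed by taxon (each ortholog group has at most one sequence per
    taxon); taxa absent from a gene receive an all-gap block.
    """
    if not groups:
        raise ValueError("no ortholog groups to concatenate")
    taxa = sorted({r.taxon for g in groups for r in g.alignment.rows})
    index = {t: i for i, t in enumerate(taxa)}
    chunks: list[list[str]] = [[] for _ in taxa]
    partitions = []
    pos = 1
    filled = 0
    for g in groups:
        width = g.alignment.n_cols
        seen = set()
        block = [GAP * width] * len(taxa)
        for r in g.alignment.rows:
            if r.taxon in seen:
                raise ValueError(
                    f"duplicate taxon {r.taxon!r} in group {g.id}")
            seen.add(r.taxon)
            block[index[r.taxon]] = r.residues
        filled += len(seen)
        for i, b in enumerate(block):
            chunks[i].append(b)
        partitions.append(Partition(g.id, pos, pos + width - 1))
        pos += width
    rows = [SeqRecord(t, "".join(chunks[i]), t) for t, i in
            ((t, index[t]) for t in taxa)]
    aln = Alignment(rows, groups[0].alignment.alphabet)
    total_cells = len(taxa) * len(groups)
    gene_occ = filled / total_cells
    nongap = sum(1 for r in aln.rows for c in r.residues if c != GAP)
    char_occ = nongap / (len(taxa) * aln.n_cols)
    per_taxon = {}
    for t in taxa:
        n = sum(1 for g in groups
                if any(r.taxon == t for r in g.alignment.rows))
        per_taxon[t] = n / len(groups)
    return Supermatrix(aln, partitions, gene_occ, char_occ, per_taxon)


def jackknife_genes(matrix: Supermatrix, fraction: float, n_reps: int,
                    seed: int) -> list[Supermatrix]:
    """Gene-wise jackknife: resample whole partitions without replacement.

    Each replicate keeps ``round(fraction * n_genes)`` intact gene regions;
    replicates are reproducible from ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    k = round(fraction * matrix.n_genes)
    if k == 0:
        raise ValueError(
            f"fraction {fraction} of {matrix.n_genes} genes rounds to 0")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        chosen = sorted(rng.choice(matrix.n_genes, size=k, replace=False))
        parts = [matrix.partitions[i] for i in chosen]
        pseudo = []
        for p in parts:
            sub = matrix.gene_alignment(p.gene_id)
            pseudo.append(_AlignmentGroup(p.gene_id, sub))
        reps.append(concatenate(pseudo))
    return reps


class _AlignmentGroup:
    """Minimal stand-in exposing the OrthologGroup surface concatenate needs."""

    def __init__(self, gene_id: str, alignment: Alignment):
        self.id = gene_id
        self.alignment = alignment


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def to_phylip(matrix: Supermatrix) -> str:
    """Relaxed phylip with names padded to a common width."""
    width = max(len(r.id) for r in matrix.alignment.rows) + 2
    buf = io.StringIO()
    buf.write(f"{matrix.n_taxa} {matrix.n_cols}\n")
    for r in matrix.alignment.rows:
        buf.write(r.id.ljust(width) + r.residues + "\n")
    return buf.getvalue()


def partition_file(matrix: Supermatrix, model: str = "WAG") -> str:
    """RAxML-style partition file: ``WAG, gene = start-end`` per gene."""
    return "".join(f"{model}, {p.gene_id} = {p.start}-{p.end}\n"
                   for p in matrix.partitions)


def occupancy_table(matrix: Supermatrix) -> str:
    """Per-taxon gene-occupancy TSV (definitions in the header comment)."""
    lines = [
        "# gene occupancy = filled (taxon,gene) cells / (n_taxa * n_genes)",
        "# character occupancy = non-gap characters / (n_taxa * n_columns)",
        f"# matrix: {matrix.n_taxa} taxa, {matrix.n_genes} genes, "
        f"{matrix.n_cols} columns; gene occupancy "
        f"{matrix.gene_occupancy:.3f}, character occupancy "
        f"{matrix.character_occupancy:.3f}",
        "taxon\tgene_fraction",
    ]
    for t, f in sorted(matrix.per_taxon_gene_fraction.items()):
        lines.append(f"{t}\t{f:.4f}")
    return "\n".join(lines) + "\n"
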