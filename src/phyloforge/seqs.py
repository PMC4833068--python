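"""Sequence records, alignments, taxon metadata, and FASTA / TSV I/O.

Sequence ids encode their taxon as the substring before a configurable
delimiter (default ``"@"``), e.g. ``Beta_vulgaris@12345``.  Ambiguity
characters (``X``, ``*``, ``?``) count as gaps for column occupancy and for
per-sequence unambiguous-character counts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

GAP = "-"
#: characters treated as gaps/ambiguity for occupancy purposes
AMBIGUOUS = {"-", "?", "X", "x", "*", "."}
#: nucleotide-alphabet ambiguity set (codon alignments)
NT_UNAMBIGUOUS = {"A", "C", "G", "T"}

DEFAULT_DELIMITER = "@"


def taxon_of(seq_id: str, delimiter: str = DEFAULT_DELIMITER) -> str:
    """Taxon code = substring of the sequence id before the delimiter."""
    return seq_id.split(delimiter, 1)[0]


@dataclass
class SeqRecord:
    """A named sequence, optionally aligned (may contain gap characters)."""

    id: str
    residues: str
    taxon: str | None = None

    def __post_init__(self):
        if self.taxon is None:
            self.taxon = taxon_of(self.id)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_unambiguous(self) -> int:
        """Count of non-gap, non-ambiguity characters."""
        return sum(1 for c in self.residues if c not in AMBIGUOUS)

    def ungapped(self) -> str:
        return "".join(c for c in self.residues if c != GAP)


class Alignment:
    """An equal-row-length multiple sequence alignment.

    ``alphabet`` is ``"amino-acid"``, ``"nucleotide"`` or ``"codon"``
    (codon alignments must have a width divisible by 3).
    """

    def __init__(self, rows: Sequence[SeqRecord], alphabet: str = "amino-acid"):
        rows = list(rows)
        if rows:
            width = len(rows[0].residues)
            for r in rows:
                if len(r.residues) != width:
                    raise ValueError(
                        f"row {r.id!r} length {len(r.residues)} != {width}")
            if alphabet == "codon" and width % 3:
                raise ValueError(f"codon alignment width {width} not divisible by 3")
        self.rows = rows
        self.alphabet = alphabet

    # -- basic queries -----------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0].residues) if self.rows else 0

    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def taxa(self) -> set[str]:
        return {r.taxon for r in self.rows}

    def row(self, seq_id: str) -> SeqRecord:
        for r in self.rows:
            if r.id == seq_id:
                return r
        raise KeyError(f"no row {seq_id!r}")

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.rows)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = set(ids)
        return Alignment([r for r in self.rows if r.id in wanted], self.alphabet)

    def char_counts(self) -> dict[str, int]:
        """id -> number of unambiguous characters in this alignment."""
        return {r.id: r.n_unambiguous for r in self.rows}

    def __iter__(self):
        return iter(self.rows)


# ---------------------------------------------------------------------------
# taxon metadata
# ---------------------------------------------------------------------------

@dataclass
class TaxonMap:
    """Per-taxon metadata: ingroup/outgroup status, habit, named clade sets.

    ``habit`` is ``"W"`` (woody), ``"H"`` (herbaceous) or ``None``;
    ``clades`` maps a clade name (e.g. an ingroup or outgroup lineage) to the
    set of member taxa; ``root_taxon`` is the single outgroup taxon used for
    rooting homolog trees.
    """

    ingroup: set[str] = field(default_factory=set)
    outgroup: set[str] = field(default_factory=set)
    habit: dict[str, str] = field(default_factory=dict)
    clades: dict[str, set[str]] = field(default_factory=dict)
    root_taxon: str | None = None
    delimiter: str = DEFAULT_DELIMITER

    def __post_init__(self):
        if self.root_taxon is not None and self.root_taxon not in self.outgroup:
            raise ValueError("root taxon must be an outgroup taxon")

    def taxon_of(self, seq_id: str) -> str:
        return taxon_of(seq_id, self.delimiter)

    def is_ingroup(self, taxon: str) -> bool:
        return taxon in self.ingroup

    def n_ingroup_taxa(self, seq_ids: Iterable[str]) -> int:
        return len({self.taxon_of(s) for s in seq_ids} & self.ingroup)

    def habit_of(self, taxon: str) -> str | None:
        return self.habit.get(taxon)

    @property
    def all_taxa(self) -> set[str]:
        return self.ingroup | self.outgroup

    # -- TSV round-trip ----------------------------------------------------
    def to_tsv(self) -> str:
        lines = ["taxon\tgroup\thabit"]
        for t in sorted(self.all_taxa):
            group = "ingroup" if t in self.ingroup else "outgroup"
            if t == self.root_taxon:
                group = "root"
            lines.append(f"{t}\t{group}\t{self.habit.get(t) or 'NA'}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, clades: dict[str, set[str]] | None = None
                 ) -> "TaxonMap":
        ingroup, outgroup, habit = set(), set(), {}
        root_taxon = None
        for i, line in enumerate(text.strip().splitlines()):
            if i == 0 and line.lower().startswith("taxon"):
                continue
            taxon, group, hab = line.rstrip("\n").split("\t")[:3]
            if group == "ingroup":
                ingroup.add(taxon)
            else:
                outgroup.add(taxon)
                if group == "root":
                    root_taxon = taxon
            if hab in ("W", "H"):
                habit[taxon] = hab
        return cls(ingroup=ingroup, outgroup=outgroup, habit=habit,
                   clades=clades or {}, root_taxon=root_taxon)


def read_clade_sets(text: str) -> dict[str, set[str]]:
    """Clade-set definitions: ``name<TAB>taxon1,taxon2,...`` per line."""
    out: dict[str, set[str]] = {}
    for line in text.strip().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, members = line.split("\t", 1)
        out[name] = {m.strip() for m in members.replace(",", "\t").split()
                     if m.strip()}
    return out


def write_clade_sets(clades: dict[str, set[str]]) -> str:
    return "".join(f"{name}\t{','.join(sorted(members))}\n"
                   for name, members in sorted(clades.items()))


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed, 80-column wrapping)
# ---------------------------------------------------------------------------

def read_fasta(handle_or_path) -> list[SeqRecord]:
    if isinstance(handle_or_path, (str, bytes)) or hasattr(handle_or_path, "__fspath__"):
        with open(handle_or_path) as fh:
            return read_fasta(fh)
    return [SeqRecord(rec.id, str(rec.seq))
            for rec in SeqIO.parse(handle_or_path, "fasta")]


def write_fasta(records: Iterable[SeqRecord], handle_or_path) -> None:
    if isinstance(handle_or_path, (str, bytes)) or hasattr(handle_or_path, "__fspath__"):
        with open(handle_or_path, "w") as fh:
            write_fasta(records, fh)
            return
    bio = [_BioSeqRecord(Seq(r.residues), id=r.id, description="")
           for r in records]
    SeqIO.write(bio, handle_or_path, "fasta")


def fasta_str(records: Iterable[SeqRecord]) -> str:
    buf = io.StringIO()
    write_fasta(records, buf)
    return buf.getvalue()
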