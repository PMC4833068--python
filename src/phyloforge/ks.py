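"""Within-taxon Ks distributions from paralog pairs.

Self-similarity hit reports are filtered (identity and identical-residue
thresholds, removal of promiscuous sequences hit by many paralogs), each
surviving pair is codon-aligned, and the synonymous distance is computed
with the Nei-Gojobori (1986) method: per-codon synonymous/nonsynonymous
site fractions averaged over the two sequences, multi-position codon
differences averaged over all orderings of single-nucleotide steps
(excluding paths through stop codons), and a Jukes-Cantor-style correction

    d = -(3/4) ln(1 - (4/3) p)

for multiple substitutions.  Peaks in the per-taxon Ks histogram mark
whole-genome duplications; the early-eudicot triplication sits near
Ks 1.8-2 while lineage-specific events appear between roughly 0.3 and 1,
shifting with lineage rate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .contrasts import GENETIC_CODE, STOP_CODONS, back_translate
from .curation import HitRecord
from .seqs import NT_UNAMBIGUOUS, Alignment, SeqRecord

NT = "ACGT"


@dataclass
class ParalogPair:
    """An unordered within-taxon paralog pair with its NG86 distances."""

    id1: str
    id2: str
    pident: float
    nident: int
    ks: float | None = None       # None iff saturated
    ka: float | None = None
    saturated: bool = False

    def key(self) -> tuple[str, str]:
        return (self.id1, self.id2) if self.id1 <= self.id2 \
            else (self.id2, self.id1)


@dataclass
class KsDistribution:
    taxon: str
    values: list[float]
    bin_edges: np.ndarray
    counts: np.ndarray
    n_overflow: int

    @property
    def modal_bin(self) -> tuple[float, float] | None:
        if self.counts.sum() == 0:
            return None
        i = int(np.argmax(self.counts))
        return float(self.bin_edges[i]), float(self.bin_edges[i + 1])


# ---------------------------------------------------------------------------
# hit filtering
# ---------------------------------------------------------------------------

def filter_self_hits(hits: list[HitRecord], min_pident: float = 20.0,
                     min_nident: int = 50, max_hits: int = 10,
                     count_prefilter: bool = False) -> list[ParalogPair]:
    """Reduce a within-taxon self-hit report to usable paralog pairs.

    Self matches are dropped, then hits below ``min_pident`` percent
    identity or ``min_nident`` identical residues; finally every sequence
    participating in ``max_hits`` or more of the remaining hits is removed
    with all its pairs (over-duplicated families would dominate the
    distribution).  With ``count_prefilter=True`` the participation count is
    taken before thresholding instead.  Pairs are deduplicated unordered.
    """
    nonself = [h for h in hits if not h.is_self]
    passing = [h for h in nonself
               if h.pident >= min_pident and h.nident >= min_nident]
    counted = nonself if count_prefilter else passing
    participation: dict[str, int] = {}
    for h in counted:
        participation[h.query] = participation.get(h.query, 0) + 1
        participation[h.subject] = participation.get(h.subject, 0) + 1
    promiscuous = {s for s, n in participation.items() if n >= max_hits}
    seen = set()
    out = []
    for h in passing:
        if h.query in promiscuous or h.subject in promiscuous:
            continue
        pair = ParalogPair(h.query, h.subject, h.pident, h.nident)
        if pair.key() in seen:
            continue
        seen.add(pair.key())
        out.append(pair)
    return out


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _syn_fraction(codon: str) -> float:
    """Synonymous site count of one codon (changes to stops = nonsynonymous)."""
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for alt in NT:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if GENETIC_CODE[mutant] == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    Multi-position differences average over all orderings of single steps;
    paths through a stop codon are excluded (all-stop paths fall back to
    counting every path).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        syn = non = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                return None
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        return syn, non

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:
        def walk_all(order):
            syn = non = 0.0
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                    syn += 1
                else:
                    non += 1
                cur = nxt
            return syn, non
        valid = [walk_all(o) for o in itertools.permutations(diff_pos)]
    syn = sum(v[0] for v in valid) / len(valid)
    non = sum(v[1] for v in valid) / len(valid)
    return syn, non


def _jc_correct(p: float) -> float | None:
    """d = -(3/4) ln(1 - (4/3) p); None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclass
class NGResult:
    ka: float | None
    ks: float | None
    pn: float
    ps: float
    n_sites: float        # nonsynonymous sites N
    s_sites: float        # synonymous sites S
    n_codons: int
    saturated_ks: bool = False
    saturated_ka: bool = False


def ng86(codon_aln: Alignment) -> NGResult:
    """Nei-Gojobori (1986) Ka/Ks for a two-row codon alignment.

    Codon columns containing gaps or ambiguity characters are dropped before
    counting; internal stop codons are an error.  ``ks`` is ``None`` (and the
    saturated flag set) when pS >= 3/4, outside the correction's domain.
    """
    if codon_aln.n_rows != 2:
        raise ValueError("NG86 needs exactly two sequences")
    if codon_aln.n_cols % 3:
        raise ValueError("alignment width not divisible by 3")
    s1, s2 = (r.residues.upper() for r in codon_aln.rows)
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    n_codons = 0
    for j in range(0, len(s1), 3):
        c1, c2 = s1[j:j + 3], s2[j:j + 3]
        if not (set(c1) <= NT_UNAMBIGUOUS and set(c2) <= NT_UNAMBIGUOUS):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise ValueError(f"internal stop codon at column {j + 1}")
        n_codons += 1
        s_sites += (_syn_fraction(c1) + _syn_fraction(c2)) / 2.0
        ds, dn = _pair_differences(c1, c2)
        sd += ds
        nd += dn
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    return NGResult(ka, ks, pn, ps, n_sites, s_sites, n_codons,
                    saturated_ks=ks is None, saturated_ka=ka is None)


def pair_ks(pep1: SeqRecord, pep2: SeqRecord, cds: dict[str, str],
            aligner=None) -> NGResult:
    """Ks for one paralog pair from peptides + CDS.

    Peptides are globally aligned (built-in BLOSUM62 global aligner unless a
    precomputed alignment callable is supplied), back-translated to codons,
    and scored with NG86.
    """
    if aligner is None:
        aligner = _default_protein_aligner()
    a1, a2 = aligner(pep1.residues, pep2.residues)
    protein_aln = Alignment([SeqRecord(pep1.id, a1, pep1.taxon),
                             SeqRecord(pep2.id, a2, pep2.taxon)])
    codon_aln = back_translate(protein_aln, cds)
    return ng86(codon_aln)


def _default_protein_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -10
    al.extend_gap_score = -0.5
    al.mode = "global"

    def run(s1: str, s2: str) -> tuple[str, str]:
        best = al.align(s1, s2)[0]
        return str(best[0]), str(best[1])

    return run


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

def ks_histogram(values: list[float], taxon: str = "",
                 bin_width: float = 0.05,
                 ks_range: tuple[float, float] = (0.0, 2.0),
                 ) -> KsDistribution:
    """Fixed-edge Ks histogram; out-of-range values go to an overflow bucket."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = ks_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    arr = np.asarray(values, dtype=float)
    in_range = arr[(arr >= lo) & (arr < edges[-1])]
    counts, _ = np.histogram(in_range, bins=edges)
    return KsDistribution(taxon, list(values), edges, counts,
                          n_overflow=int(len(arr) - len(in_range)))


def histogram_tsv(dist: KsDistribution) -> str:
    lines = [f"# taxon: {dist.taxon}  n={len(dist.values)}  "
             f"overflow={dist.n_overflow}", "bin_start\tbin_end\tcount"]
    for i, c in enumerate(dist.counts):
        lines.append(f"{dist.bin_edges[i]:.2f}\t{dist.bin_edges[i+1]:.2f}\t{c}")
    return "\n".join(lines) + "\n"


def plot_histogram(dist: KsDistribution, path) -> None:  # pragma: no cover
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(dist.bin_edges[:-1], dist.counts,
           width=np.diff(dist.bin_edges), align="edge")
    ax.set_xlabel("Ks")
    ax.set_ylabel("paralog pairs")
    ax.set_title(dist.taxon)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
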