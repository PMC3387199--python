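"""Validation of candidate primer pairs against annotated reference genomes.

Candidates are designed on spliced coding alignments; a genome decides their
fate. A primer whose binding stretch is interrupted by an intron (it spans
an exon/exon junction in the CDS) cannot bind contiguous genomic DNA and is
discarded, as is any pair whose genomic target region exceeds the size cap.
Accepted pairs get an amplicon prediction with exact exonic/intronic
nucleotide accounting from the gene model, and approximate binding sites
elsewhere in the genome feed a secondary-product risk screen.

Coordinates are 0-based half-open internally; GFF3's 1-based inclusive
intervals are converted at the I/O boundary.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from . import iupac
from .design import DesignParams, PrimerPair

_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_BITS = {
    code: sum(_BASE_BITS[b] for b in bases)
    for code, bases in iupac.IUPAC_SETS.items()
}


class GeneModelMissingError(KeyError):
    """No gene model available for a locus (distinct from a design rejection)."""


@dataclass
class GeneModel:
    """Ordered exon structure of one gene on a genome sequence."""

    gene_id: str
    seq_id: str
    strand: str  # "+" | "-"
    exons: list[tuple[int, int]]  # 0-based half-open, sorted by genome position

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if any(s >= e for s, e in ex):
            raise ValueError(f"{self.gene_id}: empty exon")
        self.exons = ex

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def _exon_order(self) -> list[tuple[int, int]]:
        """Exons in transcription (5'→3' CDS) order."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def cds_interval_to_genome(
        self, cds_start: int, cds_end: int
    ) -> list[tuple[int, int]]:
        """Genomic pieces (genome-sorted) covered by a CDS interval.

        One piece means the interval lies inside a single exon; more pieces
        mean it crosses at least one intron.
        """
        if not (0 <= cds_start < cds_end <= self.cds_len):
            raise ValueError(
                f"CDS interval [{cds_start},{cds_end}) outside gene "
                f"{self.gene_id} (CDS length {self.cds_len})"
            )
        pieces = []
        off = 0
        for s, e in self._exon_order():
            n = e - s
            lo = max(cds_start, off)
            hi = min(cds_end, off + n)
            if lo < hi:
                if self.strand == "+":
                    pieces.append((s + (lo - off), s + (hi - off)))
                else:
                    pieces.append((e - (hi - off), e - (lo - off)))
            off += n
        return sorted(pieces)

    def exonic_bp(self, start: int, end: int) -> int:
        """Exonic nucleotides within a genomic interval [start, end)."""
        return sum(
            max(0, min(e, end) - max(s, start)) for s, e in self.exons
        )

    def extract_cds(self, contig_seq: str) -> str:
        """Spliced CDS sequence (reverse-complemented on the minus strand)."""
        parts = [contig_seq[s:e] for s, e in self.exons]
        seq = "".join(parts)
        if self.strand == "-":
            seq = iupac.reverse_complement(seq)
        return seq


@dataclass(frozen=True)
class BindingSite:
    contig: str
    position: int  # 0-based start of the match on the plus strand
    strand: str  # "+": primer 5'->3' equals plus strand; "-": matches minus
    mismatches: int

    @property
    def primary(self) -> bool:
        return self.mismatches == 0


@dataclass(frozen=True)
class AmpliconPrediction:
    """Placement of a primer pair on one genome."""

    genome_id: str
    contig: str
    product_start: int
    product_end: int
    target_start: int
    target_end: int
    exonic_bp: int
    intronic_bp: int
    tail_lengths: tuple[int, int] = (0, 0)

    @property
    def target_len(self) -> int:
        return self.target_end - self.target_start

    @property
    def product_len(self) -> int:
        return (
            self.target_len
            + (self.target_start - self.product_start)
            + (self.product_end - self.target_end)
            + sum(self.tail_lengths)
        )


@dataclass(frozen=True)
class Rejection:
    reason: str  # "boundary" | "no_binding_site" | "length" | "orientation"
    detail: str = ""


def _encode(seq: str) -> np.ndarray:
    """Genome/primer to 4-bit base masks; unknown symbols get mask 0."""
    lut = np.zeros(256, dtype=np.uint8)
    for code, bits in _CODE_BITS.items():
        lut[ord(code)] = bits
        lut[ord(code.lower())] = bits
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _mismatch_counts(genome_bits: np.ndarray, primer_bits: np.ndarray) -> np.ndarray:
    """Mismatches of the primer pattern at every genome offset (vectorized)."""
    m = len(primer_bits)
    if len(genome_bits) < m:
        return np.zeros(0, dtype=np.int32)
    windows = np.lib.stride_tricks.sliding_window_view(genome_bits, m)
    return ((windows & primer_bits[None, :]) == 0).sum(axis=1, dtype=np.int32)


def find_binding_sites(
    primer: str,
    genome: dict[str, str],
    max_mismatch: int = 0,
) -> list[BindingSite]:
    """All genomic placements of a degenerate primer within a mismatch budget.

    A site matches when each genome base is contained in (or overlaps, for
    ambiguous genome symbols) the primer's IUPAC code at that position, with
    at most ``max_mismatch`` violations. Both strands are searched; a
    minus-strand site means the primer matches the reverse complement, with
    ``position`` still the plus-strand start of the covered interval.
    Output order is deterministic: by contig, position, strand.
    """
    pat_plus = _encode(primer)
    pat_minus = _encode(iupac.reverse_complement(primer))
    sites: list[BindingSite] = []
    for contig in sorted(genome):
        gbits = _encode(genome[contig])
        for strand, pat in (("+", pat_plus), ("-", pat_minus)):
            mm = _mismatch_counts(gbits, pat)
            for pos in np.nonzero(mm <= max_mismatch)[0]:
                sites.append(
                    BindingSite(contig, int(pos), strand, int(mm[pos]))
                )
    sites.sort(key=lambda s: (s.contig, s.position, s.strand))
    return sites


def _three_prime_clean(
    primer: str, contig_seq: str, site: BindingSite, m: int
) -> bool:
    """True iff the 3'-terminal m bases of the primer match without mismatch."""
    L = len(primer)
    window = contig_seq[site.position : site.position + L].upper()
    if len(window) < L:
        return False
    pat = primer if site.strand == "+" else iupac.reverse_complement(primer)
    # on the plus strand the primer 3' end is the window's right edge; on the
    # minus strand it is the left edge of the reverse-complemented pattern
    idx = range(L - m, L) if site.strand == "+" else range(0, m)
    return all(
        window[i] in iupac.IUPAC_SETS.get(pat[i], set()) for i in idx
    )


def validate_pair(
    pair: PrimerPair,
    aln_row: str,
    gene_model: GeneModel | None,
    genome: dict[str, str],
    params: DesignParams,
    genome_id: str = "",
    tail_lengths: tuple[int, int] = (0, 0),
) -> AmpliconPrediction | Rejection:
    """Place one candidate pair on one genome via its source gene.

    ``aln_row`` is this genome's row of the codon alignment the pair was
    designed on; it maps alignment columns to CDS positions, and the gene
    model maps CDS positions to the genome. Rejects with reason
    ``boundary`` when either primer's binding stretch crosses an exon/intron
    junction, ``no_binding_site`` when the genomic sequence under a primer
    is not one of its expansions, ``orientation`` when the implied primers
    do not converge, and ``length`` when the genomic target region leaves
    the configured amplicon bounds. The product additionally includes both
    primers and any 5' tails, and may therefore exceed the target-region cap.
    """
    if gene_model is None:
        raise GeneModelMissingError(pair.gene_id)

    gaps_before = _gap_prefix(aln_row)

    def cds_span(site) -> tuple[int, int]:
        if GAPB in aln_row[site.start : site.end].encode():
            raise ValueError("primer window overlaps an alignment gap")
        s = site.start - gaps_before[site.start]
        return s, s + (site.end - site.start)

    contig = gene_model.seq_id
    contig_seq = genome[contig]
    placements = {}
    for label, site in (("fwd", pair.fwd), ("rev", pair.rev)):
        cs, ce = cds_span(site)
        pieces = gene_model.cds_interval_to_genome(cs, ce)
        if len(pieces) > 1:
            return Rejection("boundary", f"{label} primer spans an exon/intron junction")
        g0, g1 = pieces[0]
        genomic = contig_seq[g0:g1].upper()
        # orient the genomic window to the primer's own 5'->3' reading
        plus = gene_model.strand == "+"
        want_fwd = (label == "fwd") == plus
        observed = genomic if want_fwd else iupac.reverse_complement(genomic)
        pattern = site.seq
        if not all(
            b in iupac.IUPAC_SETS[p] for b, p in zip(observed, pattern)
        ):
            return Rejection("no_binding_site", f"{label} primer mismatches the genome")
        placements[label] = (g0, g1)

    (f0, f1), (r0, r1) = placements["fwd"], placements["rev"]
    if gene_model.strand == "+":
        t0, t1 = f1, r0
        p0, p1 = f0, r1
    else:
        t0, t1 = r1, f0
        p0, p1 = r0, f1
    if t1 < t0:
        return Rejection("orientation", "primer sites do not converge")
    tlen = t1 - t0
    if not (params.amplicon_min <= tlen <= params.amplicon_max):
        return Rejection("length", f"genomic target region {tlen} bp out of bounds")
    ex = gene_model.exonic_bp(t0, t1)
    return AmpliconPrediction(
        genome_id=genome_id,
        contig=contig,
        product_start=p0,
        product_end=p1,
        target_start=t0,
        target_end=t1,
        exonic_bp=ex,
        intronic_bp=tlen - ex,
        tail_lengths=tail_lengths,
    )


GAPB = b"-"


def _gap_prefix(row: str) -> np.ndarray:
    """gaps_before[i] = number of gap characters in row[:i]."""
    arr = np.frombuffer(row.encode(), dtype="S1") == GAPB
    out = np.zeros(len(row) + 1, dtype=np.int64)
    np.cumsum(arr, out=out[1:])
    return out


@dataclass(frozen=True)
class SecondaryProduct:
    contig: str
    start: int
    end: int
    left_primer: str  # "fwd" | "rev"
    right_primer: str
    left_mismatches: int
    right_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SecondaryRiskReport:
    products: list[SecondaryProduct] = field(default_factory=list)

    @property
    def risky(self) -> bool:
        return bool(self.products)


def secondary_product_screen(
    pair: PrimerPair,
    genome: dict[str, str],
    params: DesignParams,
    intended: tuple[str, int, int] | None = None,
    max_mismatch: int = 2,
    clean_three_prime: int = 6,
    secondary_max_len: int = 3000,
) -> SecondaryRiskReport:
    """Probability proxy for undesired secondary amplification products.

    Scans both primers (any combination, either order) for approximate
    binding sites and reports every convergent site pair on one contig whose
    implied product is at most ``secondary_max_len`` and differs from the
    intended product (``intended`` = (contig, product_start, product_end)).
    A site only counts when its ``clean_three_prime`` 3'-terminal bases
    match perfectly — extension is primed from the 3' end.
    """
    prims = {"fwd": pair.fwd.seq, "rev": pair.rev.seq}
    hits: dict[str, list[tuple[str, BindingSite, int]]] = {}
    for name, seq in prims.items():
        for s in find_binding_sites(seq, genome, max_mismatch=max_mismatch):
            if not _three_prime_clean(seq, genome[s.contig], s, clean_three_prime):
                continue
            hits.setdefault(s.contig, []).append((name, s, len(seq)))
    report = SecondaryRiskReport()
    for contig, sites in sorted(hits.items()):
        plus = [(n, s, L) for n, s, L in sites if s.strand == "+"]
        minus = [(n, s, L) for n, s, L in sites if s.strand == "-"]
        for ln, ls, _ in plus:
            for rn, rs, rl in minus:
                if rs.position < ls.position:
                    continue
                start, end = ls.position, rs.position + rl
                if end - start > secondary_max_len:
                    continue
                if intended is not None and (contig, start, end) == tuple(intended):
                    continue
                report.products.append(
                    SecondaryProduct(
                        contig=contig, start=start, end=end,
                        left_primer=ln, right_primer=rn,
                        left_mismatches=ls.mismatches,
                        right_mismatches=rs.mismatches,
                    )
                )
    report.products.sort(key=lambda p: (p.contig, p.start, p.end))
    return report
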