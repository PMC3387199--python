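"""Conserved-window scanning and degenerate primer pair construction.

The scanner slides windows of every admissible primer length across a codon
alignment, builds the minimal IUPAC consensus of each window (the union of
observed bases per column), and keeps windows whose consensus passes the
full oligo filter battery: degeneracy cap, GC-content window, mononucleotide
run limit, 3'-terminal rules, and melting-temperature window. Conservation
is thus operationalized purely through the degeneracy cap on the minimal
consensus — more divergent windows have higher degeneracy and fall off the
cap. Surviving forward/reverse candidates are combined into pairs subject to
amplicon-length and Tm-compatibility constraints plus a dimer screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import yaml

from . import iupac, thermo
from .codon import CodonAlignment


@dataclass
class DesignParams:
    """Primer/amplicon design constraints (defaults: the standard set used
    for the hymenopteran marker panel)."""

    amplicon_min: int = 300
    amplicon_max: int = 1000
    primer_len_min: int = 20
    primer_len_max: int = 25
    max_degeneracy: int = 256
    gc_min: float = 20.0
    gc_max: float = 80.0
    max_run: int = 4
    tm_min: float = 45.0
    tm_max: float = 66.0
    max_dtm: float = 10.0
    dimer_threshold: float = -11.0
    three_prime_window: int = 6
    three_prime_max_degeneracy: int = 4
    three_prime_gc_min: float = 20.0
    three_prime_gc_max: float = 80.0
    three_prime_max_run: int = 3
    # plumbing knobs (not part of the constraint table)
    tm_enum_cap: int = 1024
    dimer_enum_cap: int = 64
    gc_semantics: str = "contain"  # or "overlap"

    def __post_init__(self):
        for lo, hi in [
            (self.amplicon_min, self.amplicon_max),
            (self.primer_len_min, self.primer_len_max),
            (self.gc_min, self.gc_max),
            (self.tm_min, self.tm_max),
        ]:
            if lo > hi:
                raise ValueError(f"minimum {lo} exceeds maximum {hi}")

    @classmethod
    def from_yaml(cls, path: str) -> "DesignParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def gc_ok(self, seq: str) -> bool:
        lo, hi = iupac.gc_range(seq)
        if self.gc_semantics == "contain":
            return lo >= self.gc_min and hi <= self.gc_max
        return hi >= self.gc_min and lo <= self.gc_max


@dataclass(frozen=True)
class CandidateSite:
    """One filtered primer candidate anchored on the alignment.

    ``start``/``end`` are 0-based half-open alignment columns. The stored
    ``seq`` is the primer 5'→3': the plus-strand consensus for a forward
    candidate, its reverse complement for a reverse candidate.
    """

    gene_id: str
    start: int
    end: int
    orientation: str  # "F" | "R"
    seq: str
    degeneracy: int
    tm_lo: float
    tm_hi: float
    diagnostics: dict = field(default_factory=dict, compare=False, hash=False)

    @property
    def tm_mid(self) -> float:
        return 0.5 * (self.tm_lo + self.tm_hi)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse candidate combination from one gene."""

    gene_id: str
    fwd: CandidateSite
    rev: CandidateSite
    dimer_worst_dG: float

    @property
    def total_degeneracy(self) -> int:
        return self.fwd.degeneracy * self.rev.degeneracy

    @property
    def target_start(self) -> int:
        """Alignment column where the target region (between primers) begins."""
        return self.fwd.end

    @property
    def target_end(self) -> int:
        return self.rev.start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


def column_consensus(rows: list[str]) -> str | None:
    """Minimal IUPAC consensus of equal-length aligned window rows.

    Per column, the smallest IUPAC code containing the union of observed
    bases. Any gap or ambiguity symbol (``N`` etc.) in any row rejects the
    window (returns None): such columns cannot anchor a primer.
    """
    out = []
    for col in zip(*rows):
        bases = set(col)
        if not bases <= set("ACGT"):
            return None
        out.append(iupac.consensus_code(bases))
    return "".join(out)


def _passes_oligo_filters(
    seq: str, params: DesignParams, model: thermo.ThermoModel
) -> tuple[bool, dict]:
    """Apply the per-oligo predicates to a 5'→3' primer sequence."""
    diag: dict = {}
    d = iupac.degeneracy(seq)
    diag["degeneracy"] = d
    if d > params.max_degeneracy:
        diag["fail"] = "degeneracy"
        return False, diag
    if not params.gc_ok(seq):
        diag["fail"] = "gc"
        return False, diag
    if iupac.max_run(seq) > params.max_run:
        diag["fail"] = "run"
        return False, diag
    tp = iupac.three_prime_checks(
        seq,
        window=params.three_prime_window,
        max_degeneracy=params.three_prime_max_degeneracy,
        gc_min=params.three_prime_gc_min,
        gc_max=params.three_prime_gc_max,
        run_max=params.three_prime_max_run,
    )
    if not tp.passed:
        diag["fail"] = "three_prime:" + ";".join(tp.reasons)
        return False, diag
    lo, hi = thermo.tm_range(seq, model, cap=params.tm_enum_cap)
    diag["tm"] = (lo, hi)
    if lo < params.tm_min or hi > params.tm_max:
        diag["fail"] = "tm"
        return False, diag
    return True, diag


def scan_gene(
    aln: CodonAlignment,
    params: DesignParams,
    model: thermo.ThermoModel | None = None,
    gene_id: str | None = None,
) -> list[CandidateSite]:
    """All primer candidates surviving the filter battery, both orientations.

    Windows of every length in ``[primer_len_min, primer_len_max]`` slide
    with step 1 nucleotide (candidates need not be frame-aligned). Output is
    deterministic: sorted by position, then length, then orientation (F
    before R).
    """
    if model is None:
        model = thermo.ThermoModel()
    gene = gene_id if gene_id is not None else (aln.cds_ids[0] if aln.cds_ids else "gene")
    ncol = len(aln)
    if ncol < params.primer_len_min:
        warnings.warn(f"{gene}: alignment shorter than minimum primer length")
        return []
    if aln.n_rows < 2:
        raise ValueError("need >= 2 aligned rows to build a consensus")
    # per-column minimal codes, computed once; None marks unusable columns
    acgt = set("ACGT")
    col_codes: list[str | None] = []
    for col in zip(*aln.rows):
        bases = set(col)
        col_codes.append(
            iupac.consensus_code(bases) if bases <= acgt else None
        )
    card = [len(iupac.IUPAC_SETS[c]) if c else 0 for c in col_codes]

    sites: list[CandidateSite] = []
    for start in range(0, ncol - params.primer_len_min + 1):
        for length in range(params.primer_len_min, params.primer_len_max + 1):
            end = start + length
            if end > ncol:
                break
            d = 1
            for c in card[start:end]:
                d *= c
            if d == 0 or d > params.max_degeneracy:
                # a gap/ambiguous column or an over-cap product can only
                # persist as the window grows rightward
                break
            cons = "".join(col_codes[start:end])  # type: ignore[arg-type]
            for orient in ("F", "R"):
                primer = cons if orient == "F" else iupac.reverse_complement(cons)
                ok, diag = _passes_oligo_filters(primer, params, model)
                if ok:
                    lo, hi = diag["tm"]
                    sites.append(
                        CandidateSite(
                            gene_id=gene,
                            start=start,
                            end=end,
                            orientation=orient,
                            seq=primer,
                            degeneracy=diag["degeneracy"],
                            tm_lo=lo,
                            tm_hi=hi,
                            diagnostics=diag,
                        )
                    )
    sites.sort(key=lambda s: (s.start, s.end - s.start, s.orientation))
    return sites


def form_pairs(
    sites: list[CandidateSite],
    params: DesignParams,
    model: thermo.ThermoModel | None = None,
) -> list[PrimerPair]:
    """All compatible (forward, reverse) combinations from one gene's sites.

    A pair requires the forward candidate strictly 5' of the reverse one,
    an alignment-implied target length within the amplicon bounds (a
    provisional pre-filter — the authoritative per-genome length check
    happens during genome validation), Tm-midpoint difference within
    ``max_dtm``, and a passing homo-/heterodimer screen.
    """
    if model is None:
        model = thermo.ThermoModel()
    fwds = [s for s in sites if s.orientation == "F"]
    revs = [s for s in sites if s.orientation == "R"]
    pairs: list[PrimerPair] = []
    for f in fwds:
        for r in revs:
            if r.start < f.end:
                continue
            span = r.start - f.end
            if not (params.amplicon_min <= span <= params.amplicon_max):
                continue
            if abs(f.tm_mid - r.tm_mid) > params.max_dtm:
                continue
            rep = thermo.dimer_screen(
                f.seq, r.seq, model,
                threshold=params.dimer_threshold,
                cap=params.dimer_enum_cap,
            )
            if not rep.passed:
                continue
            pairs.append(
                PrimerPair(
                    gene_id=f.gene_id, fwd=f, rev=r, dimer_worst_dG=rep.worst_dG
                )
            )
    return pairs
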