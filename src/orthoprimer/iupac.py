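"""IUPAC degenerate-nucleotide algebra.

A degenerate oligonucleotide is written over the 15-letter IUPAC alphabet, each
symbol standing for a set of concrete bases (``Y`` = C/T, ``N`` = A/C/G/T, ...).
The *degeneracy* ``d`` of an oligo is the number of distinct concrete sequences
it represents — the product over positions of the cardinality of each code —
and equals the pool complexity of the synthesized primer.

All functions operate on plain uppercase strings; :func:`clean` normalizes and
validates arbitrary input (lower case, RNA ``U``) once at ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse lookup: frozenset of bases -> minimal IUPAC code.
CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "S": "S", "W": "W", "N": "N",
}


class InvalidSymbolError(ValueError):
    """A symbol outside the IUPAC nucleotide alphabet, with its position."""

    def __init__(self, symbol: str, position: int):
        self.symbol = symbol
        self.position = position
        super().__init__(
            f"invalid IUPAC nucleotide symbol {symbol!r} at position {position}"
        )


class DegeneracyCapError(ValueError):
    """Refusal to enumerate an oligo whose degeneracy exceeds the cap."""


def clean(seq: str) -> str:
    """Normalize a primer string: uppercase, ``U``→``T``, validate symbols.

    Raises :class:`InvalidSymbolError` naming the first offending position.
    An empty sequence is rejected.
    """
    out = seq.upper().replace("U", "T")
    if not out:
        raise ValueError("empty sequence")
    for i, sym in enumerate(out):
        if sym not in IUPAC_SETS:
            raise InvalidSymbolError(sym, i)
    return out


def degeneracy(seq: str) -> int:
    """Degree of degeneration: product of per-position code cardinalities."""
    d = 1
    for i, sym in enumerate(seq):
        try:
            d *= len(IUPAC_SETS[sym])
        except KeyError:
            raise InvalidSymbolError(sym, i) from None
    return d


def pair_degeneracy(fwd: str, rev: str) -> int:
    """Total degeneracy of a primer pair (product of the per-primer values)."""
    return degeneracy(fwd) * degeneracy(rev)


def expand(seq: str, cap: int = 65536) -> set[str]:
    """All concrete A/C/G/T sequences consistent with the codes.

    Refuses (raises :class:`DegeneracyCapError`) when the degeneracy exceeds
    ``cap``; callers needing bounds above the cap must use the
    non-enumerating range functions instead.
    """
    d = degeneracy(seq)
    if d > cap:
        raise DegeneracyCapError(
            f"degeneracy {d} exceeds enumeration cap {cap}"
        )
    return {"".join(p) for p in product(*(sorted(IUPAC_SETS[s]) for s in seq))}


def is_expansion(concrete: str, pattern: str) -> bool:
    """True iff ``concrete`` is one of ``pattern``'s expansions."""
    if len(concrete) != len(pattern):
        return False
    return all(c in IUPAC_SETS[p] for c, p in zip(concrete, pattern))


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet (R↔Y, K↔M, ...)."""
    return "".join(COMPLEMENT[s] for s in reversed(seq))


def consensus_code(bases: Iterable[str]) -> str:
    """Minimal IUPAC code containing the union of the given concrete bases."""
    return CODE_FOR_SET[frozenset(bases)]


def gc_range(seq: str) -> tuple[float, float]:
    """Min/max GC content (percent) over all expansions.

    Computed per position without enumeration: a code contributes 1 to the
    minimum GC count iff every base it contains is G or C, and 1 to the
    maximum iff it contains at least one G or C.
    """
    gc = {"G", "C"}
    lo = sum(1 for s in seq if IUPAC_SETS[s] <= gc)
    hi = sum(1 for s in seq if IUPAC_SETS[s] & gc)
    n = len(seq)
    return 100.0 * lo / n, 100.0 * hi / n


def max_run(seq: str) -> int:
    """Worst-case longest mononucleotide run over all expansions.

    For each base ``b``, the longest stretch of consecutive codes each
    *containing* ``b`` is an achievable run (choose ``b`` at every such
    position); the maximum over the four bases is exact.
    """
    best = 0
    for b in "ACGT":
        cur = 0
        for s in seq:
            if b in IUPAC_SETS[s]:
                cur += 1
                best = max(best, cur)
            else:
                cur = 0
    return best


@dataclass(frozen=True)
class ThreePrimeReport:
    """Per-rule verdicts for the 3'-terminal window of a primer."""

    window_seq: str
    degeneracy_ok: bool
    gc_ok: bool
    run_ok: bool

    @property
    def passed(self) -> bool:
        return self.degeneracy_ok and self.gc_ok and self.run_ok

    @property
    def reasons(self) -> list[str]:
        out = []
        if not self.degeneracy_ok:
            out.append("3'-window degeneracy too high")
        if not self.gc_ok:
            out.append("3'-window GC content out of range")
        if not self.run_ok:
            out.append("3'-window mononucleotide run too long")
        return out


def three_prime_checks(
    seq: str,
    window: int = 6,
    max_degeneracy: int = 4,
    gc_min: float = 20.0,
    gc_max: float = 80.0,
    run_max: int = 3,
) -> ThreePrimeReport:
    """Evaluate the terminal-nucleotide rules on the 3' window of ``seq``.

    ``seq`` is read 5'→3', so the window is the last ``window`` symbols. The
    GC rule requires the window's whole GC range (every expansion) to lie
    within ``[gc_min, gc_max]``.
    """
    if window > len(seq):
        raise ValueError(
            f"3' window ({window}) longer than primer ({len(seq)})"
        )
    tail = seq[-window:]
    lo, hi = gc_range(tail)
    return ThreePrimeReport(
        window_seq=tail,
        degeneracy_ok=degeneracy(tail) <= max_degeneracy,
        gc_ok=(lo >= gc_min and hi <= gc_max),
        run_ok=max_run(tail) <= run_max,
    )
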