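"""Nearest-neighbor duplex thermodynamics for (degenerate) primers.

Melting temperatures use the unified nearest-neighbor model

    Tm = 1000 * dH / (dS + dS_salt + R * ln(C)) - 273.15

with dH/dS summed over dinucleotide stacking steps plus per-end initiation
terms, the entropic salt correction dS_salt = 0.368 * (N-1) * ln[Na+], and
C = C_T/4 for non-self-complementary duplexes (C_T/2 for self-complementary,
which also receive the symmetry entropy term). Parameters ship as a
plain-text table (``data/nn_unified.tsv``).

Primer-dimer risk is screened by an ungapped antiparallel offset scan: the
two oligos are slid against each other in annealing orientation and, at each
offset, the dG(37 C) stacking terms of consecutively Watson-Crick-paired
steps are summed. No bulges, internal loops or mismatch corrections are
modeled — a deliberate simplification sufficient for a threshold screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from importlib import resources
from itertools import product as _iproduct

from . import iupac

R_GAS = 1.987  # cal / (mol K)
T37 = 310.15  # K

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _load_nn_table() -> dict[str, tuple[float, float]]:
    text = (
        resources.files("orthoprimer").joinpath("data/nn_unified.tsv").read_text()
    )
    table: dict[str, tuple[float, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("step\t"):
            continue
        key, dh, ds = line.split("\t")
        table[key] = (float(dh), float(ds))
    # fill the six steps implied by reverse-complement symmetry
    for step in ["".join(p) for p in _iproduct("ACGT", repeat=2)]:
        if step not in table:
            rc = _WC[step[1]] + _WC[step[0]]
            table[step] = table[rc]
    return table


@dataclass(frozen=True)
class ThermoModel:
    """Parameter bundle: NN table plus solution conditions.

    Parameters
    ----------
    na_mM : monovalent-salt concentration (mM Na+ equivalent).
    oligo_uM : total oligonucleotide concentration per primer (µM);
        the default matches a 0.8 µM-per-primer PCR recipe.
    """

    na_mM: float = 50.0
    oligo_uM: float = 0.8
    nn: dict[str, tuple[float, float]] = field(default_factory=_load_nn_table)

    def __post_init__(self):
        if self.na_mM <= 0 or self.oligo_uM <= 0:
            raise ValueError("concentrations must be strictly positive")

    def dg37(self, step: str) -> float:
        dh, ds = self.nn[step]
        return dh - T37 * ds / 1000.0


def _is_self_complementary(seq: str) -> bool:
    return seq == "".join(_WC[b] for b in reversed(seq))


def tm_concrete(seq: str, model: ThermoModel) -> float:
    """Nearest-neighbor melting temperature (°C) of a concrete oligo.

    Degenerate symbols are rejected; use :func:`tm_range` for those.
    """
    if len(seq) < 8:
        raise ValueError("sequence too short for a nearest-neighbor Tm (< 8 nt)")
    if any(b not in "ACGT" for b in seq):
        raise ValueError("degenerate symbols present; use tm_range")
    dh = 0.0
    ds = 0.0
    for i in range(len(seq) - 1):
        h, s = model.nn[seq[i : i + 2]]
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        h, s = model.nn["init_AT" if end in "AT" else "init_GC"]
        dh += h
        ds += s
    ct = model.oligo_uM * 1e-6
    if _is_self_complementary(seq):
        h, s = model.nn["sym"]
        dh += h
        ds += s
        conc = ct / 2.0
    else:
        conc = ct / 4.0
    ds_salt = 0.368 * (len(seq) - 1) * math.log(model.na_mM / 1000.0)
    return 1000.0 * dh / (ds + ds_salt + R_GAS * math.log(conc)) - 273.15


def _extreme_expansion(seq: str, prefer: str) -> str:
    """One expansion choosing, per position, the first base in ``prefer``."""
    out = []
    for sym in seq:
        bases = iupac.IUPAC_SETS[sym]
        out.append(next(b for b in prefer if b in bases))
    return "".join(out)


def tm_range(seq: str, model: ThermoModel, cap: int = 1024) -> tuple[float, float]:
    """Min/max Tm (°C) over all expansions of a degenerate oligo.

    Exact by enumeration up to ``cap`` expansions; above the cap, bounded by
    the AT-maximizing and GC-maximizing expansions (a documented heuristic —
    Tm is dominated by GC content at fixed length).
    """
    d = iupac.degeneracy(seq)
    if d <= cap:
        tms = [tm_concrete(s, model) for s in iupac.expand(seq, cap)]
        return min(tms), max(tms)
    tms = [
        tm_concrete(_extreme_expansion(seq, order), model)
        for order in ("ATCG", "TACG", "GCTA", "CGAT")
    ]
    return min(tms), max(tms)


_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP_IDX = {0: 3, 1: 2, 2: 1, 3: 0}


def _dg_step_vector(model: ThermoModel) -> "np.ndarray":
    """dG(37) lookup indexed by 4*first_base + second_base; cached on model."""
    vec = getattr(model, "_dg_vec", None)
    if vec is None:
        bases = "ACGT"
        vec = np.array(
            [model.dg37(bases[i] + bases[j]) for i in range(4) for j in range(4)]
        )
        object.__setattr__(model, "_dg_vec", vec)
    return vec


def _init_cap_vector(model: ThermoModel) -> "np.ndarray":
    """Helix-end initiation dG(37) indexed by terminal base (A,C,G,T)."""
    vec = getattr(model, "_cap_vec", None)
    if vec is None:
        at = model.dg37("init_AT")
        gc = model.dg37("init_GC")
        vec = np.array([at, gc, gc, at])
        object.__setattr__(model, "_cap_vec", vec)
    return vec


def duplex_dG(a: str, b: str, model: ThermoModel) -> float:
    """Most favorable ungapped antiparallel duplex dG(37 C) of two oligos.

    Both inputs are concrete and written 5'→3'. ``b`` is reversed so the two
    strands anneal antiparallel and every ungapped offset is scanned. At each
    offset, every maximal contiguous Watson-Crick-paired helix is scored as
    the sum of its stacking terms plus the two helix-initiation end terms
    (disjoint paired stretches separated by mismatches are separate helices —
    no internal-loop model). Returns the minimum (most negative) helix free
    energy over all offsets, or 0.0 when no favorable duplex exists.
    """
    # dG is symmetric in (a, b); memoize per model under a canonical key
    memo = getattr(model, "_duplex_memo", None)
    if memo is None:
        memo = {}
        object.__setattr__(model, "_duplex_memo", memo)
    key = (a, b) if a <= b else (b, a)
    hit = memo.get(key)
    if hit is not None:
        return hit
    ai = np.array([_ENC[x] for x in a], dtype=np.int16)
    comp_a = np.array([_COMP_IDX[x] for x in ai], dtype=np.int16)
    rbi = np.array([_ENC[x] for x in b[::-1]], dtype=np.int16)
    na = len(ai)
    # pad so one sliding window of width na exists per antiparallel offset
    pad = np.full(na - 1, -1, dtype=np.int16)
    rbp = np.concatenate([pad, rbi, pad])
    windows = np.lib.stride_tricks.sliding_window_view(rbp, na)
    paired = windows == comp_a[None, :]  # (n_offsets, na)
    # stacked[o, j]: positions j and j+1 both paired at offset o; pad a
    # False column so helices never span flattened row boundaries
    stacked = paired[:, :-1] & paired[:, 1:]
    n_off = stacked.shape[0]
    flat = np.zeros((n_off, na), dtype=bool)
    flat[:, : na - 1] = stacked
    flat = flat.ravel()
    if not flat.any():
        memo[key] = 0.0
        return 0.0
    g = _dg_step_vector(model)[4 * ai[:-1] + ai[1:]]
    w = np.zeros(na)
    w[: na - 1] = g
    wm = np.where(flat, np.tile(w, n_off), 0.0)
    cs = np.concatenate([[0.0], np.cumsum(wm)])
    prev = np.concatenate([[False], flat[:-1]])
    nxt = np.concatenate([flat[1:], [False]])
    starts = np.nonzero(flat & ~prev)[0]
    ends = np.nonzero(flat & ~nxt)[0]
    caps = _init_cap_vector(model)
    j = starts % na  # first paired position of each helix
    k = ends % na + 1  # last paired position
    scores = (cs[ends + 1] - cs[starts]) + caps[ai[j]] + caps[ai[k]]
    out = float(min(0.0, scores.min()))
    memo[key] = out
    return out


@dataclass(frozen=True)
class DimerReport:
    passed: bool
    worst_dG: float
    worst_kind: str  # "homodimer_fwd" | "homodimer_rev" | "heterodimer" | "none"


def _representatives(seq: str, cap: int) -> list[str]:
    if iupac.degeneracy(seq) <= cap:
        return sorted(iupac.expand(seq, cap))
    return [_extreme_expansion(seq, "ATCG"), _extreme_expansion(seq, "GCTA")]


def dimer_screen(
    fwd: str,
    rev: str,
    model: ThermoModel,
    threshold: float = -11.0,
    cap: int = 64,
) -> DimerReport:
    """Homo-/heterodimer screen for a (possibly degenerate) primer pair.

    Fails iff any examined expansion pair yields a duplex dG below
    ``threshold``. Expansions are enumerated exhaustively while the number
    of combinations stays within ``cap``; beyond that, extreme-GC
    representative expansions stand in for the full pool.
    """
    if iupac.pair_degeneracy(fwd, rev) <= cap:
        fs = sorted(iupac.expand(fwd, cap))
        rs = sorted(iupac.expand(rev, cap))
    else:
        fs = _representatives(fwd, 1)
        rs = _representatives(rev, 1)
    worst = 0.0
    kind = "none"
    for label, pairs in (
        ("homodimer_fwd", [(x, y) for i, x in enumerate(fs) for y in fs[i:]]),
        ("homodimer_rev", [(x, y) for i, x in enumerate(rs) for y in rs[i:]]),
        ("heterodimer", [(x, y) for x in fs for y in rs]),
    ):
        for x, y in pairs:
            dg = duplex_dG(x, y, model)
            if dg < worst:
                worst, kind = dg, label
    return DimerReport(passed=worst >= threshold, worst_dG=worst, worst_kind=kind)
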