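"""Codon-aware back-translation and divergence statistics.

A protein multiple alignment serves as a blueprint for aligning the
underlying coding sequences: each amino-acid column becomes one codon column
and each protein gap becomes ``---``, so every gap run in the resulting
nucleotide alignment is codon-aligned. Sequence divergence over a region is
summarized by uncorrected p-distances (Hamming distances over comparable
sites).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

GAP = "-"


class BacktranslateError(ValueError):
    """CDS/protein inconsistency, naming the taxon and position."""


@dataclass
class CodonAlignment:
    """Gap-synchronized nucleotide alignment of one ortholog group.

    Rows are over ``A/C/G/T/N/-`` (ambiguity codes from the source CDS are
    carried through), all equal length divisible by 3.
    """

    ids: list[str]
    rows: list[str]
    cds_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if not self.cds_ids:
            self.cds_ids = list(self.ids)
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows have unequal lengths")
        if self.rows and len(self.rows[0]) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")

    def __len__(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def row_map(self, i: int) -> np.ndarray:
        """Alignment column -> ungapped CDS index (-1 at gap columns)."""
        row = np.frombuffer(self.rows[i].encode(), dtype="S1")
        out = np.cumsum(row != GAP.encode()) - 1
        out[row == GAP.encode()] = -1
        return out


def _translate_codon(codon: str, table: CodonTable.CodonTable) -> str:
    if any(b not in "ACGT" for b in codon):
        return "X"
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def backtranslate(
    proteins: list[tuple[str, str]],
    cds: dict[str, str],
    genetic_code: int | str = 1,
) -> CodonAlignment:
    """Project a protein multiple alignment onto coding sequences.

    Parameters
    ----------
    proteins : ordered ``(taxon_id, aligned_protein_row)`` pairs; rows may
        contain gaps and ``X`` wildcards (``X`` matches any codon, including
        selenocysteine sites recoded before protein alignment).
    cds : unaligned coding sequence per taxon id. A terminal stop codon is
        tolerated and trimmed. Each CDS must translate to its ungapped
        protein row.
    genetic_code : NCBI translation-table id or name (default: standard).

    Raises :class:`BacktranslateError` on any translation mismatch, naming
    the taxon and the protein-alignment position.
    """
    if isinstance(genetic_code, int):
        table = CodonTable.unambiguous_dna_by_id[genetic_code]
    else:
        table = CodonTable.unambiguous_dna_by_name[genetic_code]

    ids, rows = [], []
    for taxon, prow in proteins:
        if taxon not in cds:
            raise BacktranslateError(f"{taxon}: no CDS provided")
        nuc = cds[taxon].upper().replace("U", "T")
        ungapped = prow.replace(GAP, "")
        if len(nuc) == 3 * (len(ungapped) + 1) and nuc[-3:] in table.stop_codons:
            nuc = nuc[:-3]
        if len(nuc) != 3 * len(ungapped):
            raise BacktranslateError(
                f"{taxon}: CDS length {len(nuc)} incompatible with "
                f"{len(ungapped)} aligned residues"
            )
        out = []
        k = 0  # residue index into the ungapped protein
        for col, aa in enumerate(prow):
            if aa == GAP:
                out.append(GAP * 3)
                continue
            codon = nuc[3 * k : 3 * k + 3]
            aa_up = aa.upper()
            if aa_up != "X":
                trans = _translate_codon(codon, table)
                if trans != aa_up and trans != "X":
                    raise BacktranslateError(
                        f"{taxon}: codon {codon} at alignment position {col} "
                        f"translates to {trans}, protein row has {aa_up}"
                    )
            out.append(codon)
            k += 1
        ids.append(taxon)
        rows.append("".join(out))
    return CodonAlignment(ids=ids, rows=rows)


def p_distance_matrix(
    rows: list[str], ids: list[str] | None = None
) -> tuple[np.ndarray, float]:
    """Pairwise uncorrected p-distances and their mean.

    For each pair of equal-length rows, distance = mismatches / compared
    sites, where any site carrying a gap or an ambiguity symbol (anything
    outside A/C/G/T) in either row is excluded from both numerator and
    denominator. A pair with zero comparable sites is NaN and excluded from
    the mean (with a warning).
    """
    n = len(rows)
    if n < 2:
        raise ValueError("need at least 2 rows")
    if len({len(r) for r in rows}) > 1:
        raise ValueError("rows have unequal lengths")
    arr = np.array([list(r) for r in rows])
    ok = np.isin(arr, list("ACGT"))
    dist = np.zeros((n, n))
    vals = []
    for i, j in itertools.combinations(range(n), 2):
        comparable = ok[i] & ok[j]
        m = int(comparable.sum())
        if m == 0:
            name_i = ids[i] if ids else str(i)
            name_j = ids[j] if ids else str(j)
            warnings.warn(
                f"no comparable sites between {name_i} and {name_j}; "
                "pair excluded from mean p-distance"
            )
            dist[i, j] = dist[j, i] = np.nan
            continue
        d = float((arr[i][comparable] != arr[j][comparable]).sum()) / m
        dist[i, j] = dist[j, i] = d
        vals.append(d)
    mean = float(np.mean(vals)) if vals else float("nan")
    return dist, mean
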