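"""Per-gene marker selection, sequencing-tail attachment, and final tables.

Validated pairs for a gene usually overlap heavily (nearby windows of
different lengths). Selection is greedy in a documented, pluggable rank
order — ascending total degeneracy (cheaper, less ambiguous primer pools
first), ties broken by descending intronic content (fast-evolving sites are
the point of intron-rich markers), then by position — subject to a pairwise
target-overlap cap (default 50% of the shorter region). Each surviving pair
is tested for compatibility with a catalog of universal sequencing tails
attached to the 5' ends, and emitted as one row of the marker table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from . import iupac, thermo
from .design import PrimerPair
from .genome import AmpliconPrediction


@dataclass(frozen=True)
class SequencingTail:
    """A concrete universal tail pair providing sequencing-primer sites."""

    name: str
    forward: str
    reverse: str
    tm_forward: float | None = None
    tm_reverse: float | None = None

    def __post_init__(self):
        for seq in (self.forward, self.reverse):
            if iupac.degeneracy(iupac.clean(seq)) != 1:
                raise ValueError(f"tail {self.name} is not a concrete sequence")

    @property
    def code(self) -> str:
        """Single-letter suffix used in pair ids (HOG-Seq-A -> 'A')."""
        return self.name.rsplit("-", 1)[-1]


def load_tails(path: str | None = None) -> list[SequencingTail]:
    """Load a sequencing-tail catalog TSV (name, forward, reverse[, Tms]).

    With no path, the bundled universal catalog is used.
    """
    if path is None:
        with resources.files("orthoprimer").joinpath(
            "data/sequencing_tails.tsv"
        ).open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    tails = []
    for row in df.itertuples(index=False):
        tails.append(
            SequencingTail(
                name=row.name,
                forward=str(row.forward),
                reverse=str(row.reverse),
                tm_forward=getattr(row, "tm_forward", None),
                tm_reverse=getattr(row, "tm_reverse", None),
            )
        )
    return tails


def attach_tail(primer: str, tail_seq: str) -> str:
    """Concatenate a concrete 5' tail onto a primer (tail + primer, 5'→3').

    Degeneracy is unchanged; length grows by the tail length. An empty tail
    is the identity.
    """
    if tail_seq and iupac.degeneracy(iupac.clean(tail_seq)) != 1:
        raise ValueError("sequencing tails must be concrete sequences")
    return (iupac.clean(tail_seq) if tail_seq else "") + primer


def overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap of two half-open intervals as a fraction of the shorter one."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    shorter = min(a[1] - a[0], b[1] - b[0])
    return inter / shorter if shorter > 0 else 0.0


def default_rank_key(item: tuple[PrimerPair, dict]) -> tuple:
    pair, predictions = item
    intronic = [p.intronic_bp for p in predictions.values()]
    mean_intronic = sum(intronic) / len(intronic) if intronic else 0.0
    return (pair.total_degeneracy, -mean_intronic, pair.fwd.start, pair.rev.end)


def select_per_gene(
    pairs: list[tuple[PrimerPair, dict[str, AmpliconPrediction]]],
    max_overlap: float = 0.5,
    rank_key=default_rank_key,
) -> list[tuple[PrimerPair, dict[str, AmpliconPrediction]]]:
    """Greedy overlap-limited selection of one gene's validated pairs.

    Pairs are considered in rank order; a pair is kept iff its alignment
    target region overlaps every already-kept region by at most
    ``max_overlap`` of the shorter region.
    """
    chosen: list[tuple[PrimerPair, dict[str, AmpliconPrediction]]] = []
    for item in sorted(pairs, key=rank_key):
        pair = item[0]
        region = (pair.target_start, pair.target_end)
        if all(
            overlap_fraction(region, (c.target_start, c.target_end)) <= max_overlap
            for c, _ in chosen
        ):
            chosen.append(item)
    return chosen


def tail_compatibility(
    pair: PrimerPair,
    tails: list[SequencingTail],
    model: thermo.ThermoModel,
    threshold: float = -11.0,
    cap: int = 64,
) -> list[str]:
    """Names of tails whose attachment keeps the pair dimer-safe.

    A tail is compatible iff the two tailed primers (tail + primer) still
    pass the homo-/heterodimer screen at ``threshold``.
    """
    out = []
    for tail in tails:
        tf = attach_tail(pair.fwd.seq, tail.forward)
        tr = attach_tail(pair.rev.seq, tail.reverse)
        if thermo.dimer_screen(tf, tr, model, threshold=threshold, cap=cap).passed:
            out.append(tail.name)
    return out


def recommend_annealing(pair: PrimerPair, offset: float = 3.0) -> float:
    """Suggested constant annealing temperature for a pair (°C).

    The weaker primer limits annealing: min over both primers of the
    coolest-expansion Tm, minus a safety ``offset``.
    """
    return min(pair.fwd.tm_lo, pair.rev.tm_lo) - offset


@dataclass
class MarkerRecord:
    """One emitted marker: a selected, tail-annotated primer pair."""

    gene_id: str
    pair_id: str
    fwd_seq: str
    rev_seq: str
    fwd_tailed: str
    rev_tailed: str
    fwd_degeneracy: int
    rev_degeneracy: int
    total_degeneracy: int
    fwd_tm: tuple[float, float]
    rev_tm: tuple[float, float]
    annealing_c: float
    compatible_tails: list[str]
    mean_p_distance: float
    predictions: dict[str, AmpliconPrediction] = field(default_factory=dict)
    secondary_risk: bool = False


_TABLE_COLUMNS = [
    "gene_id", "pair_id", "fwd_primer", "rev_primer",
    "fwd_tailed", "rev_tailed", "fwd_d", "rev_d", "total_d",
    "fwd_tm_min", "fwd_tm_max", "rev_tm_min", "rev_tm_max",
    "annealing_c", "compatible_tails", "mean_p_distance", "secondary_risk",
    "target_len_bp", "product_len_bp", "exonic_bp", "intronic_bp",
]


def marker_table(records: list[MarkerRecord]) -> pd.DataFrame:
    """Long-format marker table: one row per record per reference genome."""
    rows = []
    for rec in records:
        base = {
            "gene_id": rec.gene_id,
            "pair_id": rec.pair_id,
            "fwd_primer": rec.fwd_seq,
            "rev_primer": rec.rev_seq,
            "fwd_tailed": rec.fwd_tailed,
            "rev_tailed": rec.rev_tailed,
            "fwd_d": rec.fwd_degeneracy,
            "rev_d": rec.rev_degeneracy,
            "total_d": rec.total_degeneracy,
            "fwd_tm_min": round(rec.fwd_tm[0], 1),
            "fwd_tm_max": round(rec.fwd_tm[1], 1),
            "rev_tm_min": round(rec.rev_tm[0], 1),
            "rev_tm_max": round(rec.rev_tm[1], 1),
            "annealing_c": round(rec.annealing_c, 1),
            "compatible_tails": ",".join(rec.compatible_tails),
            "mean_p_distance": round(rec.mean_p_distance, 4),
            "secondary_risk": rec.secondary_risk,
        }
        if rec.predictions:
            for gid, pred in sorted(rec.predictions.items()):
                rows.append(
                    base
                    | {
                        "genome": gid,
                        "target_len_bp": pred.target_len,
                        "product_len_bp": pred.product_len,
                        "exonic_bp": pred.exonic_bp,
                        "intronic_bp": pred.intronic_bp,
                    }
                )
        else:
            rows.append(base)
    cols = _TABLE_COLUMNS[:2] + ["genome"] + _TABLE_COLUMNS[2:]
    df = pd.DataFrame(rows)
    return df.reindex(columns=[c for c in cols if c in df.columns])
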