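"""End-to-end marker design: alignments + genomes in, marker table out.

Stage order per gene: back-translate (when protein alignments are the
input) → conserved-window scan → pair formation → per-genome validation
(binding sites, exon/intron boundaries, target-length bounds, intron/exon
accounting) → secondary-product screen → overlap-limited selection →
sequencing-tail compatibility → table emission. Per-gene failures are
quarantined: a malformed gene is reported and skipped, never fatal.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import io as opio
from . import markers as mk
from . import thermo
from .codon import CodonAlignment, backtranslate, p_distance_matrix
from .design import DesignParams, PrimerPair, form_pairs, scan_gene
from .genome import AmpliconPrediction, Rejection, secondary_product_screen, validate_pair

log = logging.getLogger("orthoprimer")


@dataclass
class RunConfig:
    """Fully serializable description of one design run."""

    alignments_dir: str  # <gene>.prot.fasta protein alignments
    cds_dir: str  # <gene>.cds.fasta unaligned coding sequences
    genomes_dir: str  # <taxon>.fasta + <taxon>.gff3
    out_dir: str
    params: DesignParams = field(default_factory=DesignParams)
    tails_path: str | None = None  # None: bundled catalog
    max_overlap: float = 0.5
    annealing_offset: float = 3.0
    require_all_genomes: bool = True
    seed: int = 0
    genetic_code: int = 1

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        params = DesignParams(**data.pop("params", {}))
        return cls(params=params, **data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GeneResult:
    gene_id: str
    n_sites: int = 0
    n_pairs: int = 0
    n_validated: int = 0
    n_selected: int = 0
    error: str | None = None
    rejections: dict[str, int] = field(default_factory=dict)


@dataclass
class DesignResult:
    records: list[mk.MarkerRecord]
    per_gene: list[GeneResult]
    table: "object"  # pandas DataFrame

    @property
    def counts(self) -> dict[str, int]:
        return {
            "genes": len(self.per_gene),
            "sites": sum(g.n_sites for g in self.per_gene),
            "pairs": sum(g.n_pairs for g in self.per_gene),
            "validated": sum(g.n_validated for g in self.per_gene),
            "selected": sum(g.n_selected for g in self.per_gene),
        }


def design_gene(
    gene_id: str,
    aln: CodonAlignment,
    genomes: dict[str, dict[str, str]],
    gene_models: dict[str, dict[str, "object"]],
    params: DesignParams,
    model: thermo.ThermoModel,
    tails: list[mk.SequencingTail],
    max_overlap: float = 0.5,
    annealing_offset: float = 3.0,
    require_all_genomes: bool = True,
) -> tuple[list[mk.MarkerRecord], GeneResult]:
    """Run the scan→pair→validate→select→tail stages for one gene."""
    res = GeneResult(gene_id=gene_id)
    sites = scan_gene(aln, params, model, gene_id=gene_id)
    res.n_sites = len(sites)
    pairs = form_pairs(sites, params, model)
    res.n_pairs = len(pairs)

    taxon_row = {t: aln.rows[i] for i, t in enumerate(aln.ids)}
    validated: list[tuple[PrimerPair, dict[str, AmpliconPrediction]]] = []
    for pair in pairs:
        preds: dict[str, AmpliconPrediction] = {}
        ok = True
        for taxon in sorted(genomes):
            gm = gene_models[taxon].get(gene_id)
            out = validate_pair(
                pair, taxon_row[taxon], gm, genomes[taxon], params,
                genome_id=taxon,
            )
            if isinstance(out, Rejection):
                res.rejections[out.reason] = res.rejections.get(out.reason, 0) + 1
                ok = False
                if require_all_genomes:
                    break
            else:
                preds[taxon] = out
        if (ok or not require_all_genomes) and preds:
            validated.append((pair, preds))
    res.n_validated = len(validated)

    selected = mk.select_per_gene(validated, max_overlap=max_overlap)
    res.n_selected = len(selected)

    records: list[mk.MarkerRecord] = []
    for nn, (pair, preds) in enumerate(selected, start=1):
        compatible = mk.tail_compatibility(
            pair, tails, model,
            threshold=params.dimer_threshold, cap=params.dimer_enum_cap,
        )
        risky = any(
            secondary_product_screen(
                pair, genomes[t], params,
                intended=(preds[t].contig, preds[t].product_start, preds[t].product_end),
            ).risky
            for t in preds
        )
        tail = next(
            (t for t in tails if t.name in compatible), None
        )
        code = tail.code if tail else "x"
        tail_f = tail.forward if tail else ""
        tail_r = tail.reverse if tail else ""
        preds_tailed = {
            t: dataclasses.replace(p, tail_lengths=(len(tail_f), len(tail_r)))
            for t, p in preds.items()
        }
        region_rows = [
            row[pair.target_start : pair.target_end] for row in aln.rows
        ]
        _, mean_p = p_distance_matrix(region_rows, ids=aln.ids)
        rec = mk.MarkerRecord(
            gene_id=gene_id,
            pair_id=f"{gene_id}_{nn:02d}_{code}",
            fwd_seq=pair.fwd.seq,
            rev_seq=pair.rev.seq,
            fwd_tailed=mk.attach_tail(pair.fwd.seq, tail_f),
            rev_tailed=mk.attach_tail(pair.rev.seq, tail_r),
            fwd_degeneracy=pair.fwd.degeneracy,
            rev_degeneracy=pair.rev.degeneracy,
            total_degeneracy=pair.total_degeneracy,
            fwd_tm=(pair.fwd.tm_lo, pair.fwd.tm_hi),
            rev_tm=(pair.rev.tm_lo, pair.rev.tm_hi),
            annealing_c=mk.recommend_annealing(pair, offset=annealing_offset),
            compatible_tails=compatible,
            mean_p_distance=mean_p,
            predictions=preds_tailed,
            secondary_risk=risky,
        )
        records.append(rec)
    return records, res


def run_design(config: RunConfig) -> DesignResult:
    """Execute a full design run from a :class:`RunConfig`.

    Writes ``markers.tsv``, ``per_gene_counts.tsv`` and the resolved
    ``config.yaml`` into ``config.out_dir``; reruns with the same inputs and
    config are byte-identical.
    """
    model = thermo.ThermoModel()
    tails = mk.load_tails(config.tails_path)
    taxa = opio.discover_taxa(config.genomes_dir)
    genomes = {
        t: dict(opio.read_fasta(os.path.join(config.genomes_dir, f"{t}.fasta")))
        for t in taxa
    }
    gene_models = {
        t: opio.read_gene_models(os.path.join(config.genomes_dir, f"{t}.gff3"))
        for t in taxa
    }
    genes = opio.discover_genes(config.alignments_dir)

    all_records: list[mk.MarkerRecord] = []
    per_gene: list[GeneResult] = []
    for gene in genes:
        try:
            proteins = opio.read_fasta(
                os.path.join(config.alignments_dir, f"{gene}.prot.fasta")
            )
            cds = dict(
                opio.read_fasta(os.path.join(config.cds_dir, f"{gene}.cds.fasta"))
            )
            aln = backtranslate(proteins, cds, genetic_code=config.genetic_code)
            records, res = design_gene(
                gene, aln, genomes, gene_models, config.params, model, tails,
                max_overlap=config.max_overlap,
                annealing_offset=config.annealing_offset,
                require_all_genomes=config.require_all_genomes,
            )
        except Exception as exc:
            log.error("gene %s quarantined: %s", gene, exc)
            per_gene.append(GeneResult(gene_id=gene, error=str(exc)))
            continue
        log.info(
            "gene %s: %d sites, %d pairs, %d validated, %d selected",
            gene, res.n_sites, res.n_pairs, res.n_validated, res.n_selected,
        )
        all_records.extend(records)
        per_gene.append(res)

    table = mk.marker_table(all_records)
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        table.to_csv(
            os.path.join(config.out_dir, "markers.tsv"), sep="\t", index=False
        )
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "sites": g.n_sites,
                    "pairs": g.n_pairs,
                    "validated": g.n_validated,
                    "selected": g.n_selected,
                    "error": g.error or "",
                }
                for g in per_gene
            ]
        ).to_csv(
            os.path.join(config.out_dir, "per_gene_counts.tsv"),
            sep="\t",
            index=False,
        )
        with open(os.path.join(config.out_dir, "config.yaml"), "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return DesignResult(records=all_records, per_gene=per_gene, table=table)
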