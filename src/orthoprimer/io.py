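"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Bio.SeqIO, GFF3 through gffutils (in-memory db), tables
through pandas. Gene models are converted to the package's 0-based half-open
exon intervals at this boundary.
"""

from __future__ import annotations

import glob
import os

import gffutils
import pandas as pd
from Bio import SeqIO

from .genome import GeneModel


class ParseError(ValueError):
    """Malformed input file, with the path (and line, where known)."""


def read_fasta(path: str) -> list[tuple[str, str]]:
    """Ordered (id, sequence) pairs from a FASTA file."""
    try:
        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]
    except Exception as exc:  # Bio raises assorted ValueErrors
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str, records: list[tuple[str, str]], width: int = 70):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_models(path: str) -> dict[str, GeneModel]:
    """Gene models from a GFF3 file: exon features grouped by Parent.

    The Parent may be the gene itself or an mRNA whose Parent is the gene;
    both layouts collapse onto one exon set per gene id.
    """
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc

    parent_gene: dict[str, str] = {}
    for feat in db.features_of_type(("gene", "mRNA", "transcript")):
        if feat.featuretype == "gene":
            parent_gene[feat.id] = feat.id
        else:
            parents = feat.attributes.get("Parent", [feat.id])
            parent_gene[feat.id] = parents[0]

    grouped: dict[str, list] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents:
            raise ParseError(f"{path}: exon without Parent attribute")
        gene = parent_gene.get(parents[0], parents[0])
        grouped.setdefault(gene, []).append(exon)

    models = {}
    for gene, exons in grouped.items():
        seqids = {e.seqid for e in exons}
        strands = {e.strand for e in exons}
        if len(seqids) > 1 or len(strands) > 1:
            raise ParseError(
                f"{path}: gene {gene} has exons on multiple contigs/strands"
            )
        models[gene] = GeneModel(
            gene_id=gene,
            seq_id=seqids.pop(),
            strand=strands.pop(),
            # GFF3 is 1-based inclusive; internal is 0-based half-open
            exons=sorted((e.start - 1, e.end) for e in exons),
        )
    return models


def read_primer_table(path: str) -> pd.DataFrame:
    """Primer-pair TSV with at least ``pair_id``, ``fwd``, ``rev`` columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"pair_id", "fwd", "rev"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def discover_genes(alignments_dir: str) -> list[str]:
    """Gene ids from ``<gene>.prot.fasta`` files, sorted."""
    out = []
    for path in glob.glob(os.path.join(alignments_dir, "*.prot.fasta")):
        out.append(os.path.basename(path)[: -len(".prot.fasta")])
    return sorted(out)


def discover_taxa(genomes_dir: str) -> list[str]:
    """Taxon ids from paired ``<taxon>.fasta`` / ``<taxon>.gff3`` files."""
    out = []
    for path in glob.glob(os.path.join(genomes_dir, "*.fasta")):
        taxon = os.path.basename(path)[: -len(".fasta")]
        if os.path.exists(os.path.join(genomes_dir, f"{taxon}.gff3")):
            out.append(taxon)
    return sorted(out)
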