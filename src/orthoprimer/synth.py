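"""Synthetic ortholog/genome generator with planted primer sites.

Emulates the pipeline's real inputs — per-gene codon alignments of 1:1
orthologs across several reference taxa, plus annotated genome assemblies —
at desk scale, with known ground truth. Each gene descends from a random
root coding sequence; taxa diverge by uniform per-site substitution
(codon-wise, never creating in-frame stops), except inside two planted
primer windows that are kept mutation-free across all taxa and are sampled
to pass the full oligo filter battery. Genomic copies receive GT..AG-bounded
introns at codon boundaries between the windows (optionally *inside* the
forward window, to plant an exon/intron-boundary failure). A truth table
records the planted windows and the expected per-taxon amplicon accounting.

The model deliberately omits indels, codon-usage bias and transition bias:
it exists to exercise filters and accounting, not to imitate real evolution.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from . import iupac, thermo
from .codon import CodonAlignment
from .design import DesignParams, _passes_oligo_filters
from .genome import GeneModel

_STD = CodonTable.unambiguous_dna_by_id[1]
_CODONS = sorted(
    {"".join(p) for p in itertools.product("ACGT", repeat=3)}
    - set(_STD.stop_codons)
)
_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic bundle."""

    n_taxa: int = 9
    n_genes: int = 20
    divergence: float = 0.2  # per-site substitution probability off-window
    window_mutation_prob: float = 0.0  # explicit violation of planted windows
    window_len: int = 22
    flank5_bp: int = 30  # codon multiple; window starts here
    target_bp: int = 312  # exonic distance between the two windows
    flank3_bp: int = 48
    introns_min: int = 1
    introns_max: int = 2
    intron_len_min: int = 45
    intron_len_max: int = 653
    spacer_bp: int = 300
    boundary_genes: tuple[int, ...] = ()  # gene indices with an intron in the fwd window
    seed: int = 0
    params: DesignParams = field(default_factory=DesignParams)

    @property
    def cds_len(self) -> int:
        n = self.flank5_bp + 2 * self.window_len + self.target_bp + self.flank3_bp
        return n + (-n) % 3

    @property
    def fwd_window(self) -> tuple[int, int]:
        return self.flank5_bp, self.flank5_bp + self.window_len

    @property
    def rev_window(self) -> tuple[int, int]:
        s = self.flank5_bp + self.window_len + self.target_bp
        return s, s + self.window_len

    def validate(self):
        if self.rev_window[1] > self.cds_len:
            raise ValueError("planted windows do not fit in the gene")
        if not (
            self.params.primer_len_min <= self.window_len <= self.params.primer_len_max
        ):
            raise ValueError(
                "planted window length outside the designable primer-length bounds"
            )
        if not (
            self.params.amplicon_min <= self.target_bp <= self.params.amplicon_max
        ):
            raise ValueError("planted target span outside the amplicon bounds")
        if not (0 <= self.divergence <= 1):
            raise ValueError("divergence must be a probability")
        if self.intron_len_min < 4:
            raise ValueError("introns must fit GT..AG splice sites")


@dataclass
class FixtureBundle:
    """Everything the pipeline consumes, plus the planted truth."""

    spec: FixtureSpec
    taxa: list[str]
    genes: list[str]
    cds: dict[str, dict[str, str]]  # gene -> taxon -> CDS
    proteins: dict[str, list[tuple[str, str]]]  # gene -> protein alignment rows
    alignments: dict[str, CodonAlignment]  # gene -> codon alignment
    genomes: dict[str, dict[str, str]]  # taxon -> contig -> sequence
    gene_models: dict[str, dict[str, GeneModel]]  # taxon -> gene -> model
    truth: pd.DataFrame

    def write(self, outdir: str):
        """Emit genomes (FASTA), annotations (GFF3), per-gene protein
        alignments and CDS sets (FASTA), and the truth table (TSV)."""
        os.makedirs(os.path.join(outdir, "genomes"), exist_ok=True)
        os.makedirs(os.path.join(outdir, "alignments"), exist_ok=True)
        os.makedirs(os.path.join(outdir, "cds"), exist_ok=True)
        for taxon in self.taxa:
            with open(os.path.join(outdir, "genomes", f"{taxon}.fasta"), "w") as fh:
                for contig, seq in sorted(self.genomes[taxon].items()):
                    fh.write(f">{contig}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i : i + 70] + "\n")
            with open(os.path.join(outdir, "genomes", f"{taxon}.gff3"), "w") as fh:
                fh.write("##gff-version 3\n")
                for gene in self.genes:
                    gm = self.gene_models[taxon][gene]
                    lo, hi = gm.span
                    fh.write(
                        f"{gm.seq_id}\torthoprimer-synth\tgene\t{lo + 1}\t{hi}"
                        f"\t.\t{gm.strand}\t.\tID={gene}\n"
                    )
                    for s, e in gm.exons:
                        fh.write(
                            f"{gm.seq_id}\torthoprimer-synth\texon\t{s + 1}\t{e}"
                            f"\t.\t{gm.strand}\t.\tParent={gene}\n"
                        )
        for gene in self.genes:
            with open(
                os.path.join(outdir, "alignments", f"{gene}.prot.fasta"), "w"
            ) as fh:
                for taxon, row in self.proteins[gene]:
                    fh.write(f">{taxon}\n{row}\n")
            with open(os.path.join(outdir, "cds", f"{gene}.cds.fasta"), "w") as fh:
                for taxon in self.taxa:
                    fh.write(f">{taxon}\n{self.cds[gene][taxon]}\n")
        self.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)


def _random_root(rng: np.random.Generator, n_codons: int) -> list[str]:
    return [_CODONS[i] for i in rng.integers(0, len(_CODONS), size=n_codons)]


def _has_stop(cds: str) -> bool:
    return any(cds[i : i + 3] in _STD.stop_codons for i in range(0, len(cds), 3))


def _sample_primer(
    rng: np.random.Generator,
    length: int,
    params: DesignParams,
    model: thermo.ThermoModel,
) -> str:
    """A concrete primer of the given length passing every oligo filter."""
    for _ in range(100_000):
        seq = "".join(rng.choice(_BASES, size=length))
        if _passes_oligo_filters(seq, params, model)[0]:
            return seq
    raise ValueError(
        f"no {length}-mer satisfying the oligo filters found; "
        "the filter configuration is unsatisfiable"
    )


def _mutate_codon(
    rng: np.random.Generator, codon: str, probs: list[float]
) -> str:
    """Per-site substitution within one codon, rejecting stop codons."""
    if not any(probs):
        return codon
    for _ in range(100):
        out = list(codon)
        for k, p in enumerate(probs):
            if p > 0 and rng.random() < p:
                choices = [b for b in "ACGT" if b != codon[k]]
                out[k] = choices[rng.integers(0, 3)]
        cand = "".join(out)
        if cand not in _STD.stop_codons:
            return cand
    return codon


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Build one seeded, bit-reproducible fixture bundle."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    model = thermo.ThermoModel()
    taxa = [f"taxon{i + 1:02d}" for i in range(spec.n_taxa)]
    genes = [f"g{i + 1:04d}" for i in range(spec.n_genes)]
    fw_lo, fw_hi = spec.fwd_window
    rv_lo, rv_hi = spec.rev_window
    window_pos = set(range(fw_lo, fw_hi)) | set(range(rv_lo, rv_hi))
    n_codons = spec.cds_len // 3

    cds_all: dict[str, dict[str, str]] = {}
    prot_all: dict[str, list[tuple[str, str]]] = {}
    aln_all: dict[str, CodonAlignment] = {}
    gene_seqs: dict[str, dict[str, tuple[str, list[tuple[int, int]]]]] = {}
    truth_rows = []

    for gi, gene in enumerate(genes):
        # root CDS with planted, filter-passing windows
        while True:
            root = _random_root(rng, n_codons)
            fwd_primer = _sample_primer(rng, spec.window_len, spec.params, model)
            rev_primer = _sample_primer(rng, spec.window_len, spec.params, model)
            if abs(
                _tm_mid(fwd_primer, model) - _tm_mid(rev_primer, model)
            ) > spec.params.max_dtm:
                continue
            if not thermo.dimer_screen(
                fwd_primer, rev_primer, model,
                threshold=spec.params.dimer_threshold,
            ).passed:
                continue
            seq = list("".join(root))
            seq[fw_lo:fw_hi] = fwd_primer
            seq[rv_lo:rv_hi] = iupac.reverse_complement(rev_primer)
            cand = "".join(seq)
            if not _has_stop(cand):
                root_cds = cand
                break

        # taxa: per-site substitution outside the windows, codon-wise
        per_taxon: dict[str, str] = {}
        for taxon in taxa:
            out = []
            for c in range(n_codons):
                codon = root_cds[3 * c : 3 * c + 3]
                probs = [
                    spec.window_mutation_prob
                    if 3 * c + k in window_pos
                    else spec.divergence
                    for k in range(3)
                ]
                out.append(_mutate_codon(rng, codon, probs))
            per_taxon[taxon] = "".join(out)
        cds_all[gene] = per_taxon
        prot_all[gene] = [
            (t, _translate(per_taxon[t])) for t in taxa
        ]
        aln_all[gene] = CodonAlignment(ids=list(taxa), rows=[per_taxon[t] for t in taxa])

        # intron structure: positions shared across taxa, lengths per taxon
        boundary = gi in spec.boundary_genes
        n_introns = int(rng.integers(spec.introns_min, spec.introns_max + 1))
        target_positions = sorted(
            int(p)
            for p in rng.choice(
                np.arange(fw_hi + (-fw_hi) % 3, rv_lo - 2, 3),
                size=n_introns,
                replace=False,
            )
        )
        positions = list(target_positions)
        if boundary:
            # one extra intron at a codon boundary inside the forward window
            inside = np.arange(fw_lo + 3 - fw_lo % 3 if fw_lo % 3 else fw_lo + 3, fw_hi - 1, 3)
            positions = sorted(positions + [int(rng.choice(inside))])

        gene_seqs[gene] = {}
        for taxon in taxa:
            while True:
                lens = {
                    pos: int(
                        rng.integers(spec.intron_len_min, spec.intron_len_max + 1)
                    )
                    for pos in positions
                }
                target_intronic = sum(lens[p] for p in target_positions)
                if spec.target_bp + target_intronic <= spec.params.amplicon_max:
                    break
            pieces = []
            exons = []
            cursor = 0
            offset = 0
            for pos in positions:
                pieces.append(per_taxon[taxon][cursor:pos])
                exons.append((offset + cursor, offset + pos))
                ilen = lens[pos]
                inner = "".join(rng.choice(_BASES, size=ilen - 4))
                pieces.append("GT" + inner + "AG")
                offset += ilen
                cursor = pos
            pieces.append(per_taxon[taxon][cursor:])
            exons.append((offset + cursor, offset + len(per_taxon[taxon])))
            gene_seqs[gene][taxon] = ("".join(pieces), exons)
            truth_rows.append(
                {
                    "gene": gene,
                    "taxon": taxon,
                    "fwd_primer": fwd_primer,
                    "rev_primer": rev_primer,
                    "fwd_start": fw_lo,
                    "fwd_end": fw_hi,
                    "rev_start": rv_lo,
                    "rev_end": rv_hi,
                    "target_span": rv_lo - fw_hi,
                    "n_introns": len(positions),
                    "target_intronic_bp": sum(lens[p] for p in target_positions),
                    "target_genomic_len": spec.target_bp
                    + sum(lens[p] for p in target_positions),
                    "boundary": boundary,
                }
            )

    # assemble one contig per taxon, genes in order with random spacers
    genomes: dict[str, dict[str, str]] = {}
    models: dict[str, dict[str, GeneModel]] = {}
    for taxon in taxa:
        parts = []
        cursor = 0
        models[taxon] = {}
        for gene in genes:
            spacer = "".join(rng.choice(_BASES, size=spec.spacer_bp))
            parts.append(spacer)
            cursor += spec.spacer_bp
            gseq, exons = gene_seqs[gene][taxon]
            models[taxon][gene] = GeneModel(
                gene_id=gene,
                seq_id="chr1",
                strand="+",
                exons=[(s + cursor, e + cursor) for s, e in exons],
            )
            parts.append(gseq)
            cursor += len(gseq)
        parts.append("".join(rng.choice(_BASES, size=spec.spacer_bp)))
        genomes[taxon] = {"chr1": "".join(parts)}

    return FixtureBundle(
        spec=spec,
        taxa=taxa,
        genes=genes,
        cds=cds_all,
        proteins=prot_all,
        alignments=aln_all,
        genomes=genomes,
        gene_models=models,
        truth=pd.DataFrame(truth_rows),
    )


def _translate(cds: str) -> str:
    return "".join(
        _STD.forward_table.get(cds[i : i + 3], "X") for i in range(0, len(cds), 3)
    )


def _tm_mid(seq: str, model: thermo.ThermoModel) -> float:
    return thermo.tm_concrete(seq, model)
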