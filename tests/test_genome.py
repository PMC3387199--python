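"""Binding-site search, pair validation, intron/exon accounting, secondary
product screening."""

import numpy as np
import pytest

from orthoprimer import iupac
from orthoprimer.design import CandidateSite, DesignParams, PrimerPair
from orthoprimer.genome import (
    BindingSite,
    GeneModel,
    GeneModelMissingError,
    Rejection,
    find_binding_sites,
    secondary_product_screen,
    validate_pair,
)

FWD = "ACTGGATCGTACCAGTTCGA"  # concrete 20-mers used as planted primers
REV = "TCAGACCCCACCACATTTTG"


def random_genome(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def naive_sites(primer, genome, max_mismatch):
    """Brute-force oracle: sliding IUPAC comparison on both strands."""
    out = []
    pats = {"+": primer, "-": iupac.reverse_complement(primer)}
    for contig in sorted(genome):
        seq = genome[contig]
        for strand, pat in pats.items():
            for pos in range(len(seq) - len(pat) + 1):
                mm = sum(
                    seq[pos + i] not in iupac.IUPAC_SETS[pat[i]]
                    for i in range(len(pat))
                )
                if mm <= max_mismatch:
                    out.append(BindingSite(contig, pos, strand, mm))
    out.sort(key=lambda s: (s.contig, s.position, s.strand))
    return out


def test_planted_unique_site(model):
    rng = np.random.default_rng(0)
    g = random_genome(rng, 3000)
    genome = {"c1": g[:1500] + FWD + g[1500:]}
    sites = [s for s in find_binding_sites(FWD, genome) if s.primary]
    assert len(sites) == 1
    assert sites[0].position == 1500 and sites[0].strand == "+"


def test_degenerate_primer_finds_both_expansions():
    primer = "AY" + FWD  # expansions AC+FWD and AT+FWD
    rng = np.random.default_rng(1)
    g = random_genome(rng, 2000)
    genome = {"c1": g + "AC" + FWD + g[:100] + "AT" + FWD + g[:50]}
    primary = [s for s in find_binding_sites(primer, genome) if s.primary]
    assert len(primary) == 2


def test_find_binding_sites_matches_naive_scan():
    rng = np.random.default_rng(2)
    genome = {
        "a": random_genome(rng, 4000),
        "b": random_genome(rng, 2500),
    }
    for mm in (0, 1, 2):
        primer = "".join(rng.choice(list("ACGTRY"), size=12))
        assert find_binding_sites(primer, genome, mm) == naive_sites(
            primer, genome, mm
        )


def test_site_finding_strand_symmetric():
    rng = np.random.default_rng(3)
    genome = {"c": random_genome(rng, 3000) + FWD + random_genome(rng, 100)}
    flipped = {"c": iupac.reverse_complement(genome["c"])}
    a = find_binding_sites(FWD, genome, 1)
    b = find_binding_sites(FWD, flipped, 1)
    assert len(a) == len(b)
    n = len(genome["c"]) - len(FWD)
    expect = sorted(
        (s.contig, n - s.position, "-" if s.strand == "+" else "+", s.mismatches)
        for s in a
    )
    got = sorted((s.contig, s.position, s.strand, s.mismatches) for s in b)
    assert got == expect


def test_gene_model_validation_and_mapping():
    with pytest.raises(ValueError, match="overlapping"):
        GeneModel("g", "c", "+", [(0, 100), (50, 150)])
    gm = GeneModel("g", "c", "+", [(10, 40), (140, 200)])
    assert gm.cds_len == 90
    assert gm.cds_interval_to_genome(0, 30) == [(10, 40)]
    assert gm.cds_interval_to_genome(30, 40) == [(140, 150)]
    assert gm.cds_interval_to_genome(25, 35) == [(35, 40), (140, 145)]
    assert gm.exonic_bp(0, 1000) == 90
    with pytest.raises(ValueError):
        gm.cds_interval_to_genome(80, 95)


def test_gene_model_minus_strand_extraction():
    rng = np.random.default_rng(4)
    cds = random_genome(rng, 60)
    intron = "GT" + random_genome(rng, 50) + "AG"
    # minus-strand gene: genome holds the reverse complement, exon order flips
    plus_gene = cds[:30] + intron + cds[30:]
    contig = random_genome(rng, 20) + iupac.reverse_complement(plus_gene) + random_genome(rng, 20)
    L = len(plus_gene)
    gm = GeneModel(
        "g", "c", "-",
        exons=[(20 + L - (30 + len(intron) + 30), 20 + L - (30 + len(intron))),
               (20 + L - 30, 20 + L)],
    )
    assert gm.extract_cds(contig) == cds


def _pair_for(aln_len, fwd_start, rev_start, fwd=FWD, rev=REV, gene="g"):
    f = CandidateSite(gene, fwd_start, fwd_start + len(fwd), "F", fwd,
                      iupac.degeneracy(fwd), 50.0, 55.0)
    # the plus-strand window holds revcomp(rev); the stored candidate seq is
    # the reverse primer itself, 5'->3'
    r = CandidateSite(gene, rev_start, rev_start + len(rev), "R", rev,
                      iupac.degeneracy(rev), 50.0, 55.0)
    return PrimerPair(gene_id=gene, fwd=f, rev=r, dimer_worst_dG=0.0)


def _build_locus(intron_at=None, intron_len=200, cds_len=600, lead=50):
    """A single-gene locus: CDS with FWD planted at 20, REV-site at 420, one
    optional intron. Returns (cds, genome, gene_model, pair)."""
    rng = np.random.default_rng(7)
    cds = list(random_genome(rng, cds_len))
    cds[20:40] = FWD
    rev_primer_site = iupac.reverse_complement(REV)
    cds[420:440] = rev_primer_site
    cds = "".join(cds)
    if intron_at is None:
        gene = cds
        exons = [(lead, lead + cds_len)]
    else:
        intron = "GT" + random_genome(rng, intron_len - 4) + "AG"
        gene = cds[:intron_at] + intron + cds[intron_at:]
        exons = [(lead, lead + intron_at),
                 (lead + intron_at + intron_len, lead + cds_len + intron_len)]
    contig = random_genome(rng, lead) + gene + random_genome(rng, 60)
    gm = GeneModel("g", "chr", "+", exons)
    pair = _pair_for(cds_len, 20, 420, fwd=FWD, rev=REV)
    return cds, {"chr": contig}, gm, pair


def wide_params():
    return DesignParams(amplicon_min=100, amplicon_max=1000)


def test_validate_pair_intron_accounting():
    cds, genome, gm, pair = _build_locus(intron_at=200, intron_len=200)
    pred = validate_pair(pair, cds, gm, genome, wide_params(), genome_id="t")
    assert not isinstance(pred, Rejection)
    # target region: CDS 40..420 (380 exonic bp) plus the 200 bp intron
    assert pred.target_len == 580
    assert pred.intronic_bp == 200
    assert pred.exonic_bp == 380
    assert pred.product_len == 580 + 20 + 20


def test_validate_pair_intronless():
    cds, genome, gm, pair = _build_locus(intron_at=None)
    pred = validate_pair(pair, cds, gm, genome, wide_params(), genome_id="t")
    assert pred.intronic_bp == 0
    assert pred.exonic_bp == pred.target_len == 380


def test_validate_pair_boundary_rejection():
    # intron inside the forward primer's binding stretch (CDS 20..40)
    cds, genome, gm, pair = _build_locus(intron_at=30)
    out = validate_pair(pair, cds, gm, genome, wide_params(), genome_id="t")
    assert isinstance(out, Rejection)
    assert out.reason == "boundary"


def test_validate_pair_binding_site_mutation_rejected():
    cds, genome, gm, pair = _build_locus(intron_at=None)
    # mutate the genome under the forward primer's 3' terminal base
    contig = list(genome["chr"])
    pos = 50 + 39  # lead + last base of the primer window
    contig[pos] = "A" if contig[pos] != "A" else "C"
    out = validate_pair(
        pair, cds, gm, {"chr": "".join(contig)}, wide_params(), genome_id="t"
    )
    assert isinstance(out, Rejection)
    assert out.reason == "no_binding_site"


def test_validate_pair_length_rejection():
    cds, genome, gm, pair = _build_locus(intron_at=200, intron_len=200)
    out = validate_pair(
        pair, cds, gm, genome, DesignParams(amplicon_min=300, amplicon_max=500)
    )
    assert isinstance(out, Rejection) and out.reason == "length"


def test_validate_pair_missing_gene_model():
    cds, genome, gm, pair = _build_locus()
    with pytest.raises(GeneModelMissingError):
        validate_pair(pair, cds, None, genome, wide_params())


def test_accounting_identity_on_bundle(small_bundle, model, params):
    """exonic + intronic == target on every accepted synthetic amplicon."""
    from orthoprimer.design import form_pairs, scan_gene

    gene = small_bundle.genes[0]
    aln = small_bundle.alignments[gene]
    sites = scan_gene(aln, params, model, gene_id=gene)
    pairs = form_pairs(sites, params, model)
    checked = 0
    for pair in pairs[:30]:
        for i, taxon in enumerate(small_bundle.taxa):
            out = validate_pair(
                pair, aln.rows[i], small_bundle.gene_models[taxon][gene],
                small_bundle.genomes[taxon], params, genome_id=taxon,
                tail_lengths=(18, 18),
            )
            if isinstance(out, Rejection):
                continue
            assert out.exonic_bp + out.intronic_bp == out.target_len
            assert out.product_len == out.target_len + len(pair.fwd.seq) + len(
                pair.rev.seq
            ) + 36
            checked += 1
    assert checked > 0


def test_secondary_screen_planted_convergent_pair():
    rng = np.random.default_rng(9)
    g = random_genome(rng, 1500)
    # intended locus plus one extra convergent copy 800 bp downstream
    contig = (
        g[:200] + FWD + g[200:600] + iupac.reverse_complement(REV)
        + g[600:800] + FWD + g[800:1500] + iupac.reverse_complement(REV)
    )
    pair = _pair_for(0, 0, 0)
    intended_start = 200
    intended_end = 200 + 20 + 400 + 20
    report = secondary_product_screen(
        pair, {"c": contig}, DesignParams(),
        intended=("c", intended_start, intended_end),
    )
    assert len(report.products) >= 1
    # the planted extra pair is among the reported products
    starts = {(p.start, p.end) for p in report.products}
    extra_start = 200 + 20 + 400 + 20 + 200
    assert any(s == extra_start for s, _ in starts)


def test_secondary_screen_single_locus_clean():
    rng = np.random.default_rng(10)
    g = random_genome(rng, 1200)
    contig = g[:300] + FWD + g[300:700] + iupac.reverse_complement(REV) + g[700:]
    pair = _pair_for(0, 0, 0)
    report = secondary_product_screen(
        pair, {"c": contig}, DesignParams(),
        intended=("c", 300, 300 + 20 + 400 + 20),
        max_mismatch=0,
    )
    assert report.products == []
    assert not report.risky
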