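# orthoprimer

Degenerate PCR primer design for amplifying **single-copy nuclear
protein-coding genes across divergent taxa** — the workflow behind
genome-derived phylogenetic marker panels (e.g. cross-species panels for
apocritan Hymenoptera built from nine reference genomes).

Targeted PCR of 1:1 orthologs remains the cheapest way to collect multi-gene
data from museum and field specimens. Given codon alignments of single-copy
orthologs and annotated reference genomes, `orthoprimer`:

1. **scans** each alignment for conserved windows and writes the minimal
   IUPAC consensus of every window — the *degeneracy*
   `d = ∏ᵢ |code(i)|` (the number of concrete oligos in the synthesized
   pool) operationalizes conservation;
2. **filters** candidates with the standard oligo battery — `d ≤ 256`,
   GC ∈ [20, 80] % over *every* expansion, mononucleotide runs ≤ 4,
   3′-terminal hexamer rules (`d ≤ 4`, GC ∈ [20, 80] %, run ≤ 3), and a
   nearest-neighbor melting temperature window of 45–66 °C
   (SantaLucia unified parameters, 50 mM Na⁺, 0.8 µM oligo);
3. **pairs** forward/reverse candidates with target length 300–1000 bp,
   ΔTm ≤ 10 °C, and a homo-/heterodimer screen at ΔG(37 °C) ≥ −11 kcal/mol
   (best ungapped antiparallel helix, stacking + initiation terms);
4. **validates** each pair against every reference genome: primers whose
   binding stretch straddles an exon/intron boundary are discarded, the
   genomic target length is bounded, and each accepted amplicon gets exact
   exonic/intronic nucleotide accounting from the gene models plus a
   secondary-product risk screen from approximate binding sites;
5. **selects** per-gene marker sets (amplicon overlap ≤ 50 %), attaches
   universal 5′ sequencing tails (HOG-Seq A–D) where dimer-compatible,
   reports mean pairwise uncorrected p-distance of each target region, and
   recommends an annealing temperature.

A seeded synthetic-data generator (`orthoprimer.synth`) builds ortholog
bundles and annotated mini-genomes with *planted* primer windows and known
intron truth, so the whole pipeline is testable without downloads.

## Worked example

Generate a synthetic study (9 taxa, 3 genes, 20 % background divergence)
and design markers for it:

```bash
orthoprimer fixtures --out demo --taxa 9 --genes 3 --divergence 0.2 --seed 42
orthoprimer design --alignments demo/alignments --cds demo/cds \
                   --genomes demo/genomes --out demo/run --seed 42
# designed 3 marker pair(s) from 3 gene(s)
#   (320 candidate sites, 2507 raw pairs, 2507 validated)
```

`demo/run/markers.tsv` holds one row per marker per reference genome:

```text
pair_id    genome  total_d annealing_c target_len_bp product_len_bp exonic_bp intronic_bp mean_p_distance
g0001_01_A taxon01       1        55.0           730            806       313         417          0.3294
g0001_01_A taxon02       1        55.0           554            630       313         241          0.3294
g0002_01_A taxon01       1        56.7           501            577       314         187          0.3421
```

Reading the first row: the selected pair for gene `g0001` is concrete
(pool size `total_d = 1` — the planted windows are conserved), its genomic
target region in `taxon01` is 730 bp of which 313 bp are exonic and 417 bp
intronic (`exonic + intronic = target`), and the full PCR product is
806 bp = 730 + 20 + 20 (primers) + 18 + 18 (HOG-Seq-A tails). The mean
uncorrected p-distance of the target region across the nine taxa is 32.9 %,
and a constant-annealing protocol at 55 °C is suggested.

Re-validating an external primer table (here the bundled, empirically
evaluated panel) against every filter:

```bash
orthoprimer check-primers --primers src/orthoprimer/data/evaluated_primers.tsv
# pair_id    fwd_d  fwd_tm_max  fwd_pass  total_d
# 3683_01_A     32        56.8      True      384
# 4652_02_A     24        53.9      True      384
# 4747_02_A      6        53.0      True      108
```

Library use mirrors the CLI: `scan_gene`, `form_pairs`, `validate_pair`,
`select_per_gene`, `run_design` are all importable from `orthoprimer`.

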