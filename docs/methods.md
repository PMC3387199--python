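# Methods

## Problem and model

`orthoprimer` designs degenerate oligonucleotide primer pairs that amplify
the same single-copy nuclear gene in many divergent species at once. The
input is, per gene, a codon-aware nucleotide alignment of 1:1 orthologs
(built by projecting a protein multiple alignment onto the coding
sequences), plus one annotated genome per reference taxon. The output is a
per-gene set of primer pairs with per-genome amplicon predictions.

A degenerate primer is a string over the 15-letter IUPAC nucleotide
alphabet; it denotes the pool of all concrete oligos obtained by choosing
one base per position. Its *degree of degeneration* `d` is the product of
the per-position code cardinalities and equals the pool size. The design
principle is: take the **minimal** IUPAC consensus of an alignment window
(the smallest code containing the union of observed bases per column) so
that every taxon's sequence is a member of the pool, and let the degeneracy
cap do the work of defining "conserved" — divergent windows explode
combinatorially and fall off the cap. No separate percent-identity
threshold exists. Columns containing a gap or an ambiguity code in any row
cannot anchor a primer and void every window that covers them.

## Filter battery and defaults

Per oligo (applied to the primer in its own 5′→3′ reading, so the
3′-terminal rules hit the extension end in both orientations):

| parameter | default |
|---|---|
| primer length | 20–25 nt |
| degeneracy `d` | ≤ 256 |
| GC content | 20–80 % |
| mononucleotide run | ≤ 4 |
| 3′ hexamer: `d` / GC / run | ≤ 4 / 20–80 % / ≤ 3 |
| melting temperature | 45–66 °C |

Per pair: target region (between the primers, alignment-implied, then
re-checked per genome) 300–1000 bp; Tm-midpoint difference ≤ 10 °C;
homo- and heterodimer ΔG(37 °C) ≥ −11.0 kcal/mol. The per-primer degeneracy
cap is the only degeneracy filter; the pair total is uncapped.

Interpretation choices for degenerate pools, all configurable:

* **GC rule** passes only if the *entire* range of GC over expansions lies
  inside the window (every synthesized oligo must be usable); an "overlap"
  semantics is available (`gc_semantics="overlap"`).
* **Run rule** is worst-case over expansions (a single bad expansion can
  still prime); computed in closed form as the longest stretch of
  consecutive codes all containing one base.
* **Tm rule** requires the whole `[Tm_min, Tm_max]` range inside the
  window; the pairing ΔTm uses range midpoints.
* GC and run bounds are exact without enumeration; both are verified
  against brute-force enumeration in the tests.

## Thermodynamics

Melting temperatures use the unified nearest-neighbor parameter set
(shipped as `data/nn_unified.tsv`): `Tm = 1000·ΔH / (ΔS + ΔS_salt + R·ln C)
− 273.15`, with per-end initiation terms, `ΔS_salt = 0.368·(N−1)·ln[Na⁺]`,
`C = C_T/4` for non-self-complementary duplexes, 50 mM Na⁺ and 0.8 µM oligo
(a standard multiplex-PCR primer concentration). `Tm` of a degenerate
primer is the min/max over its expansions — exact by enumeration up to a
cap (default 1024), otherwise bounded by four AT-/GC-extreme expansions.
The heuristic bound is always *contained* in the true range (its members
are real expansions) and the low end, which drives the Tm filter, tracks
the true minimum closely; it can under-cover the high end by a few tenths
of a degree on highly degenerate oligos.

Dimer risk is scored as the most favorable **ungapped antiparallel helix**
between two oligos: every relative offset is scanned and every maximal
contiguous Watson-Crick-paired stretch is scored as the sum of its stacking
ΔG(37 °C) terms plus the two helix-initiation end terms. Disjoint paired
stretches at one offset are separate helices; bulges, internal loops,
mismatch stabilization and dangling ends are not modeled. This is a
deliberate simplification of a full secondary-structure computation — it is
deterministic, exactly reproducible by a brute-force loop (the test
oracle), and discriminates well at the −11 kcal/mol screening threshold:
random filtered 20-mers pass at high rates while any ≳9 bp contiguous
complementary stretch fails. Degenerate pairs are screened over all
expansion combinations up to a cap (default 64), beyond which extreme-GC
representative expansions stand in. Hairpin self-structure is not screened;
the dimer machinery leaves an obvious extension point for it.

## Genome validation and amplicon accounting

Candidate coordinates live on the codon alignment; each genome's alignment
row maps columns to CDS positions, and the gene model (ordered exon
intervals, 0-based half-open internally, GFF3 converted at I/O) maps CDS
intervals to the genome. A primer whose CDS interval maps to more than one
genomic piece straddles an exon/intron junction and cannot bind contiguous
genomic DNA: the pair is rejected (`boundary`). The genomic sequence under
each single-exon placement must be an expansion of the primer
(`no_binding_site` otherwise — this is what rejects pairs whose binding
site was mutated in a genome), the two placements must converge
(`orientation`), and the genomic target region between them must stay
within the amplicon bounds (`length`). The 300–1000 bp bound applies to the
**target region**; the full product additionally carries both primers and
any 5′ tails and may exceed it. Accepted pairs report exonic and intronic
nucleotide counts from the source gene's model (`exonic + intronic ==
target` is asserted everywhere); genes overlapping on the other strand are
ignored.

Secondary products are assessed from approximate binding sites: both
primers are matched genome-wide with ≤ k mismatches (default 2, IUPAC-aware
on both strands, vectorized bit-mask scan verified against a naive sliding
comparison), a site only counts if its 3′-terminal m bases (default 6)
match perfectly, and every convergent same-contig site pair implying a
product ≤ 3000 bp other than the intended one is reported. These three
defaults are assumptions — the screening tolerances of the original
workflow are not published — and are configurable.

## Marker selection, tails, annealing

Within a gene, validated pairs are ranked by ascending total degeneracy
(cheaper, less ambiguous pools first), ties broken by descending mean
intronic content (intron-rich amplicons carry the fast-evolving sites such
panels exist for), then by position; greedy selection admits a pair iff its
target region overlaps every already-selected region by ≤ 50 % of the
shorter one. The ranking criterion is this package's own choice (the
selection rule used for the original panel is unpublished) and is pluggable
(`rank_key`). A sequencing tail (catalog of four concrete 18–20-nt pairs,
`data/sequencing_tails.tsv`) is compatible with a pair iff both tailed
primers still pass the dimer screen; pairs are named
`<gene>_<nn>_<tail letter>`. The recommended annealing temperature is
`min(Tm_min over both primers) − 3 °C` — invented plumbing for
constant-annealing protocols, not a reproduction of published values.
Divergence of each marker is summarized as the mean pairwise uncorrected
p-distance over the target region columns (sites with a gap or ambiguity in
either row are excluded from numerator and denominator; the target region
between the primers is used, primer sites excluded — an interpretation, as
the original computation's exact span is unstated).

## Synthetic data generator

`orthoprimer.synth.generate` emulates the real inputs at desk scale. Per
gene: a random root CDS (uniform non-stop codons) receives two planted
concrete windows sampled to pass the entire oligo battery plus the pair
constraints; taxa descend from the root by uniform per-site substitution
(default 20 % per site, codon-wise with stop-codon rejection), with the
planted windows kept mutation-free unless `window_mutation_prob` explicitly
violates them. Genomic copies insert GT..AG-bounded introns (1–2 per gene,
positions shared across taxa at codon boundaries between the windows,
lengths drawn per taxon uniform in [45, 653] bp — the intronic range
observed in real amplicons of such panels) and are concatenated into one
contig per taxon with 300 bp random spacers. Intron length sets are
rejection-sampled so the genomic target stays within the 1000 bp amplicon
cap — the generator's contract is that planted loci are amplifiable, and
the truth table records the expected per-taxon intronic bp against which
the pipeline is checked. `boundary_genes` plants one extra intron *inside*
the forward window to create known exon/intron-boundary failures. Defaults
(9 taxa, 20 genes, 22-nt windows, 312 bp exonic target span) are the
reference study conditions used by the acceptance suite.

The generator deliberately omits indels (generated protein alignments are
gap-free; gap handling in back-translation is exercised by hand-built
fixtures), codon-usage and transition bias, intron position turnover, and
paralogy. Passing tests therefore demonstrate correctness of the filters,
mapping and accounting — not robustness to alignment error or gene-model
error in real annotations. Note that with 20 % per-site divergence from the
root, *pairwise* p-distance is ≈ 34.7 % (`2p(1−p) + ⅔p²`), which is what
the marker tables report on synthetic data.

## Numerical and interface choices

* Coordinates: 0-based half-open everywhere internally; GFF3 (1-based
  inclusive) converted at the I/O boundary only.
* Scan windows slide with 1-nt step over every admissible length; output
  order is deterministic (position, then length, then orientation), and all
  randomness in the generator sits behind one seeded `numpy` generator —
  equal seeds give byte-identical bundles and marker tables.
* The per-column consensus/cardinality is precomputed once per alignment;
  a window stops extending as soon as a gap column or an over-cap product
  is reached (both persist rightward).
* The duplex scan is vectorized (padded sliding-window match matrix) and
  memoized per model under a canonical symmetric key; equality with the
  explicit-loop implementation is asserted in the tests.
* Back-translation requires each CDS to translate to its ungapped protein
  row (standard code by default, configurable); `X` accepts any codon —
  which also covers selenocysteine sites recoded to `X` upstream — and a
  terminal stop codon is trimmed. Mismatches fail loudly with taxon and
  position; per-gene failures in a pipeline run are quarantined, not fatal.
* A pair is accepted only if it validates in **all** reference genomes
  (`require_all_genomes=False` relaxes this).
* Genomes are scanned in memory; assemblies are chunk-streamed at read
  time but no index structures (suffix arrays etc.) are built — desk-scale
  genomes are the design point.

## Known limitations

Dimer screening ignores loops and mismatches; degenerate pools above the
enumeration caps are represented by extreme expansions, so rare
mid-pool dimers or Tm outliers can escape the screen; the Tm model is one
defensible convention among several and printed Tm values of external
panels are reproduced only approximately; marker ranking and annealing
recommendation are conventions, not reproductions. Scaling to thousands of
ortholog groups is linear but single-threaded.
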