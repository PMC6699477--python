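# Methods

Models, parameter values, and numerical choices used by `endofootprint`.
Nothing here is an empirical claim about real genomes; all numbers quoted are
definitions or measured properties of this code on its own synthetic data.

## Coordinates and genome model

Internally all intervals are 0-based, half-open. GenBank and GFF3 1-based
inclusive coordinates are converted at I/O. Circular genomes are first-class:
a feature or spacer spanning the origin is represented with `end > length`
(reading through the wrap), emitted to GenBank as a compound `join(...)`
location, and split into two intervals for coverage arithmetic.

Genome statistics partition every position into gene-covered (union of all
gene feature intervals, overlaps merged) and intergenic. GC percentages are
computed per partition over A/C/G/T positions (ambiguity codes excluded) and
rounded to one decimal.

Intergenic spacers (IGSs) are the maximal uncovered runs between consecutive
genes, scanning by rightmost gene end so nested/overlapping genes yield no
negative spacers; on a circular genome the run between the last and first
gene wraps the origin.

## Orthology, similarity, trees

- **Protein alignment**: `Bio.Align.PairwiseAligner`, global, BLOSUM62, gap
  open −11 / extend −1. Percent identity counts identical columns over
  aligned columns, excluding terminal-gap columns (so length differences at
  the ends do not depress identity).
- **Orthologs**: reciprocal best hits by alignment score between every genome
  pair, filtered at ≥50% identity and ≥0.5 length coverage (configurable),
  then single-linkage union across pairs. If a component would contain two
  genes of one genome, the higher-scoring gene is kept. Core groups are those
  with a member in every genome.
- **Core similarity**: column-weighted identity of the concatenated core
  protein alignments per genome pair (equivalent to summing identical columns
  over summed aligned columns), one decimal.
- **Tree**: neighbor joining (`skbio.tree.nj`, negative branch lengths
  clamped to zero) on distance = 100 − percent identity; taxa are sorted
  lexicographically first so output is deterministic.
- **Ka/Ks**: Nei–Gojobori (1986). Sequences are codon-aligned by projecting a
  protein alignment back onto the nucleotides (gapped codons dropped,
  terminal stops stripped; internal stops are errors). Synonymous site
  fractions are computed per codon from the translation-table-11 code;
  mutations creating stops count as nonsynonymous, and multi-step pathways
  between differing codons are weighted equally, which preserves
  N_sites + S_sites = aligned nucleotide length. Proportions are
  Jukes–Cantor corrected, d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is reported as
  NaN (saturation) and Ks = 0 yields ratio `None`.

## Phylogenetic footprinting

Orthologous IGSs are spacers flanked by the same ordered pair of ortholog
groups. Orientation is normalized: a genome whose locus is inverted
(flanking pair reversed) contributes its reverse complement, flagged
`flipped`. Flank pairs duplicated within one genome are discarded; a group is
kept only when exactly one spacer per genome matches (all genomes by
default).

Alignment is center-star: the member with the highest summed pairwise
identity to the others is the center (nucleotide scores +1/−1, gap −4/−1);
each member is pairwise-aligned to the center and gap patterns are merged
into a growing master alignment ("once a gap, always a gap"). This is the
declared stand-in for the original aligner; column-level results are
approximate wherever true multiple alignment would differ.

Conserved loci are maximal runs of columns that are gap-free and identical in
every row, of length ≥ 21 (strictly more than 20 nt). Column intervals are
mapped back to genomic coordinates per member via cumulative non-gap offsets
(strand-aware for flipped members). The conserved fraction reported by the
pipeline is conserved nt divided by the mean member length of all analyzed
groups. Spacer-length association between genomes is the squared Pearson
correlation of paired orthologous spacer lengths (defined as 1.0 for exactly
identical vectors, where the estimator is degenerate).

## Regulatory element scanners

- **σ³² promoter**: two-box motif CTTGAAA (−35) and CCCCATNT (−10, N matches
  anything) separated by an 11–15 nt spacer; per-box mismatch budgets default
  to 1 (−35) and 2 (−10). Scanning uses per-position mismatch profiles built
  with numpy lookup tables and enumerates every placement within budget, both
  strands, in deterministic order. Upstream windows are 200 nt on the gene's
  strand, truncated at the nearest upstream gene; genes are first collapsed
  to operons (same strand, intergenic gap ≤ 50 nt, joined across the origin
  on circular genomes) and the window is taken upstream of the operon head,
  so sites are deduplicated across operon members.
- **Shine–Dalgarno**: 5-mer AGGAG at Hamming distance ≤ 1 over conserved-locus
  consensus sequences; hits within 2 nt of each other are merged keeping the
  fewest-mismatch (then leftmost) hit. When a downstream start-codon offset
  is supplied, the SD-to-start distance is reported if ≤ 20 nt.
- **Regulon screen**: case-insensitive `gene_name` match with a substring
  fallback on `product`, optionally propagated through ortholog groups;
  returns the matching gene id per genome × name.

## RNA folding

A simplified Zuker minimum-free-energy model (kcal/mol), intentionally small
rather than a full nearest-neighbor parameter set:

- stacking energies by pair class — GC/CG −3.3, CG/GC −2.4, GC-on-GC
  (other orientations) −2.9, GC–AU −2.1, GC–GU −1.5, AU–AU −1.1, AU–GU −0.5,
  GU–GU −0.4;
- hairpin 4.0 + 0.05·(loop−3), minimum loop 3 nt;
- bulge 3.5 + 0.2·size; internal loop 3.0 + 0.15·(total unpaired);
  bulge/internal unpaired total capped at 10 nt (keeps the DP O(n²·L²) in
  pure Python; larger loops are energetically dominated in practice);
- multiloop: 4.0 closing penalty + 0.4 per branch, unpaired bases free;
- canonical pairs AU/GC/GU; lonely pairs allowed.

The fill computes V (closed), M (multiloop component) and W (exterior)
matrices; the traceback prefers paired options and smaller indices on ties,
so structures are deterministic. An independent loop-decomposition scorer
(`structure_energy`) validates and scores explicit structures and is used by
the tests to check the DP against brute-force enumeration for short
sequences. MFE values are definitions of this model, not predictions
comparable to ViennaRNA/mfold numbers; a conserved locus is an "sRNA
candidate" simply when its MFE < 0.

## qPCR (2^−ΔΔCt)

Per replicate ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the mean control
ΔCt; fold change = 2^−ΔΔCt. Mean ± SEM is over per-replicate treatment fold
changes; log2FC = log2 of the mean fold change. Significance is a two-sided
equal-variance t-test on ΔCt values (optionally on fold changes); when both
groups have zero variance the p-value is defined as 1 (equal means) or 0. No
amplification-efficiency correction is applied. Note the arithmetic mean of
fold changes is biased upward under Ct noise (E[2^−ε] = e^(σ·ln2)²/2); the
log-scale (geometric) mean is the unbiased effect estimate, and both are
exercised in the tests.

## Synthetic data simulator

Purpose: seed-reproducible micro-genomes with known regulatory truth so every
pipeline stage is testable offline. Defaults: four circular genomes
(~26 kb), two sister pairs on the tree
`((Z1:0.002,Z3:0.002):0.01,(B:0.002,Q:0.002):0.01)`, 60 ATG…TAA genes of
~100 codons (no internal stops), AT-rich composition targeting 26% GC,
~130 bp spacers, 20 planted SD motifs (5–10 nt upstream of starts), 2 σ³²
sites (upstream of the *grpE* and *groES* operon heads, spacer drawn from
11–15), 10 hairpin cassettes (10 bp stem + 4 nt loop), and a 15-name
heat-shock regulon laid out with the *grpE–dnaK–dnaJ* and *groES–groEL*
operons.

Evolution along the tree uses per-branch binomial substitution with an
HKY-like replacement rule whose stationary composition equals the GC target
(transition:transversion κ = 2), so composition does not drift. Coding
sampling GC is calibrated by bisection to offset the stop-codon rejection
bias. Start/stop codons are protected and internal stops re-rolled. IGSs
additionally receive Poisson indels (rate·length·branch, sizes 1–3) placed
outside planted spans, with truth coordinates shifted accordingly. Planted
elements plus 20 nt flanks evolve at a 10× lower substitution rate
("conserved, not frozen" — footprinting is tested against realistic
near-identity, and recall is <100% by design). The origin is rotated into the
final spacer so one spacer wraps, exercising circular code paths. Output
(GenBank, GFF3, FASTA, truth BED) is byte-identical per seed.

What the simulator does **not** emulate: real gene lengths and content
(~26 kb/60 genes vs ~350 kb/250 genes — scaled down for test speed), tRNA and
rRNA genes, genome rearrangement or gene loss (gene order is perfectly
conserved, so every spacer pairs across genomes), pseudogene decay beyond
uniform IGS indels, codon-usage structure, sequencing/annotation error, and
any real phylogeny beyond the configured tree shape.

Ct tables: control ΔCt at a baseline (5.0), treatment shifted by the planted
per-target effect, Gaussian noise on ΔCt (sd 0.2 default) plus small
reference-Ct jitter, n = 4 replicates; deterministic per seed.

## Limitations

- The center-star aligner and the compact energy model are stand-ins; counts
  derived from them (conserved nt, MFE candidates) are method-relative and
  not exactly comparable to results obtained with production MSA or folding
  tools.
- RBH orthology has no explicit paralog model; it is adequate for the
  rearrangement-free, duplication-free genomes targeted here.
- NG86 Ka/Ks saturates (NaN) beyond p = 3/4 and applies no
  transition/transversion weighting.
- The σ³² scanner is consensus+mismatch based — no position weight matrix or
  energy model — and reports all placements within budget rather than a
  single best site.
- Statistical tests assume equal variance and independence across replicates;
  no multiple-testing correction is applied to the expression table.
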