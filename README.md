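# endofootprint

Comparative genomics and phylogenetic footprinting of transcriptional
regulatory elements in highly reduced endosymbiont genomes.

Obligate bacterial symbionts of insects — such as *Candidatus* Portiera
aleyrodidarum, the primary symbiont of whiteflies — carry genomes shrunk to a
few hundred kilobases that have lost most dedicated regulatory machinery, yet
keep an unusually large intergenic fraction (~30%). Whether those spacers
still encode regulation (promoters, ribosome-binding sites, structured RNAs)
can be asked comparatively: stretches that stay identical across related
genomes while neutral sequence diverges are candidate functional elements.
`endofootprint` implements that analysis end to end:

- **Genome I/O and architecture** — GenBank or FASTA+GFF3 parsing (circular
  genomes and origin-spanning features supported), genome statistics
  (coding/intergenic GC, spacer fraction), intergenic spacer (IGS) extraction
  to BED/FASTA.
- **Orthology and evolution** — reciprocal-best-hit ortholog groups from
  protein alignments, core-genome percent identity, neighbor-joining trees,
  and Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction.
- **Phylogenetic footprinting** — pairing of orthologous IGSs (spacers flanked
  by the same ordered ortholog pair), center-star multiple alignment, and
  extraction of conserved loci: maximal identically aligned gap-free runs
  longer than 20 nt, mapped back to each genome.
- **Regulatory elements** — a two-box σ³² heat-shock promoter scanner
  (CTTGAAA — 11–15 nt spacer — CCCCATnT, per-box mismatch budgets, operon
  aware) over upstream windows, and a Shine–Dalgarno (AGGAG) consensus
  scanner over conserved loci.
- **RNA structure** — a simplified Zuker minimum-free-energy folder (stacking
  + loop penalties, deterministic traceback); conserved loci with MFE < 0 are
  flagged as sRNA candidates.
- **qPCR analysis** — comparative-Ct (2^−ΔΔCt) relative expression with
  per-replicate fold changes, SEM, and t-tests.
- **Synthetic data** — a seed-reproducible simulator of circular AT-rich
  genome quartets with planted SD motifs, σ³² sites and hairpin cassettes
  evolved along a tree, plus Ct tables with planted effects, so every stage is
  testable offline against known truth.

## Worked example

Generate a synthetic quartet (two near-identical sister pairs) and run the
full pipeline:

```sh
$ endofootprint simulate --seed 7 --outdir sim
wrote 4 genomes to sim

$ endofootprint run --seed 7 --outdir out
core=60 groups=60 loci=135 sd=71 sigma=8 srna=107
```

`out/summary.json` then holds the run's quantities — this is the actual
output for seed 7:

```
core_genes           60        # ortholog groups present in all four genomes
igs_groups           60        # orthologous spacer groups
conserved_loci       135       # identical gap-free runs > 20 nt
conserved_nt         6645
conserved_fraction   0.8301    # conserved nt / mean aligned spacer nt
sd_hits              71        # AGGAG (<=1 mismatch) hits inside loci
sigma_sites          8         # two planted sites recovered in each genome
srna_candidates      107       # loci folding with MFE < 0
length_r2            {"B-Q": 0.9999, ..., "Z1-Z3": 0.9997}
```

The σ³² site table shows the two planted promoters, upstream of the
*grpE*-operon and *groES*-operon heads:

```
$ head -3 out/sigma_sites.tsv
genome  strand  box35_start  box10_start  spacer  mm35  mm10  gene   distance
B       +       2249         2271         15      0     0     B_005  56
B       +       4348         4367         12      0     0     B_010  28
```

Other subcommands operate on individual files: `stats`, `igs`, `orthologs`,
`kaks`, `scan-sigma32`, `scan-sd`, `fold`, `qpcr`. Run
`endofootprint COMMAND --help` for options. `endofootprint run` also accepts
`--config run.yaml` (any `RunConfig` field; unknown keys are rejected) and
exits 0/1/2 for ok / config error / stage error.

Real annotated genomes are analyzed the same way by passing GenBank files
instead of simulating — see `data/accessions/README.md` for the published
*Portiera* records the acceptance tests expect.

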