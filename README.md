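# tandemlocus

Analysis toolkit for multigene loci built from near-identical tandem
repeats.  It covers the computational workflow used to characterize a
tandem-array gene locus from long-read BAC sequencing and to trace the
locus's origin from a progenitor gene family:

- **`synth`** — synthetic fixture generation with attached ground truth:
  circular tandem-array BAC molecules (vector + flanks + N mutated unit
  copies, each unit carrying a skin-style and a secreted-style gene
  cassette), error-bearing long reads, deletion-derived allele pairs,
  "provenance pairs" of loci that share only non-coding scaffold, and toy
  multi-species gene orders.
- **`repeats`** — tandem-unit copy-number estimation from long-read
  category counts: reads are classified into {vector, flank, repeat,
  ambiguous} by windowed k-mer voting and the unit count is estimated as
  `(C_repeat / C_vector) x (L_vector / L_unit)` with a seeded bootstrap
  SE/CI.  Outer units are resolved separately by anchoring reads to unique
  flank 31-mers and walking them against the unit consensus.
- **`similarity`** — global/local identity (gap columns count in the
  denominator; N never matches), seed-and-extend local homology blocks
  re-scored by alignment, block classification against annotation
  (coding / intron / UTR / intergenic) with a coding-vs-non-coding
  coverage contrast, tandem-period detection by self-comparison, and
  exon-window matching.
- **`isoforms`** — mature-peptide derivation (signal/propeptide removal,
  C-terminal Gly drop) and rule-based classification into
  skin / liver / midi / maxi / gig2_like / pseudogene with recorded
  evidence, plus a per-locus census.
- **`synteny`** — microsynteny rows (nearest non-focal flanking genes
  around a collapsed focal-family block) and pairwise relocation calls.
- **`southern`** — virtual Southern blots: restriction digest (linear or
  circular), probe hybridization by local-alignment threshold, gel-band
  merging with intensities, and scoring of observed band lists against
  candidate alleles.
- **`formats`** — FASTA/FASTQ/GFF3/BED6 and a minimal GenBank reader with
  one internal coordinate convention (0-based half-open; 1-based inclusive
  at I/O boundaries and in reports).
- **`cli`** — a config-driven pipeline runner with deterministic,
  config-hash-stamped outputs.

## Command line

```sh
tandemlocus simulate --preset allele1 --seed 1 --outdir sim/
tandemlocus count-repeats --reads reads.fa --components components.fa \
    --mode bases --bootstrap 1000 --seed 1
tandemlocus scan --a locusA.fa --b locusB.fa --gff-a locusA.gff3 \
    --min-id 0.70 --min-len 100 --bed-prefix blocks --dotplot dots.tsv
tandemlocus classify --locus locus.fa --gff locus.gff3
tandemlocus synteny --table gene_orders.tsv --focal Gig2
tandemlocus southern --seq locus.fa --probe probe.fa --enzyme DraI
tandemlocus run-all --config pipeline.yaml
```

`run-all` reads a YAML config (`seed`, `outdir`, `stages`, and per-module
parameter blocks; unknown keys are rejected), derives per-stage seeds from
the global seed, and stamps every report with the config hash so identical
configs produce byte-identical outputs.

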