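# markgene

Gene-level integration of bulk expression and histone-mark ChIP-seq across
two genotypes: per-gene mark enrichment with mark-specific counting regions,
expression fold-change classification, genotype comparison of mark levels
within expression classes, metagene profiles, joint fold-change reporting,
and a synthetic-study generator so every stage is testable without real
sequencing data.

## What it computes

* **Expression** — FPKM from fragment-count tables
  (`counts * 1e9 / (length * total)`), per-gene fold change between a test
  and a reference genotype (with a small pseudocount), and strict
  up/down/unchanged classification at a configurable threshold (1.5x for
  DE lists, 3x for the class-wise tests, by default). Log-scale Pearson
  correlation between samples is available for QC.
* **ChIP enrichment** — uniquely mapped reads are counted in mark-specific
  windows: `[TSS-2kb, TSS+2kb)` for H3K4me3 and upstream-flank + gene body
  for H3K27me3 (any >= 1 bp overlap, half-open coordinates). Counts are
  RPM-normalised per library and the per-gene enrichment is the ChIP/input
  RPM ratio (0.5-read pseudocount keeps it finite).
* **Integration** — for each expression class, an unpaired Welch t-test
  compares per-gene log2 enrichment between the genotypes; a joint table
  reports expression, H3K4me3, and H3K27me3 log2 fold changes per gene.
* **Profiles** — TSS-centred or scaled-gene-body metagene read-density
  profiles (read midpoints, per-million and per-gene normalised).
* **Simulation** — two-genotype studies with negative-binomial counts,
  planted DE genes, and ChIP libraries whose per-gene ChIP/input ratios are
  planted exactly (promoter-peaked H3K4me3, gene-body H3K27me3, uniform
  inputs) and coupled to the expression classes.

## CLI

```sh
# write a complete synthetic study (BED/GTF/TSV + a ready pipeline config)
markgene simulate --seed 1 --outdir study/

# full pipeline: expression -> enrichment -> tests -> joint table
markgene run --config study/config.yaml --outdir report/

# single stages
markgene expression --counts counts.tsv --samples samples.tsv \
    --genotype-ref XY --genotype-test XXSry --outdir out/
markgene enrich --annotation genes.bed12 --chip chip.bed --input input.bed \
    --mark H3K4me3 --genotype XY --outdir out/
markgene profile --annotation genes.bed12 --reads chip.bed --outdir out/
```

Inputs: gene annotation as GTF (Ensembl dialect) or BED6/BED12; read
libraries as BED (score column > 0 marks uniquely mapped reads — convert
BAM with `bedtools bamtobed` upstream); counts as TSV
(`gene_id`, `length`, one column per sample) plus a sample sheet
(`sample_id`, `genotype`). All outputs are TSV with stable formatting, so
a rerun with identical inputs is byte-identical; a `manifest.txt` records
versions, config hash, and seed.

## Layout

```
src/markgene/
  genome.py      coordinate types, GTF/BED I/O, mark regions, overlap counting
  expression.py  FPKM, fold change, DE classes, log correlation
  enrichment.py  RPM, ChIP/input enrichment tables, metagene profiles
  integrate.py   Welch tests per expression class, joint fold-change table
  pipeline.py    end-to-end runner + manifest
  simulate.py    synthetic two-genotype study generator
  cli.py         click CLI (simulate / expression / enrich / profile / run)
tests/           pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py
```
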