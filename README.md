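# hapi

Promoter-centric analysis of H3K27ac HiChIP enhancer-promoter loops.

Given loop calls (BEDPE with PET counts) and a TSS annotation, `hapi`:

1. **Filters and classifies loops** — drops loops with fewer than 3 PETs or
   blacklist-overlapping anchors, then groups cis loops by midpoint span into
   *local* (5 kb – 2 Mb), *long-range cis* (≥ 2 Mb) and *trans*
   (inter-chromosomal) classes; loops spanning ≤ 5 kb are discarded as
   self-ligation artifacts.
2. **Annotates anchors** as promoters (± 2.5 kb of a TSS) or enhancers and
   keeps loops with a promoter in exactly one anchor (promoter-promoter loops
   are excluded).
3. **Scores genes** at their primary promoter (the anchor with the most PETs)
   with an *enhancer contact value* (distinct enhancer anchors) and an
   *interaction intensity* (summed PETs), and calls **highly-interactive
   genes**: genes at or above the inflection-point cutoff of both
   hockey-stick ranked curves (the point where a line of slope
   `(max − min) / N` is tangent to the sorted curve).
4. **Locates enhancer activity** per gene via
   `log10(class PETs) × class anchors` activity terms; called genes with more
   than 25% of activity in trans or long-range cis are flagged as
   **enhancer-hijacking candidates**, optionally annotated with SNP-array
   copy number (`log2(CN) > 2` = high copy) and partitioned against a donor
   locus (own / donor / other enhancers within 2 Mb windows).
5. **Clusters samples** on interaction scores
   (`log10(intensity) × contact value`) with pairwise Spearman correlation
   and average linkage.
6. **Builds virtual-4C tracks** from HiC-Pro validPairs: distal ends of
   pairs anchored in a 2 kb promoter window, binned at 10 bp, scaled to
   counts per million pairs, with top-k region profile averaging.

A seeded simulator (`hapi simulate` / `hapi.simulate`) generates synthetic
genomes, TSS tables, loop files, blacklists, SEG copy-number files and
validPairs with implanted, ground-truthed hijacking events for end-to-end
testing without external data.

## CLI

```sh
# synthetic data with 3 implanted trans-hijack genes
hapi simulate --n-genes 500 --n-boosted 30 --n-hijack 3 --seed 1 --outdir fx/

# gene calling (cutoffs recorded in the table header)
hapi call --loops fx/loops.bedpe --tss fx/tss.tsv --blacklist fx/blacklist.bed --outdir call/

# enhancer origin fractions + hijacking candidates + copy number
hapi origin --loops fx/loops.bedpe --tss fx/tss.tsv --blacklist fx/blacklist.bed \
    --seg fx/copynumber.seg --outdir origin/

# own/donor/other partition against a reference locus
hapi partition --loops fx/loops.bedpe --tss fx/tss.tsv \
    --gene HJ00 --reference chr2:29999000-30001000 --outdir part/

# multi-sample clustering from two `hapi call` tables
hapi cluster --table s1=call1/hapi_table.tsv --table s2=call2/hapi_table.tsv --outdir clust/

# virtual 4C from validPairs
hapi v4c --pairs fx/pairs.validPairs --anchor chr1:30000000 --outdir v4c/
```

All thresholds (`--min-pets`, `--promoter-halfwidth`, `--min-span`,
`--max-normal-span`, `--threshold`, `--window`, `--bin`, `--top-k`) default
to the standard values above and are surfaced as flags; every run writes a
`manifest.json` of effective parameters and result tables carry a `#` header
with the tool version.

## Layout

| module               | contents                                             |
|----------------------|------------------------------------------------------|
| `hapi.io`            | BEDPE/BED/SEG/validPairs/bedgraph readers & writers  |
| `hapi.annotate`      | loop filtering, span classification, anchor roles    |
| `hapi.core`          | gene profiles, inflection cutoffs, gene calling      |
| `hapi.origin`        | contribution fractions, hijacking, CN, partitions    |
| `hapi.comparative`   | score matrix, Spearman clustering                    |
| `hapi.v4c`           | virtual-4C tracks and averaged profiles              |
| `hapi.simulate`      | seeded synthetic fixtures with ground truth          |
| `hapi.cli`           | `hapi` command-line entry point                      |
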