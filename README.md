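# breakscan

Chromosomal rearrangement calling from discordant paired-end reads, de
novo exon / chimeric gene detection from RNA fusion evidence, and
population summaries — with a synthetic-data module that generates every
input with known truth.

## The problem

In population resequencing data, a chromosomal rearrangement — a mutation
that moves or copies a DNA segment at least 1 Mb away or onto another
chromosome arm — leaves a characteristic footprint: read pairs whose two
mates map to the two loci joined by the novel junction. Such mutations
matter beyond structural variation per se: when an insertion places
previously untranscribed DNA just downstream of an existing gene's
promoter and start codon, it can create a chimeric transcript with a de
novo exon in a single mutational step. `breakscan` is a library for
geneticists who want to call these events from alignments, match them to
RNA-seq fusion evidence, polarize them against an outgroup, quantify
false-negative/false-positive rates, and summarise them across a
population sample (site frequency spectrum, transposable-element
association, chromosome-arm distribution, hotspot detection).

## The method

For each sample line, after PCR-duplicate removal, *abnormal* pairs are
those with mates on different major arms or ≥ 1 Mb apart on the same arm
(shorter separations are confounded with inversions and mid-size
duplications and are excluded). Pairs are clustered by single linkage:
two pairs are linked when both of their canonically ordered ends lie
within the library insert size (325 bp) of each other; clusters with at
least 4 independent pairs become calls. Under the fragment model
(fragment length *F*, read length *R*, depth *d*), the expected number of
junction-spanning pairs is

    E[pairs per junction] = d (F − 2R) / (2R)  ≈ 1.17 d  at F = 325, R = 75,

so a 4-pair threshold is comfortably cleared from ~20× coverage upward.

A call becomes a candidate new gene when ≥ 3 RNA split reads or spanning
pairs map within 1 kb of both call sides; candidates are classified as
chimeric when a breakpoint lies downstream (in transcription direction)
of an annotated start codon. Polarization extracts 1 kb flanks per side
and asks whether they co-locate within 2 kb in an outgroup (≥ 85%
identity, breakpoint-spanning hits, at most 10 co-locations). Population
frequencies are corrected by false-negative rescue (1–3 supporting pairs
in a line without a call), and arm distributions are compared with a
randomized-complete-block ANOVA (arm = treatment, line = block) plus
Tukey HSD on the block-model error term.

## A worked example

`examples/01_simulate_and_call.py` plants a 2 kb insertion from
2L:1,200,000–1,202,000 into 3R:902,154 in one line, simulates 40× read
pairs, and calls it back:

```
simulated 55661 read pairs (expected ~47 spanning pairs per junction)
5566 PCR duplicates removed

2 calls (one per junction of the insertion):
  CY17C_c0000: 2L:1200004-1200259 <-> 3R:901913-902152  support=47
  CY17C_c0001: 2L:1202003-1202300 <-> 3R:901904-902153  support=48
```

The two calls are the two junctions flanking the inserted segment: one
joins the destination to the source start, the other to the source end,
each supported by roughly the predicted ~47 spanning pairs. The same
script replays a known worked example — nine read pairs at the published
CY17C coordinates cluster into exactly two calls,
2L:12260976–12261228 ↔ 3R:901825–902153 (5 pairs) and
2L:12261000–12261224 ↔ 3R:902533–902654 (4 pairs).

The other example scripts cover fusion/new-gene detection
(`02_fusion_new_genes.py`), polarization and error models
(`03_polarize_and_errors.py`), and population summaries
(`04_population_summary.py`). A thin CLI mirrors the shell-facing steps:
`breakscan call`, `merge`, `sfs`, `proximity`, `arms`, `hotspots`,
`sweepjoin`, `polarize`.

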