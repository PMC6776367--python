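# Methods

## Calling model

A rearrangement is detected from *abnormal* (discordant) read pairs:
mates on different major chromosome arms, or ≥ `min_distance` (default
1 Mb) apart on the same arm. The 1 Mb floor is deliberate: between
~100 kb and 1 Mb the discordant-pair signature is confounded with
inversions and mid-size duplications, so those separations are excluded
rather than modelled. Only the five major euchromatic arms (X, 2L, 2R,
3L, 3R in the Drosophila-like default) are analysed; the dot chromosome
and heterochromatic or unplaced scaffolds are dropped because coverage
and mappability there are unreliable and the gene density is low.

PCR duplicates — pairs identical in both mates' (arm, position, strand)
— are collapsed before anything else, since amplified ligation products
would otherwise inflate support counts.

Clustering is single linkage with a both-sides window equal to the
library insert size (`cluster_window`, default 325 bp): two pairs are
linked when their canonically ordered ends are on the same arms and
within the window on *both* sides, and clusters are the connected
components of that graph (implemented with union–find after a canonical
sort, so results are independent of input order; a brute-force
transitive-closure oracle is part of the test suite). Clusters with at
least `min_support` (default 4) independent pairs become calls; clusters
with 1–3 pairs are retained for false-negative rescue. Side intervals
are the min–max span of clustered read extents. Read orientation is
recorded and summarised (`parallel_orientation` flags clusters dominated
by same-strand mate combinations) but is *not* a clustering criterion:
the method is deliberately agnostic about the orientation signature of
the underlying mutation class.

## Fusion transcripts and chimera classification

A call is promoted to a candidate new gene when at least `min_reads`
(default 3) RNA reads — split reads or spanning pairs, counted together
per tissue — map within `slack` (default 1 kb) of both call sides, with
both side assignments tried. Candidates are classified by annotation
geometry: the call is chimeric when a side's midpoint lies inside an
annotated gene downstream, in the direction of transcription, of that
gene's start codon, in which case the new transcript inherits the
promoter and translation start. Transcript-level confirmation consumes a
pre-filtered (E ≤ 1e-10) hit table of assembled transcripts and requires
one transcript with segments within 1 kb of both sides; assembly itself
is out of scope. Relative coverage (depth / total mapped reads, an
FPKM-like normalisation) makes tracks comparable between libraries.

## Polarization

Each call side contributes a 1 kb flank (clipped at arm ends and flagged
when clipped). Hits in the outgroup qualify at ≥ 85% nucleotide identity
and must span the breakpoint segment. The call is *ancestral* — the
reference, not the sample, carries the derived allele — when some pair
of qualifying hits (one per flank) co-locates on one outgroup arm with
nearest edges within 2 kb. It is *unpolarizable* when either flank lacks
a qualifying hit or when the flank pair co-locates in more than 10
places (repetitive sequence). Otherwise it is derived in the sample.
When proximal and distal hit pairs coexist the proximal evidence wins:
the criterion is existential, and a repeat-mediated distal hit should
not veto a clean co-location.

## Error models

*False-negative rescue.* For every merged variant and every line without
a call, supporting pairs (both ends within 325 bp of the variant's
sides, either orientation) are counted: 1–3 pairs mark a rescued false
negative, zero marks absence. A cell with ≥ 4 pairs and no call
contradicts the calling contract; it is logged and treated as rescued
rather than raising, since window geometry can in principle leave ≥ 4
pairs that did not pairwise-cluster.

*Coverage regression.* Ordinary least squares of call count on depth,
with per-line predictions at a common target depth (default 93.7×, the
deepest line) computed as observed + slope × (target − depth). This
residual-preserving adjustment keeps each line's prediction at its own
depth equal to its observed count — a property the test suite asserts —
instead of collapsing all lines onto the fitted line.

*Long-read confirmation.* A call is confirmed when a single long read
has hits (pre-filtered at E ≤ 1e-10) within 2 kb of both sides; the
per-line confirmation rate estimates 1 − the false positive rate.

## Population summaries

Calls merge across lines into population variants by the same
single-linkage rule with a both-sides tolerance of 325 bp (the paperless
cross-line identity rule; configurable). Frequencies are post-rescue
line counts. The SFS excludes unpolarizable variants. Site counting
follows the two/one rule — a within-arm call contributes 2 sites to its
arm, a between-arm call 1 site to each — so per line sites = 2 × calls,
an invariant asserted throughout. Rates are sites per bp of arm.

Arm differences use a randomized-complete-block ANOVA (arm = treatment,
line = block) via an OLS fit of `rate ~ C(arm) + C(line)`; Tukey HSD is
computed on the block model's error mean square with the studentized
range distribution, because a one-way Tukey MSE would ignore the
blocking. When the arm effect and the residual variance are both zero
the F statistic is reported as 0 with p = 1 (the null outcome) rather
than NaN.

Hotspots are sliding 5 kb windows (step 1 kb — the scan granularity is a
design choice; the span threshold is the scientific parameter) with
strictly more than 30 breakpoints, where breakpoints are the midpoints
of every side of every per-line call pooled across lines; surviving
windows are merged into maximal spans and counts re-tallied. The join to
precomputed population-genetic windows flags the empirical bottom
`floor(0.05 × W)` windows by Tajima's D rank (ties broken by arm then
start, so a flat distribution still flags exactly that many); computing
θπ/θW/D from sequence is out of scope.

## Synthetic data

The generator emits reference-coordinate alignment records directly,
bypassing an aligner: that preserves the caller's input contract (SAM
with mate fields, via `write_pairs_sam`) while keeping the truth exact.
Fragments are Normal(325, 30) — the insert mean is the library's stated
size; the 30 bp SD and the 75 bp read length are package defaults since
neither is dictated by the data model — and a junction yields a usable
discordant pair only when it falls in the inner gap between the two
reads, giving the expectation d(F−2R)/(2R) documented in
`expected_spanning_pairs` and verified by Monte-Carlo in the tests.
Junction-spanning pairs are drawn at the line's true depth; concordant
background pairs carry no signal and are sampled at a thinned fixed
depth (default 2×) so simulation cost scales with signal, not genome
size. PCR duplicates are exact coordinate copies injected so that a
fraction `dup_rate` of emitted records are duplicates; optional noise
pairs emulate scattered mis-mapping.

Insertions are modelled with both truth junctions at the destination
position (destination ↔ source start, destination ↔ source end). A
consequence worth knowing: the two junction clusters of an insertion
merge into a *single* call when the source segment is shorter than
roughly 2(F − 2R) + window (~800 bp at defaults), because the
source-side read groups approach within the clustering window — the
same behaviour seen in real data for insertions near read length.
Cohort generators therefore use ≥ 2 kb sources when two calls per event
are expected. Reciprocal translocations are marked by the same two
junction pairs and differ only by label.

What the generator does *not* emulate: sequencing errors and quality
strings, indels, mappability and repeat structure, heterochromatic
coverage loss, and real insert-size outliers. Passing tests therefore
demonstrate the correctness of the calling logic under the stated
fragment model, not robustness to alignment artefacts in real data. One
visible consequence: at depths ≥ 12× every junction clears the 4-pair
threshold with probability ≈ 1, so the call-count–depth regression on
the demonstration cohort has near-zero slope; the depth dependence that
real data show (driven by marginal detection and mappability) appears in
the low-depth titration (1–8×) that the acceptance script also reports.

## Problem sizes and determinism

Default demonstration scale: five 3 Mb arms, 14 lines at the published
per-line depths (12.1–93.7×), 35 planted events, background 0.5×,
duplicate rate 0.1 — chosen so a full end-to-end run completes in
seconds while every per-junction expectation stays in the asymptotic
regime of the fragment model. All generators take a single explicit
integer seed (numpy `default_rng`); identical seeds give byte-identical
SAM/TSV output, asserted in the tests. Coordinates are 1-based inclusive
internally, BED output is 0-based half-open, GFF3 1-based.

## Known limitations

* Breakpoint resolution is the cluster span (~insert size); no
  split-read base-pair refinement.
* Inversion orientation signatures, CNV-from-depth, and 100 kb–1 Mb
  events are out of scope by design.
* The cross-line merge tolerance (325 bp) is a convention; deeply
  diverged breakpoints of recurrent mutations at one locus are counted
  as separate variants, which is exactly what the hotspot scan is for.
* `tissue_sharing` reports germline/soma sharing within each sex; with
  single-end female libraries the spanning-pair evidence class is empty
  and recovery in females is expected to be lower at equal read counts.
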