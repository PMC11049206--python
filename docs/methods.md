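# Methods

`satmapper` characterizes a satellitome — the catalogue of satellite DNA
(satDNA) families of a genome — and maps each family onto assembled
chromosomes. This note documents the models, the estimators, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Domain model

A satDNA *family* is defined by a consensus monomer; its genomic copies
sit in tandem arrays, each copy diverged from the consensus by point
substitutions (and occasionally indels). Families are named
`<G><spp>Sat<NNN>-<RUL>`: genus initial, three-letter species prefix,
`Sat`, the abundance rank zero-padded to three digits, and the repeat
unit length (RUL) in bp. An optional trailing tag is preserved verbatim
(the telomeric TTAGG repeat is conventionally tagged `-tel`). Zero
padding to three digits accommodates catalogues of up to 999 families,
which recent beetle satellitomes approach.

## Chromosome annotation (in-silico mapping)

Each family's monomer is located on every chromosome at a percent-identity
threshold (default 70%), on both strands, and monomer-scale hits are
merged into tandem arrays.

**Similarity model.** Identity is matched columns divided by alignment
columns — indel columns count against identity — under semi-global
alignment of the monomer against the genome (the full monomer aligns;
genomic overhang is free). Scoring: match +1, mismatch −1, affine gaps
costing 2 + g for a gap of g columns. Under this scoring a gap column is
strictly worse than a mismatch, so on indel-free sequence the optimal
alignment is gap-free and unique; this is what makes annotation of a
chromosome and of its reverse complement exactly mirror-symmetric, a
property the test suite asserts.

**Search procedure.** A vectorized gap-free screen scores the monomer at
every genomic offset and keeps offsets within 10 percentage points of the
threshold; each surviving candidate is refined by affine semi-global
alignment (Biopython `PairwiseAligner`) in a window with RUL/8 flanks.
Scanning every offset makes the search phase-invariant by construction:
every full monomer copy in an array, whatever its phase relative to the
consensus start, begins at some offset. The 10-point screen slack covers
hits whose affine optimum uses a small number of gaps; hits must align at
least 50% of the monomer, which suppresses spurious micro-matches.

**Overlap resolution (per family).** A hit whose interval is contained in
another hit's interval is dropped as a truncation artifact. Remaining
hits overlapping by more than RUL/10 bp conflict and the higher-identity
hit wins (ties: leftmost, `+` before `−`); smaller overlaps — boundary
jitter produced by gapped alignments of adjacent copies — coexist. The
exhaustive-scan oracle in the test suite applies the identical rule, and
the two agree exactly on chromosomes up to 50 kb. Families are annotated
independently of one another; across-family overlaps are intentionally
not resolved.

**Very short monomers.** For RUL < 20 bp (telomeric TTAGG, other
microsatellite-scale families), percent identity over so few columns is
meaninglessly permissive at 70%, so these families are annotated by exact
tandem-run detection: maximal runs of at least 4 consecutive exact copies
of any rotation of the monomer, either strand. A substitution interrupts
a run, so recovery for short-monomer families is only complete at low
divergence; this is a documented limitation, not a target of the
benchmarks.

**Array merging.** Consecutive same-strand hits merge into one array when
the inter-hit gap is at most `max_gap_factor × RUL` (default factor 1).
Array identity is the unweighted mean of its hits.

**Coordinates.** 0-based half-open internally; GFF3 output is 1-based
inclusive (source `chrismapp`, type `satellite_DNA`, attributes carry the
family, hit count and mean identity); BED6 export is 0-based half-open
with score = 10 × mean identity. Reading a written GFF3 reproduces the
array list exactly.

## Read-based quantification

Genome abundance and divergence per family are estimated from unassembled
reads, RepeatMasker style. Each family contributes one search-library
entry: the monomer dimer when RUL > 100 bp, otherwise the shortest
concatemer of at least 200 bp (at exactly 100 bp the dimer already
satisfies both rules). With 101-bp reads, any read window of a tandem
array, whatever its phase, aligns contiguously inside such an entry.

Each read is aligned locally (same scoring as the annotator) against all
entries and both strands; the best-scoring alignment per entry is kept
and the winning family is the highest identity, ties broken by longer
aligned interval, then by family rank. A hit requires identity at or
above the threshold (default 70%, mirroring annotation) over at least 60
alignment columns. The 60-column floor matters: over ~40 columns,
A+T-biased background reads reach 70% identity by chance at a
few-percent rate, which would inflate abundance by roughly one
percentage point and drag divergence estimates upward; at 60 columns
chance masking is vanishing while the excluded short boundary overlaps
bias abundance by less than 1e-4 absolute for 101-bp reads.

Abundance is masked bp over total read bp, each read assigned to at most
one family. Divergence uses the Kimura two-parameter (K2P) distance

    d = −1/2 · ln[(1 − 2P − Q) · sqrt(1 − 2Q)]

with P and Q the transition and transversion column proportions; gap and
N columns are excluded from P, Q and the column count. The family value
is the aligned-bp-weighted mean of per-hit distances (weighting matches
the per-family averaging of masking tools and weights long matches
appropriately; whether published per-family values are bp-weighted is
generally not stated). Saturated hits (either logarithm argument
non-positive) count as masked bp but are excluded from the mean, with a
logged warning.

Local alignment trims mismatch-heavy read ends, which biases per-hit
divergence slightly downward (about −0.005 absolute at d = 0.15 for
101-bp reads); recovery stays within ±0.015 of the planted value across
d ∈ {0.02, 0.07, 0.15}, which the acceptance tests assert.

**Repeat landscape.** Family abundance is distributed over K2P bins
(default 1-percentage-point bins spanning [0, 30]) proportionally to the
aligned bp of its hits per bin; mass beyond the last bin edge, and the
whole mass of a family with only saturated hits, lands in the last bin,
so each family's row sums exactly to its abundance.

## Satellitome summary

`summarize` reports family count, total and top-k genome fraction,
divergence range and unweighted mean, abundance minimum, RUL range, and a
RUL histogram in 100-bp bins. Convention: the telomeric repeat is part of
the catalogue — it contributes to counts, totals, the mean divergence and
the RUL range — but is excluded from the divergence extremes, which
describe satDNA families proper; telomeric repeats are a universally
conserved repeat class whose low divergence says nothing about
satellitome turnover. With this convention the packaged *Chrysolina
americana* catalogue (165 families) reproduces every published aggregate:
total 17.97%, mean divergence 9.91%, divergence range 1.77–26.18%, RUL
range 5–3664 bp, modal RUL bin 101–200 bp. The packaged table transcribes
printed values verbatim at printed precision; aggregate checks use ±0.02
absolute to absorb printed rounding. One printed oddity is transcribed,
not corrected: the telomeric family's A+T is listed as 40.0% although
every rotation and complement of TTAGG has 60%.

`rank_and_name` re-ranks families by descending abundance (ties:
descending masked bp, then input order — fully deterministic) and
regenerates names, so ranks always reflect the quantification they ship
with.

## Synthetic data

The generator emulates the genome organization the tool targets: long
tandem arrays (hundreds of copies) and short dispersed arrays planted in
i.i.d. background sequence, plus uniform shotgun reads.

* **Mutation model.** For a copy at target divergence d (substitutions
  per site), the substitution count is Poisson(d × L); events hit uniform
  positions (multiple hits allowed) and are transitions with odds
  `tstv_ratio` : 1 (default 2) against transversions, the two transversion
  targets equiprobable. This is exactly a K2P process, so the K2P
  estimator recovers d in expectation — the calibration the recovery
  benchmarks rely on. Targets at or above 0.75 are refused as effectively
  saturated. Single-base indels are available behind `indel_rate`
  (default off).
* **Background.** i.i.d. bases at 64% A+T by default, mirroring the
  A+T-rich beetle genomes the tool is aimed at; configurable.
* **Reads.** Count = round(coverage × genome bp / read length); uniform
  start positions, strands equiprobable; default 101 bp, matching the
  short-read data used for satellitome quantification. Optional proper
  pairs at 350 bp insert and optional uniform sequencing error (both off
  by default). Every generator is a pure function of its seed.

**What passing synthetic benchmarks shows — and what it does not.** The
generator produces clean tandem arrays of a known consensus in
homogeneous background. It does not emulate higher-order repeat
structure, nested insertions of mobile elements into arrays, assembly
collapse of long arrays, or sequencing error profiles. Recovery results
(≥95% of planted bp at per-copy K2P ≤ 0.15 and threshold 70%; abundance
within binomial sampling error; divergence within ±0.015) therefore
validate the estimators' correctness, not their robustness to artifacts
of real assemblies and libraries.

## Figures

Chromosome maps mirror the standard satellitome figure: one panel per
chromosome, a top track with the k most abundant families (default 5)
colored by rank from a fixed qualitative palette, and a bottom track
pooling all remaining families in grey. Output is SVG with pinned
hash salt and no creation date, so identical inputs give byte-identical
files; every pipeline stage is byte-reproducible from (inputs, seed). The
repeat landscape is a stacked bar chart of abundance versus divergence
bin.

## Problem sizes used in the automated checks

Desk checks (catalogue aggregates, probe arithmetic) are instantaneous.
Simulation checks use 141-bp monomers with: 150 planted copies in 50 kb
for bp recovery; 500 copies in 705 kb at 1× coverage (≈7000 reads) for
abundance; 500 copies in 160 kb at 1.2× for divergence; 300 copies in
150 kb for the landscape peak; and a ~10 kb chromosome for exhaustive
oracle equivalence. These sizes put Monte Carlo noise well inside the
stated tolerances while the whole suite runs in well under a minute per
check.

## Known limitations

* Short-monomer (<20 bp) annotation is exact-match only; diverged
  microsatellite-scale arrays are under-recovered.
* The 70% "similarity" of interactive annotation tools is not formally
  defined by those tools; the alignment model here (semi-global, the
  scoring above) is this package's own, declared definition.
* Abundance from read masking is slightly conservative at array
  boundaries (overlaps shorter than 60 bp are not counted) and local
  alignment trims noisy read ends, giving a small downward divergence
  bias; both effects are far inside the stated tolerances.
* Across-family overlap of annotations is not resolved; a genomic bp may
  be annotated for two families (reads, by contrast, are assigned
  uniquely).
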