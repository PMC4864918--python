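# Methods

This note documents the models behind asmbench, the defaults that matter,
what the synthetic-data generators do and do not emulate, and the design
choices made where the design was genuinely open. Conventions first:
coordinates are 0-based half-open everywhere, fragment length is
`end − start`, and FASTQ quality is Sanger Phred+33 only.

## Synthetic genomes

A genome is an i.i.d. base sequence with an *exact-count* GC composition:
the base pool contains `round(length · target_gc)` G/C characters and is
shuffled, so the realized GC fraction deviates from the target only by
rounding and by repeat planting (the invariant enforced is ±0.02). Planted
repeats are exact duplicates of a template drawn from the genome itself;
they are the only genome feature the assembly analysis interrogates, so no
higher-order composition model (codon structure, skew, mobile elements) is
used. Multi-replicon genomes split the requested length evenly; repeats
are planted on the first replicon. Valid range: length ≥ 10 kb, GC in
[0.25, 0.80].

## Fragment-length models

Each library category carries a mean insert size: TS 641 bp, IS1 686 bp,
IS2 990 bp, IS3 1211 bp, IS4 1297 bp. The per-category spreads quoted for
such libraries (e.g. ±33 bp for IS1) describe *between-library*
variation of the category, not the within-library fragment spread; the
within-library SD defaults to 8 % of the mean and is tunable
(`FragmentModel.sd_insert`). TS libraries — the unmodified preparation —
have an asymmetric, left-tailed distribution, implemented as a skew-normal
with shape parameter −5 re-parameterised to the requested mean and SD; the
modified categories are Gaussian. Draws are truncated to
[read length, replicon length] by resampling; for all presets the
truncated mass is negligible. Empirical draws match the specified
distribution to a Kolmogorov–Smirnov distance < 0.05 at n = 10⁴ (tested).

## Quality model

The expected Phred of a base at 0-based cycle c in a read from a fragment
of f bp in a genome of GC fraction g is linear:

```
q(c) = q_start − decay_per_cycle · c
       − gc_penalty · max(0, g − 0.5)
       − insert_penalty · f / 1000
```

with two Gaussian noise terms — one offset per read (`read_noise_sd`,
emulating cluster/tile-level quality variation) and one per base
(`noise_sd`) — and clamping to [2, 40]. Defaults:

| parameter        | default | unit                  |
|------------------|---------|-----------------------|
| q_start          | 37      | Phred at cycle 1      |
| decay_per_cycle  | 0.08    | Phred / cycle         |
| gc_penalty       | 8       | Phred / unit GC > 0.5 |
| insert_penalty   | 3       | Phred / kb fragment   |
| noise_sd         | 4       | Phred (per base)      |
| read_noise_sd    | 2.5     | Phred (per read)      |

No published value exists for any of these slopes; they are simulator
choices fixed once so that the qualitative behaviour of real PCR-free
libraries emerges and sits in a sensitive regime: (80;20) pass fractions
around 0.7 at low GC falling to ~0.4 at 73 % GC, falling with the insert
preset, and (90;20) filtering of short-read high-GC libraries shifting the
retained insert mean down by amounts that grow with the preset. The
per-read noise term is essential: with per-base noise alone the (p;q)
decision at L = 189 concentrates so sharply (binomial SD ≈ 0.03 on the
base-fail fraction) that pass fractions degenerate to near 0/1 steps and
no graded trend can appear.

What the read simulator does **not** emulate: base-call substitution
errors (reads are exact genome copies; quality scores drive filtering
only), adapter contamination (the emulated preparation is PCR-free and
adapter removal is out of scope), chimeric fragments, and optical
duplicates. Passing trend tests therefore demonstrates the direction and
ordering of quality/GC/insert relationships under this model, not their
real-data magnitudes.

## Read processing

A read passes a (p;q) filter iff `count(Phred ≥ q) / length ≥ p` — both
comparisons inclusive ("at least"). All bases count in the denominator; N
bases carry whatever Phred is recorded. A pair is retained iff both mates
pass; the pass fraction is pairs retained / pairs in, reported as absent
for empty input. Trimming cuts sequence and quality in lockstep; with a
target length set, bases are removed from the 3′ end only. The pair count
for a target depth d is `N = ceil(d·G / 2L)` — ceiling, so the achieved
depth never undershoots. `ReadLibrary` enforces trim → filter → subsample
and refuses any other order, because sub-libraries are defined as random
draws *from trimmed, quality-filtered* libraries. Filter fractions are
computed on the post-trim read. Insert sizes are estimated as
rightmost end − leftmost start over proper FR same-replicon pairs
(truth coordinates, or mapped SAM records via pysam); discordant pairs are
excluded and counted, never included.

## Contiguity metrics and misassembly breaking

N50 is the length at which the longest-first cumulative sum reaches half
the assembly size; NG50 replaces the target with half the reference size
and is undefined (reported as the literal `NA`, never 0) when the
assembly never reaches it. The ≥500 bp contig filter is applied to input
contigs before *any* metric. It is not re-applied to broken pieces by
default — the filter belongs to assembly output, the correction happens
afterwards — but `filter_pieces=True` is available.

Alignment is exact-match anchoring: reference k-mers (k = 31) that are
unique genome-wide anchor contig positions (both strands via the contig's
reverse complement); anchors on one (replicon, strand, diagonal) are
merged and extended to maximal exact-match blocks; contained blocks are
dropped and residual contig overlaps trimmed. Anchors are sampled every
k/2 positions with a dense retry, so any true block ≥ 2k is found. This
is exact by construction for the mutation-free simulated contigs the
framework validates; externally assembled contigs carrying SNVs or indels
need an external aligner — a documented limitation, since such contigs are
outside the synthetic validation surface. Simulated contig sets may bypass
alignment entirely through their recorded truth blocks; both routes give
identical breakpoints on simulated data (tested).

A junction between adjacent blocks is classified as translocation
(different replicons), inversion (opposite strands), or relocation (same
replicon and strand with a reference-vs-contig gap discrepancy whose
absolute value exceeds the relocation threshold, default 1000 bp —
configurable, as the extensive-misassembly convention of assembly
validators; smaller discrepancies are tolerated without breaking).
Corrected NG50 is NG50 over the piece lengths after cutting every contig
at its junctions (m junctions → m+1 pieces partitioning the contig);
NGA50 is NG50 over aligned-block lengths, unaligned portions contributing
nothing. Whenever all three are defined, NGA50 ≤ corrected NG50 ≤ NG50.
Length ties in reports are broken by contig name for determinism.

## Library quantification

`nM = conc / ((AIS + 120) · 650) · 10⁶`, with the 120 bp adapter
allowance and 650 g·mol⁻¹·bp⁻¹ dsDNA mass exposed as overridable
constants because protocol chemistry may differ. The Bioanalyzer
correction `AIS = 0.564 · AIS_Bio + 258` ships as the default
`RegressionModel`; refitting uses unweighted ordinary least squares
(no weighting scheme is published for this calibration) on raw-read
remap estimates. Triplicate averaging of concentration and AIS_Bio
readings is the caller's responsibility — operations take scalars.

## Factorial study

The default design is the four-genome benchmark: Bce (35.4 % GC), Efa
(37.8 %), Sen (52.2 %), Pst (63.9 %); Bce/Efa/Pst with three insert
categories × five read lengths × two depths, Sen with two categories ×
five read lengths × one depth, all in triplicate — 300 sub-libraries, 100
cells, and with four assemblers 1200 optimal assemblies reduced to 400
validation entries. A fifth, very GC-rich genome is deliberately absent
from the default design (its sequenced strain diverges from its reference
in the emulated study); inclusion is a config-level genome list, not
automated divergence detection.

Study genomes default to 30 kb — a deliberate scale-down of megabase
bacterial chromosomes chosen so the full 300-sub-library factorial runs
at desk scale; every planted repeat family (800, 160, 120 bp × 3 copies)
is far below the insert presets' resolution boundary or above it in the
same way it would be on a full-size genome, so score *structure* is
preserved even though absolute NG50 values are not comparable to real
assemblies. Per-library read counts are
`ceil(margin · d_max · G / 2L_min)` with margin 5, sized so the worst
surviving fraction after (80;20) filtering still covers the largest
subsample.

Replicate seeds derive from `blake2b(master seed, sub-library key)`, so
triplicates are independent yet the whole study is reproducible from one
integer; reports are byte-identical across reruns (tested).

**Contig providers.** Assemblers themselves are out of scope. Two
providers ship: (a) a *truth-based fragmenter* that emulates an idealized
assembler whose only failure mode is repeat collapse — a repeat copy is
resolved when reads span it (repeat < L − 20) or pairs bridge it
(repeat + 2·30 bp mate anchors ≤ span_factor · mean insert), and every
unresolved copy cuts the reference, dropping the repeat interval. The
per-assembler `span_factor` (spades 1.0, abyss 0.85, velvet 0.0 — run
without scaffolding, edena 0.3 — an overlap assembler with limited pair
usage) is a synthetic emulation knob that creates assembler contrast, not
a measured property of those tools. (b) An *external-command adapter*
that renders shell commands from a template for real assemblers but never
executes anything inside the pipeline or tests; its results re-enter
through a precomputed-contig provider.

**Selection and scoring.** Among a parameter sweep's candidates the
optimal assembly has the largest N50, ties broken by fewest contigs, then
largest average contig; a residual tie goes to the smallest parameter
label (the published rule ends at the third criterion; the label rule is
this package's deterministic completion). Replicate metrics are averaged
into validation entries; an undefined NG-family value is excluded from
the mean with its count recorded and the entry flagged, never imputed.
Relative scores divide each manifestation's mean by the group maximum —
by genome for the assembler factor, by genome × assembler otherwise — so
every group's best manifestation scores exactly 1 (ties all score 1).
Groups in which a factor has a single manifestation (e.g. depth for the
single-depth genome) trivially score 1 and are retained; a factor with
fewer than two manifestations study-wide gets no score table. The
top-fraction summary counts scores ≥ 0.95, inclusive.

## Numerical and serialization choices

Undefined metrics serialize as `NA`. Report TSVs begin with a commented
provenance header (tool version, config hash, master seed); FASTA/FASTQ
cannot carry comment lines without breaking the format, so provenance for
sequence outputs goes to the run log instead. Logs contain no timestamps,
keeping reruns byte-identical. Derived seeds are 31-bit. Phred values are
clamped to [2, 40] after rounding.

## Problem sizes used in validation

The shipped test suite and acceptance script use: 10⁴ read pairs per
point for filter-trend and distribution checks, 1000 random length
multisets against an independent sort-and-scan oracle, 100 simulated
contig sets for the metric-ordering invariant, 50 sets with injected
misassemblies for truth recovery, 20 noise seeds for
regression-coefficient recovery, and the complete default factorial
(300 sub-libraries / 1200 assemblies / 400 entries) on 30 kb genomes.
These sizes were chosen as the package's own validation scale; all
stochastic checks are seeded.

## Known limitations

* No nucleotide-level sequencing-error model, adapter contamination or
  PCR bias (the emulated preparation is PCR-free); quality scores alone
  drive filtering.
* The aligner is exact-match only; real assembler output with SNVs/indels
  requires external alignment before metric computation.
* The truth-based contig provider ignores sequencing depth (its failure
  model is repeat collapse only), so depth manifestations tie at S = 1
  under default settings.
* Quality-model magnitudes are simulator conventions; only directions and
  orderings of the trends carry over to real data.
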