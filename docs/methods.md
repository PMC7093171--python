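# Methods

## Perfect SSR model

A locus is a maximal uninterrupted run of a primitive repeat unit of length
1–6 bp. "Primitive" means the unit is not itself a whole-number repetition
of a shorter unit, so a poly-A run is reported once, with unit `A`, never as
`AA` or `AAA`. "Maximal" is defined at the unit phase: the run cannot be
extended by one base on either side such that `seq[i] == seq[i+k]` still
holds. Trailing partial units are truncated, so the reported span is always
`unit_length × rcn` bases and the span sequence is exactly the unit
repeated `rcn` times. Imperfect and compound repeats are out of scope.

Detection compares the sequence against itself at each phase shift
k = 1..6 (`seq[i] == seq[i+k]`, vectorised with numpy) and reads maximal
runs off the resulting boolean arrays. Candidates whose unit is
non-primitive are dropped (the k/d-periodic run is found at the smaller
phase). `N` fails the base-validity mask and therefore terminates runs;
lowercase (soft-masked) bases are uppercased first; any character outside
`ACGTN` raises an error naming its 1-based position.

Overlap resolution is greedy left to right: candidates are ordered by
(start, unit length, −span) and a candidate is kept only if it starts after
the last consumed base. This prefers smaller units when two units explain
the same run, then earlier starts, then longer runs, and guarantees each
base belongs to at most one reported locus. The same rule is restated
independently in the test oracle, and miner/oracle equality is asserted
exhaustively on random sequences.

Minimum repeat copy numbers default to mono ≥ 12, di ≥ 7, tri ≥ 5,
tetra/penta/hexa ≥ 4 — the widely used "systemic" settings of large genome
surveys. They are a convention, not a derived quantity, and are
configurable everywhere (`MiningThresholds`, `--min-rcn`).

## Motif canonicalisation

Two units describe the same repeat if one is a circular permutation of the
other or of its reverse complement (same locus read from a different phase
or strand). The class representative is the lexicographic minimum over the
union of both rotation sets; it is idempotent and constant on each orbit.
Exhaustive enumeration over all primitive k-mers yields 2, 4, 10, 33, 102
and 350 classes for k = 1..6, which the test suite re-derives.

## Genomic region partition

Every base receives exactly one of five classes: 5′UTR, CDS, intron, 3′UTR,
intergenic. Structure comes from GFF3: the longest transcript per gene (by
summed exon length) defines exons and CDS; introns are the gaps between its
consecutive exons; UTRs are the exon−CDS remainder, sided by strand and
position relative to the CDS span. Overlapping annotation resolves with
precedence CDS > UTR > intron > intergenic. Transcripts without CDS
contribute introns only. Transposable elements are an *overlay*, not a
sixth partition class: TE intervals (BED, converted to 1-based inclusive)
may coincide with any base class, mirroring how TE-resident SSR counts are
usually reported alongside, and overlapping, genic/intergenic tallies.

The partition is materialised as a byte-per-base class array per sequence.
This makes interval arithmetic exact and the partition property (class
lengths sum to genome length) trivially checkable, at the cost of ~1 byte
per base — appropriate for the simulated and modest-sized genomes this
package targets, not for multi-gigabase assemblies.

Boundary-spanning loci are assigned by their **start coordinate** (single
counting, deterministic). TE-resident loci stay in their base class and are
additionally counted in the TE overlay column; `te_exclusive=True` moves
them out of the base classes instead. Both rules are config switches because
published surveys rarely state their convention.

## Summary statistics

* Relative abundance = loci / (class length / 10⁶); the denominator is the
  merged interval length of the class searched, in bp.
* GC content is computed over pooled repeat spans only (not flanks), from
  (unit, rcn) — exact because spans are perfect repetitions. An empty group
  has missing (NaN) GC, not 0.
* CV = S/x̄ × 100% over the RCN values of a group. S is the sample SD
  (n−1 denominator) by default, with `ddof=0` available, since the formula
  itself does not fix the denominator. CV is undefined (missing, with a
  reason code) for n < 2 or non-positive mean; it is scale-invariant and 0
  for constant input.
* Displayed tables round percentages, #/Mb and GC to 2 decimals;
  machine-readable outputs keep full precision.

## Marker screening

Candidate markers are tetranucleotide loci (larger allele spacing and less
PCR stutter than dinucleotides) with RCN in a configurable window (default
7–15), exactly 200 bp of flank on each side within the contig, and no other
detected SSR inside either flank. An optional exact-substring uniqueness
check of each flank against the whole genome is off by default (quadratic
cost). Primer design itself is downstream; primer length (18–23 bp) and
expected product size (190–450 bp) are recorded as metadata in the export.
Each candidate is either passing or carries machine-readable rejection
reasons, and widening the RCN window can only add passes (monotonicity,
tested).

## Diversity statistics

For each locus with N typed diploid individuals and allele counts
N_a over 2N gene copies:

* Ho = share of typed individuals with two distinct alleles.
* He = 2n/(2n−1) · (1 − Σp̂ᵢ²) (Nei's unbiased estimator; the plain
  plug-in form is a switch, since published tables rarely say which they
  used).
* PIC = 1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ² (Botstein), computed via
  (Σp²)² − Σp⁴ for the double sum; PIC ≤ gene diversity always.
* Ar(g) = Σ_a [1 − C(2N−N_a, g)/C(2N, g)] — the expected number of
  distinct alleles in a rarefied draw of g gene copies, exact binomials.
  g defaults to the minimum 2N across loci so values are comparable under
  uneven missingness; Ar(2N) = k and Ar is non-decreasing in g.
* HWE: exact conditional test. Given the allele counts, the probability of
  a genotype array is N! 2^H Πc_a! / ((2N)! Πn_ab!); the P value sums the
  probabilities of all arrays no more probable than the observed one.
  Arrays are enumerated recursively while the array space stays below
  `max_enum_arrays` (default 200,000); beyond that a Monte-Carlo
  permutation of the gene copies is used (default 100,000 replicates,
  explicit seed) with the (hits+1)/(reps+1) estimator, which keeps
  P ∈ (0, 1] and remains valid under the null. Monomorphic loci return
  P = 1 by convention. Ties in probability are compared with a 1e−9
  relative tolerance so enumeration and permutation agree on discrete
  spectra.
* Loci with P below `hwe_alpha` (default 0.01, no multiple-testing
  correction — deliberately mirroring common marker-panel practice) are
  flagged as candidates for removal.

## Synthetic data

The genome simulator emulates the input bundle of a survey: i.i.d.
background bases at a chosen GC fraction (default 0.42, mammal-like), genes
laid out left to right with alternating CDS exons and introns, UTRs at the
transcript ends, both strands, written as GFF3; TE intervals inside
intergenic and intronic DNA; and SSRs planted with controlled per-region
counts (intron/intergenic-heavy, coding sparse), unit-length mix
(mono-heavy, hexa-rare) and per-unit RCN ranges. Planted units are sampled
primitive and "clean" (the unit repeated rcn times mines back as exactly
itself), flanking bases are adjusted so runs are not phase-extendable, and
after planting the sequences are scrubbed: the miner runs and any
accidental background run meeting the thresholds is broken by a point
substitution until mining output equals the truth table exactly. The truth
TSV therefore lists the complete, exact mining result with region labels
and TE flags, and the end-to-end test compares two independent derivations
of the region counts (simulator paint vs GFF3-built model).

What the simulator does **not** emulate: real repeat length distributions
and mutation processes (no slippage model), TE sequence content (intervals
only), isoform complexity, assembly gaps and base-quality artefacts.
Passing the planted-recovery tests shows the algorithms are exact on
well-specified input, not that biological conclusions transfer to any real
genome.

The genotype simulator draws, per individual and locus, a homozygote
(i,i) with probability pᵢ² + F·pᵢ(1−pᵢ) and a heterozygote (i,j) with
2pᵢpⱼ(1−F); F = 0 (HWE) by default, missing calls masked at a configurable
rate. Defaults mirror a small captive-population design of 36 individuals.

## Problem sizes and seeds

The default simulated genome is three 120 kb sequences with 500 planted
SSRs — large enough that every region class and unit length is populated,
small enough that the full suite runs in about two minutes. The HWE
calibration uses 1,000 loci at 36 individuals with 4,000 Monte-Carlo
replicates per multi-allelic locus (enumeration below 20,000 arrays);
binomial error at those sizes is accounted for in the assertions (3 SE
bands). All randomness flows through explicit `numpy.random.default_rng`
seeds; identical (spec, seed) pairs produce byte-identical simulator
output, and pipeline reports embed the config hash and seed so re-runs are
byte-reproducible.

## Known limitations

* Byte-per-base region arrays cap practical genome size (~10⁸ bp).
* The flank-uniqueness screen is exact substring containment, not a
  mappability or alignment-based check.
* He/PIC estimates at n = 36 carry O(1/n) plug-in bias for PIC (~0.01);
  the unbiased correction is applied to He only, as is conventional.
* The exact HWE enumeration bound is counted in arrays produced; highly
  polymorphic loci fall through to Monte-Carlo, so P values there carry
  O(1/√reps) noise.
* Bundled published tables are inputs for the aggregation layer; the
  underlying assembly is not public, so genome-scale mining results cannot
  be regenerated from raw data.
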