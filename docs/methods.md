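# Methods

This note records the models, conventions and numerical choices behind
`atacatlas`, in the spirit of a methods appendix: what each stage computes,
what the synthetic generator does and does not emulate, and where open
design choices were resolved.

## Coordinates and containers

All genomic coordinates are 0-based, half-open (`[start, end)`, BED
convention) everywhere inside the package; 1-based dialects must be
converted at the I/O boundary. A fragment is a single interval derived from
a read pair; the package never represents mates separately. Peaks and TSSs
are `GenomicInterval` objects; fragments are held in an array-backed
`FragmentSet` because samples carry 10⁵–10⁸ of them. Matrices are pandas
DataFrames written as TSV with a `NA` sentinel for missing values and
`repr`-precision floats, so a write/read round trip is exact.

The bundled sample sheet is a plain-text transcription of a published
66-library mouse tissue panel (20 tissues, male and female, two technical
replicates per tissue-sex). Count columns keep the printed thousands
separators; the reader strips them. One obvious typographical duplication
of a sample identifier in the printed table (the second cerebellum
replicate) was corrected to the missing consecutive identifier so that
sample IDs are unique.

## Sample QC

**Usable-read percentage** is `100 × usable / total`, rounded to two
decimals for reporting; `usable` counts mapped reads surviving
mapping-quality, duplicate and mitochondrial filtering and is also the RPM
denominator. Mitochondrial reads are bookkeeping only — the package never
models a chrM sequence.

**TSS enrichment.** No single published formula defines this score, so the
package adopts the ENCODE-style convention with every width exposed as a
parameter: per-base fragment coverage is summed over all TSS-centered
windows (half-width 1000 bp, minus-strand windows flipped), averaged over
TSSs, and divided by the mean aggregate over the outermost 100 bp at both
edges; the profile is smoothed with a 25 bp moving average and the maximum
reported. A TSS-independent fragment distribution scores ≈ 1. If no
fragment touches any flank the score is undefined (NaN with a warning)
rather than infinite. Because the convention differs in detail from any
specific upstream pipeline, exact reproduction of published per-sample TSS
scores is not claimed; the bundled sheet carries the published values as
data.

**Fragment-size profile.** Lengths are binned at 1 bp over 1..1000
(longer fragments accumulate in the last bin so the histogram always sums
to the fragment count), smoothed with a 5 bp moving average; modes are
local maxima with prominence ≥ 5% of the smoothed maximum, and the period
estimate is the median spacing of consecutive modes. The 5% floor
deliberately ignores very minor modes; with the default length mixture the
tri-nucleosome mode (weight 0.05) falls below it, which is why mode
*recovery* is assessed on a mixture with heavier nucleosomal weights.

**Exclusion rule.** A sample fails QC if TSS enrichment < 10.0 **or**
reproducible peaks < 10,000, both strict. The disjunctive reading (either
deficiency disqualifies) is the conservative interpretation of the
published filtering sentence; both thresholds are parameters. Applied to
the bundled sheet it excludes 22 of 66 libraries. The absolute peak
threshold presumes a mammalian-genome peak universe; the synthetic demo
configuration (`PipelineConfig.synthetic_demo`) rescales it to 75% of the
simulated peak count, since a toy genome carries only hundreds of peaks.

## Peak consolidation and the counts matrix

**Replicate reproducibility.** The published analysis used IDR; this
package deliberately replaces it with a declared, simpler filter: a rep1
peak is retained when some rep2 peak overlaps it by at least
`min_overlap_fraction` (default 0.5) of the *shorter* peak. Retained peaks
keep rep1 coordinates (deterministic and simple); an intersection mode is
available behind a flag. The full IDR copula mixture model is out of scope.

**Consensus merge.** All tissues' reproducible peaks are merged into
maximal intervals; bookended intervals (end = start) merge, matching common
merge semantics. Consensus peaks are named sequentially and carry the
number of contributing tissues as their score.

**Counting.** A fragment increments a peak's count iff they share ≥ 1 bp
(any-overlap, interval-intersection semantics). Consensus peaks are
non-overlapping by contract — the counter validates this — so a fragment
spanning two bookended peaks increments both, which is documented behavior.
Counting fragments (not mates) is the default unit; at typical insert
sizes the distinction only rescales library size.

**Normalization.** RPM = raw × 10⁶ / library size, with library size =
usable reads (for synthetic data, the emitted fragment total — identical by
construction). The log layer is log₁₀(RPM + 1); the pseudocount keeps
zeros at zero and is configurable.

## Tissue specificity

Per-tissue accessibility `E_i` is the arithmetic mean RPM over all samples
of tissue *i*, pooling replicates and sexes, so that N in the entropy range
`0..log₂ N` is the number of tissue *types*; a `tissue_sex` mode keeps the
33 tissue-sex groups separate instead. Raw RPM (not log RPM) enters the
ratio `R_i = E_i/ΣE`, using the convention `0·log₂ 0 = 0`. Peaks with
`ΣE = 0` have undefined entropy and are excluded from classification
(reported as NA) rather than silently counted.

The restricted call is `H < threshold`, strict. The reference threshold of
3.5 bits belongs to a 20-tissue panel (maximum 4.32 bits); when the panel
size differs and no explicit threshold is given, the default rescales
proportionally (`3.5 / log₂ 20 × log₂ N`). An Otsu-style data-driven
threshold on the entropy histogram is provided for regimes where the
restriction fold-change differs from what the fixed cutoff presumes; it is
the recommended choice when a ground-truth-free, distribution-based cutoff
is wanted (the published rule itself was chosen from the score
distribution). Restricted peaks are assigned to their argmax-`R_i` tissue;
exact ties break lexicographically with a warning.

## Reproducibility analysis

Pearson correlations are computed between sample columns of the log₁₀ RPM
matrix over all consensus peaks. Constant columns give undefined
coefficients (NaN, flagged) and are excluded from clustering. Hierarchical
clustering uses Euclidean distance with average linkage by default
(complete and single available); it delegates to SciPy's agglomerative
implementation, and the test suite checks its merge heights against a
brute-force oracle on small instances. The linkage method is not specified
in the published analysis; average linkage is the conventional default for
correlation/enrichment heatmaps.

## Motif summary

The motif stage's defined computation is the *matrix summarization*, not
motif discovery. The built-in scan is a consensus matcher: a sequence is a
hit when the motif or its reverse complement occurs with at most
`max_mismatch` mismatches (IUPAC degeneracy honored; an `N` in a sequence
matches only an `N` in the consensus). Enrichment of a tissue's
restricted-peak sequences over a background set is the one-sided
hypergeometric tail of the hit table, reported as −log₁₀ P and capped at
300 to avoid infinities. The background is drawn from non-restricted peak
sequences, count-matched by deterministic downsampling. The matrix stage
equally accepts a precomputed motif × tissue −log₁₀ P table from an
external scanner, making the display rule — row mean strictly > 20, top 50
by coefficient of variation (sample SD / mean, undefined at zero mean),
ties broken by motif id — and the Euclidean tissue clustering usable on
real motif-scanner output. At synthetic scale (tens of target sequences)
−log₁₀ P cannot reach means above 20, so the pipeline falls back to
clustering on the full matrix when the display rule keeps nothing, and
records that in the manifest.

## The synthetic atlas generator

The generator emulates the statistical structure the pipeline consumes,
not sequence-level biology. A toy genome (default 5 × 10 Mb) carries
non-overlapping peaks (default 400 shared + 200 restricted, widths
300–800 bp) placed by exact gap allocation — no rejection sampling, so
infeasible requests fail with a clear error — with ≥ 1 kb between peaks
and 2 kb chromosome-end margins. TSS points (default 300) are placed
≥ 2.5 kb from any peak so TSS-proximal fragments never contaminate peak
counts.

Each sample's fragments are drawn by a single multinomial over
[background, TSS excess, peak₁..peak_J] with exactly
`fragments_per_sample` draws (conservation is exact). Background midpoints
are uniform over the genome; TSS-excess midpoints are Gaussian around a
random TSS (SD 150 bp, truncated at ±1 kb); in-peak midpoints are uniform
within a peak chosen proportionally to the sample's rates. Rates are unit
baseline for every peak, multiplied by `restricted_fold` for a restricted
peak in its home tissue, and jittered per sample by multiplicative gamma
noise with unit mean and variance `dispersion` — the simplest
overdispersion model that produces negative-binomial-like replicate
scatter. Fragment lengths come from a four-component normal mixture
(means 60/200/400/600 bp, weights 0.45/0.35/0.15/0.05), rounded and
clipped to 20..1000 bp; the interval is midpoint ± length/2 clipped to the
chromosome. Per-replicate "peak calls" are the true peaks with independent
10% dropout, giving the reproducibility filter real work. Read accounting
(total/mapped/chrM) is drawn as plausible fractions around the usable
count and is bookkeeping only.

Default study conditions mirror the target design: 20 tissues × 2
replicates, 250,000 fragments per sample (≈ 230 expected fragments per
shared peak), background fraction 0.25, TSS fraction 0.05, dispersion
0.05. The restriction fold default is 16, chosen so that a restricted
peak's expected entropy (≈ 3.3 bits against 19 unit-weight tissues) falls
clearly below the 3.5-bit reference cutoff — i.e. the generator's
"tissue-restricted element" is an element the published rule would call
restricted. No published fragment-length mixture or fold-change exists;
these are modeling choices.

`expected_counts` is the analytic oracle: the in-peak expectation is
`N · (1 − bg − tss) · w_j / Σw` from the noise-free rates, plus an optional
uniform-background overlap term
`N · bg · (width + mean_length − 1) / genome_size`. Edge clipping and
length rounding are neglected there; both effects are orders of magnitude
below sampling noise at any tested size. Convergence of observed counts to
this expectation is tested with dispersion off (so sampling is the only
noise); with dispersion on, the gamma jitter sets a depth-independent
floor on relative error, which is expected.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: Tn5 insertion-sequence bias, GC and
mappability structure, peak-strength heavy tails (all peaks share a unit
baseline), chromatin domains and peak clustering, mitochondrial and
duplicate reads as positional objects, between-animal biological
variability beyond the single dispersion knob, and any sequence-level
realism in the planted motif sequences (uniform random background, no
dinucleotide structure). Results on real atlases depend on upstream
alignment/peak-calling choices the package deliberately leaves out.

## Pipeline and determinism

The pipeline wires the stages in order (simulate/load → QC metrics →
replicate filter → QC exclusion → merge → count/normalize → specificity →
correlations → motif summary), writes every intermediate as text via the
package's writers, and emits a JSON manifest with the package version, the
seed, a hash of the analysis configuration (excluding the output
directory) and per-stage counts. One global seed drives everything;
per-stage sub-seeds are spawned from it via `numpy.random.SeedSequence`,
so identical config + seed reproduces byte-identical outputs. Replicate
pairing is by (tissue, sex); an unpaired sample's own calls stand in for
the reproducibility filter, and both members of a pair carry the pair's
reproducible-peak count, mirroring how the published table reports it.

Problem sizes used in the shipped tests and the acceptance script — a
study-scale panel of 20 × 2 samples at 250k fragments, plus smaller panels
for focused checks — were chosen as the smallest sizes at which each
statistical signature (entropy separation, correlation block structure,
nucleosomal modes) is unambiguous.

## Known limitations

* The reciprocal-overlap filter is not IDR; peak sets with systematically
  shifted replicate coordinates will behave differently.
* The entropy index ignores replicate variance; a peak with one noisy
  high-RPM tissue can fall below threshold. The data-driven cutoff
  mitigates but does not remove this.
* The hypergeometric motif test treats sequences as exchangeable and
  ignores sequence composition; it is a summarization stand-in, not a
  competitive motif-discovery method.
* `tissue` aggregation pools sexes; genuinely sex-dimorphic elements are
  averaged (use `tissue_sex` mode to see them).
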