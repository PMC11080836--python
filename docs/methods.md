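# Methods

This note records how `dimerqc` models the problem, the choices made where
the design was genuinely open, and what its synthetic-data validation does
and does not establish. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Adapter matching

The matcher solves a semi-global alignment problem: place an adapter of
length *m* inside a read of length *n* under unit-cost edit distance
(substitution, insertion, deletion each cost 1), with read ends free in the
mode-appropriate way. Three dialects mirror how trimming tools treat 3'
adapters, 5' adapters and "either" adapters:

- **back** — full adapter anywhere in the read, or an adapter *prefix*
  whose alignment reaches the read's 3' end (read-through off the end);
- **front** — full adapter anywhere, or an adapter *suffix* starting at
  the read's 5' end;
- **anywhere** — the union of both (used for Ion Torrent libraries, where
  the construct can present the adapter on either side).

A candidate is admissible iff `errors ≤ ⌊error_rate · k⌋`, where *k* is
the number of adapter bases in the alignment (the error budget scales with
how much adapter is actually aligned, floor-rounded), and `k ≥ min_overlap`
(default 3, the conventional trimming default; the smallest overlaps are
almost always spurious but cheap to allow, and the error budget at k = 3 is
zero for every preset rate). `N` never matches anything. Among admissible
candidates the winner is chosen by a total order — fewest errors, then most
adapter bases aligned, then smallest start, then smallest end — so results
are bit-stable. One documented consequence: a short zero- or one-error
overhang candidate can outrank a full-length alignment carrying more
errors, because error count is ranked before alignment length.

The implementation is a row-vectorized dynamic program over batches of
equal-length reads. Each DP cell carries the lexicographically minimal
(cost, start) pair packed into one integer, so exact tie-broken start
coordinates fall out of the DP without traceback; the front dialect runs
the same DP on reversed sequences carrying the maximal start, which maps to
the minimal end in original coordinates. Correctness is established against
two independent oracles in the test suite: a brute-force enumeration of
every (start, end) span scored by global edit distance, and a faster
enumeration (one semi-global edlib call per start or truncation length)
shown equivalent to the brute force. The matcher agrees with the oracle on
10⁴ randomized (read ≤ 100 nt, adapter, error-rate) triples.

## Read classification

Per read, in order: (1) find the 3' adapter; if the insert in front of it
(behind it, for a 5'-side hit in anywhere mode) is ≤ `dimer_max_insert` nt,
the read is a **DIMER**. The default window is 2 nt rather than 0: real
ligation junctions occasionally carry one or two junk bases, and the strict
"adapter at position 0" definition is recovered by setting it to 0.
(2) Remove the adapter and everything beyond it; run the 5'-primer pass
where the profile configures one. (3) Quality-trim the 3' tail with the
partial-sum rule (the standard BWA-style `-q` algorithm): cut at the
position minimizing the running sum of `qual − threshold` accumulated from
the 3' end, keeping the most bases on ties. (4) Reads now shorter than
`min_length` (15 nt) are **SHORT** when the shortfall is attributable to
the insert (an adapter was found, or the read was already sub-minimum
before quality trimming) and **LOW_QUALITY** otherwise. (5) Everything else
is **CLEAN**. Dimers are ranked above short reads so the two loss causes
are never double-counted. The four counts partition the raw total exactly —
an invariant asserted on every sample the tests produce.

Both platform presets quality-trim with the same partial-sum rule. One
published pipeline this mirrors used windowed trimming for its Illumina
arm; at Q20 on high-quality data the difference is a handful of bases at
read tails and does not move class fractions measurably, but it is a
dialect difference worth knowing about.

## Per-sample diagnostics

`adapter_content_curve[p]` is the percentage of reads whose 3'-adapter
match starts at or before position *p* — non-decreasing, bounded by 100,
and its value *at position 0* is the dimer fingerprint. Overrepresented
sequences are exact full-read counts with a strict > 0.1% threshold; no
truncation or subsampling is applied, preferring exactness over mimicry of
screening tools at the scale this package targets.

## Cohort segmentation

Samples are sorted by read-loss percentage; loss is regressed on rank
(1..n) — the rank axis matches how such cohorts are plotted and makes the
slope a "% loss per sample" quantity. Every placement of 0, 1 or 2
breakpoints (≥ 3 samples per segment) is fit by OLS and the model
minimizing `n·ln(RSS/n) + k·ln(n)`, `k = 2·segments + breakpoints`, is
selected — an explicit, reproducible formalization of the visual
"slope plus best R²" grouping practitioners apply by eye. The search is
exhaustive at any realistic cohort size (≤ 500 samples), so the selected
model *is* the BIC optimum; RSS is floored at `n·10⁻¹²` so exactly-linear
data selects the single-segment model instead of comparing logs of zero,
and a segment with zero loss variance reports R² = 1 for an exact fit.
BIC at this sample size still admits an occasional spurious extra segment
in two-regime data; the true breakpoint remains among the fitted ones, and
recovery is measured that way (within ± 1 rank in ≥ 90% of simulated
two-regime cohorts).

RNA input vs. loss uses Spearman rather than Pearson correlation because
input quantities span orders of magnitude across experiments; the p-value
is an exact two-sided permutation enumeration for n ≤ 9 and the
large-sample approximation above that.

## Expression-level batch-effect test

log-CPM: `log2((c + p) / (lib + 2p) · 10⁶)` with prior p = 2 — the prior
and the top-500 leading-log-fold-change pairwise distance mirror the
defaults of the standard MDS approach for count data; both are exposed as
parameters since published analyses rarely state them. Classical MDS by
double-centering and eigendecomposition; coordinates are top-k eigenvectors
scaled by √eigenvalue (negative eigenvalues clipped to zero), each axis'
sign fixed so its first nonzero loading is positive. For
Euclidean-embeddable distance matrices the embedding reproduces the input
distances to numerical precision (≤ 1e-9, asserted), and the coordinates
match an independent principal-coordinates implementation up to axis sign.

The association test formalizes the visual claim "samples cluster by dimer
content": Spearman rho between per-sample dimer percentage and each MDS
coordinate, with `p = (1 + #{perm: |rho*| ≥ |rho|}) / (n_perm + 1)` under
seeded permutations of the dimer vector. Calibration is checked on a null
where contamination is *dimer-independent by construction*: every sample
has the same expected dimer fraction (realized fractions vary binomially)
and no composition coupling. Note that unequal *expected* dimer fractions
are not a null even without coupling — contamination then shifts usable
depth, and depth interacts with the log-CPM prior to move coordinates;
that is a real technical artifact of contamination, not a test defect.

## Simulator

The generator emulates the library construct geometry of both chemistries.
Illumina: `insert + 3' adapter + post-adapter construct tail`, truncated to
the fixed 75-nt read length and padded with `G` beyond the construct end
(two-channel chemistry reports no-signal as G), so error-free dimer reads
sequence identically — which is exactly why dimers surface in
overrepresented-sequence screens. Ion Torrent: `insert + 3' adapter`,
variable length, with indels applied by default as the platform's dominant
error mode. Defaults: clean inserts Normal(22, 3) clamped to [15, 30] nt
(miRNA-sized), substitution rate 0.01, Ion indel rate 0.01, qualities
linear-decay 36 − 0.05·position with Gaussian jitter (σ = 2) clipped to
[2, 40] — a deliberately simple quality model, sufficient to exercise the
trimming path, not a claim about real instrument error profiles.

SHORT-class inserts are drawn uniform on [3, 14] nt: the lower bound sits
one base above the classifier's default dimer window so the generative
truth labels and the operational dimer definition use the same boundary —
with inserts of 1–2 nt the two would contradict each other by construction.
`matching_profile(config)` returns the pre-processing profile that matches
the simulated construct (notably without a 5'-primer pass, since simulated
reads start at the first insert base and contain no residual primer; a
primer pass run anyway occasionally makes spurious 3-nt zero-error front
matches on random insert prefixes — a known property of short-overlap
front trimming, not a bug).

Cohorts share one feature universe and per-sample seeds spawned
deterministically from the cohort seed. `dimer_bias_coupling` tilts each
sample's feature abundances multiplicatively on the log scale along one
fixed random direction, proportionally to its dimer fraction — the
mechanism that turns contamination into an expression batch effect for
power studies. `make_reads=False` draws class and feature counts
multinomially without constructing sequences (distributionally identical,
orders of magnitude faster), which is what the calibration and power
simulations use.

What passing these tests shows: the pipeline recovers the truth of data
generated under its own construct model, exactly without noise and within
binomial error with noise. What it does not show: robustness to PCR
duplicates, homopolymer error spectra, flow-cell density effects, real
miRNA sequence composition, or adapter sequences diverging from the
configured ones — none of which the generator emulates.

## Electropherogram peak calling

The trace is smoothed with a 5-point moving average; the baseline is the
5th percentile of the smoothed signal, and the noise scale is the median
absolute deviation of the *entire* smoothed trace (normal-scaled): peaks
occupy a minority of points, so the MAD tracks baseline noise, whereas a
MAD taken over a lower-quantile slice of the value distribution collapses
to near zero. A qualifying peak must exceed the baseline by 3×MAD in
height *and* by 6×MAD in prominence; the prominence gate is what makes the
caller robust — a bare height threshold at 3×MAD is exceeded by the
maximum of several hundred noise points with roughly even odds at any
noise level. Per window the tallest qualifying peak is called; areas are
trapezoidal over the window after baseline subtraction, and
`dimer_ratio = dimer_area / (dimer_area + library_area)` (0 with no dimer
peak; 1 with a dimer peak and no library peak — all callable signal is
contamination). The ratio is reported, never thresholded into a verdict:
no quantitative cutoff for "too contaminated" is defensible across
instruments. Default windows: Ion Torrent dimer 80–95 bp / library
100–130 bp; Illumina dimer 110–130 bp / library 135–170 bp. Instruments
reporting migration minutes are handled by passing windows in minutes; no
time-to-bp ladder calibration is attempted. At signal-to-noise ≥ 10,
simulated two-peak traces are recovered with centers within 2 bp and
ratios within 0.05 (asserted over randomized configurations).

## Problem sizes used in validation

The test suite and acceptance script run at sizes chosen to make every
statistical bound sharp while remaining comfortable on a laptop: 10⁴
matcher-oracle triples; 20 noise-free libraries of 10⁴ reads (exact
read-level agreement) plus noisy libraries of 10⁴ reads (3-binomial-SE
fraction recovery); 100 two-regime segmentation cohorts of 40 samples;
200 null and 200 coupled 12-sample cohorts at 1000 permutations for
calibration and power; 100 randomized electropherogram configurations.

## Known limitations

- Only 4-line single-end FASTQ (Phred+33, optional gzip); no paired-end,
  FASTA, SAM/BAM, or UMI handling.
- One adapter-removal round per adapter; no linked-adapter logic and no
  adapter discovery from data.
- The segmentation regressor is rank, not loss magnitude; it stratifies
  ordered profiles and deliberately says nothing about causality.
- The batch-effect test detects association; it does not correct it.
- Electropherogram parsing is a 2-column CSV; proprietary instrument
  formats and molarity estimation are out of scope.
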