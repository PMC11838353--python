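# Methods

## The scan statistic and its null model

The scan tests, at every focal position m on a uniform genetic-distance
grid, whether the local IBD rate is elevated above the genome-wide
baseline.  The IBD rate is

    Y̅_m = f(n)^{-1} Σ_{(a,b)} Y_{a,b}(m),

where Y_{a,b}(m) indicates that haplotypes a and b share a detected IBD
segment at least `min_cm` long overlapping position m, and f(n) is the
number of eligible haplotype pairs: `2n(2n−1)/2 − 2n` for n diploids
(within-individual pairs removed) and `n²` for haploids.  The diploid
expression subtracts 2n although a sample has only n within-individual
haplotype pairs; we keep the conventional form used in IBD-rate scans so
rates are comparable with the existing literature, and correspondingly
exclude within-individual (homozygosity-by-descent) segments from the
numerator.

Under neutrality, asymptotic theory supports treating the standardized
rates

    Z̃_m = (Y̅_m − μ̂) / σ̂

as a stationary Gaussian process along the genome.  We model it as an
Ornstein–Uhlenbeck (OU) process: autocorrelation at genetic distance d
Morgans equals exp(−θ·d), with a single decay parameter θ per genome.
The per-position test rejects where Z̃_m strictly exceeds a genome-wide
quantile z*; ties go to the null.

All internal threshold mathematics uses Morgans (θ per Morgan, L and Δ in
Morgans) because the analytical approximation mixes θ·L and θ·Δ terms and
a mixed-unit implementation invites silent 100× errors; user-facing
surfaces take centiMorgans.

## Robust standardization

Strong recent selection produces rate outliers (a selected locus can sit
tens of standard deviations above the mean), which would corrupt the
moments used for standardization.  We use a two-pass rule: an initial
threshold of median + 4·SD computed over all M rates (sample SD,
denominator M−1), then a revised mean and SD over the rates at or below
that threshold.  All positions are standardized with the revised moments;
positions above the initial threshold are flagged and excluded from
autocovariance estimation.  The rule runs once — it is not iterated to
convergence, which keeps it deterministic and matches its purpose of
shielding the moments from a handful of extreme loci rather than fitting
a contamination model.

## Estimating θ

Autocovariances of the standardized track are estimated at lags kΔ for
k = 1, 2, … up to 4.0 cM, pooling all within-chromosome pairs (pairs never
span chromosome boundaries, and pairs involving flagged outlier positions
are dropped).  The estimator centers by the mean of included z values and
divides by the pair count; a switch (`center=False`) instead assumes mean
zero, the alternative reading of a standardized track — results differ
negligibly on tracks of realistic length.  θ̂ is the no-intercept
ordinary-least-squares slope of log ĉ_k on kΔ:

    θ̂ = −Σ_k (kΔ · log ĉ_k) / Σ_k (kΔ)².

Non-positive covariance estimates are dropped before taking logs; if
fewer than three remain the fit fails loudly rather than extrapolate.
The 4.0 cM lag cap bounds the fit to the range where the exponential
model holds and estimates are well populated.  On simulated OU genomes of
≥ 400 cM the median θ̂ is within 10% of truth for 30 ≤ θ ≤ 90, and the
estimate is insensitive to the grid spacing used (0.02–0.10 cM), as the
test suite verifies.  One θ is fitted per genome: chromosome-specific
decay is visible in autocovariance plots of real data but the thresholds
need a single genome-wide parameter.

## Genome-wide thresholds

Let L be the genome length in Morgans, C the number of chromosomes, Δ the
grid spacing in Morgans, and Φ, φ the standard normal CDF and density.

**Analytical.**  The boundary-crossing approximation for the maximum of a
discretely sampled OU process,

    P(max_m Z̃_m ≥ z) ≈ 1 − exp(−[ C(1−Φ(z)) + θ·L·z·φ(z)·ν(z√(2θΔ)) ]),

is root-solved for z on the bracket [1, 10] with Brent's method to
machine tolerance; plugging z* back in recovers the family-wise level to
better than 1e−10.  The discretization correction uses the rational
approximation

    ν(y) = (2/y)(Φ(y/2) − 1/2) / [ (y/2)Φ(y/2) + φ(y/2) ],

with ν(0) = 1 (continuous limit), evaluated through a Taylor series below
y = 0.1 to avoid catastrophic cancellation.  ν is strictly decreasing, so
coarser spacing yields a smaller z* (fewer effective tests).

**Simulation.**  The OU maximum can instead be simulated: J chains of
M = ⌊L/Δ⌋ steps — one chromosome of the total genome length, a deliberate
simplification — each started at N(0,1) with AR(1) transitions of mean
z_{m−1}·e^(−θΔ).  The published transition variance is 2 − 2e^(−θΔ) and
is the default; the exactly stationary form 1 − e^(−2θΔ) (which keeps
every marginal at unit variance; the two differ at O((θΔ)²)) is available
via `stationary_variance=True`.  The threshold is the order statistic of
rank ⌈(1−α)·J⌉ of the J chain maxima.  Default J = 2000; the recursion is
evaluated as a linear filter so a threshold takes about a second.
Guardrails require J ≥ 100 and α·J ≥ 5.

**Bonferroni.**  α* = α/M over the M grid tests, for reference; it
ignores the correlation structure and is roughly an order of magnitude
more stringent than the OU-based corrections at typical θ.

For θ ≤ 20 the analytical approximation is noticeably conservative and
the results summary recommends the simulation threshold.

## Grid construction

Focal positions are laid down per chromosome from the map start plus a
trim to the map end minus the trim, spaced Δ apart (default 0.02 cM).
The trim defaults to the segment detection threshold (2.0 or 3.0 cM):
positions closer than one detectable segment length to a chromosome end
cannot be flanked by a full segment on that side.  Ten 100 cM chromosomes
at Δ = 0.02 cM with a 2.0 cM trim give 4801 points each, M = 48,010
tests.  L is the untrimmed total genetic length.  Physical coordinates
are obtained by linear interpolation of the recombination map; flat
(zero-recombination) stretches invert deterministically to their leftmost
base-pair knot.

## Rate computation

A segment covers a focal position p iff its genetic span contains p as a
closed interval, with endpoint cM interpolated from the segment's
physical bounds (the closed convention makes threshold-length arithmetic
on the grid exact).  Coverage is accumulated with a difference array —
+1 at the first covered grid index, −1 past the last, then a cumulative
sum — which is O(segments + M) and verified against an all-pairs
brute-force oracle in the tests.  Segment endpoints outside the mapped
range are clamped to it.  A warning (not an error) is emitted when a
substantial fraction of rates is zero, the signature of a sample too
small to observe segments above the detection threshold.

## Region calling and diagnostics

Maximal runs of consecutive rejected grid points within a chromosome are
candidate regions; a run of r points spans (r−1)·Δ cM and is reported
when that span reaches `min_region_cm` (default 0.50).  No gap-merging:
one sub-threshold point splits a region.  Each region reports the
position and value of its maximum rate and an upper-tail normal p value
at the peak's z, written as the marker string `underflow` when the tail
probability is exactly zero in double precision.

Two diagnostics probe marginal significance: the max–min statistic
(window 3) replaces each position by the minimum of itself and its two
in-chromosome neighbours before taking the genome-wide maximum,
suppressing isolated one-point excursions; and the window-count
diagnostic partitions each chromosome into non-overlapping windows
anchored at its first grid point and counts windows containing at least
one rejection.  On OU nulls, genomes committing a family-wise error
typically do so in a single ≥ 0.20 cM window (median 1), which the test
suite checks.

## Synthetic data and what it does and does not show

`simulate_ou_genome` draws standardized tracks directly from the OU null,
one independent chain per chromosome.  It defaults to the exactly
stationary transition variance so that every marginal is N(0,1) and the
lag-k covariance is exactly exp(−θkΔ) — i.e. the generated data *is* the
null model the thresholds assume.  This choice matters for calibration
experiments: the published-form transition variance inflates the marginal
variance by ≈ θΔ/2, which is invisible in any single track but biases a
500-genome FWER estimate upward by about half a percentage point.  In the
FWER experiment the simulation threshold is computed with the same
transition variance as the genomes it is tested against.

`synthetic_segment_file` writes toy detector-style segment files (uniform
midpoints, shifted-exponential lengths, uniformly drawn haplotype pairs)
sized so the expected rate matches a target.  It exercises the full
pipeline — parsing, rate accumulation, standardization, thresholding,
region calling — but its segments are spatially unstructured: real IBD
rates have the long-range autocorrelation, demography-driven θ, and
heavy-tailed outliers that the generator omits.  Passing pipeline tests
on these fixtures demonstrates correctness of the plumbing, not FWER
control on real IBD processes; the latter is what the OU experiments
address, and even they exclude the non-OU tail behaviour of true
coalescent IBD rates, under which the 2.0 cM scan is known to be
somewhat anti-conservative.

## FWER calibration experiments

`run_fwer_experiment` simulates null genomes (default 500 replicates of
ten 100 cM chromosomes at 0.02 cM spacing), computes each method's
threshold once from the true θ (or, optionally, re-estimates θ per
replicate), and reports the fraction of genomes with at least one
rejection.  At θ = 50 and family-wise 0.05 the simulation threshold's
empirical FWER is ≈ 0.05 and the analytical threshold's is at or slightly
below 0.05, with binomial standard error ≈ 0.01 at 500 replicates.  These
problem sizes keep the experiment around ten seconds on one CPU while
leaving Monte Carlo error comfortably below the effects being measured.

## Numerical choices and degenerate inputs

* Root solving: Brent on [1, 10]; no derivative; a missing sign change is
  reported with the offending inputs.
* Empirical quantile: order statistic of rank ⌈(1−α)J⌉, no interpolation.
* Closed-interval coverage uses a 1e−9 cM tolerance in the grid-index
  arithmetic so segment ends landing exactly on grid points are included
  regardless of float rounding.
* All-identical rates (e.g. an all-zero track from an empty segment
  file) raise a degenerate-track error at standardization.
* A single RNG seed drives every stochastic component; fixed seeds give
  bit-identical thresholds, genomes, and experiment reports.

## Known limitations

* One genome-wide θ; no per-chromosome or distance-varying decay.
* Autosomes of panmictic samples; no X-specific baseline.
* The normal-OU null undercovers heavy-tailed IBD-rate processes (founder
  or strongly bottlenecked populations); a heavier-tailed driving process
  would be needed there.
* No IBD segment detection, phasing, or genotype I/O — the pipeline
  starts from detected segments.
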