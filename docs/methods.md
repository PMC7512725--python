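# Methods

This note documents the models and conventions behind `dispen`: what
each estimator computes, the defaults and why, what the synthetic
generators emulate, and where genuinely open design choices were
resolved.

## Coarse-graining (mapping module)

All dispersion statistics start by mapping the signal to an integer
alphabet `1..c`.

* **Standardization.** The sigmoid-family maps use the mean μ and the
  *population* standard deviation σ (divide by N) of the analyzed
  signal itself.  The choice of denominator is immaterial beyond
  O(1/N) and only shifts class boundaries infinitesimally; population
  moments keep the transform symmetric in the samples.
* **Transfer functions.** `logsig`: `1/(1+e^{−(x−μ)/σ})`; `tansig`:
  `2/(1+e^{−2(x−μ)/σ})−1` (equivalently `tanh`); `ncdf`: Φ((x−μ)/σ).
  For Gaussian data the NCDF map is the probability integral
  transform, so its classes are equioccupied; logsig/tansig classes
  are *not* uniform even on Gaussian input, which is why normalized
  DispEn of white noise saturates near 0.92 under logsig but near 1.0
  under NCDF or the sorting map.  Tests assert the uniform limit only
  for NCDF.
* **Classification.** Mapped values in a range `(α, β)` are placed at
  `z = 0.5 + c(y−α)/(β−α)` and rounded half-up with clamping:
  `u = clamp(floor(z+0.5), 1, c)`.  This rounding reproduces the
  standard worked class series including its boundary samples
  (`z = 0.5 → 1`, `z = c+0.5 → c`).
* **Classification range.** Default is the transfer function's
  theoretical codomain ((0,1) or (−1,1)); this is what gives the
  sigmoid maps their outlier-compression property.  The empirical
  (min, max) of the mapped values is available via
  `theoretical_range=False`.  The distinction matters for signals with
  discrete amplitude atoms: under the theoretical range an atom can
  sit exactly on a class boundary, where sub-O(1/√N) fluctuations of
  μ̂, σ̂ flip a constant fraction of samples between classes and
  inflate the between-realization variance of the entropy.  The MIX
  benchmark (below) is exactly such a signal, and its stability study
  therefore uses the empirical range.
* **Sorting map.** Ranks (stable, ties by order of emergence) cut into
  `c` classes of size differing by at most one: `u = ceil(r·c/n)`.
  Invariant under any strictly increasing transform.
* **Degenerate input.** A constant signal has no scale; every sample
  is assigned the middle class `floor((c+1)/2)` with a warning, so a
  flat epoch yields zero entropy ("completely certain") rather than an
  error.  Series too short to embed raise — "unmeasurable" is kept
  distinct from "certain".

## DispEn, FDispEn, forbidden patterns (core module)

Patterns are counted in O(N) by encoding each embedded vector as a
mixed-radix integer (base `c`; for fluctuation patterns base `2c−1`
after offsetting differences by `c−1`).  Natural logarithms
throughout; normalization divides by the log of the pattern-space size
(`c^m`, or `(2c−1)^{m−1}` for FDispEn).

Defaults follow the noise-sensitivity analysis on the logistic map:
DispEn `m=2, c=6`, FDispEn `m=3, c=5`, delay `d=1`, logsig mapping.
All are overridable; `c` trades amplitude resolution (small `c` loses
information) against estimability and noise robustness (large `c`
fragments the counts).

`forbidden_implication_check` enumerates, for a missing ordinal
pattern given as a 1-based rank vector, the `C(c, m)` strictly-ordered
class tuples that realize it.  Only strict orderings are implied
absent: a class tuple with ties can arise from underlying real values
in more than one order, so ties are not pinned to the missing
permutation.  On the fully chaotic logistic map (α=4, N=10⁴) the
forbidden fraction at `m=3, c=6` is ≈0.90 for dispersion patterns and
≈0.83 for fluctuation patterns.  For *ordinal* patterns the fraction
at order 3 is exactly 1/6 (the map forbids a single length-3 pattern),
so the "majority forbidden" signature appears only once the ordinal
space is large enough — order 4 reaches exactly half, order 5 ≈0.74.
Tests assert the majority property at order 5 for the ordinal census.

## Baselines

* **PerEn**: ordinal patterns by stable argsort — equal values keep
  their order of emergence; no tie-breaking noise is injected.
  Normalized by `ln m!`.  Consequence asserted in tests:
  `{1,2,2,2}` and `{1,2,3,4}` both have zero PerEn at m=3.
* **SampEn**: Chebyshev distance, tolerance `r·SD` (population SD of
  the epoch being analyzed), self-matches excluded, the m-template set
  truncated to the `N−m` starting points shared with the
  (m+1)-templates; `−ln(A/B)`.  Zero counts yield an explicit
  undefined marker carrying the reason, which experiment drivers
  exclude from means and tally separately.  Distances are computed as
  running maxima over shifted diagonals of the sample-wise |Δ| matrix
  (O(N²) memory one matrix at a time).
* **LZC**: the literature rarely fixes a variant, so the standard
  biomedical-signal convention is used: binarize at the median
  (`x ≥ median → 1`), LZ76 exhaustive-history parse `c(n)`, normalize
  as `c(n)·log₂(n)/n` (→ 1 for i.i.d. equiprobable bits).
* **Hedges' g**: pooled-SD standardized mean difference with the
  small-sample correction `J = 1 − 3/(4(n_a+n_b)−9)`.

## Synthetic signals

Generators are pure functions of (parameters, seed) — identical seeds
give identical output; experiment drivers derive per-realization child
seeds from one master seed and record them per row.

* **Colored noise**: white is i.i.d. standard normal; pink (1/f) and
  brown (1/f²) shape the Fourier amplitudes of a white draw by
  `f^{−1/2}` / `f^{−1}` (random phases inherited, zero DC) and rescale
  to zero mean, unit variance.  FFT shaping hits the target spectral
  slope exactly, unlike AR filtering.
* **Logistic map** `x_{j+1} = α x_j (1−x_j)`: periodic at α=3.5
  (period 4 after burn-in), chaotic for α ≳ 3.57 with periodic pockets
  (α≈3.8); supports a per-sample α schedule for bifurcation sweeps and
  rejects initial states on the unstable finite orbits of α=4.
* **MIX process** `MIX_k = (1−z_k)·A sin(2πk/12) + z_k·U(−b, b)` with
  `z_k ~ Bernoulli(p)`: sweeps regularity from periodic (p→0) to
  random (p→1).  Default constants `A=√2, b=√3` give both components
  unit variance — the convention of the original regularity-statistic
  literature; the integer variant (`A=2, b=3`) is selectable.  Note
  the deterministic component takes only 7 distinct amplitude values,
  which is what makes this process sensitive to the classification
  range (above).
* **SNR noise**: additive white Gaussian with variance
  `var(x)/10^{SNR/10}` — "SNR" is the variance ratio in dB.
* **Noisy sinusoid** `sin(i/20) + 0.3·U(0,1)`, default N=400: the
  canonical demonstration that weak amplitude noise scrambles local
  ranks (PerEn ≈ max) while class-based estimators stay well below
  maximum.

## Benchmark experiments and problem sizes

The experiment drivers return long-format DataFrames (condition ×
realization × estimator) with seeds recorded.  Default problem sizes
mirror the benchmark studies: 40 realizations for noise-color and
noise-sensitivity sweeps at N up to 1000; 20 realizations for the MIX
stability study; sliding windows of 60 samples at 80% overlap for the
15000-sample α-sweep (step `max(1, round(length·(1−overlap)))`,
giving 1246 windows); epoching for group contrasts uses consecutive
non-overlapping epochs with the final partial epoch dropped — the
simplest deterministic choice.

The MIX stability study (CV = sample SD / mean across realizations)
evaluates each estimator once per 1500-sample realization at fixed
p=0.5 — DispEn (logsig over the empirical range, m=2, c=6), FDispEn
(same mapping, m=3, c=6), SampEn (m=2, r=0.1·SD).  The signal length
and single-evaluation protocol were fixed by consistency checks
across the full r-row of the SampEn benchmark; the empirical-range
mapping avoids the class-boundary resonance described above, which
would otherwise multiply the DispEn CV several-fold without changing
its mean.  Typical values at these settings: CV(DispEn) ≈ 0.004–0.007,
CV(FDispEn) ≈ 0.004–0.007, CV(SampEn) ≈ 0.05–0.08 — the dispersion
statistics are roughly an order of magnitude more stable than SampEn,
and that ordering (max dispersion CV < min SampEn CV across c = 2–10
and r = 0.1–0.5) is asserted in the tests rather than any single CV
value being treated as exact.

## What the synthetic benchmarks do and do not show

The generators reproduce the canonical benchmark families (colored
noise, logistic map, MIX, noisy sinusoid) but none of the structure of
real physiological data: nonstationarity beyond the scripted schedules,
oscillatory morphology (QRS complexes, spindles), artifacts, or
heavy-tailed amplitude distributions.  Passing tests show the
estimators have the documented mathematical properties and reproduce
the published synthetic benchmarks; they do not certify discrimination
power on any particular real dataset.  The epoch/effect-size workflow
(`epoch_group_comparison`) is the supported route for real two-group
studies, but no physiological data ships with the package.

## Numerical details

* `0·ln 0 := 0`; entropy of a single observed pattern is exactly 0.
* Probabilities are exact rational counts divided by
  `N − (m−1)d`; no smoothing or pseudo-counts.
* Ties in the sorting map and in PerEn argsort are resolved stably
  (first occurrence first), never randomly.
* Seeds derived from a master seed use `numpy.random.SeedSequence` and
  are reduced below 2³¹.

## Known limitations

* Univariate, single-scale only: no multiscale, refined-composite, or
  multivariate variants, and no weighted/amplitude-aware PerEn
  variants.
* No physiological file formats (EDF/WFDB); input is single-column
  text/CSV.  `read_signal` is the extension point.
* SampEn is O(N²) time and memory in the pairwise matrix; fine to
  N ≈ 20k, not intended for long recordings.
* The forbidden-pattern census is a finite-sample statistic: on short
  series "false forbidden" patterns are expected, and the curves in
  `forbidden_fraction_curve` quantify exactly that decay.
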