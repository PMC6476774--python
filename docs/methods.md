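# Methods notes

This note records the models, conventions and numerical choices behind
`gencycles`, the reasoning where the design was genuinely open, and what
the synthetic-data calibrations do and do not demonstrate.

## The census data model

The unit of analysis is one replicate mesocosm's weekly census
(`PopulationSeries`): full-cage counts of dead adults by sex, and counts
of 3rd/4th/5th-instar larvae from a small subsection of the cage, tagged
with a temperature (27/30/33 °C) × diet (standard/poor) × replicate
treatment.  Weeks are 1-based with unit spacing; the larval channels may
cover a shorter prefix of the adult span (larval sorting is laborious and
often stops earlier).  Interior gaps are rejected rather than imputed —
the sampling design is strictly weekly, and silently imputing counts
would distort the spectral analyses downstream.

Conventions for the descriptive measures:

* **Truncation.** The first 10 observed weeks are removed before any
  analysis; founding a cage with a single larval cohort produces a
  transient that would otherwise bias stationarity-based statistics.
* **Coefficient of variation** uses the n−1 standard deviation over the
  mean of the post-truncation weekly dead-adult totals.
* **Age structure** is "time-averaged" as the mean of weekly instar
  proportions over weeks with at least one counted larva.  This weights
  every sampled week equally and is robust to week-to-week variation in
  sampling effort; the alternative reading — pooled instar totals over
  pooled grand total — is exposed as `method="pooled"`.  The two coincide
  exactly when weekly totals are equal and differ only modestly otherwise.
* **Extinction** is flagged when the adult series ends in a run of at
  least 8 consecutive zero weeks (about one generation plus slack); a
  shorter terminal lull is treated as a deep cycle trough.  Extinct
  populations are excluded from spectral/wavelet analysis and from the
  linear models, which therefore cover persisting populations only.

## Spectral cycle detection

Counts are square-root transformed (the variance-stabilising transform
for overdispersed counts), mean-centred, and summarised by the raw
periodogram on the Fourier grid `f_j = j/n`:

    I(f_j) = (1/n) | Σ_t y_t exp(−2πi f_j t) |²,   j = 1..⌊n/2⌋.

No taper, padding or smoothing is applied: the surrogate series and the
data pass through the identical code path, so the Monte-Carlo threshold
construction is valid for any fixed estimator, and the untapered
estimator keeps the null analytically tractable (for Gaussian noise the
interior ordinates are exactly σ²·χ²₂/2, which the tests exploit as a
closed-form check).  A `pooled` flag exists for pooling the surrogate
quantile across frequencies; the default is per-frequency, matching how
a significance line varies across a periodogram.

**The null.** Weekly censuses of cycling insect populations are strongly
overdispersed, so the white-noise null is negative binomial with mean `m`
and shape `k` fitted to each series by moments (`k = m²/(s²−m)`;
underdispersed series fall back to Poisson).  10,000 surrogate series are
simulated, transformed and periodogram'd identically to the data, and the
per-frequency empirical 95th quantile is the significance threshold.

**Cycle calls.** The generation-cycle band is the closed period interval
[5, 7] weeks, which brackets the 6-week generation at the design's
frequency resolution (n = 72 gives grid periods 6.55, 6.00, 5.54, 5.14 in
band).  Because the band contains several frequencies, testing each
against its own 95% quantile would give a band-wise false-alarm rate of
roughly 1 − 0.95^m ≈ 19% — an unacceptable specificity for a present/absent
call.  Presence is therefore tested against the Šidák-adjusted
per-frequency quantile `0.95^(1/m)` over the `m` band frequencies, which
holds the *band-wise* false-alarm rate at 5% (measured: 3–6% on NB white
noise) while leaving power for strong 6-week signals at ~100%.  The
unadjusted per-frequency 95% quantile is retained as the reported and
plotted threshold.  The peak period is the in-band frequency maximising
the excess over threshold, ties broken toward 1/6.

## Wavelet analysis

Mesocosm series also show long fluctuations (~24–36-week wavelengths, a
sizable fraction of the record), which would dominate a wavelet spectrum.
They are removed first by loess: local quadratic regression on the time
index with tricube weights over the `floor(0.4·n)` nearest neighbours, no
robustness iterations.  The implementation was verified to reproduce R's
`stats::loess` (span 0.4, degree 2, `surface="direct"`) to ~1e-14; degree
1 is available by flag.  The square-root transform is applied before
detrending, matching the spectral path's variance stabilisation (both
orders are possible; sqrt-first keeps the two analysis paths consistent).

The continuous wavelet transform follows the standard Torrence–Compo
conventions: Morlet mother wavelet `ψ(η) = π^(−1/4) e^(iω₀η) e^(−η²/2)`
with ω₀ = 6, FFT implementation with zero-padding to the next power of
two, geometric period grid from 2·dt to ⌊n/3⌋·dt with dj = 1/20
suboctaves, Fourier period `(4π/(ω₀+√(2+ω₀²)))·s ≈ 1.033·s`, and cone of
influence at the e-folding time √2·s.  Significance contours come from
`nsim` Gaussian white-noise surrogates with the variance of the analysed
(detrended) series, thresholded pointwise at the 1−α quantile; α = 0.05
and nsim = 100 by default, with nsim ≥ 500 recommended for reported
figures (the empirical quantile of 100 draws is noticeably noisy, which
inflates the pixel exceedance rate by ~1–2 points).  A negative-binomial
surrogate option (`surrogate="nb"`) exists for sensitivity analysis; the
Gaussian default mirrors the usual white-noise option of wavelet software
and deliberately differs from the spectral module's count-level null —
the two methods are meant as independent lines of evidence.

The ridge summary reports, per time point inside the cone of influence,
the in-band period with maximal significant power, and the fraction of
assessable times with any significant in-band pixel ("coverage"): a
sustained generation cycle gives coverage near 1, white noise near α.

## Treatment-level statistics

Quantitative per-population measures (mean adult count, mean larval
count, CV, proportion of 5th instars) are compared with
`response ~ temperature * diet` least-squares models using sequential
(type I) sums of squares; with balanced designs this equals the
orthogonal decomposition, so factor order is immaterial (tested).
Backward elimination drops the interaction first if p ≥ 0.05, then
nonsignificant main effects largest-p-first, never removing a main effect
whose interaction is retained.  Constant responses short-circuit to
F = 0, p = 1 rather than reporting rounding noise.  Group means carry
t-based 95% confidence intervals on within-group variance.  No
multiple-testing correction is applied across the report's tests.

Qualitative outcomes (cycling vs not, by treatment group) are tested with
an exact r×c contingency test: full enumeration of all tables with the
observed margins, each with multivariate hypergeometric probability
`P = (Π rowᵢ! Π colⱼ!)/(N! Π cellᵢⱼ!)`, two-sided p by probability
ordering (sum of P over tables no more probable than the observed one).
All arithmetic uses exact rationals (`fractions.Fraction`), so the
enumerated probabilities sum to exactly 1 and the "no more probable"
comparison involves no floating-point tolerance.  Enumeration is guarded
at N ≤ 60; a permutation Monte-Carlo estimator with reported standard
error covers larger tables.  For the reference pattern — three groups of
three replicates all cycling, one group not — the test gives
p = 24/1320 ≈ 0.0182.

## The mechanistic simulator

The simulator is a daily boxcar model in the spirit of the classic
stage-structured models of *Plodia* dynamics: one compartment per day of
each stage (egg, L1–L5, pupa), Poisson recruitment, binomial survival per
compartment, adults held in age-structured cohorts by sex.  It is a
generating model for census-like data, not a fitted description of any
particular experiment; all parameter values are calibration choices
anchored to published life-history ranges for the species.

Daily update order: (1) eggs are laid at rate
`Σ_a females(a) · F·(1−ρ)·ρ^a` — a geometric fecundity schedule that
concentrates laying in the first days of adulthood (F = lifetime eggs of
an immortal female, default 120; ρ = 0.6); (2) every juvenile compartment
survives binomially; (3) survivors advance one compartment, pupal
graduates eclose with Binomial(1/2) sex assignment, adults age and die
with a discrete Weibull hazard (shape 3) whose mean is the scenario's
adult lifespan; (4) every 7th day a census record is emitted: the week's
accumulated dead adults by sex, and Binomial(N, 1/9) subsamples of the
L3–L5 compartments (one small section of a 9-section cage grid; L1/L2 are
simulated but never reported, being too small to count).

**Density dependence and the origin of the cycles.** Two interaction
channels with deliberately different delay structure:

* *Egg cannibalism / interference*: eggs, L1 and L2 survive an extra
  factor `exp(−c·N_late)` where `N_late` is the current 4th+5th-instar
  occupancy.  Victims reach the attacking stages one development time
  later, so this loop is delayed by ~a generation; it synchronises
  cohorts and is what generates single-generation cycles.
* *Food scramble among late instars*: L4/L5 survive an extra factor
  `exp(−β·N_late/K)`.  Late instars consume nearly all the food, so
  resource shortage is modelled as self-limitation within the late
  stages.  Acting within the same stage, this loop is nearly
  instantaneous and regulates equilibrium density without destabilising
  it.

This split is a deliberate design choice.  A crowding term applied
uniformly to all larval stages is itself a delayed feedback loop whose
strength at equilibrium equals ln R₀ regardless of β; numerically it
generates ~6–7-week cycles on its own, making cycling insensitive to the
cannibalism coefficient.  With late-stage self-limitation, removing egg
cannibalism (c = 0) switches the dynamics to weak ~3-week
(half-generation) cycles that the 5–7-week classifier correctly rejects —
reproducing the theoretical result that egg cannibalism is necessary for
full generation-length cycles, and giving the simulator a meaningful
cannibalism contrast.

**Scenario presets.**  Baseline (27 °C, standard diet): stage durations
4/4/5/6/7/7/8 days (egg→eclosion 41 days, so one generation ≈ 6 weeks),
daily background survival 0.98 (egg), 0.99 (larva), 0.995 (pupa) — about
66% egg-to-adult at low density — adult lifespan 9 days, c = 0.02,
β = 0.04, K = 400, founded with 100 larvae spread over the larval
compartments.  30 °C: development 2.5 days faster (pupa and L5 shortened),
lifetime fecundity × 0.775, adult lifespan − 2.5 days.  33 °C: juvenile
daily survival additionally × 0.905 — a *cage-level* calibration for the
observed rapid collapses at this temperature, deliberately more severe
than individual-level assay survival, standing in for unmodelled
mortality (mating failure, egg inviability, heat stress) — plus
fecundity × 0.8 and slightly shorter adult life.  Poor diet halves K.
Demographic stochasticity only by default; a log-normal daily fecundity
noise term is available (`env_noise_sd`).

Calibrated behaviour under these defaults (recomputed by
`scripts/acceptance.py`): 27/30 °C populations persist for 82 weeks and
are classified as 6-week cyclers in ≈100% of runs; 33 °C populations
collapse, mostly within 26 weeks; 30 °C runs have more adults, fewer 5th
instars in proportion, and slightly lower-amplitude larval structure than
27 °C runs; cannibalism-off runs essentially never produce an in-band
cycle call.

**What the simulator does not emulate.**  Stage durations are fixed
integers, so cohorts stay crisper than in real cages where development
times vary among individuals; simulated cycles consequently have deeper
troughs (CV of weekly adult counts ≈ 1.4 versus ≈ 0.5 in comparable real
mesocosms).  Passing calibration therefore demonstrates that the analysis
pipeline detects generation cycles of the mechanistic kind, not that the
simulator is distributionally indistinguishable from real censuses.  No
natural enemies, no evolution, no spatial structure, no fitting to
experimental data; the resource scale K is an arbitrary within-cage
scaling with no empirical anchor.

The phenomenological generator is the complementary calibration
instrument: independent negative-binomial counts whose mean is cosine
modulated at the generation period (and optionally a long period), so
cycle amplitude (A₆), overdispersion (k) and length are set directly.  It
is used for the type-I/power calibrations where ground truth must be
known exactly.

## Reproducibility

Every stochastic entry point takes an explicit seed.  The pipeline
derives per-stage, per-population seeds from the master seed by a fixed
counter scheme (`SeedSequence([master, stage, unit])`), so any stage can
be re-run independently and byte-identically; the run manifest records
SHA-256 checksums of all outputs, and re-running a configuration
reproduces the checksums exactly (tested).  Problem sizes used by the
test suite and the acceptance script — 20 simulator runs of 82 weeks per
contrast, 100 phenomenological seeds per power point, 10,000 surrogate
replicates per threshold, 200 validation series, nsim = 500 wavelet
surrogates — were chosen so each calibration's Monte-Carlo error is small
against the margin being checked.
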