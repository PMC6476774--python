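# gencycles

Generation-cycle analysis of stage-structured insect census time series,
with a mechanistic mesocosm simulator.

Laboratory populations of the Indianmeal moth *Plodia interpunctella*
typically oscillate with a period of about one generation (~6 weeks).
These **generation cycles** arise from strong asymmetric competition among
larvae: large 4th/5th-instar larvae outcompete and cannibalise eggs and
early instars, which synchronises the population's age structure.  Whether
the cycles persist depends on temperature and resource quality, which makes
them a sensitive read-out of how warming reshapes population dynamics.

`gencycles` is for population ecologists who run (or model) replicated
mesocosm experiments of this kind: weekly censuses of dead adults and
late-instar larvae across a temperature × diet factorial.  It provides

* **Census handling** — a validated CSV schema for weekly counts with
  treatment metadata, transient truncation, extinction flagging, and
  descriptive measures (means, coefficient of variation, time-averaged
  larval age structure).
* **Spectral cycle detection** — the raw periodogram
  `I(f_j) = n⁻¹ |Σ_t y_t e^(−2πi f_j t)|²` of the square-root-transformed
  counts, tested against Monte-Carlo surrogates: 10,000 replicates of
  negative-binomial white noise with the series' moment-fitted mean `m` and
  shape `k` (variance `m + m²/k`), thresholded at the per-frequency 95th
  quantile.  A cycle is called when an ordinate with period in the 5–7 week
  band exceeds the Šidák-adjusted band threshold.
* **Wavelet analysis** — loess detrending (span 0.4, local quadratic)
  followed by a Morlet continuous wavelet transform (ω₀ = 6,
  Torrence–Compo conventions) with white-noise significance contours,
  cone of influence, and a 6-week ridge summary for time-localised
  periodicity.
* **Treatment statistics** — factorial linear models with backward
  elimination to a minimal adequate model, and an exact r×c contingency
  test (full enumeration, multivariate hypergeometric probabilities in
  exact rational arithmetic) for qualitative outcomes such as
  cycling-vs-not.
* **Synthetic data** — a daily stage-structured stochastic simulator
  (boxcar compartments, Poisson recruitment, binomial survival, egg
  cannibalism by late instars, late-instar food scramble) with presets for
  27/30/33 °C × standard/poor diet, plus a phenomenological
  negative-binomial cycle generator for calibration experiments.

## Worked example

Simulate one baseline mesocosm (27 °C, standard diet, 82 weeks), drop the
10 establishment weeks, and run the full detection battery:

```python
import gencycles as g

scn = g.scenario_preset(27, "standard")
pop = g.simulate_population(scn, weeks=82, seed=42)
pop = g.truncate_transients(pop, n_drop=10)
counts = g.total_adults(pop)
print(f"analysed weeks: {pop.weeks[0]}..{pop.weeks[-1]}")
print(f"mean weekly dead adults: {counts.mean():.1f}   CV: {g.coefficient_of_variation(counts):.2f}")

pg = g.attach_threshold(counts, reps=10_000, seed=1)     # NB white-noise null
call = g.classify_cycle(pg, band=(5.0, 7.0))
print(f"NB null: mean={pg.null.m:.1f}, shape k={pg.null.k:.2f}")
print(f"generation cycle present: {call.present}  peak period: {call.peak_period:.1f} weeks")

fit = g.loess_detrend(g.sqrt_transform(counts), span=0.4)
ws = g.morlet_cwt(fit.residual)
g.wavelet_significance(ws, nsim=500, seed=2)
ridge = g.summarize_ridge(ws, band=(5.0, 7.0))
print(f"5-7 week wavelet ridge covers {100*ridge.coverage:.0f}% of the series")

res = g.fisher_exact_rxc([[3, 0], [3, 0], [3, 0], [0, 3]])
print(f"exact test of the cycling pattern: p = {res.p:.4f}")
```

Output:

```
analysed weeks: 11..82
mean weekly dead adults: 89.4   CV: 1.43
NB null: mean=89.4, shape k=0.49
generation cycle present: True  peak period: 6.0 weeks
5-7 week wavelet ridge covers 100% of the series
exact test of the cycling pattern: p = 0.0182
```

The simulated population cycles at exactly one generation (6 weeks): the
periodogram peak at frequency 1/6 clears the Monte-Carlo threshold, and
the wavelet ridge shows the periodicity is sustained across the whole
record.  The final line is the exact probability of a cycling pattern in
which three treatment groups of three replicates all cycle and a fourth
group does not — the kind of qualitative contrast the contingency test is
for.

A command-line interface wraps the same functions
(`gencycles run | simulate | spectrum | wavelet | stats | fixtures`); see
`gencycles --help`.

## Layout

```
src/gencycles/
  core_data.py        census I/O, truncation, descriptive measures
  simulate.py         mechanistic simulator + phenomenological generator
  spectral.py         periodogram, NB Monte-Carlo null, cycle calls
  wavelet.py          loess detrend, Morlet CWT, significance, ridges
  treatment_stats.py  factorial LMs, exact r x c tests, study report
  pipeline.py         config-driven end-to-end runs, fixtures, manifest
  cli.py              command-line interface
docs/methods.md       model and methods notes
```
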