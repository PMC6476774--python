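import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gencycles import (
    CycleCall,
    NBNull,
    Treatment,
    attach_threshold,
    classify_cycle,
    cycling_pattern,
    fit_nb_moments,
    mc_threshold,
    periodogram,
    sqrt_transform,
)
from gencycles.spectral import Periodogram, _periodogram_rows, nb_white_noise, surrogate_densities


def dft_periodogram(y):
    """O(n^2) direct-DFT oracle for the raw periodogram."""
    y = np.asarray(y, float)
    y = y - y.mean()
    n = y.size
    t = np.arange(1, n + 1)
    out = []
    for j in range(1, n // 2 + 1):
        z = np.sum(y * np.exp(-2j * math.pi * (j / n) * t))
        out.append(abs(z) ** 2 / n)
    return np.array(out)


def test_sqrt_transform_examples():
    np.testing.assert_array_equal(sqrt_transform([0, 1, 4, 9]), [0, 1, 2, 3])
    with pytest.raises(ValueError):
        sqrt_transform([-1.0, 4.0])
    # not idempotent (guard against accidental double application)
    x = np.array([16.0])
    assert sqrt_transform(sqrt_transform(x)) != sqrt_transform(x)


def test_sqrt_transform_stabilises_nb_variance():
    rng = np.random.default_rng(0)
    x = rng.negative_binomial(5, 5 / 105, size=50_000)  # m=100, k=5
    assert sqrt_transform(x).var() < x.var()


def test_periodogram_constant_series_is_flat_zero():
    pg = periodogram(np.full(40, 7.0))
    assert pg.density.max() == pytest.approx(0.0, abs=1e-20)


def test_periodogram_cosine_line():
    """A unit cosine at the grid frequency 1/6 puts all mass, n/4, there."""
    n = 72
    t = np.arange(1, n + 1)
    pg = periodogram(np.cos(2 * np.pi * t / 6))
    j = np.argmin(np.abs(pg.frequencies - 1 / 6))
    assert pg.density[j] == pytest.approx(n / 4, rel=1e-12)
    rest = np.delete(pg.density, j)
    assert rest.max() < 1e-10


@pytest.mark.parametrize("n", [8, 13, 37, 72, 128])
def test_periodogram_matches_direct_dft_oracle(n):
    rng = np.random.default_rng(n)
    for _ in range(5):
        y = rng.normal(0, 3, n)
        pg = periodogram(y)
        oracle = dft_periodogram(y)
        np.testing.assert_allclose(pg.density, oracle, rtol=1e-10, atol=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=9, max_size=65).filter(
    lambda v: len(v) % 2 == 1))
def test_periodogram_parseval(vals):
    """For odd n (no Nyquist ordinate), 2 * sum I(f_j) = n * var(y)."""
    y = np.array(vals)
    pg = periodogram(y)
    np.testing.assert_allclose(2 * pg.density.sum(), y.size * y.var(),
                               rtol=1e-8, atol=1e-8)


def test_periodogram_short_series_error():
    with pytest.raises(ValueError):
        periodogram(np.ones(7))


# ---------------------------------------------------------------------------
# negative-binomial null


def test_fit_nb_moments_formula():
    # mean 10, sample variance 30  ->  k = 100 / 20 = 5
    x = np.array([10 - 6, 10 - 2, 10 + 2, 10 + 6], float)
    x = 10 + (x - 10) * math.sqrt(30 / x.var(ddof=1))
    null = fit_nb_moments(x)
    assert null.m == pytest.approx(10.0)
    assert null.k == pytest.approx(10.0 ** 2 / (30.0 - 10.0), rel=1e-9)


def test_fit_nb_moments_poisson_limit_when_underdispersed():
    null = fit_nb_moments([10, 10, 11, 9, 10])
    assert null.is_poisson
    rng = np.random.default_rng(1)
    draws = nb_white_noise(null, (4, 100), rng)
    assert draws.mean() == pytest.approx(null.m, rel=0.1)


def test_fit_nb_moments_recovers_shape_from_samples():
    rng = np.random.default_rng(2)
    m, k = 10.0, 5.0
    x = rng.negative_binomial(k, k / (k + m), size=100_000)
    null = fit_nb_moments(x)
    assert null.k == pytest.approx(k, rel=0.10)


def test_nbnull_validation():
    with pytest.raises(ValueError):
        NBNull(m=0.0, k=5.0, n=72)
    with pytest.raises(ValueError):
        NBNull(m=10.0, k=5.0, n=72, q=1.0)


# ---------------------------------------------------------------------------
# Monte-Carlo thresholds


def test_threshold_at_extreme_quantile_is_the_maximum():
    null = NBNull(m=20.0, k=5.0, n=24, reps=40, q=1 - 1e-13)
    dens = surrogate_densities(null, seed=3)
    thr = mc_threshold(null, seed=3)
    np.testing.assert_allclose(thr, dens.max(axis=0), rtol=1e-9)


def test_surrogates_share_the_data_path():
    """Surrogate ordinates equal sqrt -> centre -> periodogram of the draws."""
    null = NBNull(m=15.0, k=4.0, n=30, reps=20)
    rng = np.random.default_rng(8)
    dens = surrogate_densities(null, seed=np.random.default_rng(8))
    counts = nb_white_noise(null, (null.reps, null.n), rng)
    manual = np.stack([periodogram(sqrt_transform(row)).density for row in counts])
    np.testing.assert_allclose(dens, manual, rtol=1e-12)


def test_gaussian_white_noise_threshold_matches_chi2_closed_form():
    """Interior raw-periodogram ordinates of N(0, sigma^2) noise are
    sigma^2 * chi^2_2 / 2, so the 95% line sits at -sigma^2 * ln(0.05)."""
    rng = np.random.default_rng(4)
    sigma2 = 2.5
    y = rng.normal(0, math.sqrt(sigma2), size=(40_000, 64))
    dens = _periodogram_rows(y)[:, :-1]  # drop the Nyquist column
    thr = np.quantile(dens, 0.95, axis=0)
    expected = -sigma2 * math.log(0.05)
    assert thr.mean() == pytest.approx(expected, rel=0.02)


def test_threshold_distribution_is_seed_invariant():
    null = NBNull(m=50.0, k=8.0, n=72, reps=10_000)
    t1 = mc_threshold(null, seed=1)
    t2 = mc_threshold(null, seed=2)
    ratio = t1 / t2
    assert np.all((ratio > 0.85) & (ratio < 1.18))


def test_pooled_threshold_is_flat():
    null = NBNull(m=50.0, k=8.0, n=72, reps=2_000)
    thr = mc_threshold(null, seed=5, pooled=True)
    assert np.unique(thr).size == 1


# ---------------------------------------------------------------------------
# classification


def test_classify_constant_series_absent():
    pg = attach_threshold(np.full(72, 9), reps=200, seed=0)
    call = classify_cycle(pg)
    assert not call.present
    assert call.peak_period is None


def test_classify_tie_breaks_toward_six_weeks():
    n = 72
    j = np.arange(1, n // 2 + 1)
    pg = Periodogram(frequencies=j / n, density=np.zeros(n // 2), n=n,
                     threshold=np.ones(n // 2), band_threshold=np.ones(n // 2))
    in_band = (pg.periods >= 5) & (pg.periods <= 7)
    pg.density[in_band] = 2.0  # same excess everywhere in the band
    call = classify_cycle(pg)
    assert call.present
    assert call.peak_period == pytest.approx(6.0)


def test_classify_band_outside_grid_errors():
    pg = attach_threshold(np.arange(1, 17), reps=50, seed=0)
    with pytest.raises(ValueError):
        classify_cycle(pg, band=(9.0, 11.0))


def test_classification_falls_back_to_display_threshold():
    pg = attach_threshold(np.random.default_rng(0).poisson(50, 72),
                          reps=500, seed=1)
    pg.band_threshold = None
    classify_cycle(pg)  # no error: uses the display threshold


# ---------------------------------------------------------------------------
# cycling pattern table


def _call(present):
    return CycleCall(present=present, peak_period=6.0 if present else None,
                     peak_density=1.0 if present else None)


def test_cycling_pattern_reproduces_reference_shape():
    calls = {}
    for (t, d), cyc in [((27, "standard"), True), ((27, "poor"), True),
                        ((30, "poor"), True), ((30, "standard"), False)]:
        for rep in (1, 2, 3):
            calls[Treatment(t, d, rep)] = _call(cyc)
    table = cycling_pattern(calls)
    # rows sorted by (temperature, diet): 27-poor, 27-standard, 30-poor, 30-standard
    assert table.to_numpy().tolist() == [[3, 0], [3, 0], [3, 0], [0, 3]]
    assert (table.sum(axis=1) == 3).all()


def test_cycling_pattern_all_cycling():
    calls = {Treatment(t, d, r): _call(True)
             for t in (27, 30) for d in ("standard", "poor") for r in (1, 2, 3)}
    table = cycling_pattern(calls)
    assert (table["not_cycling"] == 0).all()
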