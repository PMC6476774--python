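"""Loess detrending and Morlet continuous wavelet analysis.

The wavelet view complements the periodogram: it does not assume
stationarity, so a generation cycle that appears, drifts, or collapses
partway through an experiment shows up as a time-localised "ridge" of
power at the generation period.  Long multigeneration fluctuations (25+
week wavelengths, a sizable fraction of the record length) are removed
first by loess smoothing (default span 0.4, local quadratic, tricube
weights) so they do not leak power across the spectrum.

The transform follows the standard Torrence & Compo conventions for the
Morlet wavelet: mother wavelet ``psi(eta) = pi^(-1/4) e^(i w0 eta)
e^(-eta^2/2)`` with ``w0 = 6``; geometric scale grid with ``dj``
suboctaves; Fourier period ``= (4 pi / (w0 + sqrt(2 + w0^2))) * s``;
zero-padding to the next power of two; cone of influence at the e-folding
time ``sqrt(2) s``.  Significance contours come from Monte-Carlo Gaussian
white-noise surrogates with the variance of the analysed series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "OMEGA0",
    "FOURIER_FACTOR",
    "LoessFit",
    "WaveletSpectrum",
    "RidgeSummary",
    "loess_detrend",
    "morlet_cwt",
    "wavelet_significance",
    "summarize_ridge",
]

#: Morlet base frequency (the standard admissibility choice)
OMEGA0 = 6.0
#: conversion from scale to Fourier period for the Morlet wavelet
FOURIER_FACTOR = 4.0 * math.pi / (OMEGA0 + math.sqrt(2.0 + OMEGA0 ** 2))


# ---------------------------------------------------------------------------
# loess


@dataclass
class LoessFit:
    span: float
    degree: int
    fitted: np.ndarray
    residual: np.ndarray


def loess_detrend(
    y: Sequence[float] | np.ndarray, span: float = 0.4, degree: int = 2
) -> LoessFit:
    """Locally weighted polynomial trend removal on the time index.

    At each point the ``floor(span * n)`` nearest neighbours are fit with a
    weighted polynomial of the given degree, tricube weights on distance
    scaled by the window radius (the farthest included neighbour, which
    therefore gets weight zero); the fit evaluated at the point is the
    trend.  No robustness iterations (Gaussian family).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    q = int(math.floor(span * n + 1e-9))
    if q < degree + 2:
        raise ValueError(
            f"span {span} gives {q}-point windows, too few for degree {degree}"
        )
    t = np.arange(1.0, n + 1.0)
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(t - t[i])
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3 if dmax > 0 else np.ones(q)
        # weighted least squares on a locally centred Vandermonde basis
        x = t[idx] - t[i]
        V = np.vander(x, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(V * sw[:, None], y[idx] * sw, rcond=None)
        fitted[i] = coef[0]
    return LoessFit(span=span, degree=degree, fitted=fitted, residual=y - fitted)


# ---------------------------------------------------------------------------
# Morlet CWT


@dataclass
class WaveletSpectrum:
    """Time x period wavelet power with cone of influence.

    ``power`` has shape ``(n_periods, n_times)``; ``coi[t]`` is the longest
    period free of edge effects at time ``t``; ``signif_mask`` (same shape
    as ``power``) is attached by :func:`wavelet_significance`.
    """

    times: np.ndarray
    periods: np.ndarray
    scales: np.ndarray
    W: np.ndarray
    coi: np.ndarray
    dt: float
    dj: float
    series_var: float
    signif_mask: np.ndarray | None = None

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.W) ** 2

    def in_coi(self) -> np.ndarray:
        """Boolean (n_periods, n_times) mask of edge-effect-free pixels."""
        return self.periods[:, None] <= self.coi[None, :]


def _morlet_fourier(scale: float, omega: np.ndarray, dt: float) -> np.ndarray:
    """Fourier transform of the normalised Morlet daughter wavelet."""
    psi = np.zeros_like(omega)
    pos = omega > 0
    psi[pos] = (
        math.pi ** -0.25
        * math.sqrt(2.0 * math.pi * scale / dt)
        * np.exp(-0.5 * (scale * omega[pos] - OMEGA0) ** 2)
    )
    return psi


def morlet_cwt(
    y: Sequence[float] | np.ndarray,
    dt: float = 1.0,
    dj: float = 1.0 / 20.0,
    period_range: tuple[float, float] | None = None,
) -> WaveletSpectrum:
    """FFT-based Morlet continuous wavelet transform.

    ``y`` should already be detrended; its mean is removed before the
    transform.  The period grid is geometric from ``period_range[0]`` to
    ``period_range[1]`` (default ``2 dt`` to ``floor(n/3) dt``) with ``dj``
    suboctaves per octave.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 16:
        raise ValueError(f"series too short for wavelet analysis (n={n} < 16)")
    if period_range is None:
        period_range = (2.0 * dt, math.floor(n / 3) * dt)
    p_min, p_max = period_range
    if p_min < 2.0 * dt or p_max > n * dt or p_min >= p_max:
        raise ValueError(f"period_range {period_range} outside [2 dt, n dt]")

    s_min = p_min / FOURIER_FACTOR
    n_scales = int(math.floor(math.log2(p_max / p_min) / dj + 1e-9)) + 1
    scales = s_min * 2.0 ** (dj * np.arange(n_scales))
    periods = FOURIER_FACTOR * scales

    npad = 1 << (n - 1).bit_length()
    ypad = np.zeros(npad)
    ypad[:n] = y - y.mean()
    yhat = np.fft.fft(ypad)
    omega = 2.0 * math.pi * np.fft.fftfreq(npad, d=dt)

    W = np.empty((n_scales, n), dtype=complex)
    for j, s in enumerate(scales):
        W[j] = np.fft.ifft(yhat * np.conj(_morlet_fourier(s, omega, dt)))[:n]

    edge = np.minimum(np.arange(n), np.arange(n)[::-1]).astype(float)
    coi = FOURIER_FACTOR * math.sqrt(2.0) * dt * edge
    return WaveletSpectrum(
        times=np.arange(1, n + 1),
        periods=periods,
        scales=scales,
        W=W,
        coi=coi,
        dt=dt,
        dj=dj,
        series_var=float(y.var()),
    )


def wavelet_significance(
    ws: WaveletSpectrum,
    nsim: int = 100,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    surrogate: str = "gaussian",
    null_counts: Sequence[float] | None = None,
) -> np.ndarray:
    """Pointwise Monte-Carlo significance mask for a wavelet power matrix.

    Simulates ``nsim`` white-noise surrogates — Gaussian with the variance
    of the analysed series by default, or negative-binomial counts matched
    to ``null_counts`` (run through sqrt + detrend like data) with
    ``surrogate="nb"`` — transforms each, and marks pixels whose observed
    power exceeds the pointwise ``1 - alpha`` surrogate quantile.  The mask
    is attached to ``ws`` and returned.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if nsim < 20:
        import warnings

        warnings.warn(f"nsim={nsim} < 20: the {1-alpha:.2f} quantile is unstable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = ws.times.size
    prange = (float(ws.periods[0]), float(ws.periods[-1]))
    sd = math.sqrt(ws.series_var)

    if surrogate == "nb":
        from . import spectral

        if null_counts is None:
            raise ValueError("surrogate='nb' requires null_counts")
        null = spectral.fit_nb_moments(np.asarray(null_counts))
        def draw() -> np.ndarray:
            x = spectral.nb_white_noise(null, (1, n), rng)[0]
            return loess_detrend(np.sqrt(x)).residual
    elif surrogate == "gaussian":
        def draw() -> np.ndarray:
            return rng.normal(0.0, sd, n)
    else:
        raise ValueError(f"unknown surrogate model {surrogate!r}")

    sim_power = np.empty((nsim,) + ws.W.shape)
    for i in range(nsim):
        sim_power[i] = morlet_cwt(draw(), dt=ws.dt, dj=ws.dj, period_range=prange).power
    thresh = np.quantile(sim_power, 1.0 - alpha, axis=0)
    ws.signif_mask = ws.power > thresh
    return ws.signif_mask


@dataclass
class RidgeSummary:
    """Per-time dominant significant period and band coverage."""

    times: np.ndarray
    dominant_period: np.ndarray  # nan where no significant in-band pixel
    band: tuple[float, float]
    coverage: float  # fraction of in-coi times with a significant in-band pixel


def summarize_ridge(
    ws: WaveletSpectrum, band: tuple[float, float] = (5.0, 7.0)
) -> RidgeSummary:
    """Trace the significant ridge in a period band.

    For each time inside the cone of influence, reports the in-band period
    with maximal significant power (nan if none is significant); coverage
    is the fraction of such times over all in-coi times.
    """
    if ws.signif_mask is None:
        raise ValueError("run wavelet_significance before summarising the ridge")
    lo, hi = band
    in_band = (ws.periods >= lo) & (ws.periods <= hi)
    if not in_band.any():
        raise ValueError(f"band {band} contains no grid period")
    ok = ws.signif_mask & ws.in_coi() & in_band[:, None]
    power = np.where(ok, ws.power, -np.inf)
    dominant = np.full(ws.times.size, np.nan)
    any_sig = ok.any(axis=0)
    if any_sig.any():
        dominant[any_sig] = ws.periods[np.argmax(power[:, any_sig], axis=0)]
    # a time is assessable if the band is at least partly inside the coi there
    assessable = ws.coi >= lo
    coverage = float(any_sig[assessable].mean()) if assessable.any() else 0.0
    return RidgeSummary(
        times=ws.times, dominant_period=dominant, band=(float(lo), float(hi)),
        coverage=coverage,
    )
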