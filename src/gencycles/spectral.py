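"""Periodogram analysis of census counts against a negative-binomial null.

Generation cycles appear as a peak in the spectral density of the weekly
count series at a period of about one generation (six weeks for *Plodia
interpunctella*).  Because weekly counts are overdispersed, significance is
assessed against Monte-Carlo surrogates: negative-binomial white noise with
the mean and shape fitted to the series, passed through *exactly* the same
square-root -> mean-centre -> raw-periodogram path as the data, with the
per-frequency 95th quantile of surrogate ordinates as the threshold.

The periodogram is the raw (untapered, unpadded, unsmoothed) estimator

    I(f_j) = (1/n) | sum_t y_t exp(-2 pi i f_j t) |^2 ,   f_j = j/n,

for j = 1..floor(n/2), computed on the mean-centred transformed series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_data import PopulationSeries, Treatment

__all__ = [
    "NBNull",
    "Periodogram",
    "CycleCall",
    "sqrt_transform",
    "periodogram",
    "fit_nb_moments",
    "nb_white_noise",
    "mc_threshold",
    "attach_threshold",
    "classify_cycle",
    "cycling_pattern",
]

DEFAULT_REPS = 10_000
DEFAULT_QUANTILE = 0.95
#: period window (weeks) searched for a generation-cycle peak
DEFAULT_BAND = (5.0, 7.0)


@dataclass(frozen=True)
class NBNull:
    """Negative-binomial white-noise null: mean ``m``, shape ``k``.

    Variance is ``m + m**2/k``; ``k = inf`` marks the Poisson limit used when
    a series is not overdispersed (sample variance <= mean).
    """

    m: float
    k: float
    n: int
    reps: int = DEFAULT_REPS
    q: float = DEFAULT_QUANTILE

    def __post_init__(self) -> None:
        if not (self.m > 0):
            raise ValueError("null mean must be positive")
        if not (self.k > 0):
            raise ValueError("null shape must be positive (inf = Poisson limit)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not (0 < self.q < 1):
            raise ValueError("quantile must lie in (0, 1)")

    @property
    def is_poisson(self) -> bool:
        return math.isinf(self.k)


@dataclass
class Periodogram:
    """Raw periodogram on the Fourier grid ``f_j = j/n``, ``j = 1..n//2``.

    ``threshold`` is the per-frequency null quantile at the display level
    (the dashed line of a periodogram plot); ``band_threshold``, when set,
    is the per-frequency quantile at the Sidak-adjusted level used by
    :func:`classify_cycle` so that the false-alarm rate of the whole band
    search equals ``1 - q``.
    """

    frequencies: np.ndarray
    density: np.ndarray
    n: int
    threshold: np.ndarray | None = None
    band_threshold: np.ndarray | None = None
    null: NBNull | None = None

    @property
    def periods(self) -> np.ndarray:
        return 1.0 / self.frequencies

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "frequency": self.frequencies,
                "period": self.periods,
                "density": self.density,
            }
        )
        if self.threshold is not None:
            df["threshold"] = self.threshold
            df["significant"] = self.density > self.threshold
        return df


@dataclass(frozen=True)
class CycleCall:
    """Outcome of the generation-cycle test on one population."""

    present: bool
    peak_period: float | None
    peak_density: float | None
    band: tuple[float, float] = DEFAULT_BAND


def sqrt_transform(x: Sequence[float] | np.ndarray) -> np.ndarray:
    """Elementwise square root, the variance-stabilising transform for counts."""
    x = np.asarray(x, dtype=float)
    if x.size and x.min() < 0:
        raise ValueError("sqrt transform requires nonnegative input")
    return np.sqrt(x)


def periodogram(y: Sequence[float] | np.ndarray) -> Periodogram:
    """Raw periodogram of a mean-centred series (no taper, pad, or smoothing)."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("periodogram expects a 1-d series")
    n = y.size
    if n < 8:
        raise ValueError(f"series too short for spectral analysis (n={n} < 8)")
    dens = _periodogram_rows(y[None, :])[0]
    j = np.arange(1, n // 2 + 1)
    return Periodogram(frequencies=j / n, density=dens, n=n)


def _periodogram_rows(y: np.ndarray) -> np.ndarray:
    """Row-wise raw periodogram of a (reps, n) matrix; drops f=0."""
    y = y - y.mean(axis=1, keepdims=True)
    n = y.shape[1]
    spec = np.abs(np.fft.rfft(y, axis=1)) ** 2 / n
    return spec[:, 1 : n // 2 + 1]


def fit_nb_moments(x: Sequence[float] | np.ndarray, reps: int = DEFAULT_REPS,
                   q: float = DEFAULT_QUANTILE) -> NBNull:
    """Method-of-moments negative-binomial fit: ``k = m^2 / (s^2 - m)``.

    Underdispersed samples (``s^2 <= m``) get the Poisson-limit flag
    (``k = inf``) and surrogates are drawn Poisson(m).
    """
    x = np.asarray(x, dtype=float)
    m = x.mean()
    if m <= 0:
        raise ValueError("cannot fit a count null to a series with mean <= 0")
    s2 = x.var(ddof=1)
    k = m * m / (s2 - m) if s2 > m else math.inf
    return NBNull(m=float(m), k=float(k), n=int(x.size), reps=reps, q=q)


def nb_white_noise(null: NBNull, size: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Draw iid count white noise from the null (NB, or Poisson at k=inf)."""
    if null.is_poisson:
        return rng.poisson(null.m, size=size)
    p = null.k / (null.k + null.m)
    return rng.negative_binomial(null.k, p, size=size)


def surrogate_densities(
    null: NBNull, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """(reps, n//2) matrix of surrogate periodogram ordinates.

    Each surrogate is a white-noise count series from the null run through
    the identical sqrt -> centre -> periodogram path as the data.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = nb_white_noise(null, (null.reps, null.n), rng)
    return _periodogram_rows(sqrt_transform(counts))


def mc_threshold(
    null: NBNull,
    seed: int | np.random.Generator | None = None,
    pooled: bool = False,
    q: float | None = None,
) -> np.ndarray:
    """Per-frequency Monte-Carlo significance threshold.

    Simulates ``null.reps`` surrogate series and returns the empirical
    ``q`` quantile (default ``null.q``) of the ordinates at each frequency.
    With ``pooled=True`` a single quantile over all frequencies and
    replicates is broadcast instead (a laxer, frequency-global reading of
    the same construction).
    """
    dens = surrogate_densities(null, seed)
    q = null.q if q is None else q
    if pooled:
        return np.full(dens.shape[1], np.quantile(dens, q))
    return np.quantile(dens, q, axis=0)


def _band_mask(n: int, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    if lo >= hi or lo <= 0:
        raise ValueError(f"invalid period band {band}")
    j = np.arange(1, n // 2 + 1)
    periods = n / j
    mask = (periods >= lo) & (periods <= hi)
    if not mask.any():
        raise ValueError(f"period band {band} contains no grid frequency (n={n})")
    return mask


def attach_threshold(
    x: Sequence[float] | np.ndarray,
    reps: int = DEFAULT_REPS,
    q: float = DEFAULT_QUANTILE,
    seed: int | np.random.Generator | None = None,
    pooled: bool = False,
    band: tuple[float, float] = DEFAULT_BAND,
) -> Periodogram:
    """Full spectral path for one count series: fit null, periodogram, thresholds.

    Two thresholds come from the same surrogate ensemble: the display
    threshold at quantile ``q`` per frequency, and the classification
    threshold at the Sidak-adjusted quantile ``q**(1/m)`` (``m`` = number
    of frequencies in the searched ``band``), which keeps the band-wise
    false-alarm rate of the cycle call at ``1 - q``.
    """
    x = np.asarray(x, dtype=float)
    null = fit_nb_moments(x, reps=reps, q=q)
    pg = periodogram(sqrt_transform(x))
    dens = surrogate_densities(null, seed)
    if pooled:
        pg.threshold = np.full(dens.shape[1], np.quantile(dens, q))
    else:
        pg.threshold = np.quantile(dens, q, axis=0)
    m = int(_band_mask(pg.n, band).sum())
    q_band = q ** (1.0 / m)
    if pooled:
        pg.band_threshold = np.full(dens.shape[1], np.quantile(dens, q_band))
    else:
        pg.band_threshold = np.quantile(dens, q_band, axis=0)
    pg.null = null
    return pg


def classify_cycle(pg: Periodogram, band: tuple[float, float] = DEFAULT_BAND) -> CycleCall:
    """Call a generation cycle from a thresholded periodogram.

    The search is restricted to frequencies whose period lies in ``band``
    (closed interval, weeks).  A cycle is present when any in-band ordinate
    exceeds the classification threshold (the Sidak-adjusted one when
    attached, so the whole band search has the nominal false-alarm rate);
    the peak is the in-band frequency maximising the excess
    ``density - threshold``, ties broken toward the frequency nearest a
    six-week period.
    """
    thr = pg.band_threshold if pg.band_threshold is not None else pg.threshold
    if thr is None:
        raise ValueError("periodogram has no significance threshold attached")
    in_band = _band_mask(pg.n, band)
    periods = pg.periods
    excess = np.where(in_band, pg.density - thr, -np.inf)
    best = np.flatnonzero(excess == excess.max())
    if best.size > 1:  # tie: prefer the frequency nearest 1/6
        best = best[np.argmin(np.abs(pg.frequencies[best] - 1.0 / 6.0))]
    else:
        best = best[0]
    present = bool(excess[best] > 0)
    return CycleCall(
        present=present,
        peak_period=float(periods[best]) if present else None,
        peak_density=float(pg.density[best]) if present else None,
        band=(float(band[0]), float(band[1])),
    )


def cycling_pattern(
    calls: dict[Treatment, CycleCall] | Iterable[tuple[Treatment, CycleCall]],
) -> pd.DataFrame:
    """r x 2 contingency table of replicates cycling vs not, by treatment group.

    Rows are temperature x diet combinations (sorted), columns are
    ``cycling`` and ``not_cycling`` replicate counts.
    """
    items = list(calls.items()) if isinstance(calls, dict) else list(calls)
    if not items:
        raise ValueError("no cycle calls supplied")
    rows: dict[tuple[int, str], list[int]] = {}
    for trt, call in items:
        key = (trt.temperature, trt.diet)
        rows.setdefault(key, [0, 0])
        rows[key][0 if call.present else 1] += 1
    if len(rows) < 2:
        raise ValueError("need at least two treatment groups for a contingency table")
    idx = pd.MultiIndex.from_tuples(sorted(rows), names=["temperature_C", "diet"])
    return pd.DataFrame(
        [rows[k] for k in sorted(rows)], index=idx, columns=["cycling", "not_cycling"]
    )
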