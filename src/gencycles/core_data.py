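"""Census data structures and per-population descriptive measures.

The atom of every analysis in this package is one replicate population's
weekly census: dead adults (sexed, full-cage counts) and 3rd/4th/5th-instar
larvae (subsampled counts over a possibly shorter span), tagged with its
temperature x diet x replicate treatment. This module reads and writes those
tables, removes establishment transients, and computes the descriptive
measures used downstream (total adults, coefficient of variation,
time-averaged larval age structure, extinction flagging).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Treatment",
    "PopulationSeries",
    "AgeStructure",
    "SchemaError",
    "ValidationError",
    "CENSUS_COLUMNS",
    "read_census",
    "write_census",
    "truncate_transients",
    "total_adults",
    "coefficient_of_variation",
    "age_structure",
    "flag_extinction",
]

TEMPERATURES = (27, 30, 33)
DIETS = ("standard", "poor")

#: canonical census CSV header (larval cells may be empty once the larval
#: sampling span has ended)
CENSUS_COLUMNS = (
    "week",
    "temperature_C",
    "diet",
    "replicate",
    "adults_female",
    "adults_male",
    "larvae_L3",
    "larvae_L4",
    "larvae_L5",
)

ADULT_COLUMNS = ("adults_female", "adults_male")
LARVAL_COLUMNS = ("larvae_L3", "larvae_L4", "larvae_L5")


class SchemaError(ValueError):
    """A census table is missing a required column or factor level."""


class ValidationError(ValueError):
    """A census table contains an invalid value (negative / non-integer count)."""


@dataclass(frozen=True, order=True)
class Treatment:
    """One cell of the 3 temperature x 2 diet factorial, with replicate id."""

    temperature: int
    diet: str
    replicate: int

    def __post_init__(self) -> None:
        if self.temperature not in TEMPERATURES:
            raise ValidationError(
                f"temperature must be one of {TEMPERATURES}, got {self.temperature!r}"
            )
        if self.diet not in DIETS:
            raise ValidationError(f"diet must be one of {DIETS}, got {self.diet!r}")
        if not (isinstance(self.replicate, (int, np.integer)) and self.replicate >= 1):
            raise ValidationError(f"replicate must be a positive integer, got {self.replicate!r}")

    @property
    def label(self) -> str:
        return f"{self.temperature}C-{self.diet}-r{self.replicate}"


def _as_count_array(x: Sequence[int] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded, atol=1e-9):
            raise ValidationError(f"{name} must hold integer counts")
        arr = rounded.astype(np.int64)
    arr = arr.astype(np.int64, copy=True)
    if arr.size and arr.min() < 0:
        raise ValidationError(f"{name} must be nonnegative")
    return arr


@dataclass
class PopulationSeries:
    """One replicate's weekly census with treatment metadata.

    ``weeks`` is 1-based, strictly increasing with unit spacing.  The adult
    channels cover all of ``weeks``; larval channels cover a (possibly
    shorter) prefix of the same weeks, mirroring a design in which larval
    sorting stops before the adult census does.
    """

    treatment: Treatment
    weeks: np.ndarray
    adults_female: np.ndarray
    adults_male: np.ndarray
    larvae_L3: np.ndarray
    larvae_L4: np.ndarray
    larvae_L5: np.ndarray
    extinct_week: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, dtype=np.int64)
        if self.weeks.ndim != 1 or self.weeks.size == 0:
            raise ValidationError("weeks must be a nonempty 1-d sequence")
        if self.weeks.size > 1 and not np.all(np.diff(self.weeks) == 1):
            raise ValidationError("weeks must be strictly increasing with unit spacing")
        for name in ADULT_COLUMNS + LARVAL_COLUMNS:
            setattr(self, name, _as_count_array(getattr(self, name), name))
        if self.adults_female.shape != self.weeks.shape or self.adults_male.shape != self.weeks.shape:
            raise ValidationError("adult channels must cover every week")
        n_larv = {getattr(self, c).size for c in LARVAL_COLUMNS}
        if len(n_larv) != 1:
            raise ValidationError("larval channels must share one length")
        if n_larv.pop() > self.weeks.size:
            raise ValidationError("larval span cannot exceed adult span")

    @property
    def n_weeks(self) -> int:
        return int(self.weeks.size)

    @property
    def n_larval_weeks(self) -> int:
        return int(self.larvae_L3.size)

    @property
    def larval_weeks(self) -> np.ndarray:
        return self.weeks[: self.n_larval_weeks]

    def replace(self, **changes) -> "PopulationSeries":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class AgeStructure:
    """Time-averaged proportions of counted larvae in instars 3, 4, 5."""

    p3: float
    p4: float
    p5: float

    def __post_init__(self) -> None:
        total = self.p3 + self.p4 + self.p5
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValidationError(f"proportions must sum to 1, got {total!r}")
        if min(self.p3, self.p4, self.p5) < 0 or max(self.p3, self.p4, self.p5) > 1:
            raise ValidationError("proportions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# file I/O


def _validate_counts(df: pd.DataFrame, path: str) -> None:
    for col in ADULT_COLUMNS + LARVAL_COLUMNS:
        vals = df[col]
        bad = vals.notna() & ((vals < 0) | (vals != np.floor(vals)))
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based, + header line
            raise ValidationError(
                f"{path}: column {col!r} has a negative or non-integer count at row {row}"
            )


def read_census(
    path: str | Path,
    dialect: Mapping[str, str] | Literal["default"] = "default",
) -> list[PopulationSeries]:
    """Read a census CSV into one :class:`PopulationSeries` per population.

    Parameters
    ----------
    path:
        Delimited text file with a header row.  Lines starting with ``#`` are
        treated as comments (the simulator writes scenario/seed metadata that
        way).
    dialect:
        ``"default"`` expects the canonical :data:`CENSUS_COLUMNS` header.  A
        mapping ``{source_column: canonical_column}`` renames an alternate
        deposit layout onto the canonical schema before validation, so
        externally archived tables can be loaded by supplying a small
        user-editable mapping.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    if dialect != "default":
        df = df.rename(columns=dict(dialect))
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    _validate_counts(df, str(path))

    out: list[PopulationSeries] = []
    for (temp, diet, rep), grp in df.groupby(
        ["temperature_C", "diet", "replicate"], sort=True
    ):
        grp = grp.sort_values("week")
        weeks = grp["week"].to_numpy(dtype=np.int64)
        larv = grp[list(LARVAL_COLUMNS)]
        has_larv = larv.notna().all(axis=1).to_numpy()
        # larval records must form a prefix of the adult span
        if has_larv.any():
            n_larv = int(np.flatnonzero(has_larv)[-1]) + 1
            if not has_larv[:n_larv].all():
                raise ValidationError(
                    f"{path}: population ({temp},{diet},{rep}) has interior missing larval weeks"
                )
        else:
            n_larv = 0
        out.append(
            PopulationSeries(
                treatment=Treatment(int(temp), str(diet), int(rep)),
                weeks=weeks,
                adults_female=grp["adults_female"].to_numpy(),
                adults_male=grp["adults_male"].to_numpy(),
                larvae_L3=larv["larvae_L3"].to_numpy()[:n_larv],
                larvae_L4=larv["larvae_L4"].to_numpy()[:n_larv],
                larvae_L5=larv["larvae_L5"].to_numpy()[:n_larv],
            )
        )
    return out


def write_census(
    series: Iterable[PopulationSeries] | PopulationSeries,
    path: str | Path,
    header_comment: str | None = None,
) -> Path:
    """Write populations to the canonical census CSV schema."""
    if isinstance(series, PopulationSeries):
        series = [series]
    frames = []
    for s in series:
        n, nl = s.n_weeks, s.n_larval_weeks
        larv = {
            c: np.concatenate([getattr(s, c).astype(float), np.full(n - nl, np.nan)])
            for c in LARVAL_COLUMNS
        }
        frames.append(
            pd.DataFrame(
                {
                    "week": s.weeks,
                    "temperature_C": s.treatment.temperature,
                    "diet": s.treatment.diet,
                    "replicate": s.treatment.replicate,
                    "adults_female": s.adults_female,
                    "adults_male": s.adults_male,
                    **larv,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)[list(CENSUS_COLUMNS)]
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.0f")
    return path


# ---------------------------------------------------------------------------
# descriptive operations


def truncate_transients(s: PopulationSeries, n_drop: int = 10) -> PopulationSeries:
    """Drop the first ``n_drop`` observed weeks from every channel.

    Establishment transients from founding a cage bias stationarity-based
    analyses, so the convention is to discard the initial weeks before any
    spectral or statistical work.
    """
    if n_drop < 0:
        raise ValueError("n_drop must be >= 0")
    if s.n_weeks <= n_drop:
        raise ValueError(
            f"cannot drop {n_drop} weeks from a {s.n_weeks}-week series"
        )
    nl = max(s.n_larval_weeks - n_drop, 0)
    return s.replace(
        weeks=s.weeks[n_drop:],
        adults_female=s.adults_female[n_drop:],
        adults_male=s.adults_male[n_drop:],
        larvae_L3=s.larvae_L3[s.n_larval_weeks - nl:],
        larvae_L4=s.larvae_L4[s.n_larval_weeks - nl:],
        larvae_L5=s.larvae_L5[s.n_larval_weeks - nl:],
    )


def total_adults(s: PopulationSeries) -> np.ndarray:
    """Weekly dead-adult totals, female + male."""
    return s.adults_female + s.adults_male


def total_larvae(s: PopulationSeries) -> np.ndarray:
    """Weekly counted-larva totals (instars 3-5) over the larval span."""
    return s.larvae_L3 + s.larvae_L4 + s.larvae_L5


def coefficient_of_variation(x: Sequence[float] | np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    if m <= 0:
        raise ValueError("CV undefined for a series with nonpositive mean")
    return float(x.std(ddof=1) / m)


def age_structure(
    s: PopulationSeries, method: Literal["weekly_mean", "pooled"] = "weekly_mean"
) -> AgeStructure:
    """Time-averaged larval age structure.

    ``weekly_mean`` (default) averages per-week instar proportions over the
    weeks with at least one counted larva, which is robust to week-to-week
    variation in sampling effort; ``pooled`` divides the pooled instar totals
    by the pooled grand total.  The two coincide whenever weekly totals are
    equal.
    """
    counts = np.stack([s.larvae_L3, s.larvae_L4, s.larvae_L5], axis=1).astype(float)
    totals = counts.sum(axis=1)
    keep = totals > 0
    if not keep.any():
        raise ValueError("age structure undefined: no week has counted larvae")
    if method == "weekly_mean":
        props = counts[keep] / totals[keep, None]
        p = props.mean(axis=0)
    elif method == "pooled":
        p = counts[keep].sum(axis=0) / totals[keep].sum()
    else:
        raise ValueError(f"unknown method {method!r}")
    p = p / p.sum()  # guard rounding at the 1e-16 level
    return AgeStructure(p3=float(p[0]), p4=float(p[1]), p5=float(p[2]))


def flag_extinction(s: PopulationSeries, min_zero_run: int = 8) -> PopulationSeries:
    """Mark a population extinct if its adult series ends in a long zero run.

    The rule: if every adult count after some week is zero and at least
    ``min_zero_run`` consecutive zero weeks follow, ``extinct_week`` is set to
    the first week of that terminal zero run.  A trailing lull shorter than
    ``min_zero_run`` weeks (about one generation) is treated as a deep cycle
    trough, not extinction.
    """
    tot = total_adults(s)
    if tot.sum() == 0:
        return s.replace(extinct_week=int(s.weeks[0]))
    last_pos = int(np.flatnonzero(tot > 0)[-1])
    n_zero_tail = tot.size - last_pos - 1
    if n_zero_tail >= min_zero_run:
        return s.replace(extinct_week=int(s.weeks[last_pos + 1]))
    return s.replace(extinct_week=None)
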