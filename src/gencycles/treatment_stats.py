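"""Treatment-level inference for factorial mesocosm studies.

Quantitative per-population measures (mean adult count, mean larval count,
coefficient of variation, age-structure proportions) are compared with
factorial linear models simplified by backward elimination of
nonsignificant terms; qualitative outcomes (cycling vs not) are compared
with an exact r x c contingency test computed by full enumeration of all
tables with the observed margins under the multivariate hypergeometric
null, in exact rational arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core_data import (
    PopulationSeries,
    Treatment,
    age_structure,
    coefficient_of_variation,
    total_adults,
    total_larvae,
)
from .spectral import CycleCall, cycling_pattern

__all__ = [
    "AnovaResult",
    "ExactTestResult",
    "StudyReport",
    "factorial_lm",
    "fisher_exact_rxc",
    "fisher_exact_mc",
    "population_measures",
    "summarize_study",
]

ENUMERATION_GUARD_N = 60
ENUMERATION_GUARD_TABLES = 2_000_000


@dataclass(frozen=True)
class AnovaResult:
    term: str
    F: float
    df_num: int
    df_den: int
    p: float
    retained: bool


@dataclass(frozen=True)
class ExactTestResult:
    p: float
    n_tables: int
    observed_prob: float
    se: float | None = None  # only for the Monte-Carlo estimator


# ---------------------------------------------------------------------------
# linear models


def factorial_lm(
    data: pd.DataFrame,
    response: str,
    factors: Sequence[str] = ("temperature_C", "diet"),
    alpha: float = 0.05,
) -> list[AnovaResult]:
    """Factorial ANOVA with backward elimination to a minimal adequate model.

    Fits ``response ~ factor1 * factor2 * ...`` by least squares with
    sequential (type I) sums of squares, factors entered in the order
    given.  The highest-order interaction is dropped if its F-test p-value
    is >= ``alpha``; then nonsignificant main effects are dropped one at a
    time (largest p first), never removing a main effect while an
    interaction containing it is retained.  Results are reported for every
    term of the full model, flagged by whether it survived.
    """
    factors = [f for f in factors if f in data.columns]
    if not factors:
        raise ValueError("no model factors present in the data")
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than two levels")
    df = data.copy()

    terms = [f"C({f})" for f in factors]
    inter = ":".join(terms) if len(terms) > 1 else None
    full_terms = terms + ([inter] if inter else [])

    # a (numerically) constant response carries no information: report the
    # degenerate F = 0, p = 1 for every term rather than rounding noise
    y = df[response].to_numpy(dtype=float)
    if y.var() <= 1e-20 * (1.0 + y.mean() ** 2):
        k_levels = {t: df[f].nunique() - 1 for t, f in zip(terms, factors)}
        if inter:
            k_levels[inter] = int(np.prod([v for v in k_levels.values()]))
        df_den = len(df) - 1 - sum(k_levels.values())
        if df_den < 1:
            raise ValueError("zero residual degrees of freedom")
        return [AnovaResult(term=t.replace("C(", "").replace(")", ""), F=0.0,
                            df_num=k, df_den=df_den, p=1.0, retained=True)
                for t, k in k_levels.items()]

    def fit(model_terms: list[str]) -> pd.DataFrame:
        formula = f"{response} ~ " + " + ".join(model_terms)
        model = smf.ols(formula, data=df).fit()
        if model.df_resid < 1:
            raise ValueError("zero residual degrees of freedom")
        return sm.stats.anova_lm(model, typ=1)

    current = list(full_terms)
    anova = fit(current)

    def term_p(tab: pd.DataFrame, term: str) -> float:
        p = tab.loc[term, "PR(>F)"]
        return 1.0 if np.isnan(p) else float(p)

    # drop the interaction first if nonsignificant
    if inter and term_p(anova, inter) >= alpha:
        current.remove(inter)
        anova = fit(current)
        # then main effects, largest p first, while nonsignificant
        while len(current) > 1:
            ps = {t: term_p(anova, t) for t in current}
            worst = max(ps, key=ps.get)
            if ps[worst] < alpha:
                break
            current.remove(worst)
            anova = fit(current)

    # assemble: retained terms from the minimal model, dropped terms with
    # their statistics from the last model that contained them
    full_tab = fit(full_terms)
    out = []
    for t in full_terms:
        tab = anova if t in current else full_tab
        row = tab.loc[t]
        F = float(row["F"])
        p = float(row["PR(>F)"])
        if np.isnan(F):  # degenerate (e.g. constant response)
            F, p = 0.0, 1.0
        out.append(
            AnovaResult(
                term=t.replace("C(", "").replace(")", ""),
                F=F,
                df_num=int(row["df"]),
                df_den=int(tab.loc["Residual", "df"]),
                p=p,
                retained=t in current,
            )
        )
    return out


# ---------------------------------------------------------------------------
# exact contingency tests


def _log_fact(n: int) -> Fraction:  # pragma: no cover - helper alias
    return Fraction(math.factorial(n))


def _table_prob(table: np.ndarray, row_f: list, col_f: list, n_f) -> Fraction:
    denom = n_f
    for v in table.ravel():
        denom *= math.factorial(int(v))
    num = 1
    for f in row_f:
        num *= f
    for f in col_f:
        num *= f
    return Fraction(num, denom)


def _enumerate_tables(rows: list[int], cols: list[int]):
    """Yield all nonnegative integer tables with the given margins."""
    r, c = len(rows), len(cols)
    table = np.zeros((r, c), dtype=np.int64)
    col_rem = list(cols)
    count = [0]

    def fill_row(i: int):
        if i == r - 1:
            if all(v >= 0 for v in col_rem):
                table[i] = col_rem
                count[0] += 1
                if count[0] > ENUMERATION_GUARD_TABLES:
                    raise ValueError(
                        "enumeration too large; use fisher_exact_mc instead"
                    )
                yield table
            return
        yield from fill_cell(i, 0, rows[i])

    def fill_cell(i: int, j: int, rem: int):
        if j == c - 1:
            if rem <= col_rem[j]:
                table[i, j] = rem
                col_rem[j] -= rem
                yield from fill_row(i + 1)
                col_rem[j] += rem
            return
        for v in range(min(rem, col_rem[j]) + 1):
            table[i, j] = v
            col_rem[j] -= v
            yield from fill_cell(i, j + 1, rem - v)
            col_rem[j] += v

    yield from fill_row(0)


def _check_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if t.min() < 0:
        raise ValueError("table cells must be nonnegative")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("all row and column margins must be positive")
    return t


def fisher_exact_rxc(table: Sequence[Sequence[int]] | np.ndarray) -> ExactTestResult:
    """Exact two-sided r x c contingency test by full enumeration.

    Enumerates every table sharing the observed margins; each has
    multivariate hypergeometric probability
    ``P = (prod row_i! prod col_j!) / (N! prod cell_ij!)``.  The two-sided
    p-value sums ``P`` over tables no more probable than the observed one
    (probability ordering).  All arithmetic is exact rational, so the
    "no more probable" comparison has no floating-point ambiguity.
    """
    t = _check_table(table)
    n = int(t.sum())
    if n > ENUMERATION_GUARD_N:
        raise ValueError(
            f"table total {n} > {ENUMERATION_GUARD_N}; use fisher_exact_mc"
        )
    rows = t.sum(axis=1).tolist()
    cols = t.sum(axis=0).tolist()
    row_f = [math.factorial(int(v)) for v in rows]
    col_f = [math.factorial(int(v)) for v in cols]
    n_f = math.factorial(n)

    p_obs = _table_prob(t, row_f, col_f, n_f)
    p_sum = Fraction(0)
    total = Fraction(0)
    n_tables = 0
    for tab in _enumerate_tables(rows, cols):
        prob = _table_prob(tab, row_f, col_f, n_f)
        total += prob
        n_tables += 1
        if prob <= p_obs:
            p_sum += prob
    assert abs(total - 1) == 0, "enumerated probabilities must sum to 1"
    return ExactTestResult(
        p=float(p_sum), n_tables=n_tables, observed_prob=float(p_obs)
    )


def fisher_exact_mc(
    table: Sequence[Sequence[int]] | np.ndarray,
    reps: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> ExactTestResult:
    """Monte-Carlo estimate of the exact test for tables too large to enumerate.

    Samples tables from the fixed-margin null by randomly permuting column
    labels over the N units and cross-tabulating; the p estimate is
    ``(1 + #{P_sim <= P_obs}) / (1 + reps)`` with a binomial standard error.
    """
    if reps < 1000:
        import warnings

        warnings.warn(f"reps={reps} < 1000: Monte-Carlo p will be noisy")
    t = _check_table(table)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    row_f = [math.factorial(int(v)) for v in rows]
    col_f = [math.factorial(int(v)) for v in cols]
    n_f = math.factorial(n)
    # compare log-probabilities; only cell factorials vary across tables
    lgf = np.array([math.lgamma(v + 1) for v in range(n + 1)])
    obs_stat = lgf[t.ravel()].sum()

    labels = np.repeat(np.arange(cols.size), cols)
    row_edges = np.cumsum(rows)[:-1]
    hits = 0
    for _ in range(reps):
        rng.shuffle(labels)
        sim = np.stack(
            [np.bincount(part, minlength=cols.size) for part in np.split(labels, row_edges)]
        )
        if lgf[sim.ravel()].sum() >= obs_stat - 1e-9:
            hits += 1
    p_hat = (1 + hits) / (1 + reps)
    se = math.sqrt(p_hat * (1 - p_hat) / reps)
    return ExactTestResult(
        p=p_hat,
        n_tables=reps,
        observed_prob=float(_table_prob(t, row_f, col_f, n_f)),
        se=se,
    )


# ---------------------------------------------------------------------------
# study-level summary


MEASURES = ("adult_mean", "larval_mean", "cv", "p5")


def population_measures(series: Iterable[PopulationSeries]) -> pd.DataFrame:
    """Per-population descriptive measures for the treatment-level models.

    One row per population: mean weekly dead-adult count, mean weekly
    counted-larva count, CV of the adult series, and the time-averaged
    proportion of 5th instars.  Populations flagged extinct get NaN
    measures (they are excluded from the models).
    """
    recs = []
    for s in series:
        trt = s.treatment
        rec = {
            "temperature_C": trt.temperature,
            "diet": trt.diet,
            "replicate": trt.replicate,
            "persisted": s.extinct_week is None,
        }
        if s.extinct_week is None:
            adults = total_adults(s)
            rec["adult_mean"] = float(adults.mean())
            rec["cv"] = coefficient_of_variation(adults)
            if s.n_larval_weeks:
                larv = total_larvae(s)
                rec["larval_mean"] = float(larv.mean())
                try:
                    rec["p5"] = age_structure(s).p5
                except ValueError:
                    rec["p5"] = np.nan
            else:
                rec["larval_mean"] = np.nan
                rec["p5"] = np.nan
        else:
            rec.update({m: np.nan for m in MEASURES})
        recs.append(rec)
    return pd.DataFrame(recs)


@dataclass
class StudyReport:
    measures: pd.DataFrame
    group_means: pd.DataFrame
    anovas: dict[str, list[AnovaResult]]
    cycling_table: pd.DataFrame | None
    fisher: ExactTestResult | None

    def anova_frame(self) -> pd.DataFrame:
        rows = [
            {"measure": m, "term": r.term, "F": r.F, "df_num": r.df_num,
             "df_den": r.df_den, "p": r.p, "retained": r.retained}
            for m, results in self.anovas.items()
            for r in results
        ]
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = ["Study summary", "=" * 13, "", "Treatment means (95% CI):",
                 self.group_means.to_string(), "", "Linear models:"]
        for m, results in self.anovas.items():
            for r in results:
                keep = "retained" if r.retained else "dropped"
                lines.append(
                    f"  {m}: {r.term}  F({r.df_num},{r.df_den}) = {r.F:.2f}, "
                    f"p = {r.p:.4g}  [{keep}]"
                )
        if self.fisher is not None:
            lines += ["", "Cycling pattern:", self.cycling_table.to_string(),
                      f"Exact test p = {self.fisher.p:.4g}"]
        return "\n".join(lines)


def summarize_study(
    series: Sequence[PopulationSeries],
    calls: dict[Treatment, CycleCall] | None = None,
    alpha: float = 0.05,
) -> StudyReport:
    """Assemble the treatment-level report for one study.

    Linear models (response ~ temperature * diet, backward-simplified) are
    fit to each measure over persisting populations; the cycling pattern,
    if cycle calls are supplied, is tested with the exact r x c test.
    Group means carry t-based 95% confidence intervals on within-group
    variance.
    """
    meas = population_measures(series)
    persist = meas[meas["persisted"]]

    gm_rows = []
    for (t, d), grp in persist.groupby(["temperature_C", "diet"]):
        for m in MEASURES:
            vals = grp[m].dropna()
            if vals.empty:
                continue
            mean = vals.mean()
            if len(vals) > 1:
                from scipy import stats as sps

                half = sps.t.ppf(0.975, len(vals) - 1) * vals.std(ddof=1) / math.sqrt(len(vals))
            else:
                half = np.nan
            gm_rows.append(
                {"temperature_C": t, "diet": d, "measure": m, "mean": mean,
                 "ci_low": mean - half, "ci_high": mean + half, "n": len(vals)}
            )
    group_means = pd.DataFrame(gm_rows)

    anovas: dict[str, list[AnovaResult]] = {}
    for m in MEASURES:
        sub = persist.dropna(subset=[m])
        try:
            anovas[m] = factorial_lm(sub, m, alpha=alpha)
        except ValueError:
            continue  # e.g. a factor collapsed to one level after extinctions

    cyc_table = fisher = None
    if calls:
        cyc_table = cycling_pattern(calls)
        try:
            fisher = fisher_exact_rxc(cyc_table.to_numpy())
        except ValueError:
            fisher = None  # degenerate margin (all or none cycling)
    return StudyReport(
        measures=meas, group_means=group_means, anovas=anovas,
        cycling_table=cyc_table, fisher=fisher,
    )
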