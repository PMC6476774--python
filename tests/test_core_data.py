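import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gencycles import (
    PopulationSeries,
    SchemaError,
    Treatment,
    ValidationError,
    age_structure,
    coefficient_of_variation,
    flag_extinction,
    read_census,
    total_adults,
    truncate_transients,
    write_census,
)

# ---------------------------------------------------------------------------
# domain types


def test_treatment_validation():
    Treatment(27, "standard", 1)
    with pytest.raises(ValidationError):
        Treatment(28, "standard", 1)
    with pytest.raises(ValidationError):
        Treatment(27, "rich", 1)
    with pytest.raises(ValidationError):
        Treatment(27, "poor", 0)


def test_series_invariants_enforced():
    w = np.arange(1, 6)
    ok = dict(treatment=Treatment(27, "poor", 2), weeks=w,
              adults_female=np.ones(5, int), adults_male=np.ones(5, int),
              larvae_L3=np.ones(3, int), larvae_L4=np.ones(3, int),
              larvae_L5=np.ones(3, int))
    PopulationSeries(**ok)
    with pytest.raises(ValidationError, match="nonnegative"):
        PopulationSeries(**{**ok, "adults_male": np.array([1, 1, -1, 1, 1])})
    with pytest.raises(ValidationError, match="unit spacing"):
        PopulationSeries(**{**ok, "weeks": np.array([1, 2, 4, 5, 6])})
    with pytest.raises(ValidationError, match="larval span"):
        PopulationSeries(**{**ok, "larvae_L3": np.ones(6, int),
                            "larvae_L4": np.ones(6, int), "larvae_L5": np.ones(6, int)})


# ---------------------------------------------------------------------------
# file I/O


@st.composite
def census_series(draw):
    n = draw(st.integers(min_value=3, max_value=20))
    nl = draw(st.integers(min_value=0, max_value=n))
    count = st.integers(min_value=0, max_value=5000)
    arr = lambda size: np.array(draw(st.lists(count, min_size=size, max_size=size)))
    return PopulationSeries(
        treatment=Treatment(
            draw(st.sampled_from([27, 30, 33])),
            draw(st.sampled_from(["standard", "poor"])),
            draw(st.integers(1, 3)),
        ),
        weeks=np.arange(1, n + 1),
        adults_female=arr(n),
        adults_male=arr(n),
        larvae_L3=arr(nl),
        larvae_L4=arr(nl),
        larvae_L5=arr(nl),
    )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(series=census_series())
def test_census_round_trip(series, tmp_path_factory):
    """write_census(read_census(f)) is lossless for schema-valid tables."""
    path = tmp_path_factory.mktemp("rt") / "census.csv"
    write_census(series, path)
    back = read_census(path)
    assert len(back) == 1
    b = back[0]
    assert b.treatment == series.treatment
    np.testing.assert_array_equal(b.weeks, series.weeks)
    for ch in ("adults_female", "adults_male", "larvae_L3", "larvae_L4", "larvae_L5"):
        np.testing.assert_array_equal(getattr(b, ch), getattr(series, ch))


def test_read_census_three_row_toy(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(
        "week,temperature_C,diet,replicate,adults_female,adults_male,"
        "larvae_L3,larvae_L4,larvae_L5\n"
        "1,27,standard,1,3,2,1,0,2\n2,27,standard,1,0,1,2,2,0\n3,27,standard,1,5,4,0,1,1\n"
    )
    (s,) = read_census(path)
    np.testing.assert_array_equal(s.weeks, [1, 2, 3])
    np.testing.assert_array_equal(total_adults(s), [5, 1, 9])


def test_read_census_schema_and_validation_errors(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("week,temperature_C,diet,replicate,adults_female\n1,27,standard,1,3\n")
    with pytest.raises(SchemaError, match="adults_male"):
        read_census(path)
    path.write_text(
        "week,temperature_C,diet,replicate,adults_female,adults_male,"
        "larvae_L3,larvae_L4,larvae_L5\n"
        "1,27,standard,1,3,2,1,0,2\n2,27,standard,1,-2,1,2,2,0\n"
    )
    with pytest.raises(ValidationError, match="row 3"):
        read_census(path)


def test_read_census_dialect_mapping(tmp_path):
    path = tmp_path / "alt.csv"
    path.write_text(
        "wk,temp,food,rep,dead_f,dead_m,L3,L4,L5\n1,27,standard,1,3,2,1,0,2\n"
    )
    mapping = {"wk": "week", "temp": "temperature_C", "food": "diet",
               "rep": "replicate", "dead_f": "adults_female",
               "dead_m": "adults_male", "L3": "larvae_L3", "L4": "larvae_L4",
               "L5": "larvae_L5"}
    (s,) = read_census(path, dialect=mapping)
    assert total_adults(s)[0] == 5


# ---------------------------------------------------------------------------
# truncation


def test_truncation_drops_establishment_weeks(small_series):
    t = truncate_transients(small_series, 10)
    assert t.n_weeks == 72
    assert t.weeks[0] == 11
    assert t.n_larval_weeks == 52
    assert t.treatment == small_series.treatment
    np.testing.assert_array_equal(t.adults_female, small_series.adults_female[10:])


def test_truncation_identity_and_composition(small_series):
    same = truncate_transients(small_series, 0)
    np.testing.assert_array_equal(same.weeks, small_series.weeks)
    twice = truncate_transients(truncate_transients(small_series, 5), 5)
    once = truncate_transients(small_series, 10)
    np.testing.assert_array_equal(twice.weeks, once.weeks)
    np.testing.assert_array_equal(twice.larvae_L5, once.larvae_L5)


def test_truncation_boundary_error(small_series):
    with pytest.raises(ValueError):
        truncate_transients(small_series, 82)


# ---------------------------------------------------------------------------
# descriptive measures


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 100), st.integers(0, 100)),
                min_size=3, max_size=30))
def test_total_adults_conserves_sexes(pairs):
    f, m = (np.array(v) for v in zip(*pairs))
    s = PopulationSeries(Treatment(30, "poor", 1), np.arange(1, len(f) + 1), f, m,
                         np.zeros(0, int), np.zeros(0, int), np.zeros(0, int))
    tot = total_adults(s)
    np.testing.assert_array_equal(tot, f + m)
    assert tot.sum() == f.sum() + m.sum()


def test_cv_examples_and_scale_invariance():
    assert coefficient_of_variation([4, 4, 4, 4]) == 0.0
    assert coefficient_of_variation([1, 3]) == pytest.approx(np.sqrt(2) / 2, abs=1e-9)
    x = np.array([3.0, 9.0, 1.0, 14.0, 6.0])
    assert coefficient_of_variation(7.3 * x) == pytest.approx(
        coefficient_of_variation(x), rel=1e-12)
    with pytest.raises(ValueError):
        coefficient_of_variation([0, 0, 0])


def _series_with_larvae(l3, l4, l5):
    n = len(l3)
    z = np.zeros(n, int) + 1
    return PopulationSeries(Treatment(27, "standard", 1), np.arange(1, n + 1),
                            z, z, np.array(l3), np.array(l4), np.array(l5))


def test_age_structure_examples():
    a = age_structure(_series_with_larvae([1], [1], [2]))
    assert (a.p3, a.p4, a.p5) == (0.25, 0.25, 0.5)
    a = age_structure(_series_with_larvae([2, 4], [2, 4], [4, 8]))
    assert (a.p3, a.p4, a.p5) == pytest.approx((0.25, 0.25, 0.5), abs=1e-12)
    with pytest.raises(ValueError):
        age_structure(_series_with_larvae([0, 0], [0, 0], [0, 0]))


def test_age_structure_weekly_mean_equals_pooled_under_equal_totals():
    # identical weekly totals: the two averaging conventions coincide
    s = _series_with_larvae([1, 2, 3], [2, 3, 1], [3, 1, 2])
    w = age_structure(s, method="weekly_mean")
    p = age_structure(s, method="pooled")
    assert (w.p3, w.p4, w.p5) == pytest.approx((p.p3, p.p4, p.p5), abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)),
                min_size=1, max_size=20).filter(lambda v: any(sum(t) for t in v)))
def test_age_structure_proportions_sum_to_one(triples):
    l3, l4, l5 = (list(v) for v in zip(*triples))
    a = age_structure(_series_with_larvae(l3, l4, l5))
    assert a.p3 + a.p4 + a.p5 == pytest.approx(1.0, abs=1e-12)


def test_extinction_flagging():
    z = np.zeros(0, int)
    mk = lambda f: PopulationSeries(Treatment(33, "poor", 1), np.arange(1, len(f) + 1),
                                    np.array(f), np.zeros(len(f), int), z, z, z)
    s = flag_extinction(mk([5, 3, 1] + [0] * 10))
    assert s.extinct_week == 4
    assert total_adults(s)[3:].sum() == 0
    # a short terminal lull is a trough, not extinction
    assert flag_extinction(mk([5, 3, 1] + [0] * 5)).extinct_week is None
    # never-seen population is extinct from the start
    assert flag_extinction(mk([0] * 12)).extinct_week == 1
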