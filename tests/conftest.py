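import numpy as np
import pytest

from gencycles import PopulationSeries, Treatment


@pytest.fixture
def small_series() -> PopulationSeries:
    """An 82-week population with a 62-week larval span and easy arithmetic."""
    rng = np.random.default_rng(7)
    n, nl = 82, 62
    return PopulationSeries(
        treatment=Treatment(27, "standard", 1),
        weeks=np.arange(1, n + 1),
        adults_female=rng.poisson(40, n),
        adults_male=rng.poisson(40, n),
        larvae_L3=rng.poisson(30, nl),
        larvae_L4=rng.poisson(20, nl),
        larvae_L5=rng.poisson(25, nl),
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The deterministic census fixtures, generated once per session."""
    from gencycles.pipeline import make_fixtures

    out = tmp_path_factory.mktemp("fixtures")
    make_fixtures(seed=0, out_dir=out)
    return out
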