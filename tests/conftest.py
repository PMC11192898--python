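import hypothesis
import pytest

from lpicalc import AdjustmentConfig, PopulationSeries

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("ci")


def make_series(
    pid,
    values,
    start=1970,
    years=None,
    species=None,
    taxon="birds",
    realm="Palearctic",
    ecosystem="terrestrial",
):
    """Shorthand population builder used throughout the suite."""
    if years is None:
        years = range(start, start + len(values))
    return PopulationSeries(
        population_id=pid,
        species=species or f"species_{pid}",
        taxon=taxon,
        realm=realm,
        ecosystem=ecosystem,
        observations=dict(zip(years, (float(v) for v in values))),
    )


@pytest.fixture
def quick_config():
    """No bootstrap, otherwise defaults."""
    return AdjustmentConfig(bootstrap_reps=0)


@pytest.fixture
def mk():
    return make_series
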