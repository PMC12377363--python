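import numpy as np
import pytest
from hypothesis import settings

from floralri import PhenologySeries

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def make_series():
    """Factory for small phenology series on a fixed date grid."""

    def _make(species, n_flowering, n_sampled=100, season="s1", start="2020-01-01"):
        n_flowering = np.asarray(n_flowering)
        dates = np.datetime64(start, "D") + np.arange(len(n_flowering)) * np.timedelta64(14, "D")
        return PhenologySeries(
            species=species, season=season, dates=dates,
            n_flowering=n_flowering,
            n_sampled=np.full(len(n_flowering), n_sampled),
        )

    return _make


@pytest.fixture(scope="session")
def werauhia_morphology():
    """Simulated study-like floral measurements (session-scoped: reused by
    several morphology tests, all read-only)."""
    from floralri import simulate_morphology
    from floralri.datasets import werauhia_morphology_params

    return simulate_morphology(werauhia_morphology_params(), seed=20)
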