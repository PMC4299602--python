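import math

import pytest

from sizescreen import SimConfig, simulate_lineage, simulate_traces


def cohort_config(seed: int, n: int = 500, **kwargs) -> SimConfig:
    """Config for a founder cohort: ``n`` cells with lognormal birth sizes,
    each completing one cycle inside the movie (the movie is long enough
    that even slow small-born founders finish, avoiding survivorship bias;
    the lineage front after generation 0 is capped to keep runs cheap)."""
    defaults = dict(seed=seed, n_founders=n, movie_length=600.0, max_cells=32)
    defaults.update(kwargs)
    return SimConfig(**defaults)


def cohort(seed: int, n: int = 500, **kwargs):
    """Simulate a founder cohort and return the generation-0 records."""
    records = simulate_lineage(cohort_config(seed, n, **kwargs))
    return records.loc[records["generation"] == 0].reset_index(drop=True)


@pytest.fixture(scope="session")
def wt_lineage():
    """A wild-type-like checkpoint lineage movie with censored cells kept
    (as trace synthesis needs them)."""
    cfg = SimConfig(seed=3, n_founders=120)
    return cfg, simulate_lineage(cfg, include_censored=True)


@pytest.fixture(scope="session")
def wt_traces(wt_lineage):
    cfg, records = wt_lineage
    return simulate_traces(records, cfg)


@pytest.fixture(scope="session")
def sizer_cohort():
    """5,000 checkpoint daughters born well below the budding threshold."""
    return cohort(7, n=5000, birth_mu=math.log(20.0))
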