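import pytest

from busbenefits import SyntheticDomainSpec, build_fixture


@pytest.fixture(scope="session")
def spec():
    return SyntheticDomainSpec(n_cells=100, n_counties=6, seed=1)


@pytest.fixture(scope="session")
def bundle(spec):
    """Small synthetic domain shared across the suite (read-only)."""
    return build_fixture(spec)


@pytest.fixture(scope="session")
def damages(bundle):
    from busbenefits import county_damages_per_ton

    return county_damages_per_ton(bundle)
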