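import pytest

import pessiknock as pk


@pytest.fixture(scope="session")
def toy7():
    return pk.make_fixture("toy7")


@pytest.fixture(scope="session")
def diamond():
    return pk.make_fixture("diamond")


@pytest.fixture(scope="session")
def w_toy7(toy7):
    return pk.wild_type_fluxes(toy7)


@pytest.fixture(scope="session")
def random_model():
    """Seeded random fixture factory with per-session caching."""
    cache: dict[int, pk.MetabolicModel] = {}

    def _get(seed: int) -> pk.MetabolicModel:
        if seed not in cache:
            cache[seed] = pk.make_fixture("random", seed=seed)
        return cache[seed]

    return _get


@pytest.fixture(scope="session")
def random_wildtype(random_model):
    cache: dict[int, pk.WildTypeReference] = {}

    def _get(seed: int) -> pk.WildTypeReference:
        if seed not in cache:
            cache[seed] = pk.wild_type_fluxes(random_model(seed))
        return cache[seed]

    return _get
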