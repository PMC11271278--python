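import pytest

from hapi.simulate import FixtureConfig, HijackEvent, generate_fixture


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A compact generated dataset with two implanted trans-hijack genes."""
    config = FixtureConfig(
        n_genes=60,
        n_hapi_boosted=6,
        hijack_events=(HijackEvent(gene="HJ00"), HijackEvent(gene="HJ01")),
        seed=7,
    )
    return generate_fixture(config, tmp_path_factory.mktemp("fixture"))
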