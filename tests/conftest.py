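import pytest

from rdscan.synthetic import SyntheticConfig, gen_loci, gen_tracks


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def toy_tracks(default_config):
    return gen_tracks(default_config)


@pytest.fixture(scope="session")
def toy_loci(default_config, toy_tracks):
    loci, manifest = gen_loci(default_config, toy_tracks)
    return loci, manifest
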