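import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from regscout import read_bedgraph, read_contact_map
from regscout.simulate import build_fixture


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """The worked-example data set, written once per session."""
    return build_fixture(tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def hindiii_map(fixture_paths):
    return read_contact_map(fixture_paths["hindiii_map"])


@pytest.fixture(scope="session")
def ncoi_map(fixture_paths):
    return read_contact_map(fixture_paths["ncoi_map"])


@pytest.fixture(scope="session")
def h3k27ac_track(fixture_paths):
    return read_bedgraph(fixture_paths["signal"])
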