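import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from paleosieve.fixtures import Fixture, FixtureSpec, make_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_default(tmp_path_factory) -> Fixture:
    """Toy dataset with 50% sibling sharing and a diverged cross-order contaminant."""
    return make_fixture(FixtureSpec(seed=1), tmp_path_factory.mktemp("fx-default"))


@pytest.fixture(scope="session")
def fixture_nullshare(tmp_path_factory) -> Fixture:
    """Toy dataset where every genome is independent random sequence."""
    spec = FixtureSpec(seed=2, shared_fraction=0.0, crossorder_shared_fraction=0.0)
    return make_fixture(spec, tmp_path_factory.mktemp("fx-nullshare"))
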