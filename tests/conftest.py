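import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pisatree import (  # noqa: E402
    default_repository,
    generate_cpb_fixture,
    generate_strt_fixture,
)


@pytest.fixture(scope="session")
def repo():
    return default_repository()


@pytest.fixture(scope="session")
def cpb_tree(tmp_path_factory):
    """Session-wide CPB example tree; tests must not modify it."""
    root = tmp_path_factory.mktemp("cpb")
    return generate_cpb_fixture(root / "tree")


@pytest.fixture(scope="session")
def strt_tree(tmp_path_factory):
    """Session-wide STRT example tree; tests must not modify it."""
    root = tmp_path_factory.mktemp("strt")
    return generate_strt_fixture(root / "tree")
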