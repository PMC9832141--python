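import pytest

from nrnstim.fixtures import FixtureSpec, make_swc, materialize_preset
from nrnstim.morphology import parse_swc


@pytest.fixture(scope="session")
def ball_stick():
    """21-record ball-and-stick: soma + 20 apical points at 10 um spacing."""
    return parse_swc(make_swc(FixtureSpec("ball_and_stick", n_points=20,
                                          spacing=10.0, seed=0)))


@pytest.fixture(scope="session")
def long_cable():
    """300 um apical cable at 1 um spacing (the preset fixture geometry)."""
    return parse_swc(make_swc(FixtureSpec("ball_and_stick", n_points=300,
                                          spacing=1.0)))


@pytest.fixture(scope="session")
def y_tree():
    return parse_swc(make_swc(FixtureSpec("y_tree", n_points=10, spacing=5.0)))


@pytest.fixture()
def preset(tmp_path):
    """Factory: materialize a named session preset into tmp_path."""
    def _make(name):
        return materialize_preset(name, tmp_path)

    return _make
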