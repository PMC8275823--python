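import numpy as np
import pytest

from evsurf import NeuriteAxis, SimulationConfig, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_axis():
    """Axis along +x with the soma at the first vertex (x=0)."""
    return NeuriteAxis(np.array([[0.0, 0.0], [600.0, 0.0]]),
                       soma_end="first_vertex")


@pytest.fixture
def fast_cfg():
    """Short, cheap simulation config for unit tests."""
    return SimulationConfig(duration_s=200.0, rng_seed=7)


def make_traj(x, y, dt=2.5, diameter=0.5, **kw):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.arange(x.size) * dt
    return Trajectory(t_s=t, x_um=x, y_um=y, ev_diameter_um=diameter, **kw)


# ---------------------------------------------------------------------------
# independent straight-loop oracles (deliberately naive)
# ---------------------------------------------------------------------------

def oracle_path_length(x, y):
    total = 0.0
    for i in range(1, len(x)):
        total += ((x[i] - x[i - 1]) ** 2 + (y[i] - y[i - 1]) ** 2) ** 0.5
    return total


def oracle_excursions(s):
    max_pos = max_neg = run_pos = run_neg = 0.0
    for v in s:
        if v > max_pos:
            max_pos = v
        if -v > max_neg:
            max_neg = -v
    for i in range(1, len(s)):
        d = s[i] - s[i - 1]
        if d > 0:
            run_pos += d
        else:
            run_neg += -d
    return max_pos, max_neg, run_pos, run_neg


def oracle_radial(x, y, cx, cy):
    total = 0.0
    for xi, yi in zip(x, y):
        total += ((xi - cx) ** 2 + (yi - cy) ** 2) ** 0.5
    return total / len(x)


def oracle_moving_fraction(t, x, y, eps):
    go_time = 0.0
    for i in range(1, len(t)):
        d = ((x[i] - x[i - 1]) ** 2 + (y[i] - y[i - 1]) ** 2) ** 0.5
        if d > eps:
            go_time += t[i] - t[i - 1]
    return go_time / (t[-1] - t[0])
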