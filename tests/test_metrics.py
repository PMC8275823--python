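"""Per-EV motion metrics against hand values and straight-loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import evsurf as ev
from evsurf.metrics import (excursions, mean_speed, path_length,
                            project_onto_axis, radial_displacement, resample,
                            stop_go)

from conftest import (make_traj, oracle_excursions, oracle_moving_fraction,
                      oracle_path_length, oracle_radial)


# ---------------------------------------------------------------- resample

def test_resample_2hz_20min_gives_481_points():
    n = 2401
    traj = ev.Trajectory(t_s=np.arange(n) * 0.5,
                         x_um=np.linspace(0, 1, n),
                         y_um=np.zeros(n), ev_diameter_um=0.5)
    assert resample(traj, 2.5).n_points == 481


def test_resample_at_native_interval_is_identity():
    traj = make_traj(np.arange(10.0), np.zeros(10), dt=2.5)
    out = resample(traj, 2.5)
    assert np.array_equal(out.t_s, traj.t_s)
    assert np.array_equal(out.x_um, traj.x_um)


def test_resample_finer_than_native_raises():
    traj = make_traj(np.arange(10.0), np.zeros(10), dt=2.5)
    with pytest.raises(ValueError):
        resample(traj, 1.0)


def test_resample_keeps_first_and_last():
    t = np.array([0.0, 0.9, 2.3, 2.6, 4.9, 5.4, 6.1])
    traj = ev.Trajectory(t_s=t, x_um=t, y_um=np.zeros_like(t),
                         ev_diameter_um=0.5)
    out = resample(traj, 2.5)
    assert out.t_s[0] == 0.0 and out.t_s[-1] == 6.1


def test_resample_irregular_matches_brute_force(rng):
    t = np.sort(rng.uniform(0, 100, 80))
    t[0], t[-1] = 0.0, 100.0
    traj = ev.Trajectory(t_s=t, x_um=rng.normal(size=80),
                         y_um=rng.normal(size=80), ev_diameter_um=0.5)
    out = resample(traj, 2.5)
    targets = np.arange(0, 100.01, 2.5)
    expect = {0, t.size - 1}
    for tgt in targets:
        expect.add(int(np.argmin(np.abs(t - tgt))))
    assert set(np.searchsorted(t, out.t_s)) == expect


def test_path_length_non_increasing_under_coarser_resampling(rng):
    """Triangle inequality: nested coarser samplings shorten the path."""
    for _ in range(10):
        n = 241
        walk = np.cumsum(rng.normal(0, 0.2, size=(n, 2)), axis=0)
        traj = ev.Trajectory(t_s=np.arange(n) * 0.5, x_um=walk[:, 0],
                             y_um=walk[:, 1], ev_diameter_um=0.5)
        lengths = [path_length(resample(traj, dt)) for dt in (2.5, 5, 10)]
        assert lengths[0] >= lengths[1] >= lengths[2]


# ------------------------------------------------------------- path length

def test_path_length_unit_square():
    traj = make_traj([0, 1, 1, 0, 0], [0, 0, 1, 1, 0])
    assert path_length(traj) == pytest.approx(4.0)


def test_path_length_constant_position_is_zero():
    traj = make_traj([2, 2, 2], [3, 3, 3])
    assert path_length(traj) == 0.0


def test_path_length_matches_oracle(rng):
    for _ in range(5):
        xy = rng.normal(size=(100, 2))
        traj = make_traj(xy[:, 0], xy[:, 1])
        assert path_length(traj) == pytest.approx(
            oracle_path_length(xy[:, 0], xy[:, 1]), abs=1e-9)


# -------------------------------------------------------------- projection

def test_projection_straight_axis_soma_first(straight_axis):
    traj = make_traj([5.0, 6.0, 7.0], [0.0, 0.0, 0.0])
    series = project_onto_axis(traj, straight_axis)
    assert series.s_um == pytest.approx([0.0, 1.0, 2.0])


def test_projection_orientation_flips_with_soma_end():
    axis = ev.NeuriteAxis(np.array([[0.0, 0.0], [600.0, 0.0]]),
                          soma_end="last_vertex")
    traj = make_traj([5.0, 6.0, 7.0], [0.0, 0.0, 0.0])
    series = project_onto_axis(traj, axis)
    assert series.s_um == pytest.approx([0.0, -1.0, -2.0])


def test_projection_l_shaped_axis_matches_fine_grid():
    axis = ev.NeuriteAxis(np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 3.0]]))
    traj = make_traj([0.0, 1.0, 2.2], [0.0, 0.0, 1.0])
    series = project_onto_axis(traj, axis)
    # dense brute-force projection
    grid_s = np.linspace(0, 5.0, 50001)
    grid_xy = axis.point_at(grid_s)
    expected = []
    for x, y in zip(traj.x_um, traj.y_um):
        d2 = (grid_xy[:, 0] - x) ** 2 + (grid_xy[:, 1] - y) ** 2
        expected.append(grid_s[np.argmin(d2)])
    expected = np.array(expected) - expected[0]
    assert series.s_um == pytest.approx(expected, abs=1e-3)
    assert series.s_um[-1] == pytest.approx(3.0, abs=1e-6)


def test_projection_beyond_capture_distance_raises(straight_axis):
    traj = make_traj([5.0, 6.0], [0.0, 50.0])
    with pytest.raises(ValueError, match="capture"):
        project_onto_axis(traj, straight_axis, capture_distance_um=3.0)


# -------------------------------------------------------------- excursions

def test_excursions_hand_case():
    s = ev.SignedPositionSeries(t_s=np.arange(5) * 2.5,
                                s_um=[0, 1, 2, 1, -1])
    assert excursions(s) == pytest.approx((2.0, 1.0, 2.0, 3.0))


def test_excursions_monotone():
    s = ev.SignedPositionSeries(t_s=np.arange(6) * 2.5,
                                s_um=[0, 1, 2, 3, 4, 5])
    assert excursions(s) == pytest.approx((5.0, 0.0, 5.0, 0.0))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(-10, 10), min_size=2, max_size=60))
def test_excursions_match_oracle(deltas):
    s = np.concatenate([[0.0], np.cumsum(deltas)])
    series = ev.SignedPositionSeries(t_s=np.arange(s.size) * 2.5, s_um=s)
    got = excursions(series)
    want = oracle_excursions(s)
    assert got == pytest.approx(want, abs=1e-9)
    # invariants: max |s| and the 1D path identity
    assert max(got[0], got[1]) == pytest.approx(np.max(np.abs(s)))
    assert got[2] + got[3] == pytest.approx(np.sum(np.abs(np.diff(s))))


def test_excursions_random_walk_matches_oracle(rng):
    s = np.concatenate([[0.0], np.cumsum(rng.normal(size=999))])
    series = ev.SignedPositionSeries(t_s=np.arange(1000) * 2.5, s_um=s)
    assert excursions(series) == pytest.approx(oracle_excursions(s),
                                               abs=1e-9)


# ----------------------------------------------------------------- stop/go

def test_stop_go_alternating_moves_and_holds():
    """10 s moves at 0.2 um/s alternating with 10 s holds -> fraction 0.5."""
    t = np.arange(0, 200.1, 2.5)
    v = np.where((t % 20) < 10, 0.2, 0.0)
    x = np.concatenate([[0.0], np.cumsum(v[:-1] * np.diff(t))])
    traj = ev.Trajectory(t_s=t, x_um=x, y_um=np.zeros_like(t),
                         ev_diameter_um=0.5)
    segments, frac = stop_go(None, traj, motion_eps_um=0.1)
    assert frac == pytest.approx(0.5)
    states = [s[2] for s in segments]
    assert all(a != b for a, b in zip(states, states[1:]))
    # segments partition the record
    assert segments[0][0] == 0.0 and segments[-1][1] == 200.0
    for (_, end, _), (start, _, _) in zip(segments, segments[1:]):
        assert end == start


def test_stop_go_constant_position():
    traj = make_traj(np.zeros(9), np.zeros(9))
    segments, frac = stop_go(None, traj, motion_eps_um=0.1)
    assert frac == 0.0
    assert segments == [(0.0, 20.0, "stop")]


def test_stop_go_fraction_matches_oracle(rng):
    for _ in range(5):
        xy = np.cumsum(rng.normal(0, 0.2, size=(200, 2)), axis=0)
        traj = make_traj(xy[:, 0], xy[:, 1])
        _, frac = stop_go(None, traj, motion_eps_um=0.25)
        assert frac == pytest.approx(
            oracle_moving_fraction(traj.t_s, xy[:, 0], xy[:, 1], 0.25),
            abs=1e-9)


# -------------------------------------------------------------- mean speed

def test_mean_speed_simple():
    t = np.arange(0, 1200.1, 2.5)
    traj = ev.Trajectory(t_s=t, x_um=0.1 * t, y_um=np.zeros_like(t),
                         ev_diameter_um=0.5)
    assert mean_speed(traj) == pytest.approx(0.1, rel=1e-9)
    assert path_length(resample(traj, 2.5)) == pytest.approx(120.0)


def test_mean_speed_static_is_zero():
    traj = make_traj(np.zeros(10), np.zeros(10))
    assert mean_speed(traj) == 0.0


def test_mean_speed_recovers_simulated_velocity(straight_axis):
    cfg = ev.SimulationConfig(duration_s=200.0, p_mobile=1.0,
                              speed_min_um_s=0.2, speed_max_um_s=0.2,
                              go_dwell_mean_s=1e9, stop_dwell_mean_s=1e-9,
                              jitter_sigma_um=0.0, diffusion_um2_s=0.0,
                              rng_seed=1)
    traj, _ = ev.simulate_trajectory(cfg, straight_axis, mobility="mobile",
                                     direction="anterograde")
    assert mean_speed(traj) == pytest.approx(0.2, rel=1e-6)


# ------------------------------------------------------ radial displacement

def test_radial_displacement_at_contact_is_zero():
    traj = make_traj(np.full(5, 2.0), np.full(5, 3.0))
    assert radial_displacement(traj) == 0.0


def test_radial_displacement_circular_orbit():
    theta = np.linspace(0, 2 * np.pi, 40, endpoint=False)
    traj = ev.Trajectory(t_s=np.arange(40) * 2.5,
                         x_um=1.7 * np.cos(theta), y_um=1.7 * np.sin(theta),
                         ev_diameter_um=0.5, contact_point=(0.0, 0.0))
    assert radial_displacement(traj) == pytest.approx(1.7, rel=1e-9)


def test_radial_displacement_matches_oracle(rng):
    xy = np.cumsum(rng.normal(0, 0.1, size=(300, 2)), axis=0)
    traj = make_traj(xy[:, 0], xy[:, 1], contact_point=(0.5, -0.5))
    assert radial_displacement(traj) == pytest.approx(
        oracle_radial(xy[:, 0], xy[:, 1], 0.5, -0.5), abs=1e-9)


# ---------------------------------------------------------- compute_metrics

def test_compute_metrics_consistency(straight_axis, fast_cfg):
    traj, _ = ev.simulate_trajectory(fast_cfg, straight_axis,
                                     mobility="mobile",
                                     direction="bidirectional")
    m = ev.compute_metrics(traj, straight_axis)
    assert m.path_length_um >= m.max_dist_contact_um >= 0
    assert m.max_dist_contact_um == pytest.approx(
        max(m.max_dist_pos_um, m.max_dist_neg_um))
    assert 0 <= m.fraction_time_moving <= 1
    # 1D path identity on the signed series
    rs = resample(traj, 2.5)
    series = project_onto_axis(rs, straight_axis)
    assert m.run_length_pos_um + m.run_length_neg_um == pytest.approx(
        np.sum(np.abs(np.diff(series.s_um))))


def test_compute_metrics_without_axis_uses_2d_distance():
    traj = make_traj([0, 1, 2, 1], [0, 0, 0, 0])
    m = ev.compute_metrics(traj, axis=None, interval_s=None)
    assert m.max_dist_contact_um == pytest.approx(2.0)
    assert np.isnan(m.run_length_pos_um)
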