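"""Peak detection, phase interpolation, entropy sync index, regimes, waves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cawave.graph import build_dense_grid
from cawave.phase import (PeakOptions, PhaseSeries, classify_regime,
                          detect_peaks, network_sync, oscillation_period,
                          phase_difference, phase_interpolate, sync_index,
                          wave_speed)
from cawave.simulate import Trajectory


def test_detect_peaks_on_sinusoid():
    t = np.arange(0.0, 200.0, 0.5)
    T = 25.0
    pk = detect_peaks(t, 100 * np.sin(2 * np.pi * t / T), PeakOptions(min_prom=1))
    expected = T / 4 + T * np.arange(len(pk))
    assert np.all(np.abs(pk - expected) <= 0.5)


def test_detect_peaks_constant_and_ripple():
    t = np.arange(0.0, 100.0, 0.5)
    assert len(detect_peaks(t, np.full_like(t, 7.0))) == 0
    # dominant 25 s rhythm with a 10% fast ripple: only dominant peaks count
    x = 100 * np.sin(2 * np.pi * t / 25.0) + 10 * np.sin(2 * np.pi * t / 7.0)
    pk = detect_peaks(t, x, PeakOptions(prom_frac=0.2, min_prom=1))
    # oracle: brute-force local maxima of the pure dominant component
    assert len(pk) == len(detect_peaks(t, 100 * np.sin(2 * np.pi * t / 25.0),
                                       PeakOptions(min_prom=1)))


def test_phase_interpolation_closed_form():
    peaks = np.array([10.0, 30.0, 50.0, 70.0])
    assert phase_interpolate(peaks, 10.0) == 0.0
    assert phase_interpolate(peaks, 20.0) == pytest.approx(np.pi)
    # equally spaced peaks: Phi(t) = 2*pi*(t - tau1)/T
    t = np.linspace(10.0, 70.0, 101)
    assert np.allclose(phase_interpolate(peaks, t),
                       2 * np.pi * (t - 10.0) / 20.0)
    with pytest.raises(ValueError):
        phase_interpolate(peaks, 9.9)
    with pytest.raises(ValueError):
        phase_interpolate(np.array([5.0]), 5.0)


def test_phase_series_is_continuous_and_increasing():
    ps = PhaseSeries(np.array([5.0, 17.0, 23.0, 41.0]))
    t = np.linspace(5.0, 41.0, 500)
    phi = ps(t)
    assert np.all(np.diff(phi) > 0)
    assert phi[0] == 0.0 and phi[-1] == pytest.approx(6 * np.pi)


@pytest.mark.parametrize("du, dv, expected", [
    (1.0, 1.0, 0.0),
    (np.pi + 1.0, 1.0, np.pi),
    (1.0, 1.0 + np.pi / 2, 3 * np.pi / 2),   # wraps into [0, 2*pi)
])
def test_phase_difference_wraps(du, dv, expected):
    out = phase_difference(np.array([du]), np.array([dv]))
    assert out[0] == pytest.approx(expected)
    assert 0.0 <= out[0] < 2 * np.pi


def test_sync_index_reference_values():
    assert sync_index(np.full(100, 1.234), 10) == pytest.approx(1.0)
    # exactly uniform occupancy -> zero
    edges = np.linspace(0, 2 * np.pi, 11)
    centers = (edges[:-1] + edges[1:]) / 2
    assert sync_index(np.repeat(centers, 10), 10) == pytest.approx(0.0, abs=1e-12)
    # half the mass in each of two bins of four: Q = 1 - ln2/ln4
    samples = np.concatenate([np.full(50, 0.5), np.full(50, np.pi)])
    assert sync_index(samples, 4) == pytest.approx(1 - np.log(2) / np.log(4))
    with pytest.raises(ValueError):
        sync_index(np.array([]))


@given(st.lists(st.floats(0.0, 2 * np.pi - 1e-9), min_size=10, max_size=300))
@settings(max_examples=100, deadline=None)
def test_sync_index_matches_entropy_oracle(samples):
    samples = np.asarray(samples)
    q = sync_index(samples, 10)
    counts = np.histogram(samples, bins=10, range=(0, 2 * np.pi))[0]
    p = counts[counts > 0] / len(samples)
    expected = (np.log(10) + (p * np.log(p)).sum()) / np.log(10)
    assert q == pytest.approx(expected, rel=1e-12, abs=1e-12)
    assert 0.0 <= q <= 1.0


def test_sync_index_invariant_to_global_shift(rng):
    base = rng.uniform(0, 2 * np.pi, 400)
    phi_u = np.cumsum(rng.uniform(0.01, 0.1, 400))
    q1 = sync_index(phase_difference(phi_u, phi_u - base))
    q2 = sync_index(phase_difference(phi_u + 1.7, phi_u - base + 1.7))
    assert q1 == pytest.approx(q2)


def _toy_trajectory(traces, dt=0.5):
    times = np.arange(traces.shape[1]) * dt
    n = traces.shape[0]
    nodes = tuple((1, j + 1) for j in range(n))
    return Trajectory(times, traces, np.full_like(traces, 2e5), nodes)


def test_network_sync_identical_and_independent(rng):
    t = np.arange(0.0, 400.0, 0.5)
    base = 110 + 100 * np.clip(np.sin(2 * np.pi * t / 30.0), 0, None) ** 3
    g = build_dense_grid(1, 3)
    same = _toy_trajectory(np.vstack([base, base, base]))
    rep = network_sync(same, g)
    assert rep.m_sync == pytest.approx(1.0)
    # independent random peak trains over a long horizon -> near-zero index
    t_long = np.arange(0.0, 3000.0, 0.5)

    def train(seed):
        r = np.random.default_rng(seed)
        periods = r.uniform(18.0, 42.0, 200)
        pk = 5.0 + np.cumsum(periods)
        x = np.zeros_like(t_long)
        for p in pk[pk < t_long[-1] - 5]:
            x += 100 * np.exp(-((t_long - p) ** 2) / 4.0)
        return 110 + x
    indep = _toy_trajectory(np.vstack([train(1), train(2), train(3)]))
    rep2 = network_sync(indep, g)
    assert rep2.m_sync < 0.1


def test_oscillation_period():
    t = np.arange(0.0, 500.0, 0.5)
    T = 34.0
    x = 110 + 120 * np.clip(np.sin(2 * np.pi * t / T), 0, None) ** 5
    assert oscillation_period(t, x) == pytest.approx(T, abs=0.1)
    assert oscillation_period(t, np.full_like(t, 300.0)) is None
    assert oscillation_period(t, x, transient_cut=450.0) is None  # <3 peaks left


def test_oscillation_period_self_consistent(single_cell_default):
    tr = single_cell_default
    p600 = oscillation_period(tr.times, tr.X[0], transient_cut=100.0)
    assert p600 is not None and 20.0 < p600 < 60.0


@pytest.mark.parametrize("kind, zone", [
    ("sustained", "I"), ("damped", "II"), ("logistic", "III"),
])
def test_classify_regime_on_constructed_traces(kind, zone):
    t = np.arange(0.0, 600.0, 0.5)
    base = np.full_like(t, 110.0)
    s = np.clip(np.sin(2 * np.pi * (t - 60) / 30.0), 0, None) ** 3
    if kind == "sustained":
        x = base + 150 * np.where(t >= 60, s, 0.0)
    elif kind == "damped":
        x = base + 150 * np.where(t >= 60, s * np.exp(-(t - 60) / 60.0), 0.0)
    else:
        x = base + 250.0 / (1.0 + np.exp(-(t - 80) / 5.0))
    assert classify_regime(t, x, t1=60.0).zone == zone


def test_wave_speed_on_synthetic_plane_wave():
    """A front advancing one cell per dt crosses at speed 1/dt."""
    n = m = 15
    g = build_dense_grid(n, m)
    nodes = sorted(g.nodes)
    times = np.arange(0.0, 400.0, 0.5)
    step = 2.0  # s per cell of radial distance
    X = np.zeros((len(nodes), len(times)))
    center = ((n + 1) // 2, (m + 1) // 2)
    for k, (i, j) in enumerate(nodes):
        r = max(abs(i - center[0]), abs(j - center[1]))
        for wave_start in (120.0, 220.0, 320.0):
            arr = wave_start + r * step
            X[k] += 200 * np.exp(-((times - arr) ** 2) / 4.0)
    X += 110.0
    traj = Trajectory(times, X, np.full_like(X, 2e5), tuple(nodes))
    speed, ci, n_waves = wave_speed(traj, g, t_min=100.0)
    assert speed == pytest.approx(1.0 / step, rel=0.08)
    assert n_waves >= 2


def test_wave_speed_ci_shrinks_with_more_waves():
    n = m = 9
    g = build_dense_grid(n, m)
    nodes = sorted(g.nodes)
    center = ((n + 1) // 2, (m + 1) // 2)
    rng = np.random.default_rng(0)

    def build(n_waves):
        times = np.arange(0.0, 100.0 + 60.0 * n_waves, 0.5)
        X = np.full((len(nodes), len(times)), 110.0)
        starts = 80.0 + 60.0 * np.arange(n_waves)
        jitter = rng.normal(0, 0.3, (len(nodes), n_waves))
        for k, (i, j) in enumerate(nodes):
            r = max(abs(i - center[0]), abs(j - center[1]))
            for w, s in enumerate(starts):
                arr = s + r * 2.0 + (jitter[k, w] if r else 0.0)
                X[k] += 200 * np.exp(-((times - arr) ** 2) / 4.0)
        return Trajectory(times, X, np.full_like(X, 2e5), tuple(nodes))

    _, ci4, k4 = wave_speed(build(4), g, t_min=60.0)
    _, ci16, k16 = wave_speed(build(16), g, t_min=60.0)
    assert k16 > k4
    assert ci16 < ci4  # CI narrows roughly like 1/sqrt(waves)


def test_wave_speed_requires_waves(grid_5x5):
    times = np.arange(0.0, 100.0, 0.5)
    flat = np.full((25, len(times)), 110.0)
    traj = Trajectory(times, flat, np.full_like(flat, 2e5),
                      tuple(sorted(grid_5x5.nodes)))
    with pytest.raises(ValueError):
        wave_speed(traj, grid_5x5)
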