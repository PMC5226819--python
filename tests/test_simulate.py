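"""Coupled network integration: conservation, reduction, reproducibility."""

import numpy as np
import pytest

from cawave import (CellParams, SimulationConfig, StimulusParams,
                    build_dense_grid, cell_rhs, field_homogeneous,
                    network_rhs, network_sync, simulate)
from cawave.presets import (NON_OSC_STIM, ZONE_I_STIM, ZONE_III_STIM,
                            list_presets, preset_config, run_experiment)
from cawave.sensitivity import NoiseLevels, Region, field_deterministic, field_random
from cawave.simulate import NetworkRHS
from cawave.phase import PeakOptions, detect_peaks


def _random_state(rng, n):
    return np.concatenate([rng.uniform(50, 500, n), rng.uniform(1e4, 3e5, n)])


def test_coupling_vanishes_for_identical_cells(grid_5x5, rng):
    f = field_homogeneous(grid_5x5)
    cfg_d = SimulationConfig(grid_5x5.with_coupling(0.01), f)
    cfg_0 = SimulationConfig(grid_5x5.with_coupling(0.0), f)
    x = np.full(25, 234.5)
    y = rng.uniform(1e5, 2e5, 1) * np.ones(25)
    state = np.concatenate([x, y])
    assert np.allclose(network_rhs(state, 100.0, cfg_d),
                       network_rhs(state, 100.0, cfg_0))


def test_gap_junction_conservation_machine_precision(grid_5x5, rng):
    """Coupling only redistributes Ca2+: its contributions sum to zero."""
    f = field_homogeneous(grid_5x5)
    rhs_d = NetworkRHS(SimulationConfig(grid_5x5.with_coupling(0.3), f))
    rhs_0 = NetworkRHS(SimulationConfig(grid_5x5.with_coupling(0.0), f))
    for _ in range(200):
        s = _random_state(rng, 25)
        coupling = rhs_d(80.0, s)[:25] - rhs_0(80.0, s)[:25]
        assert abs(coupling.sum()) < 1e-9 * np.abs(coupling).sum() + 1e-12


def test_single_node_reduces_to_cell_rhs():
    g = build_dense_grid(1, 1, d=0.5)
    stim = StimulusParams(60.0, 1.8, 0.9)
    cfg = SimulationConfig(g, field_homogeneous(g, stim))
    for t, x, y in [(10.0, 110.0, 260e3), (100.0, 300.0, 8e4)]:
        got = network_rhs(np.array([x, y]), t, cfg)
        dx, dy = cell_rhs(x, y, t, stim)
        assert got[0] == pytest.approx(float(dx), rel=1e-12)
        assert got[1] == pytest.approx(float(dy), rel=1e-12)


def test_network_rhs_validates_state(grid_5x5):
    cfg = SimulationConfig(grid_5x5, field_homogeneous(grid_5x5))
    with pytest.raises(ValueError):
        network_rhs(np.ones(7), 0.0, cfg)
    with pytest.raises(ValueError):
        network_rhs(np.full(50, np.nan), 0.0, cfg)


def test_initial_conditions_and_positivity(single_cell_default):
    tr = single_cell_default
    assert tr.X[0, 0] == 110.0
    assert tr.Y[0, 0] == 260_000.0
    assert np.all(tr.X > 0) and np.all(tr.Y > 0)
    assert np.all(np.isfinite(tr.X)) and np.all(np.isfinite(tr.Y))
    assert tr.times[0] == 0.0 and tr.times[-1] == 600.0
    assert np.allclose(np.diff(tr.times), 0.5)


def test_decoupled_cells_match_isolated_runs():
    g2 = build_dense_grid(1, 2, d=0.0)
    f = field_deterministic(g2, StimulusParams(50.0, 1.8, 0.9),
                            [Region(1, 2, 1, 1, StimulusParams(80.0, 1.4, 0.7))])
    tr = simulate(SimulationConfig(g2, f, t_end=200.0))
    for k, stim in [(0, StimulusParams(50.0, 1.8, 0.9)),
                    (1, StimulusParams(80.0, 1.4, 0.7))]:
        g1 = build_dense_grid(1, 1)
        solo = simulate(SimulationConfig(g1, field_homogeneous(g1, stim),
                                         t_end=200.0))
        # identical dynamics up to adaptive step-size history differences
        assert np.allclose(tr.X[k], solo.X[0], rtol=1e-3, atol=1.0)


def test_simulation_reproducible(grid_5x5):
    f = field_random(grid_5x5, StimulusParams(), NoiseLevels.named("low"), seed=2)
    cfg = SimulationConfig(grid_5x5.with_coupling(0.003), f, t_end=150.0)
    a = simulate(cfg)
    b = simulate(cfg)
    assert np.array_equal(a.X, b.X) and np.array_equal(a.Y, b.Y)


def test_single_cell_regimes():
    g = build_dense_grid(1, 1)
    osc = simulate(SimulationConfig(g, field_homogeneous(g, ZONE_I_STIM),
                                    t_end=600.0))
    pk = detect_peaks(osc.times, osc.X[0], PeakOptions(t_min=60.0))
    assert len(pk) >= 5  # sustained spiking
    sat = simulate(SimulationConfig(g, field_homogeneous(g, ZONE_III_STIM),
                                    t_end=600.0))
    pk3 = detect_peaks(sat.times, sat.X[0], PeakOptions(t_min=60.0))
    assert len(pk3) <= 1  # saturates after the onset transient
    assert sat.X[0, -1] > 140.0  # elevated plateau


def test_er_shows_sawtooth_loading(single_cell_default):
    """ER loads slowly between spikes and releases rapidly at each spike."""
    tr = single_cell_default
    sel = tr.times > 150.0
    dy = np.diff(tr.Y[0][sel])
    assert dy.max() > 0 and dy.min() < 0
    # sawtooth: long slow-loading stretches, brief steep releases
    assert (dy > 0).sum() > 3 * (dy < 0).sum()
    assert abs(dy.min()) > 2 * dy.max()


def test_presets_build_and_override():
    assert "fig3" in list_presets()
    cfg = preset_config("fig3", seed=0)
    assert cfg.coupling == pytest.approx(0.003)
    cfg6 = preset_config("fig6c", seed=1)
    assert cfg6.coupling == pytest.approx(0.009)
    assert cfg6.field.variant == "random"
    over = preset_config("fig3", seed=0, d=0.0)
    assert over.coupling == 0.0
    with pytest.raises(ValueError):
        preset_config("nope")
    with pytest.raises(ValueError):
        preset_config("fig3", seed=0, bogus=1)


def test_run_experiment_echoes_metadata():
    tr = run_experiment("single-zone1", seed=0, t_end=120.0)
    assert tr.config["preset"] == "single-zone1"
    assert tr.config["overrides"] == {"t_end": 120.0}
    assert tr.config["t_end"] == 120.0


def test_msync_stable_under_tighter_tolerances(grid_25x25):
    """Halving the integrator tolerances moves m_sync by well under 0.02."""
    f = field_random(grid_25x25, StimulusParams(60.0, 1.8, 0.9),
                     NoiseLevels.named("high"), seed=11)
    vals = []
    for rtol, atol in [(1e-6, 1e-9), (5e-7, 5e-10)]:
        cfg = SimulationConfig(grid_25x25.with_coupling(0.0015), f,
                               t_end=600.0, rtol=rtol, atol=atol)
        vals.append(network_sync(simulate(cfg), grid_25x25).m_sync)
    assert abs(vals[0] - vals[1]) < 0.02
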