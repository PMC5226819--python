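"""Named experiment presets.

Each preset reconstructs one published network configuration (grid, coupling
strength, sensitivity field and noise level) on the 25 x 25 dense lattice,
from a single master seed.  The master seed is split into independent child
streams (graph field, link removal, sensitivity draw), so changing one
stage's randomness never perturbs the others.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .cell import StimulusParams
from .graph import (build_dense_grid, link_removal_probabilities, punch_holes,
                    sample_gaussian_field, sparsify)
from .sensitivity import (NoiseLevels, Region, central_block,
                          field_deterministic, field_homogeneous, field_random,
                          field_random_with_center)
from .simulate import SimulationConfig, Trajectory, simulate

__all__ = ["PRESETS", "list_presets", "preset_config", "run_experiment",
           "ZONE_I_STIM", "ZONE_II_STIM", "ZONE_III_STIM", "NON_OSC_STIM"]

#: single-cell exemplars of the three response regimes
ZONE_I_STIM = StimulusParams(60.0, 1.8, 0.9)      # sustained oscillation
ZONE_II_STIM = StimulusParams(60.0, 1.8, 0.05)    # few damped transients
ZONE_III_STIM = StimulusParams(60.0, 1.8, 12.0)   # saturated plateau, no repeats
#: InsP3-responsive but influx-starved: silent alone, entrainable by neighbors
NON_OSC_STIM = StimulusParams(60.0, 1.8, 0.02)


def _seeds(seed, k: int):
    return np.random.SeedSequence(seed).spawn(k)


def _single(seed, stim: StimulusParams, t_end: float = 600.0) -> SimulationConfig:
    g = build_dense_grid(1, 1)
    return SimulationConfig(g, field_homogeneous(g, stim), t_end=t_end, seed=seed)


def _fig3(seed, d: float = 0.003, center_stim=StimulusParams(72.0, 2.16, 1.08),
          t_end: float = 600.0) -> SimulationConfig:
    """Wave initiation: a more sensitive 3 x 3 central region on a default
    background (this reference configuration gives the center a later onset,
    t1 = 72 s, even though that breaks the usual onset/plateau rank pairing)."""
    g = build_dense_grid(25, 25, d=d)
    i0, j0 = central_block(25, 25, 3, 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # reference values violate rank pairing
        f = field_deterministic(g, StimulusParams(),
                                [Region(i0, j0, 3, 3, center_stim)])
    return SimulationConfig(g, f, t_end=t_end, seed=seed)


def _fig5(seed, d: float = 0.0045, t_end: float = 600.0) -> SimulationConfig:
    """Entrainment: sensitive center + a non-self-oscillating block (zone
    III parameters) embedded in an oscillating default background."""
    g = build_dense_grid(25, 25, d=d)
    i0, j0 = central_block(25, 25, 3, 3)
    regions = [Region(i0, j0, 3, 3, StimulusParams(50.0, 2.16, 1.08)),
               Region(4, 4, 3, 3, NON_OSC_STIM)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f = field_deterministic(g, StimulusParams(), regions)
    return SimulationConfig(g, f, t_end=t_end, seed=seed)


def _fig6(seed, d: float, t_end: float = 3000.0) -> SimulationConfig:
    """Random model, high noise, low mean influx (mu_iJINF,max = 0.108).

    At this weak mean influx the cells oscillate slowly (periods of roughly
    100-600 s), so the horizon is 3000 s: the phase-difference statistics
    need on the order of ten cycles per cell to be meaningful, just as a
    600 s window suffices at the default influx where the period is ~35 s.
    """
    g = build_dense_grid(25, 25, d=d)
    (s_field,) = _seeds(seed, 1)
    f = field_random(g, StimulusParams(60.0, 1.8, 0.108),
                     NoiseLevels.named("high"), seed=s_field)
    return SimulationConfig(g, f, t_end=t_end, seed=seed)


def _fig7(seed, p: float, holes_q: float = 0.0, d: float = 0.0045,
          t_end: float = 600.0) -> SimulationConfig:
    """Random model on a sparsified lattice (moderate noise and coupling)."""
    s_field, s_rm, s_sens = _seeds(seed, 3)
    g0 = build_dense_grid(25, 25, d=d)
    fld = sample_gaussian_field(25, 25, seed=s_field)
    g = sparsify(g0, link_removal_probabilities(fld, p), seed=s_rm)
    if holes_q > 0:
        g = punch_holes(g, fld, holes_q)
    f = field_random(g, StimulusParams(), NoiseLevels.named("moderate"),
                     seed=s_sens)
    return SimulationConfig(g, f, t_end=t_end, seed=seed)


def _fig8a(seed, d: float = 0.003, t_end: float = 600.0) -> SimulationConfig:
    """Three sensitive regions on a noise-free lattice (transient spirals)."""
    g = build_dense_grid(25, 25, d=d)
    stim = StimulusParams(50.0, 2.16, 1.08)
    regions = [Region(4, 4, 3, 3, stim), Region(16, 7, 3, 3, stim),
               Region(9, 18, 3, 3, stim)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f = field_deterministic(g, StimulusParams(), regions)
    return SimulationConfig(g, f, t_end=t_end, seed=seed)


def _fig9(seed, variant: str, d: float = 0.0045,
          t_end: float = 600.0) -> SimulationConfig:
    """Low-noise random models: spirals (a), a central pacemaker zone giving
    concentric circles (b), and an overstimulated center losing them (c)."""
    g = build_dense_grid(25, 25, d=d)
    (s_sens,) = _seeds(seed, 1)
    low = NoiseLevels.named("low")
    zone_sds = NoiseLevels(0.01, 0.001, 0.0)
    if variant == "a":
        f = field_random(g, StimulusParams(60.0, 1.8, 0.6), low, seed=s_sens)
    elif variant == "b":
        f = field_random_with_center(g, StimulusParams(60.0, 1.8, 0.6), low,
                                     StimulusParams(60.0, 2.6, 0.7), zone_sds,
                                     (3, 3), seed=s_sens)
    elif variant == "c":
        f = field_random_with_center(g, StimulusParams(60.0, 4.0, 0.6), low,
                                     StimulusParams(60.0, 5.5, 0.7), zone_sds,
                                     (3, 3), seed=s_sens)
    else:  # pragma: no cover
        raise ValueError(variant)
    return SimulationConfig(g, f, t_end=t_end, seed=seed)


PRESETS = {
    "single-zone1": lambda seed: _single(seed, ZONE_I_STIM),
    "single-zone2": lambda seed: _single(seed, ZONE_II_STIM),
    "single-zone3": lambda seed: _single(seed, ZONE_III_STIM),
    "fig3": lambda seed: _fig3(seed),
    "fig5": lambda seed: _fig5(seed),
    "fig6a": lambda seed: _fig6(seed, d=0.0),
    "fig6b": lambda seed: _fig6(seed, d=0.0015),
    "fig6c": lambda seed: _fig6(seed, d=0.009),
    "fig7a": lambda seed: _fig7(seed, p=0.5),
    "fig7b": lambda seed: _fig7(seed, p=1.0),
    "fig7c": lambda seed: _fig7(seed, p=1.0, holes_q=0.10),
    "fig8a": lambda seed: _fig8a(seed),
    "fig8b": lambda seed: _fig5(seed),
    "fig9a": lambda seed: _fig9(seed, "a"),
    "fig9b": lambda seed: _fig9(seed, "b"),
    "fig9c": lambda seed: _fig9(seed, "c"),
}

_CONFIG_OVERRIDES = {"d", "t_end", "output_dt", "rtol", "atol", "method"}


def list_presets() -> list[str]:
    return sorted(PRESETS)


def preset_config(name: str, seed=0, **overrides) -> SimulationConfig:
    """Build a preset's SimulationConfig; keyword overrides (d, t_end,
    output_dt, rtol, atol, method) are applied on top and echoed in the
    config metadata."""
    try:
        builder = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; known: {list_presets()}") from None
    cfg = builder(seed)
    bad = set(overrides) - _CONFIG_OVERRIDES
    if bad:
        raise ValueError(f"unsupported overrides: {sorted(bad)}")
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def regime_map(i_jinf_values, i_ip3_values, t1: float = 60.0,
               t_end: float = 1000.0, params=None):
    """Single-cell response regimes over a stimulus grid.

    Returns an (n_jinf, n_ip3) array of zone labels ("I"/"II"/"III"), each
    from an isolated-cell simulation with onset at ``t1``.
    """
    from .cell import CellParams
    from .phase import classify_regime
    from .sensitivity import field_homogeneous

    params = params or CellParams()
    g1 = build_dense_grid(1, 1)
    zones = np.empty((len(i_jinf_values), len(i_ip3_values)), dtype=object)
    for a, jinf in enumerate(i_jinf_values):
        for b, ip3 in enumerate(i_ip3_values):
            f = field_homogeneous(g1, StimulusParams(t1, float(ip3), float(jinf)))
            tr = simulate(SimulationConfig(g1, f, params=params, t_end=t_end))
            zones[a, b] = classify_regime(tr.times, tr.X[0], t1=t1).zone
    return zones


def run_experiment(name: str, seed=0, **overrides) -> Trajectory:
    """Simulate a named preset; the returned trajectory echoes the full
    configuration (preset name, overrides, seed) in its metadata."""
    cfg = preset_config(name, seed=seed, **overrides)
    traj = simulate(cfg)
    traj.config["preset"] = name
    traj.config["overrides"] = dict(overrides)
    return traj
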