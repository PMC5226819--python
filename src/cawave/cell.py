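"""Single-cell Ca2+ handling: fluxes, InsP3-dependent receptor parameters and stimuli.

The cell is a two-variable oscillator: free cytosolic Ca2+ ``x`` (nM) and free
ER-luminal Ca2+ ``y`` (nM).  Ca2+ leaves the cytosol through a lumped linear
extrusion flux (``j_eff``) and the SERCA pump (``j_serca``); it returns from
the ER through a constant leak (``j_erleak``) and the InsP3-receptor channel
(``j_ereff``), whose open flux is the clipped sum of a bell-shaped dependence
on log10(x) and an affine dependence on log10(y).  Raising [InsP3] shifts the
bell (mean, height) and lowers the ER set point, which is what makes the cell
an excitable/oscillatory unit.

Unit conventions used throughout the package: concentrations in nM
(``y0 = 260_000`` nM is the 260 uM ER resting level), time in s, [InsP3] in uM
(matching ``Kb = 1`` uM).  All logarithms in the receptor terms are base 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "CellParams",
    "StimulusParams",
    "j_eff",
    "j_serca",
    "j_erleak",
    "ip3r_params",
    "j_ereff",
    "stimulus_ip3",
    "stimulus_jinf",
    "cell_rhs",
]


@dataclass(frozen=True)
class CellParams:
    """Constants of the single-cell model (defaults: the reference parameter set).

    Rates are nM/s unless noted; ``gamma`` is the dimensionless ratio between
    the change in ER and cytosolic free Ca2+ produced by the same transported
    amount.  ``mu_min``/``mu_max`` and ``sigma_bell`` are log10-nM quantities
    describing the bell-shaped cytosolic dependence of the InsP3R flux; the
    ``_min`` value is attained at saturating [InsP3] and the ``_max``-weighted
    value at [InsP3] = 0 (note ``rim_min > rim_max``: the bell is *higher* at
    high InsP3).
    """

    gamma: float = 450.0
    re1: float = 0.17          # 1/s, slope of lumped extrusion
    re2: float = 18.8          # nM/s, extrusion offset
    rs1: float = 0.27          # 1/s, SERCA slope
    rs2: float = 26.5          # nM/s, SERCA offset
    sigma_bell: float = 0.3    # log10-nM width of the InsP3R bell curve
    ri1: float = 1300.0        # nM/s per log10-nM unit, ER-load sensitivity
    mu_min: float = 2.4        # log10-nM, bell mean at saturating InsP3
    mu_max: float = 2.18       # log10-nM, bell mean at zero InsP3
    rim_min: float = 821.3     # nM/s, bell height at saturating InsP3
    rim_max: float = 24.3      # nM/s, bell height at zero InsP3
    ri2_min: float = 6352.0    # nM/s, ER-term offset at saturating InsP3
    ri2_max: float = 7042.0    # nM/s, ER-term offset at zero InsP3
    Kb: float = 1.0            # uM, InsP3 half-saturation of receptor modulation
    beta: float = 2.5          # nM/s, constant ER leak
    K_ip3: float = 6.0         # s, stimulus rise constant for [InsP3]
    K_jinf: float = 6.0        # s, stimulus rise constant for influx
    x0: float = 110.0          # nM, initial cytosolic Ca2+
    y0: float = 260_000.0      # nM, initial ER Ca2+ (260 uM)
    ip3_baseline: float = 0.015  # uM, pre-onset [InsP3]
    jinf_baseline: float = 0.1   # nM/s, pre-onset influx

    def __post_init__(self) -> None:
        for name in ("gamma", "re1", "re2", "rs1", "rs2", "sigma_bell", "ri1",
                     "Kb", "beta", "K_ip3", "K_jinf", "x0", "y0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StimulusParams:
    """Per-cell agonist sensitivity: onset time and plateau stimulus levels."""

    t1: float = 60.0          # s, onset of the InsP3/influx rise
    i_ip3_max: float = 1.8    # uM, plateau [InsP3]
    i_jinf_max: float = 0.9   # nM/s, plateau Ca2+ influx

    def __post_init__(self) -> None:
        if self.t1 < 0:
            raise ValueError("t1 must be >= 0")
        if self.i_ip3_max <= 0 or self.i_jinf_max <= 0:
            raise ValueError("stimulus plateaus must be positive")


def _check_nonneg(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite and non-negative")
    return arr


def j_eff(x, params: CellParams = CellParams()):
    """Lumped cytosolic Ca2+ removal flux max(re1*x - re2, 0) in nM/s."""
    x = _check_nonneg(x, "x")
    return np.maximum(params.re1 * x - params.re2, 0.0)


def j_serca(x, params: CellParams = CellParams()):
    """SERCA pump flux cytosol -> ER, max(rs1*x - rs2, 0) in nM/s."""
    x = _check_nonneg(x, "x")
    return np.maximum(params.rs1 * x - params.rs2, 0.0)


def j_erleak(params: CellParams = CellParams()) -> float:
    """Constant ER -> cytosol leak (nM/s)."""
    return params.beta


def ip3r_params(ip3, params: CellParams = CellParams()):
    """InsP3-dependent receptor parameters (M, Ri_max, Ri2).

    Each interpolates between its ``_min`` endpoint (at saturating [InsP3])
    and its ``_max`` endpoint (at [InsP3] = 0) through the saturating factor
    Kb / (Kb + [InsP3]).
    """
    ip3 = _check_nonneg(ip3, "ip3")
    k = params.Kb / (params.Kb + ip3)
    M = params.mu_min + (params.mu_max - params.mu_min) * k
    ri_max = params.rim_min + (params.rim_max - params.rim_min) * k
    ri2 = params.ri2_min + (params.ri2_max - params.ri2_min) * k
    return M, ri_max, ri2


def j_ereff(x, y, ip3, params: CellParams = CellParams()):
    """InsP3R channel flux ER -> cytosol (nM/s), clipped at zero.

    Sum of a bell curve in log10(x) (height Ri_max, mean M, width sigma) and
    the ER-load term ri1*log10(y) - Ri2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("x and y must be positive (logarithms are taken)")
    M, ri_max, ri2 = ip3r_params(ip3, params)
    j_cyt = ri_max * np.exp(-((np.log10(x) - M) ** 2) / params.sigma_bell**2)
    j_er = params.ri1 * np.log10(y) - ri2
    return np.maximum(j_cyt + j_er, 0.0)


def stimulus_ip3(t, stim: StimulusParams, params: CellParams = CellParams()):
    """[InsP3](t) in uM: baseline before onset, Michaelis-type rise after.

    The printed time course evaluates to 0 exactly at t = t1 (below the
    baseline) before rising towards ``i_ip3_max``; the jump is reproduced
    as stated and the integrator restarts there.
    """
    t = np.asarray(t, dtype=float)
    dt = t - stim.t1
    rise = stim.i_ip3_max * np.where(dt >= 0, dt, 0.0) / (params.K_ip3 + np.abs(dt))
    return np.where(dt < 0, params.ip3_baseline, rise)


def stimulus_jinf(t, stim: StimulusParams, params: CellParams = CellParams()):
    """Plasma-membrane Ca2+ influx J_INF(t) in nM/s (baseline, then rise)."""
    t = np.asarray(t, dtype=float)
    dt = t - stim.t1
    rise = stim.i_jinf_max * np.where(dt >= 0, dt, 0.0) / (params.K_jinf + np.abs(dt))
    return np.where(dt < 0, params.jinf_baseline, rise)


def cell_rhs(x, y, t, stim: StimulusParams, params: CellParams = CellParams()):
    """Right-hand side of the uncoupled cell: (dx/dt, dy/dt) in nM/s.

    dx/dt = J_INF(t) - J_EFF(x) - J_SERCA(x) + J_EREFF(x, y, t) + beta
    dy/dt = gamma * (J_SERCA(x) - J_EREFF(x, y, t) - beta)

    The ER-exchange terms appear in both equations with opposite sign (scaled
    by gamma), so no Ca2+ is created at the ER membrane.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("state must be finite")
    ip3 = stimulus_ip3(t, stim, params)
    jinf = stimulus_jinf(t, stim, params)
    serca = j_serca(x, params)
    ereff = j_ereff(x, y, ip3, params)
    f = -j_eff(x, params) - serca + ereff + params.beta
    g = params.gamma * (serca - ereff - params.beta)
    return jinf + f, g
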