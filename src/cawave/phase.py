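"""Phase-synchronization and wave analytics for cytosolic Ca2+ traces.

Synchronization between two neighboring cells is quantified from the *timing*
of their Ca2+ spikes, never the amplitudes.  Each trace is reduced to its peak
times tau_1 < tau_2 < ...; between consecutive peaks the phase grows linearly
by 2*pi:

    Phi(t) = 2*pi * ((t - tau_n) / (tau_{n+1} - tau_n) + n - 1)

The pairwise phase difference (Phi_u - Phi_v) mod 2*pi is histogrammed, and
the entropy-based index

    Q_{u,v} = (S_max - S) / S_max,   S_max = log(n_bins)

is 0 for a uniform difference distribution (independent oscillators) and 1
when every sample lands in one bin (phase locking).  The network measure
m_sync averages Q over all edges.

The module also classifies the single-cell response regime (sustained
oscillation / damped transient / saturation) and estimates the radial speed
of waves launched from a central initiating region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .graph import CellGraph
from .simulate import Trajectory

__all__ = [
    "PeakOptions",
    "PhaseSeries",
    "SyncReport",
    "RegimeLabel",
    "detect_peaks",
    "phase_interpolate",
    "phase_difference",
    "sync_index",
    "network_sync",
    "oscillation_period",
    "classify_regime",
    "wave_speed",
]


@dataclass(frozen=True)
class PeakOptions:
    """Peak-detection knobs.

    ``prom_frac``: prominence threshold as a fraction of the series range
    (max - min) within the detection window, which keeps the detector focused
    on full-size Ca2+ spikes and ignores sub-threshold bumps that diffusive
    coupling bleeds in from spiking neighbors.  ``min_prom``: absolute
    prominence floor in nM, suppressing integrator ripple on flat plateaus.
    ``min_sep``: minimum peak separation in seconds.  ``t_min``: start of the
    detection window.
    """

    prom_frac: float = 0.2
    min_sep: float = 5.0
    t_min: float = 0.0
    min_prom: float = 2.0
    refine: bool = True


def _series_range(x: np.ndarray) -> float:
    return float(x.max() - x.min())


def detect_peaks(times: np.ndarray, series: np.ndarray,
                 options: PeakOptions = PeakOptions()) -> np.ndarray:
    """Times of the qualifying local maxima of a uniformly sampled series.

    Peaks must rise at least ``prom_frac`` of the windowed series range
    (but no less than ``min_prom`` nM) above their surroundings and be
    ``min_sep`` apart; each peak time is refined by a parabolic fit through
    the three samples around the maximum.
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    if len(times) != len(series) or len(times) < 3:
        raise ValueError("need a sampled series of length >= 3")
    sel = times >= options.t_min
    t = times[sel]
    x = series[sel]
    if len(t) < 3:
        return np.empty(0)
    rng = _series_range(x)
    if rng <= 0:
        return np.empty(0)
    dt = float(np.median(np.diff(t)))
    idx, _ = find_peaks(x, prominence=max(options.prom_frac * rng,
                                          options.min_prom),
                        distance=max(1, int(round(options.min_sep / dt))))
    if not options.refine or len(idx) == 0:
        return t[idx]
    out = []
    for k in idx:
        if 0 < k < len(t) - 1:
            y0, y1, y2 = x[k - 1], x[k], x[k + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            out.append(t[k] + shift * dt)
        else:
            out.append(t[k])
    return np.asarray(out)


@dataclass(frozen=True)
class PhaseSeries:
    """Piecewise-linear phase of one trace, defined on [tau_1, tau_last]."""

    peak_times: np.ndarray

    def __post_init__(self) -> None:
        pt = np.asarray(self.peak_times, dtype=float)
        if len(pt) < 2 or np.any(np.diff(pt) <= 0):
            raise ValueError("need >= 2 strictly increasing peak times")

    @property
    def t_start(self) -> float:
        return float(self.peak_times[0])

    @property
    def t_end(self) -> float:
        return float(self.peak_times[-1])

    def __call__(self, t) -> np.ndarray:
        return phase_interpolate(self.peak_times, t)


def phase_interpolate(peak_times: np.ndarray, query_times) -> np.ndarray:
    """Phase at the query times: 2*pi*(n-1) at peak n, linear in between.

    Queries outside [tau_1, tau_last] raise: the phase is not extrapolated.
    """
    pt = np.asarray(peak_times, dtype=float)
    if len(pt) < 2:
        raise ValueError("need at least two peaks to define a phase")
    t = np.asarray(query_times, dtype=float)
    if np.any(t < pt[0]) or np.any(t > pt[-1]):
        raise ValueError("query time outside the phase definition interval")
    return 2.0 * np.pi * np.interp(t, pt, np.arange(len(pt), dtype=float))


def phase_difference(phase_u: np.ndarray, phase_v: np.ndarray) -> np.ndarray:
    """(Phi_u - Phi_v) mod 2*pi, element-wise, in [0, 2*pi)."""
    phase_u = np.asarray(phase_u, dtype=float)
    phase_v = np.asarray(phase_v, dtype=float)
    if phase_u.shape != phase_v.shape:
        raise ValueError("phase arrays must share a common time grid")
    return np.mod(phase_u - phase_v, 2.0 * np.pi)


def sync_index(delta_samples: np.ndarray, n_bins: int = 10) -> float:
    """Entropy-based synchronization index Q of phase-difference samples.

    Q = (log n_bins - S) / log n_bins with S the Shannon entropy of the
    histogram of the samples on n_bins equal bins over [0, 2*pi).
    """
    d = np.asarray(delta_samples, dtype=float)
    if d.size == 0:
        raise ValueError("no phase-difference samples")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if d.size < n_bins:
        warnings.warn(f"only {d.size} samples for {n_bins} bins; "
                      "Q will be biased upward", stacklevel=2)
    counts, _ = np.histogram(np.mod(d, 2.0 * np.pi),
                             bins=n_bins, range=(0.0, 2.0 * np.pi))
    p = counts[counts > 0] / d.size
    s = float(-(p * np.log(p)).sum())
    s_max = float(np.log(n_bins))
    return (s_max - s) / s_max


@dataclass(frozen=True)
class SyncReport:
    """Per-edge synchronization indices and the network mean m_sync."""

    m_sync: float
    edge_q: dict
    n_bins: int
    n_edges_used: int
    n_edges_skipped: int
    meta: dict = field(default_factory=dict, compare=False)


def network_sync(traj: Trajectory, graph: CellGraph, n_bins: int = 10,
                 peak_options: PeakOptions | None = None,
                 t_min: float | None = None) -> SyncReport:
    """m_sync of a trajectory: mean entropy index Q over usable edges.

    An edge is usable when both cells have >= 2 detected peaks; its Q is
    computed from phase differences sampled on the trajectory's own output
    grid restricted to the overlap of the two phase-definition intervals.
    Edges without such an overlap are skipped and counted.
    """
    if peak_options is None:
        peak_options = PeakOptions(t_min=0.0 if t_min is None else t_min)
    node_idx = {v: k for k, v in enumerate(traj.nodes)}
    phases: dict[int, PhaseSeries | None] = {}

    def get_phase(k: int) -> PhaseSeries | None:
        if k not in phases:
            pt = detect_peaks(traj.times, traj.X[k], peak_options)
            phases[k] = PhaseSeries(pt) if len(pt) >= 2 else None
        return phases[k]

    edge_q: dict = {}
    skipped = 0
    for u, v in sorted(graph.edges):
        pu, pv = get_phase(node_idx[u]), get_phase(node_idx[v])
        if pu is None or pv is None:
            skipped += 1
            continue
        a = max(pu.t_start, pv.t_start)
        b = min(pu.t_end, pv.t_end)
        sel = (traj.times >= a) & (traj.times <= b)
        if not sel.any():
            skipped += 1
            continue
        t = traj.times[sel]
        dphi = phase_difference(pu(t), pv(t))
        edge_q[(u, v)] = sync_index(dphi, n_bins)
    if not edge_q:
        raise ValueError("no usable edges: too few peaks for phase analysis")
    m = float(np.mean(list(edge_q.values())))
    return SyncReport(m, edge_q, n_bins, len(edge_q), skipped,
                      {"t_min": peak_options.t_min})


def oscillation_period(times: np.ndarray, series: np.ndarray,
                       transient_cut: float = 0.0,
                       options: PeakOptions | None = None) -> float | None:
    """Mean inter-peak interval after ``transient_cut``; None if < 3 peaks."""
    opts = options or PeakOptions()
    pt = detect_peaks(times, series, PeakOptions(opts.prom_frac, opts.min_sep,
                                                 max(opts.t_min, transient_cut),
                                                 opts.refine))
    if len(pt) < 3:
        return None
    return float(np.mean(np.diff(pt)))


@dataclass(frozen=True)
class RegimeLabel:
    """Single-cell response regime with diagnostics.

    ``zone``: "I" sustained oscillation, "II" damped transient, "III" rapid
    saturation without repeated spiking.
    """

    zone: str
    n_peaks: int
    n_late_peaks: int
    baseline: float
    final_level: float
    peak_amplitude: float


def classify_regime(times: np.ndarray, series: np.ndarray, t1: float = 60.0,
                    options: PeakOptions | None = None,
                    min_prominence: float = 5.0) -> RegimeLabel:
    """Classify one cell's post-onset response.

    Zone I: spiking persists into the final third of the run (>= 3 peaks, at
    least one late).  Zone II: transient spiking that dies out before the
    final third.  Zone III: at most one (onset) spike, the trace settling
    onto a plateau.  Peaks must clear ``min_prominence`` (nM) in absolute
    terms as well, so the ripple of an almost-flat plateau never counts.
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    pre = times < t1
    baseline = float(series[pre].mean()) if pre.any() else float(series[0])
    sel = times >= t1
    t, x = times[sel], series[sel]
    if len(t) < 3:
        raise ValueError("series has fewer than 3 samples after onset")
    opts = options or PeakOptions(t_min=t1)
    rng = _series_range(x)
    dt = float(np.median(np.diff(t)))
    prom = max(opts.prom_frac * rng, min_prominence)
    idx, _ = find_peaks(x, prominence=prom,
                        distance=max(1, int(round(opts.min_sep / dt))))
    pk_t = t[idx]
    t_late = times[0] + (times[-1] - times[0]) * 2.0 / 3.0
    late = int(np.sum(pk_t >= t_late))
    amp = float(x[idx].max() - baseline) if len(idx) else 0.0
    if len(idx) >= 3 and late >= 1:
        zone = "I"
    elif len(idx) >= 2:
        zone = "II"
    else:
        zone = "III"
    return RegimeLabel(zone, len(idx), late, baseline, float(x[-1]), amp)


def first_spiker(traj: Trajectory, t_from: float = 0.0,
                 options: PeakOptions | None = None):
    """Node with the earliest detected spike at or after ``t_from``.

    Identifies wave initiators: with heterogeneous onset times, pass the
    latest onset so the comparison is made once every cell is stimulated.
    """
    opts = options or PeakOptions(t_min=t_from)
    best_node, best_t = None, np.inf
    for k, v in enumerate(traj.nodes):
        pk = detect_peaks(traj.times, traj.X[k], opts)
        pk = pk[pk >= t_from]
        if pk.size and pk[0] < best_t:
            best_node, best_t = v, float(pk[0])
    if best_node is None:
        raise ValueError("no spikes detected in any cell")
    return best_node, best_t


def _crossing_times(t: np.ndarray, x: np.ndarray, level: float) -> np.ndarray:
    """Upward threshold crossings, linearly interpolated."""
    above = x >= level
    up = np.flatnonzero(~above[:-1] & above[1:])
    if up.size == 0:
        return np.empty(0)
    frac = (level - x[up]) / (x[up + 1] - x[up])
    return t[up] + frac * (t[up + 1] - t[up])


def wave_speed(traj: Trajectory, graph: CellGraph,
               center: tuple[int, int] | None = None,
               threshold_frac: float = 0.5,
               min_waves: int = 2,
               t_min: float | None = None) -> tuple[float, float, int]:
    """Radial speed (cells/s) of waves launched from the grid center.

    Per completed wave, speed = (Chebyshev lattice distance from center to
    the boundary) / (median boundary upward-crossing time - center crossing
    time); crossings use a per-cell threshold ``threshold_frac`` of the way
    from baseline to spike top (1st/99th percentile of the windowed trace).
    The analysis starts at ``t_min`` (default: after the first quarter of the
    run) so the large stimulus-onset transient, whose amplitude dwarfs the
    steady-state waves, never sets the crossing level.  Returns (mean speed,
    half-width of the normal-theory 95% CI, number of waves).
    """
    n, m = graph.n, graph.m
    if t_min is None:
        t_min = float(traj.times[0] + 0.25 * (traj.times[-1] - traj.times[0]))
    window = traj.times >= t_min
    if window.sum() < 10:
        raise ValueError("analysis window too short for wave detection")
    if center is None:
        center = ((n + 1) // 2, (m + 1) // 2)
    node_idx = {v: k for k, v in enumerate(traj.nodes)}
    if center not in node_idx:
        raise ValueError("center cell missing from the trajectory")
    boundary = [v for v in traj.nodes
                if v[0] in (1, n) or v[1] in (1, m)]
    dist = float(max(center[0] - 1, n - center[0], center[1] - 1, m - center[1]))

    def crossings(v) -> np.ndarray:
        x = traj.X[node_idx[v]][window]
        lo, hi = np.percentile(x, [1.0, 99.0])
        if hi - lo < 10.0:  # nM: no spiking, no wave through this cell
            return np.empty(0)
        level = lo + threshold_frac * (hi - lo)
        return _crossing_times(traj.times[window], x, level)

    c_times = crossings(center)
    if len(c_times) < min_waves:
        raise ValueError("no detectable wave: too few center crossings")
    b_cross = [crossings(v) for v in boundary]
    speeds = []
    for k, ck in enumerate(c_times):
        next_c = c_times[k + 1] if k + 1 < len(c_times) else np.inf
        arrivals = []
        for bc in b_cross:
            cand = bc[(bc > ck) & (bc <= next_c)]
            if cand.size:
                arrivals.append(cand[0])
        if len(arrivals) < len(boundary) // 2:
            continue  # wave did not (yet) reach most of the boundary
        t_b = float(np.median(arrivals))
        if t_b > ck:
            speeds.append(dist / (t_b - ck))
    if len(speeds) < min_waves:
        raise ValueError(f"only {len(speeds)} completed waves detected")
    speeds = np.asarray(speeds)
    mean = float(speeds.mean())
    sem = float(speeds.std(ddof=1) / np.sqrt(len(speeds)))
    return mean, 1.96 * sem, len(speeds)
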