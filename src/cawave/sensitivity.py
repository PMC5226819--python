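"""Per-cell agonist-sensitivity fields for the four network model variants.

Every cell carries a stimulus triple (t1, i_IP3,max, i_JINF,max): its onset
time and the plateau levels of [InsP3] and of plasma-membrane Ca2+ influx.
More strongly activated cells reach higher plateaus *and* start earlier, so
across any generated field the three parameters are rank-coupled: sorting
cells by i_IP3,max sorts them identically by i_JINF,max and in reverse by t1.

Variants:

* homogeneous  — every cell identical (an isolated cell is the 1 x 1 case);
* deterministic — a uniform background plus rectangular subregions with their
  own triples (noise-free "distinct regions" model);
* random — white-noise triples: i_IP3,max gets i.i.d. normal noise, and the
  t1 / i_JINF,max noises are independent normal draws *reassigned by the rank
  of the i_IP3,max noise*, which makes the Spearman correlations exactly +1
  (with i_JINF,max) and -1 (with t1) while keeping all three marginals normal;
* random with a central zone — as random, with a small central block drawn
  from its own means/SDs (the "pacemaker region" model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cell import StimulusParams
from .graph import CellGraph, Node

__all__ = [
    "NoiseLevels",
    "Region",
    "SensitivityField",
    "central_block",
    "scaled_stimulus",
    "field_homogeneous",
    "field_deterministic",
    "field_random",
    "field_random_with_center",
]


@dataclass(frozen=True)
class NoiseLevels:
    """White-noise standard deviations for (i_IP3,max, i_JINF,max, t1)."""

    sigma_ip3: float = 0.6   # uM
    sigma_jinf: float = 0.04  # nM/s
    sigma_t1: float = 10.0   # s

    def __post_init__(self) -> None:
        if min(self.sigma_ip3, self.sigma_jinf, self.sigma_t1) < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @classmethod
    def named(cls, level: str) -> "NoiseLevels":
        presets = {
            "low": cls(0.2, 0.01, 4.0),
            "moderate": cls(0.4, 0.025, 10.0),
            "high": cls(0.6, 0.04, 10.0),
            "none": cls(0.0, 0.0, 0.0),
        }
        try:
            return presets[level]
        except KeyError:
            raise ValueError(f"unknown noise level {level!r}; "
                             f"choose from {sorted(presets)}") from None


@dataclass(frozen=True)
class Region:
    """A rectangular block of cells: rows i0..i0+ni-1, columns j0..j0+mj-1."""

    i0: int
    j0: int
    ni: int
    mj: int
    stim: StimulusParams

    def nodes(self) -> frozenset[Node]:
        return frozenset((i, j)
                         for i in range(self.i0, self.i0 + self.ni)
                         for j in range(self.j0, self.j0 + self.mj))


@dataclass(frozen=True)
class SensitivityField:
    """Stimulus triples for every node of a graph, in row-major node order."""

    variant: str
    nodes: tuple[Node, ...]
    t1: np.ndarray
    i_ip3_max: np.ndarray
    i_jinf_max: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        n = len(self.nodes)
        for name in ("t1", "i_ip3_max", "i_jinf_max"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per node")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be positive everywhere")

    @property
    def n_cells(self) -> int:
        return len(self.nodes)

    def stim_for(self, node: Node) -> StimulusParams:
        k = self.nodes.index(node)
        return StimulusParams(float(self.t1[k]), float(self.i_ip3_max[k]),
                              float(self.i_jinf_max[k]))

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "i": [v[0] for v in self.nodes],
            "j": [v[1] for v in self.nodes],
            "t1": self.t1,
            "i_ip3_max": self.i_ip3_max,
            "i_jinf_max": self.i_jinf_max,
        })


def central_block(n: int, m: int, ni: int, mj: int) -> tuple[int, int]:
    """Top-left corner (i0, j0) of the central ni x mj block of an n x m grid.

    For even leftovers the block is biased toward lower indices.
    """
    if ni > n or mj > m:
        raise ValueError("central block does not fit in the grid")
    return (n - ni) // 2 + 1, (m - mj) // 2 + 1


def scaled_stimulus(stim0: StimulusParams, k: float) -> StimulusParams:
    """The k-fold-sensitivity triple (k*i_IP3, k*i_JINF, t1/k)."""
    if k <= 0:
        raise ValueError("k must be positive")
    return StimulusParams(stim0.t1 / k, stim0.i_ip3_max * k, stim0.i_jinf_max * k)


def _node_order(graph: CellGraph) -> tuple[Node, ...]:
    return tuple(graph.node_list())


def field_homogeneous(graph: CellGraph,
                      stim0: StimulusParams = StimulusParams()) -> SensitivityField:
    """Every cell gets the same stimulus triple."""
    nodes = _node_order(graph)
    n = len(nodes)
    return SensitivityField(
        "homogeneous", nodes,
        np.full(n, stim0.t1), np.full(n, stim0.i_ip3_max),
        np.full(n, stim0.i_jinf_max))


def _check_rank_consistency(triples: list[StimulusParams]) -> bool:
    ip3 = np.array([s.i_ip3_max for s in triples])
    jinf = np.array([s.i_jinf_max for s in triples])
    inv_t1 = 1.0 / np.array([s.t1 for s in triples])
    order = np.argsort(ip3, kind="stable")
    return (np.array_equal(order, np.argsort(jinf, kind="stable"))
            and np.array_equal(order, np.argsort(inv_t1, kind="stable")))


def field_deterministic(graph: CellGraph, background_stim: StimulusParams,
                        regions: list[Region]) -> SensitivityField:
    """Uniform background plus disjoint rectangular regions with own triples.

    The sensitivity convention (higher plateaus go with earlier onset) is
    validated across the background and region triples; a violation is
    reported as a warning, not an error, since user-supplied regions may
    legitimately explore other configurations.
    """
    nodes = _node_order(graph)
    node_set = set(nodes)
    seen: set[Node] = set()
    for k, reg in enumerate(regions):
        block = reg.nodes()
        if not block <= node_set:
            raise ValueError(f"region {k} extends outside the graph")
        if block & seen:
            raise ValueError("regions overlap")
        seen |= block
    if regions and not _check_rank_consistency(
            [background_stim] + [r.stim for r in regions]):
        warnings.warn("region triples violate the sensitivity rank convention "
                      "(i_IP3,max, i_JINF,max ascending together, t1 opposite)",
                      stacklevel=2)
    n = len(nodes)
    t1 = np.full(n, background_stim.t1)
    ip3 = np.full(n, background_stim.i_ip3_max)
    jinf = np.full(n, background_stim.i_jinf_max)
    index = {v: k for k, v in enumerate(nodes)}
    for reg in regions:
        for v in reg.nodes():
            k = index[v]
            t1[k] = reg.stim.t1
            ip3[k] = reg.stim.i_ip3_max
            jinf[k] = reg.stim.i_jinf_max
    return SensitivityField("deterministic", nodes, t1, ip3, jinf,
                            {"n_regions": len(regions)})


def _positive_floor(values: np.ndarray, mean: float, meta: dict, key: str) -> np.ndarray:
    """Remap values below 1% of the mean into (0, floor], preserving order.

    A plain constant clip would create ties and break the exact rank coupling
    of the field, so the offending values are spread over distinct positive
    values below the floor in their original order.
    """
    floor = 0.01 * abs(mean)
    if floor == 0:
        floor = 1e-9
    bad = np.flatnonzero(values < floor)
    if bad.size:
        order = bad[np.argsort(values[bad], kind="stable")]
        repl = floor * (np.arange(1, bad.size + 1) / (bad.size + 1.0))
        out = values.copy()
        out[order] = repl
        meta[key] = int(bad.size)
        return out
    return values


def _rank_coupled_noise(rng: np.random.Generator, n: int,
                        sds: NoiseLevels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (eps, phi, psi) white noises and rank-couple phi/psi to eps.

    phi (i_JINF,max noise) is rearranged to share eps's ranks; psi (t1 noise)
    gets the reversed ranks.  Ties in eps are broken by node index.
    """
    eps = rng.standard_normal(n) * sds.sigma_ip3
    phi = np.sort(rng.standard_normal(n) * sds.sigma_jinf)
    psi = np.sort(rng.standard_normal(n) * sds.sigma_t1)[::-1]
    ranks = np.argsort(np.argsort(eps, kind="stable"), kind="stable")
    return eps, phi[ranks], psi[ranks]


def field_random(graph: CellGraph,
                 means: StimulusParams = StimulusParams(),
                 sds: NoiseLevels = NoiseLevels(),
                 seed=None) -> SensitivityField:
    """White-noise sensitivities with exact rank coupling across parameters."""
    nodes = _node_order(graph)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    eps, phi, psi = _rank_coupled_noise(rng, n, sds)
    meta: dict = {}
    ip3 = _positive_floor(means.i_ip3_max + eps, means.i_ip3_max, meta, "clipped_ip3")
    jinf = _positive_floor(means.i_jinf_max + phi, means.i_jinf_max, meta, "clipped_jinf")
    t1 = _positive_floor(means.t1 + psi, means.t1, meta, "clipped_t1")
    return SensitivityField("random", nodes, t1, ip3, jinf, meta)


def field_random_with_center(graph: CellGraph,
                             means0: StimulusParams = StimulusParams(),
                             sds0: NoiseLevels = NoiseLevels(),
                             means1: StimulusParams | None = None,
                             sds1: NoiseLevels = NoiseLevels(0.01, 0.001, 0.0),
                             zone_size: tuple[int, int] = (3, 3),
                             seed=None,
                             center_t1: float | str = "min_background") -> SensitivityField:
    """Random field with a distinguished central zone drawn from its own
    means/SDs (the rank coupling is applied within each population).

    ``center_t1`` may be a number, or ``"min_background"`` to give the zone
    the minimal background onset time (the zone then always leads the
    network); in that mode ``means1.t1`` is ignored.
    """
    if means1 is None:
        means1 = StimulusParams(means0.t1, 2.6, 0.7)
    nodes = _node_order(graph)
    n = len(nodes)
    i0, j0 = central_block(graph.n, graph.m, *zone_size)
    zone = Region(i0, j0, zone_size[0], zone_size[1], means1).nodes()
    in_zone = np.array([v in zone for v in nodes])
    rng = np.random.default_rng(seed)
    meta: dict = {"zone_size": zone_size, "zone_origin": (i0, j0)}

    t1 = np.empty(n)
    ip3 = np.empty(n)
    jinf = np.empty(n)
    for mask, means, sds, tag in ((~in_zone, means0, sds0, "bg"),
                                  (in_zone, means1, sds1, "zone")):
        k = int(mask.sum())
        eps, phi, psi = _rank_coupled_noise(rng, k, sds)
        ip3[mask] = _positive_floor(means.i_ip3_max + eps, means.i_ip3_max,
                                    meta, f"clipped_ip3_{tag}")
        jinf[mask] = _positive_floor(means.i_jinf_max + phi, means.i_jinf_max,
                                     meta, f"clipped_jinf_{tag}")
        if tag == "zone" and center_t1 == "min_background":
            mu_t1 = float(t1[~in_zone].min())
            meta["zone_t1_mean"] = mu_t1
        elif tag == "zone" and not isinstance(center_t1, str):
            mu_t1 = float(center_t1)
        else:
            mu_t1 = means.t1
        t1[mask] = _positive_floor(mu_t1 + psi, mu_t1, meta, f"clipped_t1_{tag}")
    return SensitivityField("random_center", nodes, t1, ip3, jinf, meta)
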