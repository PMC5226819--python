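"""Experiment configuration: a flat, fully serializable description of a run.

A config file (YAML or JSON) names the model variant, grid, coupling,
noise/sensitivity specification, cell-parameter overrides and integration
settings.  Unknown keys are rejected by name; omitted keys fall back to the
package defaults.  A single master seed is split into named child streams
(graph field, link removal, sensitivity) so a config re-runs to identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from .cell import CellParams, StimulusParams
from .graph import (build_dense_grid, link_removal_probabilities, punch_holes,
                    sample_gaussian_field, sparsify)
from .sensitivity import (NoiseLevels, Region, field_deterministic,
                          field_homogeneous, field_random,
                          field_random_with_center)
from .simulate import SimulationConfig

__all__ = ["ExperimentConfig", "load_config", "COUPLING_LEVELS"]

#: named gap-junctional coupling strengths (1/s)
COUPLING_LEVELS = {"low": 0.0015, "moderate": 0.0045, "high": 0.0075}

_TOP_KEYS = {"variant", "n", "m", "d", "noise", "means", "regions", "center",
             "graph", "params", "t_end", "output_dt", "rtol", "atol",
             "method", "n_bins", "seed"}
_MEANS_KEYS = {"t1", "i_ip3_max", "i_jinf_max"}
_NOISE_KEYS = {"sigma_ip3", "sigma_jinf", "sigma_t1"}
_GRAPH_KEYS = {"p", "holes_q", "edge_rule"}
_REGION_KEYS = {"i0", "j0", "ni", "mj"} | _MEANS_KEYS
_CENTER_KEYS = {"zone", "means", "sds", "t1_mode"}
_PARAM_KEYS = {f.name for f in dataclasses.fields(CellParams)}


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    bad = set(mapping) - allowed
    if bad:
        raise ValueError(f"unknown key(s) in {where}: {sorted(bad)}")


def _coupling(value) -> float:
    if isinstance(value, str):
        try:
            return COUPLING_LEVELS[value]
        except KeyError:
            raise ValueError(f"d must be a number or one of "
                             f"{sorted(COUPLING_LEVELS)}, got {value!r}") from None
    return float(value)


def _noise(value) -> NoiseLevels:
    if isinstance(value, str):
        return NoiseLevels.named(value)
    _reject_unknown(value, _NOISE_KEYS, "noise")
    return NoiseLevels(**value)


def _means(value, base: StimulusParams = StimulusParams()) -> StimulusParams:
    _reject_unknown(value, _MEANS_KEYS, "means")
    return StimulusParams(value.get("t1", base.t1),
                          value.get("i_ip3_max", base.i_ip3_max),
                          value.get("i_jinf_max", base.i_jinf_max))


@dataclass(frozen=True)
class ExperimentConfig:
    variant: str = "G0"                 # G0 | GD | GR | GRC
    n: int = 1
    m: int = 1
    d: float = 0.0
    noise: NoiseLevels = NoiseLevels.named("none")
    means: StimulusParams = StimulusParams()
    regions: tuple[Region, ...] = ()
    center_zone: tuple[int, int] = (3, 3)
    center_means: StimulusParams | None = None
    center_sds: NoiseLevels = NoiseLevels(0.01, 0.001, 0.0)
    center_t1_mode: float | str = "min_background"
    p_remove: float = 0.0
    holes_q: float = 0.0
    edge_rule: str = "mean"
    params: CellParams = CellParams()
    t_end: float = 600.0
    output_dt: float = 0.5
    rtol: float = 1e-6
    atol: float = 1e-9
    method: str = "RK45"
    n_bins: int = 10
    seed: int = 0
    extras: dict = dc_field(default_factory=dict, compare=False)

    def build(self, seed: int | None = None) -> SimulationConfig:
        """Materialize graph + sensitivity field + simulation settings."""
        seed = self.seed if seed is None else seed
        s_field, s_remove, s_sens = np.random.SeedSequence(seed).spawn(3)
        g = build_dense_grid(self.n, self.m, d=self.d)
        if self.p_remove > 0 or self.holes_q > 0:
            fld = sample_gaussian_field(self.n, self.m, seed=s_field)
            if self.p_remove > 0:
                probs = link_removal_probabilities(fld, self.p_remove)
                g = sparsify(g, probs, seed=s_remove, rule=self.edge_rule)
            if self.holes_q > 0:
                g = punch_holes(g, fld, self.holes_q)
        if self.variant == "G0":
            f = field_homogeneous(g, self.means)
        elif self.variant == "GD":
            f = field_deterministic(g, self.means, list(self.regions))
        elif self.variant == "GR":
            f = field_random(g, self.means, self.noise, seed=s_sens)
        elif self.variant == "GRC":
            f = field_random_with_center(
                g, self.means, self.noise,
                self.center_means, self.center_sds, self.center_zone,
                seed=s_sens, center_t1=self.center_t1_mode)
        else:
            raise ValueError(f"unknown variant {self.variant!r}")
        return SimulationConfig(g, f, self.params, t_end=self.t_end,
                                output_dt=self.output_dt, rtol=self.rtol,
                                atol=self.atol, method=self.method, seed=seed)


def load_config(path) -> ExperimentConfig:
    """Parse and validate a YAML/JSON experiment config.

    An empty file yields the package defaults; validation errors name the
    offending key.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config")

    kwargs: dict = {}
    for key in ("variant", "n", "m", "t_end", "output_dt", "rtol", "atol",
                "method", "n_bins", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "d" in raw:
        kwargs["d"] = _coupling(raw["d"])
    if "noise" in raw:
        kwargs["noise"] = _noise(raw["noise"])
    if "means" in raw:
        kwargs["means"] = _means(raw["means"])
    if "params" in raw:
        _reject_unknown(raw["params"], _PARAM_KEYS, "params")
        kwargs["params"] = CellParams(**{**CellParams().as_dict(),
                                         **raw["params"]})
    if "regions" in raw:
        regions = []
        for k, reg in enumerate(raw["regions"]):
            _reject_unknown(reg, _REGION_KEYS, f"regions[{k}]")
            stim = _means({kk: reg[kk] for kk in _MEANS_KEYS if kk in reg})
            regions.append(Region(reg["i0"], reg["j0"],
                                  reg.get("ni", 1), reg.get("mj", 1), stim))
        kwargs["regions"] = tuple(regions)
    if "center" in raw:
        c = raw["center"]
        _reject_unknown(c, _CENTER_KEYS, "center")
        if "zone" in c:
            kwargs["center_zone"] = tuple(int(z) for z in c["zone"])
        if "means" in c:
            kwargs["center_means"] = _means(c["means"])
        if "sds" in c:
            kwargs["center_sds"] = _noise(c["sds"])
        if "t1_mode" in c:
            kwargs["center_t1_mode"] = c["t1_mode"]
    if "graph" in raw:
        gr = raw["graph"]
        _reject_unknown(gr, _GRAPH_KEYS, "graph")
        if "p" in gr:
            kwargs["p_remove"] = float(gr["p"])
        if "holes_q" in gr:
            kwargs["holes_q"] = float(gr["holes_q"])
        if "edge_rule" in gr:
            kwargs["edge_rule"] = gr["edge_rule"]
    try:
        return ExperimentConfig(**kwargs)
    except TypeError as exc:
        raise ValueError(f"invalid config: {exc}") from None


def config_to_dict(cfg: ExperimentConfig) -> dict:
    """JSON-serializable echo of an ExperimentConfig."""
    out = {
        "variant": cfg.variant, "n": cfg.n, "m": cfg.m, "d": cfg.d,
        "noise": dataclasses.asdict(cfg.noise),
        "means": dataclasses.asdict(cfg.means),
        "regions": [dataclasses.asdict(r) for r in cfg.regions],
        "center": {
            "zone": list(cfg.center_zone),
            "means": (dataclasses.asdict(cfg.center_means)
                      if cfg.center_means else None),
            "sds": dataclasses.asdict(cfg.center_sds),
            "t1_mode": cfg.center_t1_mode,
        },
        "graph": {"p": cfg.p_remove, "holes_q": cfg.holes_q,
                  "edge_rule": cfg.edge_rule},
        "params": cfg.params.as_dict(),
        "t_end": cfg.t_end, "output_dt": cfg.output_dt,
        "rtol": cfg.rtol, "atol": cfg.atol, "method": cfg.method,
        "n_bins": cfg.n_bins, "seed": cfg.seed,
    }
    return json.loads(json.dumps(out))
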