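"""Readers and writers: trajectories, graphs, fields, analysis tables.

``write_outputs`` lays out one run directory deterministically:

    config.json       full configuration echo
    trajectory.csv    tidy table (time, i, j, c_cyt_nM, c_ER_uM)
    trajectory.npz    exact float64 arrays (times, X, Y, nodes) for round-trip
    <name>.csv        one file per analysis table passed in
    manifest.json     sha256 content hashes of everything above

Concentrations are stored in nM internally; the tidy CSV reports c_ER in uM
to mirror the usual presentation of ER traces.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import CellGraph
from .simulate import Trajectory

__all__ = ["write_outputs", "read_trajectory", "write_edge_list",
           "read_edge_list", "write_field_csv"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(traj: Trajectory, reports: dict | None, out_dir) -> dict:
    """Write a run directory; returns the manifest (also written as JSON).

    ``reports`` maps table names to DataFrames (or dicts of columns).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    cfg_path = out / "config.json"
    cfg_path.write_text(json.dumps(traj.config, indent=2, sort_keys=True,
                                   default=str) + "\n")
    files.append(cfg_path)

    csv_path = out / "trajectory.csv"
    traj.to_frame().to_csv(csv_path, index=False, float_format="%.8g")
    files.append(csv_path)

    npz_path = out / "trajectory.npz"
    np.savez_compressed(npz_path, times=traj.times, X=traj.X, Y=traj.Y,
                        nodes=np.array(traj.nodes, dtype=np.int64),
                        n_floor_clamps=traj.n_floor_clamps)
    files.append(npz_path)

    for name, table in (reports or {}).items():
        path = out / f"{name}.csv"
        pd.DataFrame(table).to_csv(path, index=False)
        files.append(path)

    manifest = {p.name: _sha256(p) for p in files}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def read_trajectory(run_dir) -> Trajectory:
    """Reload the exact trajectory arrays written by ``write_outputs``."""
    run = Path(run_dir)
    with np.load(run / "trajectory.npz") as npz:
        times = npz["times"]
        X = npz["X"]
        Y = npz["Y"]
        nodes = tuple((int(i), int(j)) for i, j in npz["nodes"])
        clamps = int(npz["n_floor_clamps"])
    config = json.loads((run / "config.json").read_text())
    return Trajectory(times, X, Y, nodes, config, clamps)


def write_edge_list(graph: CellGraph, path) -> None:
    """Plain-text graph export: header n m d, then one 'i1 j1 i2 j2' per edge."""
    lines = [f"# n={graph.n} m={graph.m} d={graph.d}"]
    lines += [f"{u[0]} {u[1]} {v[0]} {v[1]}" for u, v in sorted(graph.edges)]
    isolated = graph.nodes - {w for e in graph.edges for w in e}
    lines += [f"{v[0]} {v[1]} {v[0]} {v[1]}" for v in sorted(isolated)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path) -> CellGraph:
    """Inverse of ``write_edge_list`` (self-referencing lines mark isolated
    nodes)."""
    text = Path(path).read_text().strip().splitlines()
    header = text[0].lstrip("# ").split()
    meta = dict(kv.split("=") for kv in header)
    nodes, edges = set(), set()
    for line in text[1:]:
        i1, j1, i2, j2 = (int(w) for w in line.split())
        u, v = (i1, j1), (i2, j2)
        nodes |= {u, v}
        if u != v:
            edges.add((u, v) if u <= v else (v, u))
    return CellGraph(int(meta["n"]), int(meta["m"]), frozenset(nodes),
                     frozenset(edges), float(meta["d"]),
                     {"source": str(path)})


def write_field_csv(values_by_node: dict, n: int, m: int, path) -> None:
    """Dense n x m CSV of per-node values (NaN for holes)."""
    mat = np.full((n, m), np.nan)
    for (i, j), val in values_by_node.items():
        mat[i - 1, j - 1] = val
    pd.DataFrame(mat).to_csv(path, index=False, header=False,
                             float_format="%.17g")
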