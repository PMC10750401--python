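"""Multicellular SAN simulation: coupled-clock cells on a cell network.

Every node of the network runs the single-cell model with its module's
parameter set; every edge injects Ohmic gap-junctional current
(V_j - V_i)/R_ij.  All cells advance synchronously with a shared fixed
time step; AP upstrokes are detected online at full step resolution while
voltage traces are recorded at a coarser stride.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import networkx as nx
import numpy as np

from . import _engine
from .cell_model import (
    AutonomicMode, CellParameters, apply_autonomic, basal_mode,
    default_initial_state, N_STATES,
)

__all__ = [
    "TissueConfig", "SimulationResult", "coupling_currents",
    "simulate_tissue", "save_result", "load_result",
]


@dataclass(frozen=True)
class TissueConfig:
    """Configuration of one tissue run.

    ``module_params`` maps each module id appearing in the graph to its
    cell parameter set (the reference two-module system uses
    LRM: g_CaL = 0.52 nS/pF, P_up = 9 mM/s and
    HRM: g_CaL = 0.30 nS/pF, P_up = 12 mM/s).
    """

    graph: nx.Graph
    module_params: dict[int, CellParameters]
    mode: AutonomicMode = field(default_factory=basal_mode)
    duration: float = 8.0           # s
    dt: float = 0.005               # ms
    record_stride: int = 20         # samples between recorded points
    transient_discard: float = 2.0  # s
    seed: int = 0
    init_jitter: float = 0.0        # relative SD of seeded per-cell jitter
    ap_threshold: float = -20.0     # mV
    ap_refractory: float = 50.0     # ms

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= self.transient_discard:
            raise ValueError("duration must exceed transient_discard")
        modules = {d["module"] for _, d in self.graph.nodes(data=True)}
        missing = modules - set(self.module_params)
        if missing:
            raise ValueError(f"no parameters for module ids {sorted(missing)}")


@dataclass
class SimulationResult:
    """Output of a tissue (or batch single-cell) run."""

    time: np.ndarray                # ms, uniform at dt * record_stride
    V: np.ndarray                   # (n_cells, n_samples), mV
    ap_times: list[np.ndarray]      # per cell, ms, full resolution
    module_of: np.ndarray           # (n_cells,) module id
    config: dict                    # echo: sizes, parameters, mode, seeds

    @property
    def n_cells(self) -> int:
        return self.V.shape[0]


def _node_order(graph: nx.Graph) -> list:
    return sorted(graph.nodes)


def coupling_currents(V: np.ndarray, graph: nx.Graph) -> np.ndarray:
    """Gap-junctional current into each cell, nA (positive = depolarizing).

    current_i = sum over neighbors j of (V_j - V_i) / R_ij, with R in MOhm
    and V in mV (mV/MOhm = nA).  Antisymmetric per edge, so the total over
    cells is zero to rounding.
    """
    order = _node_order(graph)
    idx = {n: k for k, n in enumerate(order)}
    V = np.asarray(V, dtype=float)
    if V.shape[0] != len(order):
        raise ValueError("V length must equal the node count")
    out = np.zeros(len(order))
    for a, b, data in graph.edges(data=True):
        if a not in idx or b not in idx:
            raise ValueError(f"edge ({a},{b}) references unknown node")
        i, j = idx[a], idx[b]
        flow = (V[j] - V[i]) / data["resistance"]
        out[i] += flow
        out[j] -= flow
    return out


def _csr_adjacency(graph: nx.Graph):
    order = _node_order(graph)
    idx = {n: k for k, n in enumerate(order)}
    n = len(order)
    neigh: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for a, b, data in graph.edges(data=True):
        r = float(data["resistance"])
        neigh[idx[a]].append((idx[b], 1.0 / r))
        neigh[idx[b]].append((idx[a], 1.0 / r))
    indptr = np.zeros(n + 1, dtype=np.int64)
    indices = []
    inv_r = []
    for i, lst in enumerate(neigh):
        lst.sort()
        indptr[i + 1] = indptr[i] + len(lst)
        for j, g in lst:
            indices.append(j)
            inv_r.append(g)
    return (indptr, np.asarray(indices, dtype=np.int64),
            np.asarray(inv_r, dtype=np.float64))


def simulate_tissue(cfg: TissueConfig) -> SimulationResult:
    """Integrate the full coupled system; deterministic given the config."""
    order = _node_order(cfg.graph)
    n = len(order)
    module_of = np.array([cfg.graph.nodes[v]["module"] for v in order],
                         dtype=int)
    mod_ids = sorted(set(module_of))
    param_sets = [apply_autonomic(cfg.module_params[m], cfg.mode)
                  for m in mod_ids]
    param_idx = np.array([mod_ids.index(m) for m in module_of],
                         dtype=np.int64)

    y0 = default_initial_state()
    states = np.tile(y0, (n, 1))
    if cfg.init_jitter > 0:
        rng = np.random.default_rng(cfg.seed)
        states *= 1.0 + cfg.init_jitter * rng.standard_normal(states.shape)

    indptr, indices, inv_r = _csr_adjacency(cfg.graph)
    t, V, aps = _engine.integrate(
        states, param_sets, param_idx,
        duration_ms=cfg.duration * 1000.0, dt=cfg.dt,
        record_stride=cfg.record_stride,
        indptr=indptr, indices=indices, inv_R=inv_r,
        ap_thresh=cfg.ap_threshold, ap_refract=cfg.ap_refractory)

    echo = {
        "n_cells": n,
        "module_sizes": {str(m): int(np.sum(module_of == m))
                         for m in mod_ids},
        "mode": cfg.mode.mode,
        "mode_scalings": dict(cfg.mode.effector_scalings),
        "i_kach_conductance": cfg.mode.i_kach_conductance,
        "mode_calibrated": cfg.mode.calibrated,
        "module_params": {str(m): {"g_CaL": cfg.module_params[m].g_CaL,
                                   "P_up": cfg.module_params[m].P_up}
                          for m in mod_ids},
        "duration_s": cfg.duration,
        "dt_ms": cfg.dt,
        "record_stride": cfg.record_stride,
        "transient_discard_s": cfg.transient_discard,
        "seed": cfg.seed,
        "init_jitter": cfg.init_jitter,
    }
    return SimulationResult(time=t, V=V, ap_times=aps,
                            module_of=module_of, config=echo)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def save_result(res: SimulationResult, path: str | Path) -> None:
    """Write /time, /V, ragged /ap_times (+offsets), module ids, config."""
    with h5py.File(path, "w") as f:
        kw = {"track_times": False}  # bitwise-reproducible files
        f.create_dataset("time", data=res.time, **kw)
        f.create_dataset("V", data=res.V, compression="gzip",
                         shuffle=True, **kw)
        flat = (np.concatenate(res.ap_times) if res.ap_times
                else np.zeros(0))
        offsets = np.cumsum([0] + [len(a) for a in res.ap_times])
        f.create_dataset("ap_times", data=flat, **kw)
        f.create_dataset("ap_offsets", data=offsets, **kw)
        f.create_dataset("module_of", data=res.module_of, **kw)
        f.attrs["config"] = json.dumps(res.config)


def load_result(path: str | Path) -> SimulationResult:
    with h5py.File(path, "r") as f:
        time = f["time"][:]
        V = f["V"][:]
        flat = f["ap_times"][:]
        off = f["ap_offsets"][:]
        aps = [flat[off[i]:off[i + 1]] for i in range(len(off) - 1)]
        module_of = f["module_of"][:]
        config = json.loads(f.attrs["config"])
    return SimulationResult(time=time, V=V, ap_times=aps,
                            module_of=module_of, config=config)
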