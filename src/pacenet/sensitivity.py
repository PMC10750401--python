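"""Parametric sensitivity maps over (g_CaL, P_up) for isolated cells.

One simulation per pixel classifies the cell as silent, regular or
chaotic and records its AP rate; the published full-resolution grid is
97 x 61 pixels of 0.0025 nS/pF x 0.2 mM/s.  Pixels are simulated in one
batch of uncoupled cells, which keeps the sweep a single call into the
integration engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine
from .cell_model import (
    AutonomicMode, CellParameters, apply_autonomic, basal_mode,
    classify_firing, default_initial_state,
)

__all__ = ["GridSpec", "SensitivityMap", "plan_grid", "sweep",
           "extract_border"]

#: published pixel sizes
PIXEL_G_CAL = 0.0025   # nS/pF
PIXEL_P_UP = 0.2       # mM/s

_LABEL_CODE = {"silent": 0, "regular": 1, "chaotic": 2}
_CODE_LABEL = {v: k for k, v in _LABEL_CODE.items()}


@dataclass(frozen=True)
class GridSpec:
    """Axis specification of a sensitivity sweep.

    Defaults cover both module parameter points with margin; the axis
    ranges of the published figure are not recoverable from its text, so
    they are configurable here.
    """

    g_cal_min: float = 0.30
    g_cal_max: float = 0.54
    p_up_min: float = 0.2
    p_up_max: float = 12.2
    g_cal_step: float = PIXEL_G_CAL
    p_up_step: float = PIXEL_P_UP
    thin: int = 1   # keep every thin-th pixel on each axis

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        g = np.round(np.arange(self.g_cal_min,
                               self.g_cal_max + 0.5 * self.g_cal_step,
                               self.g_cal_step), 10)
        p = np.round(np.arange(self.p_up_min,
                               self.p_up_max + 0.5 * self.p_up_step,
                               self.p_up_step), 10)
        if self.thin > 1:
            g = g[::self.thin]
            p = p[::self.thin]
        return g, p


@dataclass
class SensitivityMap:
    """Classified (g_CaL, P_up) grid for one autonomic mode."""

    g_cal_axis: np.ndarray        # nS/pF
    p_up_axis: np.ndarray         # mM/s
    label: np.ndarray             # (n_p_up, n_g_cal) int codes, see labels()
    rate: np.ndarray              # Hz, same shape
    cv: np.ndarray                # cycle-length CV, same shape
    mode: str

    def labels(self) -> np.ndarray:
        return np.vectorize(_CODE_LABEL.get)(self.label)

    def classification_at(self, g_cal: float, p_up: float) -> str:
        i = int(np.argmin(np.abs(self.p_up_axis - p_up)))
        j = int(np.argmin(np.abs(self.g_cal_axis - g_cal)))
        return _CODE_LABEL[int(self.label[i, j])]

    def rate_at(self, g_cal: float, p_up: float) -> float:
        i = int(np.argmin(np.abs(self.p_up_axis - p_up)))
        j = int(np.argmin(np.abs(self.g_cal_axis - g_cal)))
        return float(self.rate[i, j])


def plan_grid(grid: GridSpec) -> dict:
    """Dry-run planner: pixel counts and simulation tally, no simulation."""
    g, p = grid.axes()
    return {"n_g_cal": len(g), "n_p_up": len(p),
            "n_simulations": len(g) * len(p),
            "g_cal_axis": g, "p_up_axis": p}


def sweep(grid: GridSpec,
          mode: AutonomicMode | None = None,
          base_params: CellParameters | None = None,
          duration: float = 12.0,
          dt: float = 0.005,
          transient_discard: float = 2.0,
          cv_threshold: float = 0.05) -> SensitivityMap:
    """Classify every pixel of the grid for one autonomic mode.

    Each pixel is an isolated cell simulated for ``duration`` s; the first
    ``transient_discard`` s are excluded from classification.  All pixels
    run as one uncoupled batch.  A pixel whose simulation blows up is
    flagged with label code -1 rather than failing the sweep.
    """
    base = base_params if base_params is not None else CellParameters()
    mode = mode if mode is not None else basal_mode()
    g_ax, p_ax = grid.axes()
    n_g, n_p = len(g_ax), len(p_ax)
    pixels = [(i, j) for i in range(n_p) for j in range(n_g)]
    param_sets = [apply_autonomic(base.with_(g_CaL=g_ax[j], P_up=p_ax[i]),
                                  mode)
                  for (i, j) in pixels]
    y0 = default_initial_state()
    states = np.tile(y0, (len(pixels), 1))
    label = np.full((n_p, n_g), -1, dtype=int)
    rate = np.zeros((n_p, n_g))
    cv = np.zeros((n_p, n_g))
    try:
        _, _, aps = _engine.integrate(
            states, param_sets, np.arange(len(pixels), dtype=np.int64),
            duration_ms=duration * 1000.0, dt=dt,
            record_stride=max(1, int(round(duration * 1000.0 / dt / 4))))
    except RuntimeError:
        # a blow-up anywhere aborts the batch: fall back to per-pixel runs
        aps = []
        for ps in param_sets:
            st = y0[None, :].copy()
            try:
                _, _, a = _engine.integrate(
                    st, [ps], np.zeros(1, dtype=np.int64),
                    duration_ms=duration * 1000.0, dt=dt,
                    record_stride=10 ** 9)
                aps.append(a[0])
            except RuntimeError:
                aps.append(None)
    window = (duration - transient_discard) * 1000.0
    for k, (i, j) in enumerate(pixels):
        a = aps[k]
        if a is None:
            continue
        a = a[a >= transient_discard * 1000.0]
        fc = classify_firing(a, window, cv_threshold=cv_threshold)
        label[i, j] = _LABEL_CODE[fc.label]
        rate[i, j] = fc.mean_rate
        cv[i, j] = fc.cv_cycle_length
    return SensitivityMap(g_cal_axis=g_ax, p_up_axis=p_ax, label=label,
                          rate=rate, cv=cv, mode=mode.mode)


def extract_border(smap: SensitivityMap) -> list[np.ndarray]:
    """Bifurcation borders as ordered polylines in parameter units.

    Walks every boundary segment between 4-adjacent pixels with different
    classifications and chains collinear/adjacent segments into ordered
    point lists ((g_CaL, P_up) pairs at pixel boundaries).  A single-class
    map yields an empty list.
    """
    lab = smap.label
    n_p, n_g = lab.shape
    dg = (smap.g_cal_axis[1] - smap.g_cal_axis[0]) if n_g > 1 else PIXEL_G_CAL
    dp = (smap.p_up_axis[1] - smap.p_up_axis[0]) if n_p > 1 else PIXEL_P_UP

    # segment endpoints on the half-step lattice, keyed for chaining
    segments = []
    for i in range(n_p):
        for j in range(n_g - 1):
            if lab[i, j] != lab[i, j + 1]:
                x = smap.g_cal_axis[j] + 0.5 * dg
                y0 = smap.p_up_axis[i] - 0.5 * dp
                y1 = smap.p_up_axis[i] + 0.5 * dp
                segments.append(((x, y0), (x, y1)))
    for i in range(n_p - 1):
        for j in range(n_g):
            if lab[i, j] != lab[i + 1, j]:
                y = smap.p_up_axis[i] + 0.5 * dp
                x0 = smap.g_cal_axis[j] - 0.5 * dg
                x1 = smap.g_cal_axis[j] + 0.5 * dg
                segments.append(((x0, y), (x1, y)))
    if not segments:
        return []

    # chain segments endpoint-to-endpoint into polylines
    def key(pt):
        return (round(pt[0], 9), round(pt[1], 9))

    remaining = {k: seg for k, seg in enumerate(segments)}
    endpoint_map: dict[tuple, list[int]] = {}
    for k, (a, b) in remaining.items():
        endpoint_map.setdefault(key(a), []).append(k)
        endpoint_map.setdefault(key(b), []).append(k)

    polylines = []
    while remaining:
        k0, (a, b) = next(iter(remaining.items()))
        del remaining[k0]
        chain = [a, b]
        # extend forward
        for end in (1, 0):
            while True:
                pt = key(chain[-1] if end else chain[0])
                nxt = [k for k in endpoint_map.get(pt, []) if k in remaining]
                if not nxt:
                    break
                k = nxt[0]
                sa, sb = remaining.pop(k)
                other = sb if key(sa) == pt else sa
                if end:
                    chain.append(other)
                else:
                    chain.insert(0, other)
        polylines.append(np.asarray(chain))
    return polylines
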