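"""Basic figure export: voltage traces, sensitivity maps, CL histograms."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import CycleStats, cycle_length_histogram
from .sensitivity import SensitivityMap
from .tissue import SimulationResult

__all__ = ["plot_traces", "plot_sensitivity_map", "plot_cl_histogram"]


def plot_traces(res: SimulationResult, cells_per_module: int = 3,
                path: str | None = None):
    """Overlay a few voltage traces per module (one panel per module)."""
    mods = sorted(set(int(m) for m in res.module_of))
    fig, axes = plt.subplots(len(mods), 1, sharex=True,
                             figsize=(8, 2.2 * len(mods)), squeeze=False)
    for ax, m in zip(axes[:, 0], mods):
        cells = np.nonzero(res.module_of == m)[0][:cells_per_module]
        for c in cells:
            ax.plot(res.time / 1000.0, res.V[c], lw=0.6)
        ax.set_ylabel(f"module {m}\nV (mV)")
    axes[-1, 0].set_xlabel("time (s)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_sensitivity_map(smap: SensitivityMap, path: str | None = None,
                         rate_max: float = 4.0):
    """Firing-rate map over (g_CaL, P_up), silent pixels black."""
    fig, ax = plt.subplots(figsize=(5, 4))
    img = np.clip(smap.rate / rate_max, 0.0, 1.0)
    extent = (smap.g_cal_axis[0], smap.g_cal_axis[-1],
              smap.p_up_axis[0], smap.p_up_axis[-1])
    im = ax.imshow(img, origin="lower", aspect="auto", cmap="hot",
                   vmin=0.0, vmax=1.0, extent=extent)
    fig.colorbar(im, ax=ax, label=f"AP rate / {rate_max:g} Hz")
    ax.set_xlabel("g_CaL (nS/pF)")
    ax.set_ylabel("P_up (mM/s)")
    ax.set_title(f"{smap.mode} state")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_cl_histogram(stats: CycleStats, module_of: np.ndarray,
                      path: str | None = None, bin_ms: float = 5.0):
    """Per-module histogram of per-cell mean cycle lengths."""
    hist = cycle_length_histogram(stats, module_of, bin_ms=bin_ms)
    fig, ax = plt.subplots(figsize=(6, 3))
    for m, (edges, counts) in hist.items():
        if counts.size:
            ax.stairs(counts, edges, label=f"module {m}", fill=True,
                      alpha=0.5)
    ax.set_xlabel("mean cycle length (ms)")
    ax.set_ylabel("cells")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
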