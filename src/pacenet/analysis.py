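"""Readouts of tissue simulations: cycle-length statistics, leadership,
dormancy and the autonomic rate range.

Module aggregates weight cells equally (means "among cells"): each firing
cell contributes its own mean cycle length once, and silent cells are
reported through the firing fraction instead of entering the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .tissue import SimulationResult

__all__ = [
    "CycleStats", "detect_aps", "module_stats", "leading_module",
    "rate_range", "cycle_length_histogram",
]


@dataclass
class CycleStats:
    """Per-cell and per-module cycle-length statistics of one run."""

    cell_mean_cl: np.ndarray     # ms, NaN for silent cells
    cell_sd_cl: np.ndarray       # ms, NaN for silent cells
    module_ids: list[int]
    module_mean_cl: dict[int, float]     # ms, among firing cells
    module_sd_cl: dict[int, float]       # ms, among firing cells
    firing_fraction: dict[int, float]
    leader: int | None
    lead_delay: float            # ms, mean follower-behind-leader gap

    def module_rate_hz(self, module: int) -> float:
        cl = self.module_mean_cl[module]
        return 1000.0 / cl if np.isfinite(cl) and cl > 0 else 0.0


def detect_aps(trace: np.ndarray, time: np.ndarray,
               threshold: float = -20.0, refractory: float = 50.0
               ) -> np.ndarray:
    """Upstroke times (ms) from a uniformly sampled voltage trace.

    Upward threshold crossings separated by at least ``refractory`` ms,
    with linear interpolation between samples.
    """
    time = np.asarray(time, float)
    trace = np.asarray(trace, float)
    if time.size != trace.size:
        raise ValueError("time and trace must have equal length")
    dt = np.diff(time)
    if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("detect_aps requires a uniform time base")
    below = trace[:-1] < threshold
    above = trace[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    out = []
    last = -np.inf
    for i in idx:
        frac = (threshold - trace[i]) / (trace[i + 1] - trace[i])
        t_ap = time[i] + frac * (time[i + 1] - time[i])
        if t_ap - last >= refractory:
            out.append(t_ap)
            last = t_ap
    return np.asarray(out)


def _window_aps(res: SimulationResult, window: tuple[float, float] | None):
    """AP trains clipped to the analysis window (defaults to post-transient)."""
    if window is None:
        t0 = res.config.get("transient_discard_s", 2.0) * 1000.0
        t1 = res.time[-1]
    else:
        t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty analysis window")
    return [a[(a >= t0) & (a <= t1)] for a in res.ap_times], (t0, t1)


def module_stats(res: SimulationResult,
                 window: tuple[float, float] | None = None,
                 min_aps: int = 2) -> CycleStats:
    """Cycle-length statistics per cell and per module.

    Cells with fewer than ``min_aps`` upstrokes in the window count as
    silent.  Module means and SDs are taken among firing cells' per-cell
    mean cycle lengths.
    """
    aps, _ = _window_aps(res, window)
    n = res.n_cells
    mean_cl = np.full(n, np.nan)
    sd_cl = np.full(n, np.nan)
    for i, a in enumerate(aps):
        if len(a) >= min_aps:
            cl = np.diff(a)
            mean_cl[i] = cl.mean()
            sd_cl[i] = cl.std()
    mods = sorted(set(int(m) for m in res.module_of))
    mod_mean, mod_sd, frac = {}, {}, {}
    for m in mods:
        sel = res.module_of == m
        firing = np.isfinite(mean_cl) & sel
        frac[m] = float(firing.sum() / sel.sum())
        mod_mean[m] = float(np.mean(mean_cl[firing])) if firing.any() else np.nan
        mod_sd[m] = float(np.std(mean_cl[firing])) if firing.any() else np.nan
    leader, delay = _leader_from_aps(aps, res.module_of)
    return CycleStats(cell_mean_cl=mean_cl, cell_sd_cl=sd_cl,
                      module_ids=mods, module_mean_cl=mod_mean,
                      module_sd_cl=mod_sd, firing_fraction=frac,
                      leader=leader, lead_delay=delay)


def _leader_from_aps(aps, module_of):
    """Leading module and mean lead delay from upstroke trains.

    Beats are clusters of merged upstrokes split at gaps longer than half
    the median cycle length; within each beat the module with the earlier
    median upstroke leads, and the overall vote is the majority.  When the
    firing modules' mean cycle lengths separate by more than 2% the
    modules are not phase-locked and per-beat ordering drifts, so the
    faster-firing module (the pacing source) overrides the vote.  Modules
    with fewer than half their cells firing are not leader candidates.
    Returns (leader, mean delay ms); delay is NaN if modules never share
    a beat.
    """
    module_of = np.asarray(module_of)
    mods = sorted(set(int(m) for m in module_of))
    all_t, all_m = [], []
    for i, a in enumerate(aps):
        all_t.extend(a)
        all_m.extend([module_of[i]] * len(a))
    if not all_t:
        return None, float("nan")
    order = np.argsort(all_t)
    t = np.asarray(all_t)[order]
    m = np.asarray(all_m)[order]
    firing_mods = [mm for mm in mods if np.any(m == mm)]
    if len(firing_mods) < 2:
        return (firing_mods[0] if firing_mods else None), float("nan")

    # leader candidates: modules where most cells fire repetitively
    frac = {}
    mean_cl_mod = {}
    for mm in mods:
        cells = [i for i in range(len(aps)) if module_of[i] == mm]
        firing_cells = [i for i in cells if len(aps[i]) >= 2]
        frac[mm] = len(firing_cells) / len(cells) if cells else 0.0
        if firing_cells:
            mean_cl_mod[mm] = float(np.mean(
                [np.mean(np.diff(aps[i])) for i in firing_cells]))
    candidates = [mm for mm in firing_mods if frac.get(mm, 0.0) >= 0.5]
    if not candidates:
        candidates = firing_mods
    # median cycle length from the most active module's cells
    percell_cl = [np.diff(a) for a in aps if len(a) >= 2]
    med_cl = np.median(np.concatenate(percell_cl)) if percell_cl else 300.0
    gap = 0.5 * med_cl
    splits = np.nonzero(np.diff(t) > gap)[0]
    beats = np.split(np.arange(len(t)), splits + 1)
    votes = {mm: 0 for mm in firing_mods}
    delays = []
    for beat in beats:
        tb, mb = t[beat], m[beat]
        med = {mm: np.median(tb[mb == mm]) for mm in firing_mods
               if np.any(mb == mm)}
        if len(med) < 2:
            continue
        first = min(med, key=med.get)
        votes[first] += 1
        delays.append(max(med.values()) - min(med.values()))
    # rate override for unlocked modules
    cl_cands = {mm: mean_cl_mod[mm] for mm in candidates
                if mm in mean_cl_mod}
    if len(cl_cands) >= 2:
        ordered = sorted(cl_cands, key=cl_cands.get)
        fastest, second = ordered[0], ordered[1]
        if (cl_cands[second] - cl_cands[fastest]) / cl_cands[fastest] > 0.02:
            delay = float(np.mean(delays)) if delays else float("nan")
            return int(fastest), delay
    if not delays:
        # modules never share a beat; earliest-median module leads overall
        med = {mm: np.median(t[m == mm]) for mm in firing_mods}
        return min(med, key=med.get), float("nan")
    leader = max(votes, key=votes.get)
    if leader not in candidates:
        leader = min({mm: mean_cl_mod.get(mm, np.inf) for mm in candidates},
                     key=lambda k: mean_cl_mod.get(k, np.inf))
    return int(leader), float(np.mean(delays))


def leading_module(res: SimulationResult,
                   window: tuple[float, float] | None = None
                   ) -> tuple[int, float]:
    """Leading module id and mean lead delay (ms) over the window."""
    aps, _ = _window_aps(res, window)
    if not any(len(a) >= 1 for a in aps):
        raise ValueError("all modules silent; no leader")
    leader, delay = _leader_from_aps(aps, res.module_of)
    if leader is None:
        raise ValueError("all modules silent; no leader")
    return leader, delay


def rate_range(stats_by_mode: dict[str, CycleStats]) -> tuple[float, float]:
    """(min, max) leader-module AP rate in Hz over modes, to 0.1 Hz."""
    if not stats_by_mode:
        raise ValueError("need at least one mode")
    rates = []
    for st in stats_by_mode.values():
        if st.leader is None:
            continue
        rates.append(st.module_rate_hz(st.leader))
    if not rates:
        raise ValueError("no firing leader in any mode")
    return round(min(rates), 1), round(max(rates), 1)


def cycle_length_histogram(stats: CycleStats, module_of: np.ndarray,
                           bin_ms: float = 5.0):
    """Per-module histogram of per-cell mean cycle lengths.

    Returns {module: (bin_edges_ms, counts)} over firing cells, for
    comparison with the per-module cycle-length histograms of the
    reference simulations.
    """
    out = {}
    for m in sorted(set(int(x) for x in module_of)):
        vals = stats.cell_mean_cl[(module_of == m)
                                  & np.isfinite(stats.cell_mean_cl)]
        if vals.size == 0:
            out[m] = (np.zeros(1), np.zeros(0, dtype=int))
            continue
        lo = np.floor(vals.min() / bin_ms) * bin_ms
        hi = np.ceil(vals.max() / bin_ms) * bin_ms + bin_ms
        edges = np.arange(lo, hi + 0.5 * bin_ms, bin_ms)
        counts, _ = np.histogram(vals, edges)
        out[m] = (edges, counts)
    return out
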