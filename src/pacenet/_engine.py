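"""Fixed-step integration engine (numba) for single cells and tissues.

One kernel serves every use: N cells with per-cell conductance rows, an
optional gap-junction adjacency in CSR form, forward-Euler (default) or RK4
stepping, online AP-upstroke detection at full dt resolution, and strided
voltage recording.  Voltage-dependent gate kinetics and exchanger
exponentials are pre-tabulated on a 0.02-mV grid and linearly interpolated,
which keeps the per-step cost dominated by arithmetic rather than exp().
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .cell_model import (
    CellParameters, F_FARADAY, RTF, N_STATES, STATE_NAMES, gate_kinetics,
    _kach_rectification,
)

# ---- voltage table ---------------------------------------------------------

V_MIN, V_MAX, V_STEP = -120.0, 100.0, 0.02
_N_TAB = int(round((V_MAX - V_MIN) / V_STEP)) + 1

# gates resolved through the table, in kernel order; fCa is Ca-dependent
_TAB_GATES = ("dL", "fL", "dT", "fT", "paF", "paS", "piK",
              "n", "q", "r", "y", "qa", "qi")
_GATE_Y_IDX = np.array([STATE_NAMES.index(g) for g in _TAB_GATES],
                       dtype=np.int64)
_N_GATES = len(_TAB_GATES)
# extra voltage-dependent rows appended after the 2*_N_GATES gate rows
_ROW_EXP_POS = 2 * _N_GATES       # exp(+Qn V / 2RTF)
_ROW_EXP_NEG = 2 * _N_GATES + 1   # exp(-Qn V / 2RTF)
_ROW_EXP_QCI = 2 * _N_GATES + 2   # exp(-Qci V / RTF)
_ROW_INAK_V = 2 * _N_GATES + 3    # voltage factor of I_NaK
_ROW_KACH = 2 * _N_GATES + 4      # I_KACh rectification factor
_N_ROWS = 2 * _N_GATES + 5

_table_cache: dict = {}


def build_tables(p: CellParameters) -> np.ndarray:
    key = (p.Qn, p.Qci, p.E_Na, p.E_K, p.K_m_Kp, p.K_m_Nap,
           p.V_dL_half, p.k_dL, p.V_y_shift)
    tab = _table_cache.get(key)
    if tab is not None:
        return tab
    V = np.linspace(V_MIN, V_MAX, _N_TAB)
    tab = np.empty((_N_ROWS, _N_TAB))
    kin = gate_kinetics(V, p)
    for g_i, g in enumerate(_TAB_GATES):
        inf, tau = kin[g]
        tab[2 * g_i] = inf
        tab[2 * g_i + 1] = 1.0 / tau
    tab[_ROW_EXP_POS] = np.exp(p.Qn * V / (2.0 * RTF))
    tab[_ROW_EXP_NEG] = np.exp(-p.Qn * V / (2.0 * RTF))
    tab[_ROW_EXP_QCI] = np.exp(-p.Qci * V / RTF)
    tab[_ROW_INAK_V] = 1.0 / (1.0 + np.exp(-(V - p.E_Na + 110.0) / 20.0))
    tab[_ROW_KACH] = _kach_rectification(V, p.E_K)
    _table_cache[key] = tab
    return tab


# ---- parameter packing -----------------------------------------------------

# per-cell row: quantities that may differ between modules / autonomic states
_PC_FIELDS = ("g_CaL", "g_CaT", "g_Kr", "g_Ks", "g_to", "g_sus", "g_if",
              "g_st", "g_b_Na", "g_b_Ca", "g_KACh", "k_NaCa", "k_s")
# appended computed entries: [13] effective i_NaK_max, [14] P_up in mM/ms
_N_PC = len(_PC_FIELDS) + 2

# shared-constant vector layout
_SH_FIELDS = ("C_m", "E_CaL", "E_CaT", "E_st",
              "K_up", "tau_tr", "tau_dif_Ca",
              "k_oCa", "k_iCa", "k_om", "k_im",
              "EC50_SR", "Max_SR", "Min_SR", "HSR",
              "CM_tot", "TC_tot", "TMC_tot", "CQ_tot",
              "kf_TC", "kb_TC", "kf_TMC", "kb_TMC", "kf_TMM", "kb_TMM",
              "kf_CM", "kb_CM", "kf_CQ", "kb_CQ",
              "Mg_i", "V_sub", "V_i", "V_nsr", "V_jsr",
              "alpha_fCa", "K_m_fCa", "Kci", "Kcni")
# appended computed entries
_SH_EXTRA = ("E_Na", "E_K", "E_Ks", "ncx_k43", "ncx_k34", "ncx_k21",
             "ncx_c23", "ncx_cnai", "ncx_nai_kcni", "ncx_cnai14", "F")
_SH = {name: i for i, name in enumerate(_SH_FIELDS + _SH_EXTRA)}
_N_SH = len(_SH)


def pack_params(param_sets: list[CellParameters],
                cell_param_idx: np.ndarray):
    """Build (per_cell (N,_N_PC), shared (_N_SH,), tab) arrays.

    All entries outside ``_PC_FIELDS`` + the NaK/concentration scalars must
    agree across the supplied parameter sets (cells may only differ in
    conductances, pump rates and exchanger scaling).
    """
    p0 = param_sets[0]
    shared_names = set(_SH_FIELDS) | {
        "Na_o", "K_o", "Ca_o", "Na_i", "K_i",
        "K1ni", "K1no", "K2ni", "K2no", "K3ni", "K3no", "Kco",
        "Qci", "Qco", "Qn", "K_m_Kp", "K_m_Nap"}
    for p in param_sets[1:]:
        for name in shared_names:
            if getattr(p, name) != getattr(p0, name):
                raise ValueError(
                    f"parameter {name!r} must be identical across cells")

    rows = np.empty((len(param_sets), _N_PC))
    for r, p in enumerate(param_sets):
        for c, name in enumerate(_PC_FIELDS):
            rows[r, c] = getattr(p, name)
        rows[r, len(_PC_FIELDS)] = (
            p.i_NaK_max
            / (1.0 + (p.K_m_Kp / p.K_o) ** 1.2)
            / (1.0 + (p.K_m_Nap / p.Na_i) ** 1.3))
        rows[r, len(_PC_FIELDS) + 1] = p.P_up / 1000.0
    per_cell = rows[np.asarray(cell_param_idx, dtype=np.int64)]

    sh = np.empty(_N_SH)
    for name in _SH_FIELDS:
        sh[_SH[name]] = getattr(p0, name)
    sh[_SH["E_Na"]] = p0.E_Na
    sh[_SH["E_K"]] = p0.E_K
    sh[_SH["E_Ks"]] = p0.E_Ks
    sh[_SH["ncx_k43"]] = p0.Na_i / (p0.K3ni + p0.Na_i)
    sh[_SH["ncx_k34"]] = p0.Na_o / (p0.K3no + p0.Na_o)
    do = (1.0 + p0.Ca_o / p0.Kco * (1.0 + np.exp(0.0 * p0.Qco))
          + p0.Na_o / p0.K1no
          * (1.0 + p0.Na_o / p0.K2no * (1.0 + p0.Na_o / p0.K3no)))
    if p0.Qco != 0.0:
        raise NotImplementedError("table path assumes Qco = 0")
    sh[_SH["ncx_k21"]] = p0.Ca_o / p0.Kco / do
    sh[_SH["ncx_c23"]] = (p0.Na_o / p0.K1no * p0.Na_o / p0.K2no
                          * (1.0 + p0.Na_o / p0.K3no) / do)
    sh[_SH["ncx_cnai"]] = (p0.Na_i / p0.K1ni
                           * (1.0 + p0.Na_i / p0.K2ni
                              * (1.0 + p0.Na_i / p0.K3ni)))
    sh[_SH["ncx_nai_kcni"]] = p0.Na_i / p0.Kcni
    sh[_SH["ncx_cnai14"]] = (p0.Na_i / p0.K1ni * p0.Na_i / p0.K2ni
                             * (1.0 + p0.Na_i / p0.K3ni))
    sh[_SH["F"]] = F_FARADAY
    return per_cell, sh, build_tables(p0)


# ---- kernels ---------------------------------------------------------------

@njit(cache=True, inline="always")
def _deriv(y, pc, sh, tab, coup_dv, dy):
    """dy/dt for one cell; coup_dv is the gap-junctional dV/dt term (mV/ms)."""
    V = y[0]
    u = (V - V_MIN) * (1.0 / V_STEP)
    i0 = int(u)
    if i0 < 0:
        i0 = 0
    elif i0 > _N_TAB - 2:
        i0 = _N_TAB - 2
    w = u - i0
    # gate relaxation
    for g in range(_N_GATES):
        gi = _GATE_Y_IDX[g]
        inf = tab[2 * g, i0] * (1.0 - w) + tab[2 * g, i0 + 1] * w
        invtau = tab[2 * g + 1, i0] * (1.0 - w) + tab[2 * g + 1, i0 + 1] * w
        dy[gi] = (inf - y[gi]) * invtau
    Csub = y[15]
    Cai = y[16]
    Cansr = y[17]
    Cajsr = y[18]
    # fCa (Ca-dependent I_CaL inactivation)
    fca_inf = sh[35] / (sh[35] + Csub)
    dy[3] = (fca_inf - y[3]) * sh[34] / fca_inf

    E_Na = sh[38]
    E_K = sh[39]
    E_Ks = sh[40]
    # currents, pA/pF
    i_CaL = pc[0] * (V - sh[1]) * y[1] * y[2] * y[3]
    i_CaT = pc[1] * (V - sh[2]) * y[4] * y[5]
    i_Kr = pc[2] * (V - E_K) * (0.6 * y[6] + 0.4 * y[7]) * y[8]
    i_Ks = pc[3] * (V - E_Ks) * y[9] * y[9]
    i_to = pc[4] * (V - E_K) * y[10] * y[11]
    i_sus = pc[5] * (V - E_K) * y[11]
    y2 = y[12] * y[12]
    i_f = pc[6] * y2 * (0.3833 * (V - E_Na) + 0.6167 * (V - E_K))
    i_st = pc[7] * (V - sh[3]) * y[13] * y[14]
    i_bNa = pc[8] * (V - E_Na)
    i_bCa = pc[9] * (V - sh[1])
    kach = tab[_ROW_KACH, i0] * (1.0 - w) + tab[_ROW_KACH, i0 + 1] * w
    i_KACh = pc[10] * (V - E_K) * kach
    inak_v = tab[_ROW_INAK_V, i0] * (1.0 - w) + tab[_ROW_INAK_V, i0 + 1] * w
    i_NaK = pc[13] * inak_v
    # NCX
    exp_pos = tab[_ROW_EXP_POS, i0] * (1.0 - w) + tab[_ROW_EXP_POS, i0 + 1] * w
    exp_neg = tab[_ROW_EXP_NEG, i0] * (1.0 - w) + tab[_ROW_EXP_NEG, i0 + 1] * w
    exp_qci = tab[_ROW_EXP_QCI, i0] * (1.0 - w) + tab[_ROW_EXP_QCI, i0 + 1] * w
    k43 = sh[41]
    k34 = sh[42]
    k21 = sh[43]
    k23 = sh[44] * exp_neg
    di = 1.0 + Csub / sh[36] * (1.0 + exp_qci + sh[46]) + sh[45]
    k12 = Csub / sh[36] * exp_qci / di
    k14 = sh[47] * exp_pos / di
    k41 = exp_neg
    k32 = exp_pos
    x1 = k41 * k34 * (k23 + k21) + k21 * k32 * (k43 + k41)
    x2 = k32 * k43 * (k14 + k12) + k41 * k12 * (k34 + k32)
    x3 = k14 * k43 * (k23 + k21) + k12 * k23 * (k43 + k41)
    x4 = k23 * k34 * (k14 + k12) + k14 * k21 * (k34 + k32)
    i_NaCa = pc[11] * (x2 * k21 - x1 * k12) / (x1 + x2 + x3 + x4)

    i_tot = (i_CaL + i_CaT + i_Kr + i_Ks + i_to + i_sus + i_f + i_st
             + i_bNa + i_bCa + i_KACh + i_NaK + i_NaCa)
    dy[0] = -i_tot + coup_dv

    # RyR gating
    ratio = sh[11] / Cajsr if Cajsr > 1e-12 else 1e12
    kCaSR = sh[12] - (sh[12] - sh[13]) / (1.0 + ratio ** sh[14])
    koSRCa = sh[7] / kCaSR
    kiSRCa = sh[8] * kCaSR
    R_ = y[19]
    O_ = y[20]
    I_ = y[21]
    RI_ = y[22]
    c2 = Csub * Csub
    dy[19] = sh[10] * RI_ - kiSRCa * Csub * R_ - (koSRCa * c2 * R_ - sh[9] * O_)
    dy[20] = koSRCa * c2 * R_ - sh[9] * O_ - (kiSRCa * Csub * O_ - sh[10] * I_)
    dy[21] = kiSRCa * Csub * O_ - sh[10] * I_ - (sh[9] * I_ - koSRCa * c2 * RI_)
    dy[22] = sh[9] * I_ - koSRCa * c2 * RI_ - (sh[10] * RI_ - kiSRCa * Csub * R_)

    # buffers
    dfTC = sh[19] * Cai * (1.0 - y[23]) - sh[20] * y[23]
    dfTMC = sh[21] * Cai * (1.0 - y[24] - y[25]) - sh[22] * y[24]
    dfTMM = sh[23] * sh[29] * (1.0 - y[24] - y[25]) - sh[24] * y[25]
    dfCMi = sh[25] * Cai * (1.0 - y[26]) - sh[26] * y[26]
    dfCMs = sh[25] * Csub * (1.0 - y[27]) - sh[26] * y[27]
    dfCQ = sh[27] * Cajsr * (1.0 - y[28]) - sh[28] * y[28]
    dy[23] = dfTC
    dy[24] = dfTMC
    dy[25] = dfTMM
    dy[26] = dfCMi
    dy[27] = dfCMs
    dy[28] = dfCQ

    # Ca fluxes
    j_rel = pc[12] * O_ * (Cajsr - Csub)
    j_up = pc[14] / (1.0 + sh[4] / (Cai if Cai > 1e-12 else 1e-12))
    j_tr = (Cansr - Cajsr) / sh[5]
    j_dif = (Csub - Cai) / sh[6]
    C_m = sh[0]
    i_ca_net = (i_CaL + i_CaT + i_bCa - 2.0 * i_NaCa) * C_m
    V_sub = sh[30]
    dy[15] = (j_rel * sh[33] / V_sub
              - i_ca_net / (2.0 * sh[48] * V_sub)
              - j_dif - sh[15] * dfCMs)
    dy[16] = ((j_dif * V_sub - j_up * sh[32]) / sh[31]
              - (sh[15] * dfCMi + sh[16] * dfTC + sh[17] * dfTMC))
    dy[17] = j_up - j_tr * sh[33] / sh[32]
    dy[18] = j_tr - j_rel - sh[18] * dfCQ


@njit(cache=True)
def _coupling(y, indptr, indices, inv_R, coef, out):
    n = y.shape[0]
    for i in range(n):
        acc = 0.0
        Vi = y[i, 0]
        for ptr in range(indptr[i], indptr[i + 1]):
            acc += (y[indices[ptr], 0] - Vi) * inv_R[ptr]
        out[i] = acc * coef[i]


@njit(cache=True)
def _run(y, per_cell, sh, tab, indptr, indices, inv_R,
         n_steps, dt, record_stride, v_rec, ap_times, ap_counts,
         ap_thresh, ap_refract, use_rk4):
    n = y.shape[0]
    coef = np.empty(n)
    for i in range(n):
        coef[i] = 1000.0 / sh[0]  # nA -> pA, per pF
    coup = np.zeros(n)
    dy = np.empty((n, N_STATES))
    last_ap = np.full(n, -1e18)
    v_prev = np.empty(n)
    if use_rk4:
        k1 = np.empty((n, N_STATES))
        k2 = np.empty((n, N_STATES))
        k3 = np.empty((n, N_STATES))
        k4 = np.empty((n, N_STATES))
        ytmp = np.empty((n, N_STATES))
    rec_i = 0
    for i in range(n):
        v_rec[i, 0] = y[i, 0]
    rec_i = 1
    for step in range(1, n_steps + 1):
        for i in range(n):
            v_prev[i] = y[i, 0]
        if use_rk4:
            _coupling(y, indptr, indices, inv_R, coef, coup)
            for i in range(n):
                _deriv(y[i], per_cell[i], sh, tab, coup[i], k1[i])
            for i in range(n):
                for j in range(N_STATES):
                    ytmp[i, j] = y[i, j] + 0.5 * dt * k1[i, j]
            _coupling(ytmp, indptr, indices, inv_R, coef, coup)
            for i in range(n):
                _deriv(ytmp[i], per_cell[i], sh, tab, coup[i], k2[i])
            for i in range(n):
                for j in range(N_STATES):
                    ytmp[i, j] = y[i, j] + 0.5 * dt * k2[i, j]
            _coupling(ytmp, indptr, indices, inv_R, coef, coup)
            for i in range(n):
                _deriv(ytmp[i], per_cell[i], sh, tab, coup[i], k3[i])
            for i in range(n):
                for j in range(N_STATES):
                    ytmp[i, j] = y[i, j] + dt * k3[i, j]
            _coupling(ytmp, indptr, indices, inv_R, coef, coup)
            for i in range(n):
                _deriv(ytmp[i], per_cell[i], sh, tab, coup[i], k4[i])
            for i in range(n):
                for j in range(N_STATES):
                    y[i, j] += dt / 6.0 * (k1[i, j] + 2.0 * k2[i, j]
                                           + 2.0 * k3[i, j] + k4[i, j])
        else:
            _coupling(y, indptr, indices, inv_R, coef, coup)
            for i in range(n):
                _deriv(y[i], per_cell[i], sh, tab, coup[i], dy[i])
            for i in range(n):
                for j in range(N_STATES):
                    y[i, j] += dt * dy[i, j]
        t_now = step * dt
        for i in range(n):
            v_new = y[i, 0]
            if not (-200.0 < v_new < 200.0) or v_new != v_new:
                return step, i  # blow-up
            if (v_prev[i] < ap_thresh <= v_new
                    and t_now - last_ap[i] >= ap_refract):
                frac = (ap_thresh - v_prev[i]) / (v_new - v_prev[i])
                t_ap = (step - 1) * dt + frac * dt
                c = ap_counts[i]
                if c < ap_times.shape[1]:
                    ap_times[i, c] = t_ap
                    ap_counts[i] = c + 1
                last_ap[i] = t_ap
        if step % record_stride == 0 and rec_i < v_rec.shape[1]:
            for i in range(n):
                v_rec[i, rec_i] = y[i, 0]
            rec_i += 1
    return 0, -1


def integrate(states: np.ndarray,
              param_sets: list,
              cell_param_idx: np.ndarray,
              duration_ms: float,
              dt: float,
              record_stride: int = 20,
              indptr: np.ndarray | None = None,
              indices: np.ndarray | None = None,
              inv_R: np.ndarray | None = None,
              ap_thresh: float = -20.0,
              ap_refract: float = 50.0,
              method: str = "euler"):
    """Integrate N cells; returns (t_rec_ms, V_rec (N, n_rec), ap_times list).

    ``states`` is modified in place to the final state. Raises RuntimeError
    naming the cell and step on numerical blow-up.
    """
    states = np.ascontiguousarray(states, dtype=np.float64)
    n = states.shape[0]
    per_cell, sh, tab = pack_params(param_sets, cell_param_idx)
    if indptr is None:
        indptr = np.zeros(n + 1, dtype=np.int64)
        indices = np.zeros(0, dtype=np.int64)
        inv_R = np.zeros(0, dtype=np.float64)
    n_steps = int(round(duration_ms / dt))
    n_rec = n_steps // record_stride + 1
    v_rec = np.empty((n, n_rec))
    max_ap = int(duration_ms / ap_refract) + 16
    ap_times = np.zeros((n, max_ap))
    ap_counts = np.zeros(n, dtype=np.int64)
    if method not in ("euler", "rk4"):
        raise ValueError(f"unknown method {method!r}")
    bad_step, bad_cell = _run(
        states, per_cell, sh, tab,
        np.asarray(indptr, dtype=np.int64),
        np.asarray(indices, dtype=np.int64),
        np.asarray(inv_R, dtype=np.float64),
        n_steps, dt, record_stride, v_rec, ap_times, ap_counts,
        ap_thresh, ap_refract, method == "rk4")
    if bad_step:
        raise RuntimeError(
            f"numerical blow-up in cell {bad_cell} at step {bad_step} "
            f"(t = {bad_step * dt:.3f} ms)")
    t_rec = np.arange(n_rec) * (dt * record_stride)
    aps = [ap_times[i, :ap_counts[i]].copy() for i in range(n)]
    return t_rec, v_rec, aps
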