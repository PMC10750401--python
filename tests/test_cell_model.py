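"""Single-cell coupled-clock model: derivatives, autonomic modes,
simulation and firing classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pacenet import (
    CellParameters, apply_autonomic, basal_mode, beta_ar_mode, chr_mode,
    classify_firing, default_initial_state, derivatives, simulate_cell,
)
from pacenet.cell_model import STATE_NAMES, N_STATES, _CONC_IDX, _GATE_IDX
from pacenet import _engine


def zeroed_params() -> CellParameters:
    """No transmembrane or inter-compartment flux at all."""
    return CellParameters(
        g_CaL=0.0, g_CaT=0.0, g_Kr=0.0, g_Ks=0.0, g_to=0.0, g_sus=0.0,
        g_if=0.0, g_st=0.0, g_b_Na=0.0, g_b_Ca=0.0, g_KACh=0.0,
        i_NaK_max=0.0, k_NaCa=0.0, P_up=0.0, k_s=0.0,
        tau_dif_Ca=1e12, tau_tr=1e12,
        CM_tot=0.0, TC_tot=0.0, TMC_tot=0.0, CQ_tot=0.0)


class TestDerivatives:
    def test_zero_flux_limit(self):
        """With every conductance and pump zeroed, the membrane potential
        and all Ca concentrations are frozen (gates may still relax)."""
        y = default_initial_state()
        d = derivatives(y, zeroed_params())
        assert d[0] == 0.0
        # inter-compartment transfer is suppressed by huge time constants,
        # leaving only O(1e-12) numerical residue
        assert np.allclose(d[list(_CONC_IDX)], 0.0, atol=1e-11)

    def test_zero_flux_voltage_constant_under_integration(self):
        p = zeroed_params()
        y = default_initial_state()[None, :].copy()
        _engine.integrate(y, [p], np.zeros(1, dtype=np.int64),
                          duration_ms=100.0, dt=0.01, record_stride=10000)
        assert y[0, 0] == pytest.approx(default_initial_state()[0], abs=1e-12)

    def test_rejects_non_finite_state(self):
        y = default_initial_state()
        y[STATE_NAMES.index("Ca_sub")] = np.nan
        with pytest.raises(ValueError, match="Ca_sub"):
            derivatives(y, CellParameters())

    def test_engine_step_matches_reference_derivatives(self):
        """One forward-Euler step through the table-based kernel agrees
        with the exact NumPy evaluation of the same equations."""
        p = CellParameters()
        y0 = default_initial_state()
        dt = 0.002
        ref = y0 + dt * derivatives(y0, p)
        y = y0[None, :].copy()
        _engine.integrate(y, [p], np.zeros(1, dtype=np.int64),
                          duration_ms=dt, dt=dt, record_stride=10)
        # table interpolation error is ~1e-8 relative on the gate rates
        np.testing.assert_allclose(y[0], ref, rtol=1e-6, atol=1e-12)

    def test_derivative_regression(self):
        """Derivative vector at the default initial state is locked to
        guard the equation set against accidental edits."""
        d = derivatives(default_initial_state(), CellParameters())
        expected = _FROZEN_DERIVATIVE
        np.testing.assert_allclose(d, expected, rtol=1e-9)


class TestAutonomicModes:
    def test_basal_is_identity(self):
        p = CellParameters()
        assert apply_autonomic(p, basal_mode()) == p

    def test_input_never_mutated(self):
        p = CellParameters()
        before = p.as_dict()
        apply_autonomic(p, beta_ar_mode(1.0))
        assert p.as_dict() == before

    def test_chr_enables_ikach(self):
        p = apply_autonomic(CellParameters(), chr_mode(1.0))
        assert p.g_KACh > 0.0

    def test_beta_ar_scales_up(self):
        p = CellParameters()
        q = apply_autonomic(p, beta_ar_mode(1.0))
        assert q.P_up > p.P_up and q.g_CaL > p.g_CaL and q.g_Ks > p.g_Ks

    def test_unknown_mode_rejected(self):
        from pacenet import AutonomicMode
        with pytest.raises(ValueError):
            AutonomicMode(mode="vagal")

    def test_basal_with_scalings_rejected(self):
        from pacenet import AutonomicMode
        with pytest.raises(ValueError):
            AutonomicMode(mode="basal", effector_scalings={"P_up": 2.0})

    def test_beta_ar_accelerates_isolated_cell(self, lrm, lrm_basal_run):
        """Sympathetic stimulation raises the isolated-cell rate."""
        _, _, ap_b = lrm_basal_run
        _, _, ap_s = simulate_cell(lrm, beta_ar_mode(1.0), duration=12.0,
                                   dt=0.005, record_stride=100)
        rate_b = classify_firing(ap_b, 10000.0).mean_rate
        rate_s = classify_firing(ap_s, 10000.0).mean_rate
        assert rate_s > rate_b


class TestSimulateCell:
    def test_lrm_fires_regularly(self, lrm_basal_run):
        """The lower-rate-module parameter point lies in the firing
        region of the basal state."""
        _, _, ap = lrm_basal_run
        fc = classify_firing(ap, 10000.0)
        assert fc.label == "regular"
        assert 2.0 < fc.mean_rate < 3.5

    def test_duration_shorter_than_transient_rejected(self, lrm):
        with pytest.raises(ValueError):
            simulate_cell(lrm, duration=1.0, transient_discard=2.0)

    def test_dt_convergence(self, lrm):
        """Halving the step changes the measured cycle length by <0.5%."""
        cls = []
        for dt in (0.005, 0.0025):
            _, _, ap = simulate_cell(lrm, duration=8.0, dt=dt,
                                     record_stride=1000)
            cls.append(np.mean(np.diff(ap)))
        assert abs(cls[1] - cls[0]) / cls[0] < 0.005

    def test_rk4_agrees_with_euler(self, lrm):
        """The two integrators give the same cycle length at a step
        size where both are well converged."""
        cls = []
        for method in ("euler", "rk4"):
            _, _, ap = simulate_cell(lrm, duration=6.0, dt=0.01,
                                     record_stride=1000, method=method)
            cls.append(np.mean(np.diff(ap)))
        assert cls[1] == pytest.approx(cls[0], rel=1e-4)

    def test_state_bounds_along_trajectory(self, lrm):
        """Gating variables stay in [0,1] and concentrations stay
        non-negative over a long trajectory."""
        y = default_initial_state()[None, :].copy()
        _engine.integrate(y, [lrm], np.zeros(1, dtype=np.int64),
                          duration_ms=6000.0, dt=0.005, record_stride=10 ** 9)
        gates = y[0, list(_GATE_IDX)]
        concs = y[0, list(_CONC_IDX)]
        assert np.all(gates >= 0.0) and np.all(gates <= 1.0)
        assert np.all(concs >= 0.0)

    def test_rate_monotone_in_gcal(self):
        """Across the firing region, the basal rate does not decrease
        with the L-type conductance (spot check, 5 grid points)."""
        rates = []
        for g in (0.36, 0.42, 0.48, 0.54, 0.60):
            _, _, ap = simulate_cell(CellParameters(g_CaL=g, P_up=12.0),
                                     duration=10.0, dt=0.005,
                                     record_stride=1000)
            rates.append(classify_firing(ap, 8000.0).mean_rate)
        rates = np.asarray(rates)
        assert np.all(np.diff(rates) > -0.02 * rates[:-1])

    def test_blowup_reports_step(self, lrm):
        y = default_initial_state()[None, :].copy()
        y[0, 0] = np.inf
        with pytest.raises(RuntimeError, match="cell 0"):
            _engine.integrate(y, [lrm], np.zeros(1, dtype=np.int64),
                              duration_ms=10.0, dt=0.005)


class TestClassifyFiring:
    def test_empty_train_is_silent(self):
        fc = classify_firing(np.array([]), 3000.0)
        assert fc.label == "silent" and fc.mean_rate == 0.0

    def test_exact_periodicity_is_regular(self):
        t = np.arange(0.0, 3000.1, 300.0)
        fc = classify_firing(t, 3000.0)
        assert fc.label == "regular"
        assert fc.mean_rate == pytest.approx(1000.0 / 300.0, rel=1e-9)
        assert fc.cv_cycle_length == 0.0

    def test_alternans_is_chaotic(self):
        """Alternating 250/450 ms cycles: cv = 100/350 = 0.286 > 0.05."""
        cls = np.tile([250.0, 450.0], 5)
        t = np.concatenate([[0.0], np.cumsum(cls)])
        fc = classify_firing(t, 4000.0)
        assert fc.label == "chaotic"
        assert fc.cv_cycle_length == pytest.approx(100.0 / 350.0, rel=1e-9)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            classify_firing(np.array([0.0, 300.0]), 1000.0)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            classify_firing(np.array([300.0, 0.0, 600.0]), 3000.0)

    @given(cl=st.floats(min_value=150.0, max_value=1000.0),
           n=st.integers(min_value=3, max_value=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_periodic_trains_always_regular(self, cl, n):
        """Any strictly periodic train classifies regular with the
        rate implied by its cycle length."""
        t = cl * np.arange(n)
        fc = classify_firing(t, max(2000.0, cl * n), cv_threshold=0.05)
        assert fc.label == "regular"
        assert fc.mean_rate == pytest.approx(1000.0 / cl, rel=1e-6)


# locked at package creation from the reference NumPy evaluation
_FROZEN_DERIVATIVE = np.array([
    6.2078835415035394e-01, 6.0370749978869772e-04, -8.9040600754152356e-04,
    -3.0659999999999967e-03, 1.7389858889718821e-02, -2.2232327667019568e-02,
    -1.0263888113174898e-03, -1.0047092294507504e-03, -3.4757068656891640e-02,
    -7.2318975620744411e-05, 5.9042926400911721e-03, -1.2514847855461665e-03,
    8.5520995004989629e-04, 1.2345587090244907e-02, 4.6025810759159469e-05,
    -9.4500639570424330e-03, 1.2961638858008010e-04, -1.0136554621848737e-03,
    -8.0234044424999995e-01, 6.0222237298633292e-04, 2.4642958692676728e-07,
    6.6015812591541096e-08, -6.0253481838585122e-04, -2.1760000000000009e-04,
    -1.7224999999999996e-03, -4.0433999999999981e-01, 1.7919999999999742e-04,
    9.2827029999999894e-03, 8.2876800000000000e-02,
])
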