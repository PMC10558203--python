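"""Single-compartment forward model: protocol building, opsin gating,
voltage and pH integration, fluorescence rendering, movie rasterization."""

import dataclasses

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

import optoacid as oa
from optoacid.core_model import (
    ProtocolError,
    StabilityError,
    ph_rate,
    proton_current_pA,
    voltage_stability_bound,
)

from conftest import dff_of


# ---------------------------------------------------------------------------
# Stimulus protocol
# ---------------------------------------------------------------------------

class TestBuildProtocol:
    def test_canonical_interleaved_run(self, fig1_protocol):
        stim = [e for e in fig1_protocol.epochs if e.channel == "stim"]
        image = [e for e in fig1_protocol.epochs if e.channel == "image"]
        assert len(stim) == 100
        assert all(e.duration == 0.5 for e in stim)
        # imaging continues through recovery at the same cadence
        assert len(image) == 200
        assert fig1_protocol.total_duration == pytest.approx(300.0)

    def test_short_run_without_recovery(self):
        p = oa.build_protocol(0.5, 1.0, 60.0, 0.0)
        assert sum(e.channel == "stim" for e in p.epochs) == 40
        assert p.total_duration == pytest.approx(60.0)

    def test_pure_imaging_protocol(self):
        p = oa.build_protocol(0.0, 1.0, 10.0, 0.0)
        assert sum(e.channel == "stim" for e in p.epochs) == 0
        assert p.total_duration == pytest.approx(10.0)

    def test_negative_argument_rejected(self):
        with pytest.raises(ProtocolError):
            oa.build_protocol(-0.5, 1.0, 10.0, 0.0)
        with pytest.raises(ProtocolError):
            oa.build_protocol(0.0, 0.0, 10.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(stim_s=st.floats(0.0, 2.0), image_s=st.floats(0.1, 3.0),
           active=st.floats(1.0, 100.0), recovery=st.floats(0.0, 100.0))
    def test_epochs_sorted_contiguous_positive(self, stim_s, image_s,
                                               active, recovery):
        assume(active >= stim_s + image_s)
        p = oa.build_protocol(stim_s, image_s, active, recovery)
        t = 0.0
        for ep in p.epochs:
            assert ep.duration > 0
            assert ep.t_start == pytest.approx(t)
            t = ep.t_end
        assert p.total_duration == pytest.approx(
            sum(ep.duration for ep in p.epochs))

    def test_blue_dose_accumulates_only_during_stim(self, fig1_protocol):
        dose = fig1_protocol.blue_dose_at(np.array([0.0, 150.0, 300.0]))
        expected = 100 * 0.5 * oa.core_model.DEFAULT_STIM_INTENSITY * 1e-3
        assert dose[0] == 0.0
        assert dose[1] == pytest.approx(expected)
        assert dose[2] == pytest.approx(expected)  # no blue in recovery


# ---------------------------------------------------------------------------
# Opsin gating
# ---------------------------------------------------------------------------

class TestOpsinGate:
    def test_half_activation_at_epd50(self):
        a = oa.CHERIFF_LIKE.steady_state_activation(oa.CHERIFF_LIKE.EPD50,
                                                    488.0)
        assert a == pytest.approx(0.5)

    def test_saturation_limit(self):
        opsin = dataclasses.replace(oa.CHERIFF_LIKE,
                                    desensitization_ratio=1.0)
        t = np.arange(0.0, 0.5, 1e-4)
        a = oa.opsin_gate(opsin, 100 * opsin.EPD50, 488.0, t)
        assert a[-1] == pytest.approx(1.0, abs=0.01)

    def test_single_exponential_closure(self):
        opsin = dataclasses.replace(oa.CHERIFF_LIKE,
                                    desensitization_ratio=1.0)
        tau_off_s = opsin.tau_off * 1e-3
        t = np.array([0.0, tau_off_s])
        a = oa.opsin_gate(opsin, 500.0, 488.0, t,
                          light_on=np.zeros(2, dtype=bool), a0=1.0)
        assert a[1] == pytest.approx(np.exp(-1.0), abs=1e-6)

    def test_unknown_wavelength_is_an_error(self):
        with pytest.raises(ValueError, match="absent from the action"):
            oa.CHERIFF_LIKE.steady_state_activation(500.0, 450.0)

    def test_desensitization_sag_to_steady_ratio(self):
        t = np.arange(0.0, 10.0, 1e-3)
        a = oa.opsin_gate(oa.CHERIFF_LIKE, 5000.0, 488.0, t)
        peak, steady = a.max(), a[-1]
        assert steady / peak == pytest.approx(
            oa.CHERIFF_LIKE.desensitization_ratio, rel=0.02)


# ---------------------------------------------------------------------------
# Voltage step
# ---------------------------------------------------------------------------

class TestStepVoltage:
    def test_relaxes_to_potassium_reversal_without_light(self, phys):
        V, dt = 0.0, 1e-4
        for _ in range(5000):
            V = oa.step_voltage(V, 0.0, oa.CHERIFF_LIKE, phys, dt)
        assert V == pytest.approx(phys.E_K, abs=1e-6)

    def test_dominant_opsin_conductance_pulls_to_its_reversal(self, phys):
        opsin = dataclasses.replace(oa.CHERIFF_LIKE, g_max=2000.0)
        V, dt = phys.E_K, 1e-6
        for _ in range(50000):
            V = oa.step_voltage(V, 1.0, opsin, phys, dt)
        assert V == pytest.approx(opsin.E_ops, abs=0.1)

    def test_conductance_weighted_steady_state(self, phys):
        opsin = dataclasses.replace(oa.CHERIFF_LIKE, g_max=phys.g_leak,
                                    E_ops=10.0)
        V, dt = phys.E_K, 1e-4
        for _ in range(200000):
            V = oa.step_voltage(V, 0.5, opsin, phys, dt)
        assert V == pytest.approx((-70.0 * 1 + 10.0 * 0.5) / 1.5, abs=1e-4)
        assert V == pytest.approx(-43.3333, abs=1e-3)

    def test_stability_bound_violation_names_the_bound(self, phys):
        bound = voltage_stability_bound(1.0, oa.CHERIFF_LIKE, phys)
        with pytest.raises(StabilityError, match="stability bound"):
            oa.step_voltage(-70.0, 1.0, oa.CHERIFF_LIKE, phys, 2 * bound)

    def test_explicit_euler_matches_closed_form(self, phys):
        """Constant activation: the two-conductance ODE has a single-
        exponential solution; Euler at dt = 1e-4 * C/g_tot tracks it to
        relative error < 1e-4."""
        a = 1.0
        opsin = oa.CHERIFF_LIKE
        g_tot = phys.g_leak + opsin.g_max * a
        V_inf = (phys.g_leak * phys.E_K + opsin.g_max * a * opsin.E_ops) / g_tot
        tau_s = phys.C_m / g_tot * 1e-3
        dt = 1e-4 * tau_s
        V = phys.E_K
        n = int(round(3 * tau_s / dt))
        for _ in range(n):
            V = oa.step_voltage(V, a, opsin, phys, dt)
        exact = V_inf + (phys.E_K - V_inf) * np.exp(-n * dt / tau_s)
        assert abs(V - exact) / abs(exact) < 1e-4


# ---------------------------------------------------------------------------
# pH step
# ---------------------------------------------------------------------------

class TestStepPH:
    def test_no_proton_pathway_holds_resting_pH(self, soma, phys):
        opsin = dataclasses.replace(oa.CHERIFF_LIKE, f_H=0.0)
        pH = phys.pH_rest
        for _ in range(1000):
            pH = oa.step_pH(pH, -30.0, 0.8, opsin, soma, phys, 1e-3)
        assert pH == pytest.approx(phys.pH_rest, abs=1e-12)

    def test_surface_to_volume_sets_initial_rate_ratio(self, phys):
        cyl = oa.CompartmentGeometry("cylinder", 1.0, 50.0)
        sph = oa.CompartmentGeometry("sphere", 10.0)
        J = 0.05  # pA / um^2, identical membrane proton current density
        r_cyl = oa.initial_acidification_rate(J, cyl, phys)
        r_sph = oa.initial_acidification_rate(J, sph, phys)
        assert r_cyl / r_sph == pytest.approx((2.0 / 1.0) / (3.0 / 10.0),
                                              rel=1e-12)

    def test_recovery_is_first_order_toward_rest(self, soma, phys):
        """With no proton current the deficit decays with tau = 1/k_rec."""
        opsin = dataclasses.replace(oa.CHERIFF_LIKE, g_max=1e-12)
        pH0 = phys.pH_rest - 0.5
        dt = 1e-3
        tau = 1.0 / phys.k_rec
        n = int(round(tau / dt))
        pH = pH0
        for _ in range(n):
            pH = oa.step_pH(pH, -70.0, 0.0, opsin, soma, phys, dt)
        assert (phys.pH_rest - pH) == pytest.approx(0.5 * np.exp(-1.0),
                                                    rel=1e-3)

    def test_nonphysical_buffering_rejected(self, soma):
        with pytest.raises(ValueError):
            oa.PhysiologyParams(beta_buff=-1.0)

    def test_proton_bookkeeping_matches_analytic_integral(self, soma):
        """k_rec = 0, constant inward current: total pH change equals
        -I*t/(F*Vol*beta) within integrator tolerance."""
        phys = oa.PhysiologyParams(k_rec=0.0)
        opsin = oa.CHERIFF_LIKE
        V, a, dt, n = -40.0, 0.6, 1e-3, 5000
        pH = phys.pH_rest
        for _ in range(n):
            pH = oa.step_pH(pH, V, a, opsin, soma, phys, dt)
        I_H = proton_current_pA(V, a, opsin)
        expected = I_H * 1e-12 * n * dt / (
            oa.core_model.FARADAY_C_PER_MOL * soma.volume_um3 * 1e-15
            * phys.beta_buff)
        assert (pH - phys.pH_rest) == pytest.approx(expected, abs=1e-6)


# ---------------------------------------------------------------------------
# Fluorescence rendering
# ---------------------------------------------------------------------------

class TestRenderFluorescence:
    def test_half_protonation_point(self, fig1_protocol):
        sensor = oa.SensorParams(artifact_rate=0.0, noise_sd=0.0)
        F = oa.render_fluorescence(np.array([sensor.pKa]), np.array([0.0]),
                                   fig1_protocol, sensor)
        assert F[0] == pytest.approx(sensor.F_max / 2)

    def test_constant_pH_without_artifact_gives_flat_dff(self, fig1_protocol):
        sensor = oa.SensorParams(artifact_rate=0.0, noise_sd=0.0)
        t = np.linspace(0, 300, 301)
        F = oa.render_fluorescence(np.full_like(t, 7.3), t, fig1_protocol,
                                   sensor)
        np.testing.assert_allclose((F - F[0]) / F[0], 0.0, atol=1e-12)

    def test_control_artifact_reaches_plus_011_dff(self, control_trace):
        """Opsin-negative control under the canonical protocol shows the
        +0.11 dF/F blue-light photoactivation artifact at 150 s."""
        i = np.searchsorted(control_trace.t, 150.0)
        assert dff_of(control_trace)[i] == pytest.approx(0.11, abs=0.005)
        # pH itself never moved
        assert np.ptp(control_trace.pH) < 1e-9


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------

class TestSimulateCell:
    def test_cheriff_defaults_acidify_within_reported_envelope(
            self, cheriff_trace):
        i = np.searchsorted(cheriff_trace.t, 150.0)
        drop = 7.3 - cheriff_trace.pH[i]
        assert 0.3 < drop < 0.8

    def test_proton_tight_opsin_leaves_pH_unchanged(self, control_trace):
        i = np.searchsorted(control_trace.t, 150.0)
        assert abs(control_trace.pH[i] - 7.3) < 0.02

    def test_same_seed_is_bitwise_reproducible(self, fig1_protocol, soma,
                                               phys):
        sensor = oa.SensorParams(noise_sd=0.02)
        kw = dict(dt=2e-3, seed=7)
        a = oa.simulate_cell(soma, oa.CHERIFF_LIKE, sensor, phys,
                             fig1_protocol, **kw)
        b = oa.simulate_cell(soma, oa.CHERIFF_LIKE, sensor, phys,
                             fig1_protocol, **kw)
        np.testing.assert_array_equal(a.F, b.F)
        np.testing.assert_array_equal(a.pH, b.pH)
        np.testing.assert_array_equal(a.V, b.V)

    def test_pH_monotone_nonincreasing_during_continuous_light(self, soma):
        phys = oa.PhysiologyParams(k_rec=0.0)
        protocol = oa.StimulusProtocol((
            oa.Epoch(0.0, 30.0, "stim", 488.0, 500.0),))
        trace = oa.simulate_cell(soma, oa.CHERIFF_LIKE, oa.SensorParams(),
                                 phys, protocol, dt=1e-3)
        assert np.all(np.diff(trace.pH) <= 1e-15)

    def test_recovery_is_slow_and_incomplete(self, cheriff_trace):
        """After 150 s without stimulation the pH has recovered only
        partway toward rest, matching the slow extrusion kinetics."""
        i = np.searchsorted(cheriff_trace.t, 150.0)
        assert cheriff_trace.pH[-1] > cheriff_trace.pH[i]
        assert cheriff_trace.pH[-1] < 7.15


# ---------------------------------------------------------------------------
# Movie rasterization
# ---------------------------------------------------------------------------

def _flat_trace(F_value, duration=10.0, dt=0.1):
    n = int(duration / dt) + 1
    t = np.arange(n) * dt
    return oa.SimTrace(t=t, V=np.full(n, -70.0), pH=np.full(n, 7.3),
                       F=np.full(n, F_value),
                       epoch=np.full(n, "image"), metadata={})


class TestRenderMovie:
    def test_single_roi_constant_trace_zero_noise(self):
        tr = _flat_trace(500.0)
        shp = oa.ROIShape(1, (16, 16), 5.0)
        stack, t, labels, mask = oa.render_movie([tr], [shp], (32, 32))
        roi = mask == 1
        assert np.all(stack[:, roi] == 500.0)
        assert np.all(stack[:, ~roi] == 0.0)

    def test_two_rois_recover_their_traces_within_noise(self):
        rng = np.random.default_rng(0)
        tr1, tr2 = _flat_trace(400.0), _flat_trace(800.0)
        shapes = [oa.ROIShape(1, (10, 10), 5.0), oa.ROIShape(2, (10, 26), 5.0)]
        sd = 10.0
        stack, t, labels, mask = oa.render_movie(
            [tr1, tr2], shapes, (20, 40), seed=3, pixel_noise_sd=sd)
        for lbl, val in [(1, 400.0), (2, 800.0)]:
            sel = mask == lbl
            means = stack[:, sel].mean(axis=1)
            tol = 4 * sd / np.sqrt(sel.sum())
            assert np.all(np.abs(means - val) < tol)

    def test_overlapping_rois_rejected(self):
        tr = _flat_trace(1.0)
        shapes = [oa.ROIShape(1, (10, 10), 5.0), oa.ROIShape(2, (10, 13), 5.0)]
        with pytest.raises(ValueError, match="overlap"):
            oa.render_movie([tr, tr], shapes, (20, 20))

    def test_empty_layout_gives_background_stack(self):
        stack, t, labels, mask = oa.render_movie([], [], (8, 8))
        assert np.all(stack == 0.0)
        assert np.all(mask == 0)
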