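"""Biomarker analyses: exponential and Boltzmann fit recovery, G-V and
rectification construction, protective currents, AP-clamp metrics and
reversal-potential estimation."""

import numpy as np
import pytest

import hergkin as hk
import hergkin.biomarkers as bm
from hergkin.biomarkers import BiomarkerError, NoReversalError


@pytest.fixture(scope="module")
def wt_deactivation_trace():
    wt = hk.load_parameters("WT")
    proto = hk.build_deactivation_protocol(sampling_ms=0.5)
    cell = hk.CellConfig.hek_37C(g_kr_uS=0.0847)
    trace = hk.simulate_current(wt, proto, cell, hk.SimulationSettings(sampling_ms=0.5))
    return trace, proto, cell


class TestExponentialFits:
    def test_mono_exponential_exact_recovery(self):
        t = np.arange(0, 400, 0.5)
        y = 1.7 * np.exp(-t / 50.0)
        fit = bm.fit_exponential_decay(y, n_terms=1, t=t)
        assert fit.tau_fast_ms == pytest.approx(50.0, rel=1e-3)
        assert fit.amp_fast_nA == pytest.approx(1.7, rel=1e-3)

    def test_biexponential_recovers_deactivation_constants(self):
        # generating values: fast/slow deactivation time constants and the
        # fast-fraction reported for the fast-deactivating variant at 37 C
        t = np.arange(0, 750, 0.5)
        y = 0.93 * np.exp(-t / 43.5) + 0.07 * np.exp(-t / 539.8)
        fit = bm.fit_exponential_decay(y, n_terms=2, t=t)
        assert fit.tau_fast_ms == pytest.approx(43.5, rel=0.01)
        assert fit.tau_slow_ms == pytest.approx(539.8, rel=0.01)
        assert fit.fast_fraction == pytest.approx(0.93, rel=0.01)
        assert fit.tau_fast_ms <= fit.tau_slow_ms
        assert not fit.degenerate

    def test_constant_trace_flagged_degenerate(self):
        y = np.full(200, 3.3)
        fit = bm.fit_exponential_decay(y, n_terms=2)
        assert fit.degenerate

    def test_window_too_small_rejected(self):
        with pytest.raises(BiomarkerError):
            bm.fit_exponential_decay(np.ones(10), n_terms=1)

    def test_simulated_wt_tail_is_biexponential(self, wt_deactivation_trace):
        trace, proto, _ = wt_deactivation_trace
        # sweep at -110 mV tail: fit the 750-ms decay after the peak
        idx = [sw.metadata["tail_voltage_mV"] for sw in proto.sweeps].index(-110.0)
        offset = proto.sweep_offsets()[idx]
        fit = bm.fit_exponential_decay(
            trace, window=(offset + 260.0, offset + 1000.0), n_terms=2
        )
        assert 0 < fit.tau_fast_ms < fit.tau_slow_ms
        assert 0.0 < fit.fast_fraction <= 1.0


class TestBoltzmann:
    def test_generating_value_recovery(self):
        # activation midpoint/slope reported for WT at 37 C
        v = np.arange(-60, 45, 10.0)
        y = 1.0 / (1.0 + np.exp((-25.8 - v) / 6.2))
        fit = bm.fit_boltzmann(v, y)
        assert fit.v_half_mV == pytest.approx(-25.8, rel=1e-3)
        assert fit.k_mV == pytest.approx(6.2, rel=1e-3)

    def test_midpoint_value_is_half(self):
        fit = bm.BoltzmannFitResult(v_half_mV=-20.0, k_mV=8.0, scale=1.0)
        assert fit.value_at(-20.0) == pytest.approx(0.5)

    def test_sign_flip_mirrors_curve(self):
        up = bm.BoltzmannFitResult(-20.0, 8.0)
        down = bm.BoltzmannFitResult(-20.0, -8.0)
        for dv in (-15.0, 5.0, 30.0):
            assert up.value_at(-20.0 + dv) == pytest.approx(
                down.value_at(-20.0 - dv)
            )

    def test_too_few_points(self):
        with pytest.raises(BiomarkerError):
            bm.fit_boltzmann([0, 1, 2], [0.1, 0.5, 0.9])


@pytest.fixture(scope="module")
def wt_activation():
    wt = hk.load_parameters("WT")
    proto = hk.build_activation_protocol("oocyte_21C", sampling_ms=1.0)
    cell = hk.CellConfig.hek_37C(g_kr_uS=0.0847)
    trace = hk.simulate_current(
        wt, proto, cell, hk.SimulationSettings(sampling_ms=1.0)
    )
    return wt, proto, cell, trace


class TestGVFromTails:

    def test_series_maximum_is_one(self, wt_activation):
        _, proto, _, trace = wt_activation
        gv = bm.build_gv_from_tails(trace, proto)
        assert gv.g_norm.max() == 1.0

    def test_conductance_scaling_invariance(self, wt_activation):
        wt, proto, cell, trace = wt_activation
        doubled = hk.simulate_current(
            wt, proto,
            hk.CellConfig(g_kr_uS=2 * cell.g_kr_uS, e_k_mV=cell.e_k),
            hk.SimulationSettings(sampling_ms=1.0),
        )
        gv1 = bm.build_gv_from_tails(trace, proto)
        gv2 = bm.build_gv_from_tails(doubled, proto)
        assert np.allclose(gv1.g_norm, gv2.g_norm, atol=1e-12)

    def test_v_half_matches_open_probability_oracle(self, wt_activation):
        # oracle: apply the same truncated-step procedure to noise-free open
        # probabilities instead of currents
        wt, proto, cell, trace = wt_activation
        gv = bm.build_gv_from_tails(trace, proto)
        fit = bm.fit_boltzmann(gv.test_voltage_mV, gv.g_norm)
        gating = hk.simulate_gating(
            wt, proto, cell, hk.SimulationSettings(sampling_ms=1.0)
        )
        peaks = []
        ranges = bm.sweep_sample_ranges(proto, 1.0)
        for si in range(proto.n_sweeps):
            i, j = ranges[si][1]
            peaks.append(np.max(gating.open[i + 1:j]))
        peaks = np.array(peaks) / np.max(peaks)
        oracle = bm.fit_boltzmann(
            [sw.metadata["test_voltage_mV"] for sw in proto.sweeps], peaks
        )
        assert fit.v_half_mV == pytest.approx(oracle.v_half_mV, abs=1.0)

    def test_all_zero_tails_rejected(self, wt_activation):
        _, proto, _, trace = wt_activation
        zero = hk.CurrentTrace(
            trace.t0_ms, trace.dt_ms, np.zeros_like(trace.current_nA)
        )
        with pytest.raises(BiomarkerError):
            bm.build_gv_from_tails(zero, proto)


class TestLinearConductanceAndRectification:
    def test_exact_line(self):
        v = np.arange(-140, -100, 10.0)
        i = 0.08 * (v + 93.0)
        slope, _ = bm.estimate_linear_conductance(v, i)
        assert slope == pytest.approx(0.08, rel=1e-12)
        slope2, icpt = bm.estimate_linear_conductance(v, i + 0.5)
        assert slope2 == pytest.approx(0.08, rel=1e-12)

    def test_insufficient_points(self):
        with pytest.raises(BiomarkerError):
            bm.estimate_linear_conductance([-140, -130], [1.0, 2.0])

    def test_simulated_slope_matches_gating_oracle(self, wt_deactivation_trace):
        trace, proto, cell = wt_deactivation_trace
        iv = bm.fully_activated_iv(trace, proto)
        slope, _ = bm.estimate_linear_conductance(iv.voltage_mV, iv.current_nA)
        # oracle: regress g_kr * peak-open * driving force computed from the
        # gating trajectory (bypassing the current trace) over the same window
        wt = hk.load_parameters("WT")
        gating = hk.simulate_gating(
            wt, proto, cell, hk.SimulationSettings(sampling_ms=0.5)
        )
        ranges = bm.sweep_sample_ranges(proto, 0.5)
        volts, currents = [], []
        for si, sw in enumerate(proto.sweeps):
            v = sw.metadata["tail_voltage_mV"]
            if -140.0 <= v <= -110.0:
                i, j = ranges[si][1]
                peak_o = np.max(gating.open[i + 2:j])
                volts.append(v)
                currents.append(cell.g_kr_uS * peak_o * (v - cell.e_k))
        expected, _ = bm.estimate_linear_conductance(volts, currents)
        assert slope == pytest.approx(expected, rel=0.02)

    def test_ohmic_conductor_rectifies_to_one(self):
        v = np.arange(-140, 50, 10.0)
        i = 0.08 * 0.9 * (v + 93.0)
        rc = bm.compute_rectification(v, i, 0.08, 0.9, -93.0)
        good = ~np.isnan(rc.r)
        assert np.allclose(rc.r[good], 1.0)
        masked = np.abs(v + 93.0) < 5.0
        assert np.all(np.isnan(rc.r[masked]))

    def test_simulated_rectification_decays_at_positive_voltages(
        self, wt_deactivation_trace
    ):
        trace, proto, _ = wt_deactivation_trace
        iv = bm.fully_activated_iv(trace, proto)
        G, _ = bm.estimate_linear_conductance(iv.voltage_mV, iv.current_nA)
        rc = bm.compute_rectification(iv.voltage_mV, iv.current_nA, G, 1.0, -93.04)
        r = dict(zip(rc.voltages_mV, rc.r))
        assert r[-120.0] > 0.8
        assert r[0.0] < r[-60.0]
        assert r[40.0] < 0.2

    def test_rectification_midpoint_against_gating_oracle(self, wt_deactivation_trace):
        # The closed-form h-gate midpoint (ah = bh) sits near -33 mV for WT.
        # The tail-peak procedure reads out the peak of Oa*h during each
        # repolarizing step, which sits depolarized of the h-gate midpoint
        # because deactivation races recovery at strongly negative voltages;
        # the oracle is therefore the same procedure applied to noise-free
        # open probabilities.
        trace, proto, cell = wt_deactivation_trace
        wt = hk.load_parameters("WT")
        v_mid = np.log(wt.p7 / wt.p5) / (wt.p6 + wt.p8)
        assert v_mid == pytest.approx(-33.0, abs=1.0)
        iv = bm.fully_activated_iv(trace, proto)
        G, _ = bm.estimate_linear_conductance(iv.voltage_mV, iv.current_nA)
        rc = bm.compute_rectification(iv.voltage_mV, iv.current_nA, G, 1.0, -93.04)
        sel = ~np.isnan(rc.r)
        fit = bm.fit_boltzmann(rc.voltages_mV[sel], rc.r[sel])
        gating = hk.simulate_gating(
            wt, proto, cell, hk.SimulationSettings(sampling_ms=0.5)
        )
        ranges = bm.sweep_sample_ranges(proto, 0.5)
        volts, peaks = [], []
        for si, sw in enumerate(proto.sweeps):
            i, j = ranges[si][1]
            volts.append(sw.metadata["tail_voltage_mV"])
            peaks.append(np.max(gating.open[i + 2:j]))
        peaks = np.array(peaks) / np.max(peaks)
        oracle = bm.fit_boltzmann(volts, peaks)
        assert fit.v_half_mV == pytest.approx(oracle.v_half_mV, abs=2.0)
        assert fit.k_mV < 0  # availability falls with depolarization


@pytest.fixture(scope="module")
def protective_curves():
    proto = hk.build_premature_stimulation_protocol(sampling_ms=0.5)
    cell = hk.CellConfig.hek_37C(g_kr_uS=0.0847)
    settings = hk.SimulationSettings(sampling_ms=0.5)
    out = {}
    for name in ("WT", "R56Q", "R56Q+RPR"):
        trace = hk.simulate_current(hk.load_parameters(name), proto, cell, settings)
        out[name] = bm.measure_protective_currents(trace, proto, 0.0847)
    return out


class TestProtectiveCurrents:
    def test_synthetic_exponential_extrapolates_exactly(self):
        proto = hk.build_premature_stimulation_protocol(
            intervals=[0.0, 100.0], sampling_ms=0.5
        )
        dt = 0.5
        n = int(round(proto.duration_ms / dt))
        t = np.arange(n) * dt
        y = np.zeros(n)
        offsets = proto.sweep_offsets()
        for si, sw in enumerate(proto.sweeps):
            onset = offsets[si] + sw.metadata["step_onset_ms"]
            sel = (t >= onset) & (t < onset + 40.0)
            y[sel] = 2.0 * np.exp(-(t[sel] - onset) / 12.0)
        trace = hk.CurrentTrace(0.0, dt, y)
        curve = bm.measure_protective_currents(trace, proto, conductance_uS=1.0)
        assert curve.amplitudes_nA == pytest.approx([2.0, 2.0], rel=1e-3)
        assert not curve.fallback_used.any()

    @pytest.mark.parametrize("tau", [5.0, 50.0, 500.0])
    def test_extrapolation_exact_across_time_constants(self, tau):
        proto = hk.build_premature_stimulation_protocol(
            intervals=[50.0], sampling_ms=0.2
        )
        dt = 0.2
        n = int(round(proto.duration_ms / dt))
        t = np.arange(n) * dt
        y = np.zeros(n)
        onset = proto.sweep_offsets()[0] + proto.sweeps[0].metadata["step_onset_ms"]
        sel = (t >= onset) & (t < onset + 40.0)
        y[sel] = 1.5 * np.exp(-(t[sel] - onset) / tau)
        curve = bm.measure_protective_currents(
            hk.CurrentTrace(0.0, dt, y), proto, conductance_uS=1.0
        )
        assert curve.amplitudes_nA[0] == pytest.approx(1.5, rel=1e-3)

    def test_fast_deactivating_variant_has_smaller_protective_current(
        self, protective_curves
    ):
        ratio = protective_curves["R56Q"].amplitude_at(100.0) / protective_curves[
            "WT"
        ].amplitude_at(100.0)
        assert ratio < 1.0

    def test_fast_deactivating_variant_peaks_earlier(self, protective_curves):
        assert (
            protective_curves["R56Q"].peak_interval_ms
            < protective_curves["WT"].peak_interval_ms
        )

    def test_activator_kinetics_restore_protective_current(self, protective_curves):
        assert protective_curves["R56Q+RPR"].amplitude_at(
            100.0
        ) > protective_curves["R56Q"].amplitude_at(100.0)


class TestAPClampMetrics:
    def test_single_hump_trace(self):
        proto = hk.build_ap_clamp_protocol(n_beats=1, period_ms=1000.0,
                                           sampling_ms=0.5)
        dt = 0.5
        n = int(round(proto.duration_ms / dt))
        t = np.arange(n) * dt
        onset = proto.sweeps[0].metadata["beat_onsets_ms"][0]
        y = np.exp(-0.5 * ((t - (onset + 200.0)) / 30.0) ** 2)
        _, v = proto.render_samples(dt)
        trace = hk.CurrentTrace(0.0, dt, y, v)
        m = bm.measure_ap_clamp_metrics(trace, proto)
        assert m.peak_resurgent == pytest.approx(np.max(y), rel=1e-6)
        assert m.peak_voltage_mV == pytest.approx(
            proto.voltage_at(onset + 200.0), abs=1.0
        )

    def test_activator_boosts_transient_more_than_resurgent(self):
        proto = hk.build_ap_clamp_protocol(n_beats=3, period_ms=1000.0,
                                           sampling_ms=0.5)
        cell = hk.CellConfig.hek_37C(g_kr_uS=0.0847)
        settings = hk.SimulationSettings(sampling_ms=0.5)
        metrics = {}
        for name in ("WT", "WT+RPR"):
            trace = hk.simulate_current(hk.load_parameters(name), proto, cell, settings)
            metrics[name] = bm.measure_ap_clamp_metrics(
                trace, proto, normalization="conductance", normalization_value=0.0847
            )
        assert metrics["WT+RPR"].peak_transient > metrics["WT"].peak_transient
        assert (
            metrics["WT+RPR"].peak_resurgent / metrics["WT"].peak_resurgent < 2.0
        )

    def test_unknown_normalization_rejected(self):
        proto = hk.build_ap_clamp_protocol(n_beats=1, sampling_ms=0.5)
        n = int(round(proto.duration_ms / 0.5))
        trace = hk.CurrentTrace(0.0, 0.5, np.zeros(n))
        with pytest.raises(BiomarkerError):
            bm.measure_ap_clamp_metrics(trace, proto, normalization="bogus")


class TestReversalPotential:
    def test_linear_crossing(self):
        v = np.arange(-120, -60, 10.0)
        i = 0.05 * (v + 93.0)
        assert bm.estimate_reversal_potential(v, i) == pytest.approx(-93.0, abs=0.5)

    def test_offset_shifts_estimate(self, wt):
        proto = hk.build_deactivation_protocol(
            [-120.0, -110.0, -100.0, -90.0, -80.0, -70.0], sampling_ms=0.5
        )
        settings = hk.SimulationSettings(sampling_ms=0.5)
        ests = []
        for v_off in (0.0, 5.0):
            cell = hk.CellConfig(g_kr_uS=0.1, e_k_mV=-93.04, v_off_mV=v_off)
            trace = hk.simulate_current(wt, proto, cell, settings)
            iv = bm.instantaneous_tail_iv(trace, proto)
            ests.append(bm.estimate_reversal_potential(iv.voltage_mV, iv.current_nA))
        assert ests[1] - ests[0] == pytest.approx(5.0, abs=1.0)

    def test_no_sign_change_raises(self):
        with pytest.raises(NoReversalError):
            bm.estimate_reversal_potential([-60, -50, -40], [0.1, 0.2, 0.3])
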