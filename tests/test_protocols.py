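"""Voltage-protocol construction: printed protocol numbers, time conventions,
and sampled-waveform round trips."""

import numpy as np
import pytest

import hergkin as hk
from hergkin.protocols import (
    ProtocolError,
    ProtocolSegment,
    default_coupling_intervals,
    load_bundled_complex_ap,
    save_sampled_protocol,
)


class TestActivationProtocols:
    def test_oocyte_21C_matches_published_numbers(self):
        p = hk.build_activation_protocol("oocyte_21C")
        assert p.holding_mV == -100.0
        assert p.n_sweeps == 17  # -100 to +60 in 10-mV increments
        assert p.sweeps[0].metadata["test_voltage_mV"] == -100.0
        assert p.sweeps[-1].metadata["test_voltage_mV"] == 60.0
        for sw in p.sweeps:
            test, tail = sw.segments
            assert (test.duration_ms, tail.duration_ms) == (250.0, 750.0)
            assert tail.v_start == -110.0

    def test_hek_37C_matches_published_numbers(self):
        p = hk.build_activation_protocol("hek_37C")
        assert p.holding_mV == -80.0
        assert p.n_sweeps == 7  # -50 to +40 in 15-mV increments
        volts = [sw.metadata["test_voltage_mV"] for sw in p.sweeps]
        assert volts == [-50.0, -35.0, -20.0, -5.0, 10.0, 25.0, 40.0]
        for sw in p.sweeps:
            test, tail, hold = sw.segments
            assert test.duration_ms == 1500.0
            assert (tail.v_start, tail.duration_ms) == (-40.0, 800.0)
            assert (hold.v_start, hold.duration_ms) == (-80.0, 200.0)

    @pytest.mark.parametrize("variant", ["oocyte_21C", "hek_37C"])
    def test_duration_is_segment_sum_times_sweeps(self, variant):
        p = hk.build_activation_protocol(variant)
        per_sweep = sum(s.duration_ms for s in p.sweeps[0].segments)
        assert p.duration_ms == per_sweep * p.n_sweeps

    def test_unknown_variant(self):
        with pytest.raises(ProtocolError):
            hk.build_activation_protocol("frog_4C")


class TestDeactivationProtocol:
    def test_single_tail(self):
        p = hk.build_deactivation_protocol([-110.0])
        (sw,) = p.sweeps
        assert p.holding_mV == -100.0
        assert (sw.segments[0].v_start, sw.segments[0].duration_ms) == (40.0, 250.0)
        assert (sw.segments[1].v_start, sw.segments[1].duration_ms) == (-110.0, 750.0)

    def test_default_covers_linear_conductance_region(self):
        p = hk.build_deactivation_protocol()
        tails = [sw.metadata["tail_voltage_mV"] for sw in p.sweeps]
        assert {-140.0, -130.0, -120.0, -110.0} <= set(tails)

    def test_duplicates_and_empty_rejected(self):
        with pytest.raises(ProtocolError):
            hk.build_deactivation_protocol([-110.0, -110.0])
        with pytest.raises(ProtocolError):
            hk.build_deactivation_protocol([])


class TestInactivationProtocol:
    def test_matches_published_numbers(self):
        p = hk.build_inactivation_protocol_37C()
        assert p.n_sweeps == 7  # -140 to +40 in 30-mV increments
        volts = [sw.metadata["test_voltage_mV"] for sw in p.sweeps]
        assert volts[0] == -140.0 and volts[-1] == 40.0
        for sw in p.sweeps:
            pre, test = sw.segments
            assert (pre.v_start, pre.duration_ms) == (20.0, 500.0)
            assert test.duration_ms == 800.0


class TestPrematureStimulation:
    def test_zero_interval_lands_on_t90(self):
        ap = hk.StylizedAPSpec()
        p = hk.build_premature_stimulation_protocol(ap, [0.0], pre_hold_ms=100.0)
        meta = p.sweeps[0].metadata
        assert meta["step_onset_ms"] == pytest.approx(100.0 + ap.t90_ms)

    def test_default_grid_span_and_step_shape(self):
        p = hk.build_premature_stimulation_protocol()
        intervals = [sw.metadata["coupling_interval_ms"] for sw in p.sweeps]
        assert min(intervals) == -80.0 and max(intervals) == 380.0
        spacings = np.diff(sorted(intervals))
        assert set(spacings) <= {10.0, 20.0}
        for sw in p.sweeps:
            steps = [s for s in sw.segments if s.kind == "step" and s.v_start == 0.0]
            assert any(s.duration_ms == 40.0 for s in steps)

    def test_sweeps_identical_before_step_onset(self):
        p = hk.build_premature_stimulation_protocol(intervals=[50.0, 150.0, 300.0])
        dt = 0.5
        rendered = []
        for sw in p.sweeps:
            single = hk.VoltageProtocol(p.holding_mV, [sw], dt)
            _, v = single.render_samples(dt)
            onset_idx = int(sw.metadata["step_onset_ms"] / dt)
            rendered.append((v, onset_idx))
        n = min(idx for _, idx in rendered)
        base = rendered[0][0][:n]
        for v, _ in rendered[1:]:
            assert np.array_equal(v[:n], base)

    def test_step_before_upstroke_rejected(self):
        ap = hk.StylizedAPSpec()
        with pytest.raises(ProtocolError):
            hk.build_premature_stimulation_protocol(ap, [-ap.t90_ms - 1.0])

    def test_ap_spec_invariants(self):
        ap = hk.StylizedAPSpec()
        assert 0 < ap.t90_ms < ap.duration_ms
        # monotone repolarization over the ramp
        ts = np.linspace(ap.plateau_duration_ms, ap.duration_ms, 50)
        vs = [ap.voltage(t) for t in ts]
        assert np.all(np.diff(vs) < 0)
        with pytest.raises(ProtocolError):
            hk.StylizedAPSpec(plateau_end_mV=-120.0, post_hold_mV=-100.0)


class TestStaircase:
    def test_deterministic(self):
        a = hk.build_staircase_protocol()
        b = hk.build_staircase_protocol()
        assert a.to_json() == b.to_json()

    def test_default_voltage_range(self):
        p = hk.build_staircase_protocol()
        volts = [s.v_start for s in p.sweeps[0].segments]
        assert min(volts) >= -120.0 and max(volts) <= 60.0

    def test_bad_configs_rejected(self):
        with pytest.raises(ProtocolError):
            hk.build_staircase_protocol({"holding_mV": -80, "steps": [[-80, 0.0]]})
        with pytest.raises(ProtocolError):
            hk.build_staircase_protocol({"steps": "nonsense"})


class TestVoltageAt:
    def test_half_open_boundary_takes_later_segment(self):
        p = hk.build_deactivation_protocol([-110.0])
        assert hk.voltage_at(p, 250.0) == -110.0
        assert hk.voltage_at(p, 249.999) == 40.0

    def test_ramp_midpoint_interpolates(self):
        seg = ProtocolSegment("ramp", 100.0, -80.0, 0.0)
        p = hk.VoltageProtocol(-80.0, [hk.protocols.Sweep([seg])], 1.0)
        assert hk.voltage_at(p, 50.0) == pytest.approx(-40.0)

    def test_time_zero_and_out_of_range(self):
        p = hk.build_staircase_protocol()
        assert hk.voltage_at(p, 0.0) == p.sweeps[0].segments[0].v_start
        with pytest.raises(ProtocolError):
            hk.voltage_at(p, -1.0)
        with pytest.raises(ProtocolError):
            hk.voltage_at(p, p.duration_ms)


class TestSampledWaveforms:
    def test_render_save_load_round_trip(self, tmp_path):
        p = hk.build_staircase_protocol(sampling_ms=1.0)
        path = tmp_path / "wave.csv"
        save_sampled_protocol(p, path)
        q = hk.load_sampled_protocol(path)
        t, v = p.render_samples(1.0)
        t2, v2 = q.render_samples(1.0)
        assert np.max(np.abs(v - v2)) < 1e-9

    def test_bundled_complex_ap_duration(self):
        p = load_bundled_complex_ap()
        assert p.duration_ms > 5000.0
        t, v = p.render_samples()
        assert v.min() >= -120.0 and v.max() <= 60.0

    def test_builder_matches_bundled_fixture(self):
        built = hk.build_complex_ap_train()
        bundled = load_bundled_complex_ap()
        _, v1 = built.render_samples()
        _, v2 = bundled.render_samples()
        assert np.max(np.abs(v1 - v2)) < 1e-9

    def test_shuffled_and_nonuniform_rejected(self, tmp_path):
        t = np.arange(50) * 2.0
        v = np.linspace(-80, 40, 50)
        rows = np.column_stack([t, v])
        bad = tmp_path / "shuffled.csv"
        rng = np.random.default_rng(0)
        shuffled = rows[rng.permutation(len(rows))]
        np.savetxt(bad, shuffled, delimiter=",", header="time_ms,voltage_mV", comments="")
        with pytest.raises(ProtocolError):
            hk.load_sampled_protocol(bad)
        rows[10, 0] += 0.5
        bad2 = tmp_path / "nonuniform.csv"
        np.savetxt(bad2, rows, delimiter=",", header="time_ms,voltage_mV", comments="")
        with pytest.raises(ProtocolError):
            hk.load_sampled_protocol(bad2)

    def test_protocol_json_round_trip(self, tmp_path):
        p = hk.build_premature_stimulation_protocol(intervals=[0.0, 100.0])
        path = tmp_path / "p.json"
        p.save(path)
        q = hk.VoltageProtocol.load(path)
        assert q.duration_ms == p.duration_ms
        t, v = p.render_samples(0.5)
        _, v2 = q.render_samples(0.5)
        assert np.array_equal(v, v2)
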