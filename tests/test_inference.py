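"""Joint-inference unit tests: likelihood structure, voltage-offset logic,
parameter transforms, quality control, and zero-noise fit fixed points."""

import numpy as np
import pytest

import hergkin as hk
import hergkin.biomarkers as bm
from hergkin.inference import (
    FitSettings,
    InferenceError,
    TransformSpec,
    _band_ok,
    dataset_from_sweepsets,
)


@pytest.fixture(scope="module")
def zero_noise_cohort():
    """Two noise-free cells with distinct conductances and offsets on a
    coarse staircase grid (fast, exact fixed point for the fit)."""
    wt = hk.load_parameters("WT")
    wtr = hk.load_parameters("WT+RPR")
    suite = {"C": hk.build_staircase_protocol(sampling_ms=2.0)}
    base = hk.SyntheticCellSpec(
        kinetics_control=wt, kinetics_rpr=wtr, noise_sd_nA=0.0,
        leak=(0.01, 0.0), seed=3, cell_id="zn",
    )
    cohort = hk.generate_cohort(
        2, base, {"g_kr_values": [0.08, 0.12], "v_off_limit": 2.0},
        seed=3, protocols=suite,
    )
    return cohort, wt, wtr


@pytest.fixture(scope="module")
def zero_noise_dataset(zero_noise_cohort):
    cohort, _, _ = zero_noise_cohort
    return dataset_from_sweepsets(cohort)


class TestTransform:
    def test_bijection_round_trip(self, wt):
        tf = TransformSpec()
        x = tf.to_transformed(wt.values)
        assert np.allclose(tf.from_transformed(x), wt.values, rtol=1e-14)

    def test_sampled_starts_are_plausible(self):
        tf = TransformSpec()
        rng = np.random.default_rng(0)
        lo, hi = tf.bounds()
        for _ in range(20):
            x = tf.sample_start(rng)
            assert np.all(x >= lo) and np.all(x <= hi)
            params = hk.KineticParameterSet.from_values(tf.from_transformed(x))
            assert _band_ok(params)


class TestTraceLogLikelihood:
    def test_zero_residual_at_generating_parameters(self, zero_noise_cohort):
        cohort, wt, _ = zero_noise_cohort
        ss = cohort[0]
        control, _ = hk.subtract_sweeps(ss)
        cell = hk.CellConfig(
            g_kr_uS=1.0, e_k_mV=ss.truth.e_k_mV, v_off_mV=ss.truth.v_off_mV
        )
        ll = hk.trace_log_likelihood(
            wt, ss.truth.g_kr_uS, cell, control["C"], ss.protocols["C"]
        )
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_single_point_perturbation_changes_ll_by_r_squared(
        self, zero_noise_cohort
    ):
        cohort, wt, _ = zero_noise_cohort
        ss = cohort[0]
        control, _ = hk.subtract_sweeps(ss)
        trace = control["C"]
        r = 0.37
        bumped = hk.CurrentTrace(
            trace.t0_ms, trace.dt_ms, trace.current_nA.copy(), metadata={}
        )
        bumped.current_nA[1000] += r
        cell = hk.CellConfig(
            g_kr_uS=1.0, e_k_mV=ss.truth.e_k_mV, v_off_mV=ss.truth.v_off_mV
        )
        ll0 = hk.trace_log_likelihood(
            wt, ss.truth.g_kr_uS, cell, trace, ss.protocols["C"]
        )
        ll1 = hk.trace_log_likelihood(
            wt, ss.truth.g_kr_uS, cell, bumped, ss.protocols["C"]
        )
        assert ll0 - ll1 == pytest.approx(r**2, rel=1e-9)

    def test_invariant_to_parameterization(self, zero_noise_cohort):
        # evaluating through transform-and-back must not change the value
        cohort, wt, _ = zero_noise_cohort
        ss = cohort[0]
        control, _ = hk.subtract_sweeps(ss)
        tf = TransformSpec()
        wt2 = hk.KineticParameterSet.from_values(
            tf.from_transformed(tf.to_transformed(wt.values))
        )
        cell = hk.CellConfig(
            g_kr_uS=1.0, e_k_mV=ss.truth.e_k_mV, v_off_mV=ss.truth.v_off_mV
        )
        args = (ss.truth.g_kr_uS, cell, control["C"], ss.protocols["C"])
        assert hk.trace_log_likelihood(wt, *args) == pytest.approx(
            hk.trace_log_likelihood(wt2, *args), abs=1e-10
        )


class TestVoltageOffset:
    def test_difference(self):
        assert hk.compute_voltage_offset(-88.0, -93.0) == 5.0
        assert hk.compute_voltage_offset(-93.0, -93.0) == 0.0

    def test_round_trip_through_reversal_estimation(self, wt):
        delta = 3.0
        proto = hk.build_deactivation_protocol(
            [-120.0, -110.0, -100.0, -90.0, -80.0, -70.0], sampling_ms=0.5
        )
        cell = hk.CellConfig(g_kr_uS=0.1, e_k_mV=-93.04, v_off_mV=delta)
        trace = hk.simulate_current(
            wt, proto, cell, hk.SimulationSettings(sampling_ms=0.5)
        )
        iv = bm.instantaneous_tail_iv(trace, proto)
        e_meas = bm.estimate_reversal_potential(iv.voltage_mV, iv.current_nA)
        assert hk.compute_voltage_offset(e_meas, -93.04) == pytest.approx(
            delta, abs=1.0
        )


class TestParameterCount:
    def test_three_cell_joint_problem(self):
        assert hk.count_free_parameters(3) == 27

    def test_single_cell(self):
        assert hk.count_free_parameters(1) == 25

    def test_zero_cells_rejected(self):
        with pytest.raises(InferenceError):
            hk.count_free_parameters(0)


class TestJointLikelihood:
    def test_single_cell_is_sum_of_trace_likelihoods(self, zero_noise_cohort):
        cohort, wt, wtr = zero_noise_cohort
        ds = dataset_from_sweepsets(cohort[:1])
        cell = ds.cells[0]
        cfg = hk.CellConfig(g_kr_uS=1.0, e_k_mV=ds.e_k_mV, v_off_mV=cell.v_off_mV)
        g = cohort[0].truth.g_kr_uS
        expected = hk.trace_log_likelihood(
            wt, g, cfg, cell.control_trace, ds.protocol
        ) + hk.trace_log_likelihood(wtr, g, cfg, cell.activator_trace, ds.protocol)
        assert hk.joint_log_likelihood(wt, wtr, [g], ds) == pytest.approx(expected)

    def test_invariant_to_cell_order(self, zero_noise_cohort):
        cohort, wt, wtr = zero_noise_cohort
        gs = [ss.truth.g_kr_uS for ss in cohort]
        a = hk.joint_log_likelihood(wt, wtr, gs, dataset_from_sweepsets(cohort))
        b = hk.joint_log_likelihood(
            wt, wtr, gs[::-1], dataset_from_sweepsets(cohort[::-1])
        )
        assert a == pytest.approx(b, rel=1e-12, abs=1e-12)

    def test_truth_beats_perturbed_parameters(self, wt, wt_rpr):
        suite = {"C": hk.build_staircase_protocol(sampling_ms=2.0)}
        base = hk.SyntheticCellSpec(
            kinetics_control=wt, kinetics_rpr=wt_rpr, g_kr_uS=0.08,
            noise_sd_nA=0.02, seed=12, cell_id="n",
        )
        cohort = hk.generate_cohort(2, base, {}, seed=12, protocols=suite)
        ds = dataset_from_sweepsets(cohort)
        gs = [ss.truth.g_kr_uS for ss in cohort]
        ll_truth = hk.joint_log_likelihood(wt, wt_rpr, gs, ds)
        doubled = list(wt.values)
        doubled[0] *= 2.0
        ll_bad = hk.joint_log_likelihood(
            hk.KineticParameterSet.from_values(doubled), wt_rpr, gs, ds
        )
        assert ll_truth > ll_bad


class TestFitJoint:
    def test_zero_noise_truth_start_is_fixed_point(self, zero_noise_dataset):
        ds = zero_noise_dataset
        wt = hk.load_parameters("WT")
        wtr = hk.load_parameters("WT+RPR")
        tf = TransformSpec()
        res = hk.fit_joint(
            ds,
            FitSettings(n_starts=1, polish_top=1, max_nfev_joint=10),
            seed=1,
            x0_control=tf.to_transformed(wt.values),
            x0_rpr=tf.to_transformed(wtr.values),
        )
        assert res.sse < 1e-12
        assert np.max(np.abs(res.theta_control.values / wt.values - 1)) < 1e-4
        assert np.max(np.abs(res.theta_rpr.values / wtr.values - 1)) < 1e-4
        assert np.allclose(res.g_kr_uS, [0.08, 0.12], rtol=1e-4)
        assert res.n_parameters == 26  # 24 kinetics + 2 cells
        assert res.band_satisfied

    def test_scaling_traces_doubles_conductance_only(self, zero_noise_dataset):
        ds = zero_noise_dataset
        wt = hk.load_parameters("WT")
        wtr = hk.load_parameters("WT+RPR")
        scaled_cells = []
        for c in ds.cells:
            scaled_cells.append(
                type(c)(
                    cell_id=c.cell_id,
                    control_trace=hk.CurrentTrace(
                        0.0, c.control_trace.dt_ms, 2 * c.control_trace.current_nA
                    ),
                    activator_trace=hk.CurrentTrace(
                        0.0, c.activator_trace.dt_ms, 2 * c.activator_trace.current_nA
                    ),
                    e_k_measured_mV=c.e_k_measured_mV,
                    v_off_mV=c.v_off_mV,
                )
            )
        ds2 = type(ds)(cells=scaled_cells, protocol=ds.protocol, e_k_mV=ds.e_k_mV)
        tf = TransformSpec()
        res = hk.fit_joint(
            ds2,
            FitSettings(n_starts=1, polish_top=1, max_nfev_joint=10),
            seed=1,
            x0_control=tf.to_transformed(wt.values),
            x0_rpr=tf.to_transformed(wtr.values),
        )
        assert np.allclose(res.g_kr_uS, [0.16, 0.24], rtol=1e-4)
        assert np.max(np.abs(res.theta_control.values / wt.values - 1)) < 1e-3

    def test_objective_locally_concave_at_zero_noise_optimum(
        self, zero_noise_dataset
    ):
        # identifiability smoke test: the log-likelihood falls in every
        # transformed coordinate direction around the optimum
        ds = zero_noise_dataset
        wt = hk.load_parameters("WT")
        wtr = hk.load_parameters("WT+RPR")
        gs = [0.08, 0.12]
        tf = TransformSpec()
        ll0 = hk.joint_log_likelihood(wt, wtr, gs, ds)
        for block, params in (("control", wt), ("rpr", wtr)):
            x = tf.to_transformed(params.values)
            for j in range(12):
                for sign in (-1, 1):
                    xp = x.copy()
                    xp[j] += sign * 1e-3
                    perturbed = hk.KineticParameterSet.from_values(
                        tf.from_transformed(xp)
                    )
                    if block == "control":
                        ll = hk.joint_log_likelihood(perturbed, wtr, gs, ds)
                    else:
                        ll = hk.joint_log_likelihood(wt, perturbed, gs, ds)
                    assert ll <= ll0 + 1e-12


class TestStaircaseQC:
    def _trace(self, values):
        return hk.CurrentTrace(0.0, 1.0, np.asarray(values, dtype=float))

    def test_identical_traces_pass(self):
        t = self._trace(np.sin(np.linspace(0, 10, 500)))
        ok, drift = hk.staircase_qc_check(t, t)
        assert ok and drift == 0.0

    def test_half_scaled_repeat_fails(self):
        base = np.sin(np.linspace(0, 10, 500))
        ok, drift = hk.staircase_qc_check(
            self._trace(base), self._trace(0.5 * base)
        )
        assert not ok
        assert drift == pytest.approx(0.5)

    def test_noise_level_differences_pass(self):
        rng = np.random.default_rng(5)
        base = np.sin(np.linspace(0, 10, 2000))
        sigma = 0.05 * np.sqrt(np.mean(base**2))
        repeat = base + rng.normal(0, sigma * np.sqrt(2), size=base.size)
        ok, drift = hk.staircase_qc_check(self._trace(base), self._trace(repeat))
        assert ok

    def test_grid_mismatch_rejected(self):
        with pytest.raises(InferenceError):
            hk.staircase_qc_check(
                self._trace(np.zeros(10) + 1), self._trace(np.zeros(11) + 1)
            )
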