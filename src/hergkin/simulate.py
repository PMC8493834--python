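"""Simulation of model current against a voltage protocol.

The factorized gating system is linear and time-invariant at fixed voltage,
so on ``step`` segments (and on the piecewise-constant sub-steps of
``sampled`` segments) the state is propagated with the exact matrix
exponential of the reduced 2x2 activation system plus the closed-form
relaxation of the ``h`` gate.  ``ramp`` segments are integrated with a stiff
adaptive ODE solver at tight tolerances (1e-8 absolute and relative by
default).  The integrator is restarted at every segment boundary so that
voltage discontinuities are never smeared; the gating state itself is carried
across boundaries unchanged.

An independent six-state Markov integrator (:func:`simulate_markov`) exists
as an equivalence oracle for the factorized path; it is not used for
production simulation.

Current follows the Ohmic expression ``I = g_Kr * O * (V - E_K)`` in nA
(conductance in uS, voltages in mV), with the effective membrane voltage
``V = V_cmd - V_off`` and an optional additive linear leak
``g_leak * (V_cmd - E_leak)``.  Outward current is positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    GateState,
    KineticParameterSet,
    RateValues,
    evaluate_rates,
    expand_to_markov,
    gate_steady_state,
    markov_rate_matrix,
)
from .protocols import ProtocolSegment, VoltageProtocol

__all__ = [
    "FARADAY_C_PER_MOL",
    "GAS_CONSTANT_J_PER_MOL_K",
    "SimulationError",
    "CellConfig",
    "SimulationSettings",
    "CurrentTrace",
    "GatingTrace",
    "nernst_potential",
    "initial_state",
    "simulate_gating",
    "simulate_current",
    "simulate_markov",
]

GAS_CONSTANT_J_PER_MOL_K = 8.31446261815324
FARADAY_C_PER_MOL = 96485.33212331001


class SimulationError(RuntimeError):
    """Integrator failure or inconsistent simulation inputs."""


def nernst_potential(k_out_mM: float, k_in_mM: float, temperature_K: float) -> float:
    """K+ reversal potential (mV): (R*T/(z*F)) * ln([K]_o/[K]_i), z = 1."""
    if k_out_mM <= 0 or k_in_mM <= 0:
        raise ValueError("K+ concentrations must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive (K)")
    return (
        1e3
        * GAS_CONSTANT_J_PER_MOL_K
        * temperature_K
        / FARADAY_C_PER_MOL
        * math.log(k_out_mM / k_in_mM)
    )


@dataclass
class CellConfig:
    """Cell-level configuration: maximal conductance g_Kr (uS), the K+
    reversal potential (either directly in mV or via concentrations in mM
    plus temperature in K), a command-voltage offset V_off (mV, applied as
    V = V_cmd - V_off), and an optional linear leak (g_leak uS, E_leak mV).
    """

    g_kr_uS: float = 0.1
    e_k_mV: float | None = None
    k_out_mM: float | None = None
    k_in_mM: float | None = None
    temperature_K: float | None = None
    v_off_mV: float = 0.0
    leak: tuple[float, float] | None = None  # (g_leak uS, E_leak mV)
    cell_id: str = ""

    def __post_init__(self) -> None:
        if self.g_kr_uS < 0:
            raise ValueError("g_kr must be >= 0")
        concs = (self.k_out_mM, self.k_in_mM, self.temperature_K)
        has_concs = all(c is not None for c in concs)
        if (self.e_k_mV is None) == (not has_concs):
            raise ValueError(
                "supply exactly one of e_k_mV or (k_out_mM, k_in_mM, temperature_K)"
            )

    @property
    def e_k(self) -> float:
        if self.e_k_mV is not None:
            return self.e_k_mV
        return nernst_potential(self.k_out_mM, self.k_in_mM, self.temperature_K)

    @classmethod
    def hek_37C(cls, g_kr_uS: float = 0.1, **kw) -> "CellConfig":
        """Physiological-temperature whole-cell defaults: 4 mM external /
        130 mM internal K+ at 310.15 K (E_K about -93 mV)."""
        return cls(g_kr_uS=g_kr_uS, k_out_mM=4.0, k_in_mM=130.0,
                   temperature_K=310.15, **kw)


@dataclass
class SimulationSettings:
    """Integration and output settings.  Tolerances default to the 1e-8 used
    for all reported simulations; ``sampling_ms`` of None adopts the
    protocol's own sampling interval."""

    abs_tol: float = 1e-8
    rel_tol: float = 1e-8
    sampling_ms: float | None = None
    max_step_ms: float | None = None
    method: str = "auto"  # "auto" | "analytic" | "ode"

    def __post_init__(self) -> None:
        if self.abs_tol <= 0 or self.rel_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.sampling_ms is not None and self.sampling_ms <= 0:
            raise ValueError("sampling interval must be > 0")


@dataclass
class CurrentTrace:
    """A uniformly sampled current trace (nA) with optional stored command
    voltage and free-form metadata."""

    t0_ms: float
    dt_ms: float
    current_nA: np.ndarray
    voltage_mV: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current_nA = np.asarray(self.current_nA, dtype=float)
        if self.dt_ms <= 0:
            raise ValueError("dt must be > 0")
        if not np.all(np.isfinite(self.current_nA)):
            raise ValueError("current samples must be finite")

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + self.dt_ms * np.arange(len(self.current_nA))

    def __len__(self) -> int:
        return len(self.current_nA)

    def to_csv(self, path: str | Path) -> None:
        cols = [self.times_ms, self.current_nA]
        header = "time_ms,current_nA"
        if self.voltage_mV is not None:
            cols.append(self.voltage_mV)
            header += ",voltage_mV"
        np.savetxt(path, np.column_stack(cols), delimiter=",",
                   header=header, comments="")

    @classmethod
    def from_csv(cls, path: str | Path, metadata: dict | None = None) -> "CurrentTrace":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        t = data[:, 0]
        if len(t) < 2:
            raise ValueError("trace needs >= 2 samples")
        dt = float(t[1] - t[0])
        if np.max(np.abs(np.diff(t) - dt)) > 1e-6 * max(dt, 1.0):
            raise ValueError("non-uniform trace sampling")
        return cls(
            t0_ms=float(t[0]),
            dt_ms=dt,
            current_nA=data[:, 1],
            voltage_mV=data[:, 2] if data.shape[1] > 2 else None,
            metadata=dict(metadata or {}),
        )


@dataclass
class GatingTrace:
    """Gating-state time series on the protocol output grid."""

    t_ms: np.ndarray
    Oa: np.ndarray
    C1a: np.ndarray
    h: np.ndarray

    @property
    def C2a(self) -> np.ndarray:
        return 1.0 - self.Oa - self.C1a

    @property
    def open(self) -> np.ndarray:
        """Open probability O(t) = Oa(t) * h(t)."""
        return self.Oa * self.h

    def state_at(self, i: int) -> GateState:
        return GateState(
            Oa=float(self.Oa[i]), C1a=float(self.C1a[i]),
            C2a=float(self.C2a[i]), h=float(self.h[i]),
        )


def initial_state(
    params: KineticParameterSet, cell: CellConfig, protocol: VoltageProtocol
) -> GateState:
    """Steady state at the protocol's holding potential, seen through the
    cell's voltage offset (V = V_hold - V_off)."""
    return gate_steady_state(params, protocol.holding_mV - cell.v_off_mV)


# ---------------------------------------------------------------------------
# analytic propagation at fixed voltage
# ---------------------------------------------------------------------------


def _chain_system(r: RateValues) -> tuple[np.ndarray, np.ndarray]:
    """Reduced activation system d(C1a, Oa)/dt = A @ x + b with C2a eliminated."""
    a = np.array(
        [
            [-(r.a1 + r.a2 + r.b1), r.b2 - r.a1],
            [r.a2, -r.b2],
        ]
    )
    b = np.array([r.a1, 0.0])
    return a, b


def _propagate_fixed_v(
    r: RateValues,
    x0: np.ndarray,
    h0: float,
    tau_out: np.ndarray,
    duration: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Exact solution of the gating system at fixed voltage.

    Returns (C1a, Oa, h) evaluated at the offsets ``tau_out`` plus the exact
    state at ``duration`` (as a length-3 array C1a, Oa, h).
    """
    a, b = _chain_system(r)
    tr = a[0, 0] + a[1, 1]
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    t_all = np.append(tau_out, duration)

    if det != 0.0:
        x_ss = np.linalg.solve(a, -b)
    else:
        x_ss = None

    if x_ss is None:
        # Singular reduced system (all activation rates zero, or a detached
        # chain): no finite stationary point; integrate numerically.
        def rhs(_t, y):
            return a @ y + b

        sol = solve_ivp(rhs, (0.0, duration), x0, t_eval=t_all,
                        rtol=1e-10, atol=1e-12, method="LSODA")
        if not sol.success:
            raise SimulationError(f"degenerate-segment integration failed: {sol.message}")
        xs = sol.y
    else:
        d = x0 - x_ss
        disc = tr * tr - 4.0 * det
        sq = math.sqrt(disc) if disc > 0 else 0.0
        lam1 = 0.5 * (tr + sq)
        lam2 = 0.5 * (tr - sq)
        if sq > 1e-12 * max(abs(lam1), abs(lam2), 1e-300):
            # spectral projectors of the 2x2 system
            u1 = (a @ d - lam2 * d) / (lam1 - lam2)
            u2 = d - u1
            e1 = np.exp(lam1 * t_all)
            e2 = np.exp(lam2 * t_all)
            xs = x_ss[:, None] + np.outer(u1, e1) + np.outer(u2, e2)
        else:
            # defective/degenerate eigenvalue: e^{At} = e^{lt}(I + t(A - lI))
            lam = 0.5 * tr
            ad = a @ d - lam * d
            e = np.exp(lam * t_all)
            xs = x_ss[:, None] + e * (d[:, None] + np.outer(ad, t_all))

    denom = r.ah + r.bh
    if denom > 0:
        hs = r.h_inf + (h0 - r.h_inf) * np.exp(-denom * t_all)
    else:
        hs = np.full_like(t_all, h0)

    end = np.array([xs[0, -1], xs[1, -1], hs[-1]])
    return xs[0, :-1], xs[1, :-1], hs[:-1], end


def _segment_sample_offsets(
    seg_start: float, seg_dur: float, dt: float, n_total: int
) -> tuple[int, int]:
    """Output-grid index range [i, j) of samples with times in
    [seg_start, seg_start + seg_dur)."""
    i = int(math.ceil(seg_start / dt - 1e-9))
    j = min(int(math.ceil((seg_start + seg_dur) / dt - 1e-9)), n_total)
    return max(i, 0), j


def _integrate_segment_ode(
    params: KineticParameterSet,
    seg: ProtocolSegment,
    v_off: float,
    y0: np.ndarray,
    tau_out: np.ndarray,
    settings: SimulationSettings,
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive stiff integration of one segment; returns states at tau_out
    and the end state."""

    def v_of(t: float) -> float:
        return seg.voltage(min(t, seg.duration_ms * (1 - 1e-15))) - v_off

    def rhs(t, y):
        r = evaluate_rates(params, v_of(t))
        c1a, oa, h = y
        c2a = 1.0 - oa - c1a
        return [
            r.b2 * oa + r.a1 * c2a - (r.a2 + r.b1) * c1a,
            r.a2 * c1a - r.b2 * oa,
            (r.h_inf - h) * (r.ah + r.bh),
        ]

    t_all = np.append(tau_out, seg.duration_ms)
    kwargs = dict(rtol=settings.rel_tol, atol=settings.abs_tol, method="LSODA")
    if settings.max_step_ms:
        kwargs["max_step"] = settings.max_step_ms
    sol = solve_ivp(rhs, (0.0, seg.duration_ms), y0, t_eval=t_all, **kwargs)
    if not sol.success:
        raise SimulationError(
            f"integrator failed in segment ({seg.kind}, {seg.duration_ms} ms) "
            f"at state {y0}: {sol.message}"
        )
    return sol.y[:, :-1], sol.y[:, -1]


def simulate_gating(
    params: KineticParameterSet,
    protocol: VoltageProtocol,
    cell: CellConfig | None = None,
    settings: SimulationSettings | None = None,
) -> GatingTrace:
    """Integrate the factorized gating ODEs over a protocol.

    Each sweep starts from the steady state at the (offset-corrected) holding
    potential; the state is continuous across segment boundaries within a
    sweep.  Output lands on the uniform grid ``k * dt`` over the protocol
    duration.  ``settings.method``:

    * ``"auto"`` (default): exact propagation on step/sampled segments,
      adaptive ODE on ramps;
    * ``"ode"``: adaptive ODE everywhere (restarted at each boundary);
    * ``"analytic"``: exact propagation only; raises on ramp segments.
    """
    cell = cell or CellConfig.hek_37C()
    settings = settings or SimulationSettings()
    dt = settings.sampling_ms or protocol.sampling_ms
    n_total = int(round(protocol.duration_ms / dt))
    t_grid = np.arange(n_total) * dt
    oa = np.empty(n_total)
    c1a = np.empty(n_total)
    h = np.empty(n_total)
    v_off = cell.v_off_mV

    t_cursor = 0.0
    for sweep in protocol.sweeps:
        s0 = gate_steady_state(params, protocol.holding_mV - v_off)
        y = np.array([s0.C1a, s0.Oa, s0.h])  # (C1a, Oa, h)
        for seg in sweep.segments:
            i, j = _segment_sample_offsets(t_cursor, seg.duration_ms, dt, n_total)
            tau = t_grid[i:j] - t_cursor
            use_ode = settings.method == "ode" or (
                settings.method == "auto" and seg.kind == "ramp"
            )
            if settings.method == "analytic" and seg.kind == "ramp":
                raise SimulationError("analytic method cannot integrate ramp segments")
            if use_ode:
                ys, y_end = _integrate_segment_ode(params, seg, v_off, y, tau, settings)
                c1a[i:j], oa[i:j], h[i:j] = ys
                y = y_end
            elif seg.kind == "sampled":
                x = np.array([y[0], y[1]])
                h0 = y[2]
                sub_dt = seg.dt_ms
                for k, v_cmd in enumerate(seg.samples):
                    sub_start = t_cursor + k * sub_dt
                    ii, jj = _segment_sample_offsets(sub_start, sub_dt, dt, n_total)
                    sub_tau = t_grid[ii:jj] - sub_start
                    r = evaluate_rates(params, float(v_cmd) - v_off)
                    c1s, oas, hs, end = _propagate_fixed_v(r, x, h0, sub_tau, sub_dt)
                    c1a[ii:jj], oa[ii:jj], h[ii:jj] = c1s, oas, hs
                    x = end[:2]
                    h0 = end[2]
                y = np.array([x[0], x[1], h0])
            else:  # step
                r = evaluate_rates(params, seg.v_start - v_off)
                c1s, oas, hs, end = _propagate_fixed_v(
                    r, y[:2], y[2], tau, seg.duration_ms
                )
                c1a[i:j], oa[i:j], h[i:j] = c1s, oas, hs
                y = end
            t_cursor += seg.duration_ms

    return GatingTrace(t_ms=t_grid, Oa=oa, C1a=c1a, h=h)


def simulate_current(
    params: KineticParameterSet,
    protocol: VoltageProtocol,
    cell: CellConfig | None = None,
    settings: SimulationSettings | None = None,
    g_scale_of_t: Callable[[np.ndarray], np.ndarray] | None = None,
    store_voltage: bool = True,
) -> CurrentTrace:
    """Model current I(t) = g_Kr * O(t) * (V(t) - E_K) in nA, with
    V(t) = V_cmd(t) - V_off, plus the configured linear leak (which sees the
    raw command voltage).  ``g_scale_of_t`` optionally scales the channel
    conductance continuously with protocol time (used to emulate rundown)."""
    cell = cell or CellConfig.hek_37C()
    settings = settings or SimulationSettings()
    dt = settings.sampling_ms or protocol.sampling_ms
    _, v_cmd = protocol.render_samples(dt)
    gating = simulate_gating(params, protocol, cell, settings)
    g = cell.g_kr_uS
    if g_scale_of_t is not None:
        g = g * np.asarray(g_scale_of_t(gating.t_ms), dtype=float)
    i_kr = g * gating.open * (v_cmd - cell.v_off_mV - cell.e_k)
    if cell.leak is not None:
        g_leak, e_leak = cell.leak
        i_kr = i_kr + g_leak * (v_cmd - e_leak)
    return CurrentTrace(
        t0_ms=0.0,
        dt_ms=dt,
        current_nA=i_kr,
        voltage_mV=v_cmd if store_voltage else None,
        metadata={
            "protocol": protocol.name,
            "cell_id": cell.cell_id,
            "params": params.label,
        },
    )


def simulate_markov(
    params: KineticParameterSet,
    protocol: VoltageProtocol,
    cell: CellConfig | None = None,
    settings: SimulationSettings | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Six-state Markov integration (equivalence oracle for the factorized
    path).  Returns ``(t, occupancies)`` with occupancies of shape (n, 6) in
    :data:`hergkin.model.MARKOV_STATE_NAMES` order."""
    cell = cell or CellConfig.hek_37C()
    settings = settings or SimulationSettings()
    dt = settings.sampling_ms or protocol.sampling_ms
    n_total = int(round(protocol.duration_ms / dt))
    t_grid = np.arange(n_total) * dt
    occ = np.empty((n_total, 6))
    v_off = cell.v_off_mV

    t_cursor = 0.0
    for sweep in protocol.sweeps:
        s0 = gate_steady_state(params, protocol.holding_mV - v_off)
        y = expand_to_markov(s0).as_array()
        for seg in sweep.segments:
            i, j = _segment_sample_offsets(t_cursor, seg.duration_ms, dt, n_total)
            tau = t_grid[i:j] - t_cursor

            def v_of(t: float) -> float:
                return seg.voltage(min(t, seg.duration_ms * (1 - 1e-15))) - v_off

            def rhs(t, yy):
                return markov_rate_matrix(params, v_of(t)) @ yy

            t_all = np.append(tau, seg.duration_ms)
            sol = solve_ivp(
                rhs, (0.0, seg.duration_ms), y, t_eval=t_all,
                rtol=settings.rel_tol, atol=settings.abs_tol, method="LSODA",
            )
            if not sol.success:
                raise SimulationError(
                    f"six-state integration failed at t={t_cursor}: {sol.message}"
                )
            occ[i:j] = sol.y[:, :-1].T
            y = sol.y[:, -1]
            t_cursor += seg.duration_ms

    return t_grid, occ
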