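"""Joint maximum-likelihood inference of channel kinetics across cells.

The statistical model is ``I_data = I_model + eps`` with iid Gaussian noise
``eps ~ N(0, sigma^2)``, so the maximum-likelihood parameters coincide with
the least-sum-of-squares fit and the per-trace log-likelihood is
proportional to minus the sum of squared residuals over time points.
Inference is joint over a cohort: one set of control kinetics and one set of
activator (RPR) kinetics are shared across cells, each cell contributes its
own maximal conductance (unchanged by the activator), and per-cell
variability in the effective voltage is absorbed by a fixed command-voltage
offset ``V_off = E_K,measured - E_K`` determined from the measured reversal
potential before fitting.  For N cells the joint problem has 12 + 12 + N
free parameters (27 for the three-cell design).

Numerically, the rate prefactors (p1, p3, p5, p7, p9, p11) are
log-transformed; slopes are fitted on their natural scale within [0, 0.4]
mV^-1; every candidate must keep all six rates inside the plausibility band
over the working voltage range (enforced by a smooth penalty plus final
rejection).  Because the model current is linear in the conductance, each
cell's g_Kr is profiled out analytically at every objective evaluation,
reducing the search to the 24 kinetic parameters.  The optimizer is a
multi-start global-then-local strategy: each start fits the control and
activator blocks sequentially (CMA-ES over the transformed 12-parameter
space on a subsampled grid, then trust-region least squares, conductances
profiled throughout), after which the best starts are polished on the full
joint 24 + N problem at full data resolution; the best result by joint
sum-of-squares is returned.  Noise sigma never enters the optimization (it
cancels from the MLE) and is reported post hoc from residual variance.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from ._cmaes import cma_es_minimize
from .model import (
    RATE_BAND,
    V_PLAUSIBILITY_RANGE,
    KineticParameterSet,
    rate_extrema,
)
from .protocols import VoltageProtocol
from .simulate import (
    CellConfig,
    CurrentTrace,
    SimulationSettings,
    simulate_gating,
)
from .synth import SweepSet, subtract_sweeps

__all__ = [
    "InferenceError",
    "TransformSpec",
    "CellRecords",
    "JointDataset",
    "FitSettings",
    "StartRecord",
    "InferenceResult",
    "trace_log_likelihood",
    "compute_voltage_offset",
    "count_free_parameters",
    "joint_log_likelihood",
    "fit_joint",
    "staircase_qc_check",
    "dataset_from_sweepsets",
]


class InferenceError(RuntimeError):
    """All optimizer starts failed, or the dataset is inconsistent."""


_LOG_IDX = (0, 2, 4, 6, 8, 10)
_SLOPE_IDX = (1, 3, 5, 7, 9, 11)


@dataclass
class TransformSpec:
    """Bijective reparameterization of the 12 kinetic parameters: listed
    indices (default: the prefactors) are log-transformed; bounds are given
    in transformed space."""

    log_indices: tuple[int, ...] = _LOG_IDX
    prefactor_bounds: tuple[float, float] = RATE_BAND
    slope_bounds: tuple[float, float] = (0.0, 0.4)

    def to_transformed(self, values: np.ndarray) -> np.ndarray:
        x = np.array(values, dtype=float)
        for i in self.log_indices:
            x[i] = math.log(x[i])
        return x

    def from_transformed(self, x: np.ndarray) -> np.ndarray:
        v = np.array(x, dtype=float)
        for i in self.log_indices:
            v[i] = math.exp(v[i])
        return v

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.empty(12)
        hi = np.empty(12)
        for i in range(12):
            if i in self.log_indices:
                lo[i] = math.log(self.prefactor_bounds[0])
                hi[i] = math.log(self.prefactor_bounds[1])
            else:
                lo[i], hi[i] = self.slope_bounds
        return lo, hi

    def sample_start(
        self, rng: np.random.Generator, max_tries: int = 10000
    ) -> np.ndarray:
        """Draw a transformed start (log-uniform prefactors, uniform slopes)
        subject to rate plausibility, rejecting per rate pair (each
        (prefactor, slope) pair constrains one rate independently)."""
        lo, hi = self.bounds()
        x = np.empty(12)
        band_lo, band_hi = math.log(RATE_BAND[0]), math.log(RATE_BAND[1])
        v_lo, v_hi = V_PLAUSIBILITY_RANGE
        for k in range(6):
            ip, isl = 2 * k, 2 * k + 1
            sign = 1.0 if k % 2 == 0 else -1.0  # a1,bh,a2 forward; b1,ah,b2 backward
            for tries in range(max_tries):
                lp = rng.uniform(lo[ip], hi[ip])
                s = rng.uniform(lo[isl], hi[isl])
                ext = (lp + sign * s * v_lo, lp + sign * s * v_hi)
                if min(ext) >= band_lo and max(ext) <= band_hi:
                    x[ip], x[isl] = lp, s
                    break
            else:
                raise InferenceError("could not sample a rate-plausible start")
        return x


def _band_ok(
    params: KineticParameterSet,
    band: tuple[float, float] = RATE_BAND,
    v_range: tuple[float, float] = V_PLAUSIBILITY_RANGE,
) -> bool:
    for rmin, rmax in rate_extrema(params, v_range).values():
        if rmax > band[1] or rmin < band[0]:
            return False
    return True


def _band_penalties(
    values: np.ndarray,
    band: tuple[float, float] = RATE_BAND,
    v_range: tuple[float, float] = V_PLAUSIBILITY_RANGE,
    weight: float = 1e2,
) -> np.ndarray:
    """Smooth penalty residuals, zero inside the plausibility band and
    growing with the log-distance of each rate extremum outside it."""
    pens = np.zeros(12)
    params = KineticParameterSet.from_values(np.abs(values) + 1e-300)
    for k, (rmin, rmax) in enumerate(rate_extrema(params, v_range).values()):
        pens[2 * k] = weight * max(0.0, math.log(rmax / band[1]))
        pens[2 * k + 1] = weight * max(0.0, math.log(band[0] / max(rmin, 1e-300)))
    return pens


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------


@dataclass
class CellRecords:
    """One cell's calibration data: blocker-subtracted control and activator
    traces on the calibration protocol, its measured reversal potential and
    the derived voltage offset."""

    cell_id: str
    control_trace: CurrentTrace
    activator_trace: CurrentTrace
    e_k_measured_mV: float
    v_off_mV: float = 0.0


@dataclass
class JointDataset:
    """Cohort calibration dataset: all cells share the calibration protocol
    and the theoretical Nernst reversal potential."""

    cells: list[CellRecords]
    protocol: VoltageProtocol
    e_k_mV: float

    def __post_init__(self) -> None:
        if not self.cells:
            raise InferenceError("dataset holds no cells")
        n = None
        for c in self.cells:
            for tr in (c.control_trace, c.activator_trace):
                if n is None:
                    n = (len(tr), tr.dt_ms)
                elif (len(tr), tr.dt_ms) != n:
                    raise InferenceError("cells are not aligned to a common grid")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def dataset_from_sweepsets(
    sweep_sets: Sequence[SweepSet], protocol_id: str = "C"
) -> JointDataset:
    """Build a calibration dataset from synthetic three-sweep recordings:
    blocker-subtract each cell, take the calibration-protocol traces, and fix
    each cell's voltage offset from its measured reversal potential."""
    cells = []
    protocol = None
    e_k = None
    for ss in sweep_sets:
        control, activator = subtract_sweeps(ss)
        protocol = ss.protocols[protocol_id]
        e_k = ss.truth.e_k_mV
        v_off = compute_voltage_offset(ss.truth.e_k_measured_mV, e_k)
        cells.append(
            CellRecords(
                cell_id=ss.truth.cell_id,
                control_trace=control[protocol_id],
                activator_trace=activator[protocol_id],
                e_k_measured_mV=ss.truth.e_k_measured_mV,
                v_off_mV=v_off,
            )
        )
    return JointDataset(cells=cells, protocol=protocol, e_k_mV=e_k)


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------


def trace_log_likelihood(
    params: KineticParameterSet,
    g_kr_uS: float,
    cell: CellConfig,
    trace: CurrentTrace,
    protocol: VoltageProtocol,
    settings: SimulationSettings | None = None,
) -> float:
    """Gaussian log-likelihood of one trace, up to an additive constant and
    the 1/(2 sigma^2) factor: minus the sum of squared residuals between the
    simulated and observed current at the trace's sample times."""
    settings = settings or SimulationSettings(sampling_ms=trace.dt_ms)
    basis = _model_basis(params, protocol, cell.v_off_mV, cell.e_k, settings)
    if len(basis) != len(trace):
        raise InferenceError(
            f"trace length {len(trace)} does not match protocol grid {len(basis)}"
        )
    resid = g_kr_uS * basis - trace.current_nA
    return -float(resid @ resid)


def _model_basis(
    params: KineticParameterSet,
    protocol: VoltageProtocol,
    v_off: float,
    e_k: float,
    settings: SimulationSettings,
) -> np.ndarray:
    """Unit-conductance model current O(t) * (V(t) - E_K)."""
    dt = settings.sampling_ms or protocol.sampling_ms
    gating = simulate_gating(
        params, protocol,
        CellConfig(g_kr_uS=1.0, e_k_mV=e_k, v_off_mV=v_off),
        settings,
    )
    _, v_cmd = protocol.render_samples(dt)
    return gating.open * (v_cmd - v_off - e_k)


def compute_voltage_offset(e_k_measured_mV: float, e_k_mV: float) -> float:
    """Cell-specific command-voltage offset V_off = E_K,measured - E_K,
    applied downstream as V = V_cmd - V_off."""
    if not (math.isfinite(e_k_measured_mV) and math.isfinite(e_k_mV)):
        raise InferenceError("reversal potentials must be finite")
    return e_k_measured_mV - e_k_mV


def count_free_parameters(n_cells: int) -> int:
    """Dimension of the joint problem: 12 control + 12 activator kinetic
    parameters + one conductance per cell."""
    if n_cells < 1:
        raise InferenceError("need at least one cell")
    return 24 + n_cells


def joint_log_likelihood(
    theta_control: KineticParameterSet,
    theta_rpr: KineticParameterSet,
    g_list: Sequence[float],
    dataset: JointDataset,
    settings: SimulationSettings | None = None,
) -> float:
    """Joint log-likelihood (up to constants): the sum over cells of the
    control-trace and activator-trace log-likelihoods, sharing kinetics
    across cells with cell-specific conductances and fixed offsets."""
    if len(g_list) != dataset.n_cells:
        raise InferenceError("need one conductance per cell")
    total = 0.0
    for cell, g in zip(dataset.cells, g_list):
        cfg = CellConfig(g_kr_uS=1.0, e_k_mV=dataset.e_k_mV, v_off_mV=cell.v_off_mV)
        total += trace_log_likelihood(
            theta_control, g, cfg, cell.control_trace, dataset.protocol, settings
        )
        total += trace_log_likelihood(
            theta_rpr, g, cfg, cell.activator_trace, dataset.protocol, settings
        )
    return total


# ---------------------------------------------------------------------------
# joint fit
# ---------------------------------------------------------------------------


@dataclass
class FitSettings:
    """Optimizer configuration (the recovery property, not these settings,
    is the contract).  ``n_starts`` random starts are drawn log-uniform /
    uniform within the transform bounds, subject to rate plausibility.
    ``block_stride`` subsamples the traces during the per-condition search
    stage (the final joint polish always uses every sample)."""

    n_starts: int = 10
    transform: TransformSpec = field(default_factory=TransformSpec)
    g_bounds_uS: tuple[float, float] = (1e-6, 10.0)
    block_stride: int = 10
    cma_stride: int = 20
    cma_max_evals: int = 1500
    max_nfev_block: int = 600
    max_nfev_joint: int = 60
    xtol: float = 1e-12
    ftol: float = 1e-10
    polish_top: int = 2
    sequential_only: bool = False


@dataclass
class StartRecord:
    index: int
    x0_control: np.ndarray
    x0_rpr: np.ndarray
    sse: float
    success: bool
    message: str = ""
    seconds: float = 0.0


@dataclass
class InferenceResult:
    """Joint-fit output: shared control and activator kinetics, per-cell
    conductances and offsets, the final sum of squared residuals, the
    post-hoc noise estimate and per-start diagnostics."""

    theta_control: KineticParameterSet
    theta_rpr: KineticParameterSet
    g_kr_uS: list[float]
    v_off_mV: list[float]
    sse: float
    sigma_hat_nA: float
    starts: list[StartRecord]
    n_parameters: int
    band_satisfied: bool

    @property
    def log_likelihood(self) -> float:
        return -self.sse


class _ConditionObjective:
    """Per-condition residual with per-cell conductances profiled out.

    The model current is linear in g, so for fixed kinetics each cell's
    conductance has the closed-form least-squares solution
    g* = <basis, data> / <basis, basis> (clipped to its bounds).  ``stride``
    subsamples the data (and simulates on the matching coarser grid) for the
    global-search stage.
    """

    def __init__(self, dataset: JointDataset, condition: str,
                 transform: TransformSpec, g_bounds: tuple[float, float],
                 stride: int = 1):
        self.dataset = dataset
        dt = dataset.cells[0].control_trace.dt_ms
        self.settings = SimulationSettings(sampling_ms=dt * stride)
        # subsampled grid may overhang the simulated grid by one sample when
        # the protocol duration is not a multiple of the coarse interval
        n_sim = int(round(dataset.protocol.duration_ms / (dt * stride)))
        self.data = [
            (c.control_trace if condition == "control" else c.activator_trace)
            .current_nA[::stride][:n_sim]
            for c in dataset.cells
        ]
        self.transform = transform
        self.g_bounds = g_bounds

    def bases(self, x: np.ndarray) -> list[np.ndarray] | None:
        values = self.transform.from_transformed(x)
        try:
            params = KineticParameterSet.from_values(values)
            return [
                _model_basis(params, self.dataset.protocol, c.v_off_mV,
                             self.dataset.e_k_mV, self.settings)
                for c in self.dataset.cells
            ]
        except Exception:
            return None

    def profile_g(self, basis: np.ndarray, data: np.ndarray) -> float:
        bb = float(basis @ basis)
        if bb <= 0:
            return self.g_bounds[0]
        g = float(basis @ data) / bb
        return float(np.clip(g, *self.g_bounds))

    def residuals(self, x: np.ndarray) -> np.ndarray:
        bases = self.bases(x)
        if bases is None:
            return np.full(self._n_resid(), 1e6)
        out = []
        for basis, y in zip(bases, self.data):
            g = self.profile_g(basis, y)
            out.append(g * basis - y)
        out.append(_band_penalties(self.transform.from_transformed(x)))
        return np.concatenate(out)

    def _n_resid(self) -> int:
        return sum(len(y) for y in self.data) + 12


class _JointProblem:
    """The full joint problem in its natural 24 + N parameterization:
    x = [theta_control (transformed, 12), theta_rpr (transformed, 12),
    g_1..g_N (uS)], evaluated at full data resolution.

    The Jacobian exploits the block structure: control kinetics touch only
    control residuals (and vice versa; finite differences re-simulate just
    the affected condition), and the conductance columns are analytic
    (the residual is linear in each g)."""

    def __init__(self, dataset: JointDataset, transform: TransformSpec,
                 g_bounds: tuple[float, float]):
        self.dataset = dataset
        self.transform = transform
        self.g_bounds = g_bounds
        self.settings = SimulationSettings(
            sampling_ms=dataset.cells[0].control_trace.dt_ms
        )
        self.y_c = [c.control_trace.current_nA for c in dataset.cells]
        self.y_r = [c.activator_trace.current_nA for c in dataset.cells]
        self.n_pts = len(self.y_c[0])
        self.n_cells = dataset.n_cells
        self._cache: dict[bytes, list[np.ndarray]] = {}

    def _bases(self, x12: np.ndarray) -> list[np.ndarray]:
        key = x12.tobytes()
        if key not in self._cache:
            params = KineticParameterSet.from_values(
                self.transform.from_transformed(x12)
            )
            if len(self._cache) > 8:
                self._cache.clear()
            self._cache[key] = [
                _model_basis(params, self.dataset.protocol, c.v_off_mV,
                             self.dataset.e_k_mV, self.settings)
                for c in self.dataset.cells
            ]
        return self._cache[key]

    def n_resid(self) -> int:
        return 2 * self.n_cells * self.n_pts + 24

    def residuals(self, x: np.ndarray) -> np.ndarray:
        bc = self._bases(x[:12])
        br = self._bases(x[12:24])
        g = x[24:]
        out = []
        for i in range(self.n_cells):
            out.append(g[i] * bc[i] - self.y_c[i])
            out.append(g[i] * br[i] - self.y_r[i])
        out.append(_band_penalties(self.transform.from_transformed(x[:12])))
        out.append(_band_penalties(self.transform.from_transformed(x[12:24])))
        return np.concatenate(out)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        n = self.n_resid()
        jac = np.zeros((n, 24 + self.n_cells))
        bc = self._bases(x[:12])
        br = self._bases(x[12:24])
        g = x[24:]
        blk = 2 * self.n_pts  # rows per cell: control then activator
        pen_c0 = 2 * self.n_cells * self.n_pts
        pen_r0 = pen_c0 + 12

        def fd_block(x12: np.ndarray, bases0, col0: int, row_off: int,
                     pen_off: int) -> None:
            pen0 = _band_penalties(self.transform.from_transformed(x12))
            for j in range(12):
                h = 1e-6 * max(1.0, abs(x12[j]))
                xp = x12.copy()
                xp[j] += h
                bp = self._bases(xp)
                for i in range(self.n_cells):
                    rows = slice(i * blk + row_off, i * blk + row_off + self.n_pts)
                    jac[rows, col0 + j] = g[i] * (bp[i] - bases0[i]) / h
                penp = _band_penalties(self.transform.from_transformed(xp))
                jac[pen_off:pen_off + 12, col0 + j] = (penp - pen0) / h

        fd_block(x[:12].copy(), bc, 0, 0, pen_c0)
        fd_block(x[12:24].copy(), br, 12, self.n_pts, pen_r0)
        for i in range(self.n_cells):
            jac[i * blk: i * blk + self.n_pts, 24 + i] = bc[i]
            jac[i * blk + self.n_pts: (i + 1) * blk, 24 + i] = br[i]
        return jac

    def profiled_g(self, x24: np.ndarray) -> np.ndarray:
        bc = self._bases(x24[:12])
        br = self._bases(x24[12:24])
        gs = np.empty(self.n_cells)
        for i in range(self.n_cells):
            denom = float(bc[i] @ bc[i] + br[i] @ br[i])
            g = (
                float(bc[i] @ self.y_c[i] + br[i] @ self.y_r[i]) / denom
                if denom > 0
                else 0.0
            )
            gs[i] = float(np.clip(g, *self.g_bounds))
        return gs


def fit_joint(
    dataset: JointDataset,
    settings: FitSettings | None = None,
    seed: int = 1,
    x0_control: np.ndarray | None = None,
    x0_rpr: np.ndarray | None = None,
) -> InferenceResult:
    """Maximize the joint likelihood over shared kinetics and per-cell
    conductances.

    Each start (deterministic under ``seed``) fits the control block, then
    the activator block (12 transformed parameters each, conductances
    profiled per cell), and the top starts are polished jointly in 24
    dimensions with conductances profiled across both conditions.
    ``x0_control``/``x0_rpr`` optionally seed the first start (e.g. at a
    known truth for zero-noise checks).  Raises :class:`InferenceError` when
    every start fails.
    """
    settings = settings or FitSettings()
    transform = settings.transform
    lo, hi = transform.bounds()
    rng = np.random.default_rng(seed)

    obj_c = _ConditionObjective(dataset, "control", transform,
                                settings.g_bounds_uS, settings.block_stride)
    obj_r = _ConditionObjective(dataset, "activator", transform,
                                settings.g_bounds_uS, settings.block_stride)
    cma_c = _ConditionObjective(dataset, "control", transform,
                                settings.g_bounds_uS, settings.cma_stride)
    cma_r = _ConditionObjective(dataset, "activator", transform,
                                settings.g_bounds_uS, settings.cma_stride)
    joint = _JointProblem(dataset, transform, settings.g_bounds_uS)

    def _fit_block(obj_cma, obj_trf, x0, use_cma=True):
        """Global (CMA-ES) then local (trust-region LSQ) fit of one block."""
        if use_cma and settings.cma_max_evals > 0:
            def f(x):
                r = obj_cma.residuals(x)
                return float(r @ r)
            x0, _, _ = cma_es_minimize(
                f, x0, lo, hi, rng, max_evals=settings.cma_max_evals
            )
        return least_squares(
            obj_trf.residuals, np.clip(x0, lo, hi), bounds=(lo, hi),
            method="trf", x_scale="jac", max_nfev=settings.max_nfev_block,
            xtol=settings.xtol, ftol=settings.ftol,
        )

    starts: list[StartRecord] = []
    candidates: list[tuple[float, np.ndarray]] = []
    block_c: list[tuple[float, np.ndarray]] = []
    block_r: list[tuple[float, np.ndarray]] = []
    for k in range(settings.n_starts):
        t_start = time.perf_counter()
        seeded = k == 0 and x0_control is not None and x0_rpr is not None
        if seeded:
            xc0 = np.asarray(x0_control, dtype=float)
            xr0 = np.asarray(x0_rpr, dtype=float)
        else:
            xc0 = transform.sample_start(rng)
            xr0 = transform.sample_start(rng)
        ok = True
        msg = ""
        try:
            sol_c = _fit_block(cma_c, obj_c, xc0, use_cma=not seeded)
            sol_r = _fit_block(cma_r, obj_r, xr0, use_cma=not seeded)
            block_c.append((float(sol_c.fun @ sol_c.fun), sol_c.x))
            block_r.append((float(sol_r.fun @ sol_r.fun), sol_r.x))
            x24 = np.concatenate([sol_c.x, sol_r.x])
            x_full = np.concatenate([x24, joint.profiled_g(x24)])
            resid = joint.residuals(x_full)
            sse = float(resid @ resid)
            candidates.append((sse, x_full))
        except Exception as exc:  # pragma: no cover - defensive
            ok = False
            msg = str(exc)
            sse = float("inf")
        starts.append(
            StartRecord(
                index=k, x0_control=xc0, x0_rpr=xr0, sse=sse, success=ok,
                message=msg, seconds=time.perf_counter() - t_start,
            )
        )
    if not candidates:
        details = "; ".join(f"start {s.index}: {s.message}" for s in starts)
        raise InferenceError(f"all optimizer starts failed ({details})")

    # The two condition blocks are independent given the profiled
    # conductances, so candidates can mix the best control and best
    # activator solutions across starts.  Additionally, because activator
    # kinetics are a perturbation of control kinetics, each block is
    # cross-seeded once from the other block's best solution — this escapes
    # a persistent activator-side local optimum cheaply.
    if block_c and block_r:
        best_c = min(block_c, key=lambda b: b[0])
        best_r = min(block_r, key=lambda b: b[0])
        try:
            sol_r2 = _fit_block(cma_r, obj_r, best_c[1], use_cma=False)
            block_r.append((float(sol_r2.fun @ sol_r2.fun), sol_r2.x))
            sol_c2 = _fit_block(cma_c, obj_c, best_r[1], use_cma=False)
            block_c.append((float(sol_c2.fun @ sol_c2.fun), sol_c2.x))
        except Exception:
            pass
        best_c = min(block_c, key=lambda b: b[0])
        best_r = min(block_r, key=lambda b: b[0])
        x24 = np.concatenate([best_c[1], best_r[1]])
        x_full = np.concatenate([x24, joint.profiled_g(x24)])
        resid = joint.residuals(x_full)
        candidates.append((float(resid @ resid), x_full))

    candidates.sort(key=lambda c: c[0])
    best_sse, best_x = candidates[0]
    if not settings.sequential_only:
        g_lo, g_hi = settings.g_bounds_uS
        lo_full = np.concatenate([lo, lo, np.full(dataset.n_cells, g_lo)])
        hi_full = np.concatenate([hi, hi, np.full(dataset.n_cells, g_hi)])
        for sse0, x0 in candidates[: max(1, settings.polish_top)]:
            try:
                sol = least_squares(
                    joint.residuals, x0, jac=joint.jacobian,
                    bounds=(lo_full, hi_full), method="trf", x_scale="jac",
                    tr_solver="exact", max_nfev=settings.max_nfev_joint,
                    xtol=settings.xtol, ftol=settings.ftol,
                )
            except Exception:
                continue
            sse = float(sol.fun @ sol.fun)
            if sse < best_sse:
                best_sse, best_x = sse, sol.x

    theta_c = KineticParameterSet.from_values(
        transform.from_transformed(best_x[:12]), label="control (fitted)"
    )
    theta_r = KineticParameterSet.from_values(
        transform.from_transformed(best_x[12:24]), label="activator (fitted)"
    )
    g_list = [float(g) for g in best_x[24:]]
    n_points = 2 * sum(len(c.control_trace) for c in dataset.cells)
    sigma_hat = math.sqrt(max(best_sse, 0.0) / n_points)
    band_ok = _band_ok(theta_c) and _band_ok(theta_r)
    return InferenceResult(
        theta_control=theta_c,
        theta_rpr=theta_r,
        g_kr_uS=g_list,
        v_off_mV=[c.v_off_mV for c in dataset.cells],
        sse=best_sse,
        sigma_hat_nA=sigma_hat,
        starts=starts,
        n_parameters=count_free_parameters(dataset.n_cells),
        band_satisfied=band_ok,
    )


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def staircase_qc_check(
    first: CurrentTrace,
    repeat: CurrentTrace,
    threshold: float = 0.10,
    expected_noise_sd: float | None = None,
) -> tuple[bool, float]:
    """Stability check between the first and repeated calibration staircase:
    drift = RMS(first - repeat) / RMS(first); passes when drift is below the
    threshold.

    When the measurement noise is known, ``expected_noise_sd`` (the sd of
    ``first - repeat`` under pure noise, i.e. sqrt(sd1^2 + sd2^2)) removes
    the noise contribution from the drift so the metric reflects genuine
    instability (rundown, seal changes) only.
    """
    if len(first) != len(repeat) or abs(first.dt_ms - repeat.dt_ms) > 1e-12:
        raise InferenceError("staircase traces are on different grids")
    denom = float(np.sqrt(np.mean(first.current_nA**2)))
    if denom == 0:
        raise InferenceError("reference staircase trace is identically zero")
    diff_var = float(np.mean((first.current_nA - repeat.current_nA) ** 2))
    if expected_noise_sd is not None:
        diff_var = max(diff_var - expected_noise_sd**2, 0.0)
    drift = math.sqrt(diff_var) / denom
    return drift < threshold, drift
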