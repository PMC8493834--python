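"""Quantitative trace analyses (gating biomarkers).

Implements the standard analyses applied to hERG voltage-clamp recordings:

* bi-exponential fits of tail-current decay (deactivation time constants
  tau_f <= tau_s and the fast fraction A_f/(A_f+A_s)),
* conductance-voltage (G-V) curves from peak tail currents, fitted with a
  Boltzmann function y = scale / (1 + exp((V1/2 - V)/k)),
* whole-cell conductance from the linear region of the fully activated I-V
  relation at strongly hyperpolarized voltages,
* the rectification-method inactivation curve
  R = I_hERG / [G * n * (V_t - E_rev)],
* protective currents in response to premature depolarizations (single
  exponential fits extrapolated back to the step onset, normalized to
  whole-cell conductance),
* action-potential-clamp metrics (peak early transient current, peak
  resurgent current and the voltage at which it occurs),
* reversal-potential estimation from the zero crossing of instantaneous tail
  currents.

All fits exclude a configurable blanking window (default 1 ms) after each
voltage step; experimental records carry capacitive transients there, and the
analysis contract is kept identical for synthetic traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from .protocols import VoltageProtocol
from .simulate import CurrentTrace

__all__ = [
    "BiomarkerError",
    "NoReversalError",
    "ExponentialFitResult",
    "BoltzmannFitResult",
    "RectificationCurve",
    "ProtectiveCurrentCurve",
    "APClampMetrics",
    "fit_exponential_decay",
    "build_gv_from_tails",
    "fit_boltzmann",
    "estimate_linear_conductance",
    "compute_rectification",
    "measure_protective_currents",
    "measure_ap_clamp_metrics",
    "estimate_reversal_potential",
    "instantaneous_tail_iv",
    "fully_activated_iv",
    "sweep_sample_ranges",
]

DEFAULT_BLANK_MS = 1.0


class BiomarkerError(RuntimeError):
    """Fit failure or inconsistent analysis inputs."""


class NoReversalError(BiomarkerError):
    """Tail I-V does not span a sign change."""


# ---------------------------------------------------------------------------
# helpers for slicing traces by protocol structure
# ---------------------------------------------------------------------------


def sweep_sample_ranges(
    protocol: VoltageProtocol, dt_ms: float
) -> list[list[tuple[int, int]]]:
    """Per sweep, per segment: the half-open output-grid index range
    [i, j) of samples belonging to that segment."""
    n_total = int(round(protocol.duration_ms / dt_ms))
    ranges: list[list[tuple[int, int]]] = []
    offset = 0.0
    for sweep in protocol.sweeps:
        segs = []
        for seg in sweep.segments:
            i = int(math.ceil(offset / dt_ms - 1e-9))
            j = min(int(math.ceil((offset + seg.duration_ms) / dt_ms - 1e-9)), n_total)
            segs.append((i, j))
            offset += seg.duration_ms
        ranges.append(segs)
    return ranges


def _segment_window(
    trace: CurrentTrace, protocol: VoltageProtocol, sweep_idx: int, seg_idx: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """(t_rel, current, seg_start_time) for one segment of one sweep;
    t_rel is measured from the segment start."""
    ranges = sweep_sample_ranges(protocol, trace.dt_ms)
    i, j = ranges[sweep_idx][seg_idx]
    start = sum(
        s.duration_ms
        for sw in protocol.sweeps[:sweep_idx]
        for s in sw.segments
    ) + sum(s.duration_ms for s in protocol.sweeps[sweep_idx].segments[:seg_idx])
    t = trace.times_ms[i:j] - start
    return t, trace.current_nA[i:j], start


# ---------------------------------------------------------------------------
# exponential decay fits
# ---------------------------------------------------------------------------


@dataclass
class ExponentialFitResult:
    """Result of a one- or two-term exponential decay fit.

    Amplitudes are signed (nA); time constants are ordered tau_f <= tau_s
    (ms); ``fast_fraction`` is A_f/(A_f + A_s).  ``degenerate`` flags fits
    that are effectively mono-exponential (amplitude ratio < 1e-3 or time
    constants within 20% of each other) or have vanishing amplitude.
    """

    n_terms: int
    amp_fast_nA: float
    amp_slow_nA: float
    tau_fast_ms: float
    tau_slow_ms: float
    offset_nA: float
    residual_rms_nA: float
    degenerate: bool = False

    @property
    def fast_fraction(self) -> float:
        total = self.amp_fast_nA + self.amp_slow_nA
        if total == 0:
            return float("nan")
        return self.amp_fast_nA / total

    def value_at(self, t: float | np.ndarray) -> np.ndarray:
        """Fitted model evaluated at time t (ms) from the window start."""
        out = self.offset_nA + self.amp_fast_nA * np.exp(-np.asarray(t) / self.tau_fast_ms)
        if self.n_terms == 2:
            out = out + self.amp_slow_nA * np.exp(-np.asarray(t) / self.tau_slow_ms)
        return out


def _exp_model(t: np.ndarray, x: np.ndarray, n_terms: int) -> np.ndarray:
    if n_terms == 1:
        c, a, log_tau = x
        return c + a * np.exp(-t / np.exp(log_tau))
    c, a1, lt1, a2, lt2 = x
    return c + a1 * np.exp(-t / np.exp(lt1)) + a2 * np.exp(-t / np.exp(lt2))


def fit_exponential_decay(
    trace: CurrentTrace | np.ndarray,
    window: tuple[float, float] | None = None,
    n_terms: int = 2,
    t: np.ndarray | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> ExponentialFitResult:
    """Least-squares fit of a (bi-)exponential decay to a trace segment.

    ``window`` selects [t0, t1) in trace time; the fitted time axis starts at
    the window start (amplitudes refer to t = window start).  Initial guesses
    come from log-linear regression on the head and tail of the segment and
    are refined from ``n_starts`` jittered multi-starts; time constants are
    relabeled so tau_f <= tau_s.  Raises on non-convergence of every start.
    """
    if n_terms not in (1, 2):
        raise BiomarkerError("n_terms must be 1 or 2")
    if isinstance(trace, CurrentTrace):
        tt = trace.times_ms
        yy = trace.current_nA
    else:
        yy = np.asarray(trace, dtype=float)
        tt = np.asarray(t, dtype=float) if t is not None else np.arange(len(yy), dtype=float)
    if window is not None:
        sel = (tt >= window[0]) & (tt < window[1])
        tt, yy = tt[sel], yy[sel]
    if len(yy) < 50:
        raise BiomarkerError(f"fit window holds {len(yy)} samples; need >= 50")
    tt = tt - tt[0]
    span = float(tt[-1])

    y_end = float(np.mean(yy[-max(5, len(yy) // 20):]))
    amp0 = float(yy[0] - y_end)
    scale = max(abs(amp0), float(np.std(yy)), 1e-12)

    if abs(amp0) < 1e-12 * max(1.0, abs(y_end)) and np.std(yy) < 1e-15:
        # constant input: no decay to fit
        return ExponentialFitResult(
            n_terms, 0.0, 0.0, span / 4 or 1.0, span or 1.0, y_end, 0.0,
            degenerate=True,
        )

    # crude tau estimates from log-linear regression on |y - y_end|
    resid = np.abs(yy - y_end)
    pos = resid > 1e-3 * scale
    if np.count_nonzero(pos) >= 10:
        coeffs = np.polyfit(tt[pos], np.log(resid[pos]), 1)
        tau_guess = -1.0 / coeffs[0] if coeffs[0] < 0 else span / 3
    else:
        tau_guess = span / 3
    tau_guess = min(max(tau_guess, 1e-3), 10 * span)

    rng = np.random.default_rng(seed)
    best = None
    for k in range(max(1, n_starts)):
        jitter = rng.lognormal(0.0, 0.5, size=2) if k else np.array([1.0, 1.0])
        if n_terms == 1:
            x0 = np.array([y_end, amp0, np.log(tau_guess * jitter[0])])
        else:
            x0 = np.array(
                [
                    y_end,
                    0.6 * amp0,
                    np.log(max(tau_guess * 0.3 * jitter[0], 1e-3)),
                    0.4 * amp0,
                    np.log(tau_guess * 3.0 * jitter[1]),
                ]
            )
        try:
            sol = least_squares(
                lambda x: _exp_model(tt, x, n_terms) - yy, x0,
                method="lm", max_nfev=4000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise BiomarkerError("exponential fit failed to converge from every start")

    rms = float(np.sqrt(2 * best.cost / len(yy)))
    if n_terms == 1:
        c, a, lt = best.x
        tau = float(np.exp(lt))
        deg = bool(abs(a) < 1e-3 * scale)
        return ExponentialFitResult(1, float(a), 0.0, tau, tau, float(c), rms, deg)
    c, a1, lt1, a2, lt2 = best.x
    t1, t2 = float(np.exp(lt1)), float(np.exp(lt2))
    if t1 > t2:
        a1, a2, t1, t2 = a2, a1, t2, t1
    amp_scale = max(abs(a1), abs(a2), 1e-300)
    deg = bool(
        min(abs(a1), abs(a2)) / amp_scale < 1e-3
        or t2 / max(t1, 1e-300) < 1.2
        or amp_scale < 1e-3 * scale
    )
    return ExponentialFitResult(2, float(a1), float(a2), t1, t2, float(c), rms, deg)


# ---------------------------------------------------------------------------
# G-V and Boltzmann
# ---------------------------------------------------------------------------


def build_gv_from_tails(
    trace: CurrentTrace,
    protocol: VoltageProtocol,
    tail_segment: int = 1,
    blank_ms: float = DEFAULT_BLANK_MS,
) -> pd.DataFrame:
    """Normalized conductance-voltage relation from peak tail currents.

    For each sweep of an activation protocol, the peak absolute tail current
    after the blanking window is measured and normalized to the maximum
    across sweeps (series maximum exactly 1).  Returns a DataFrame with
    columns ``test_voltage_mV``, ``peak_tail_nA``, ``g_norm``.
    """
    volts, peaks = [], []
    for si, sweep in enumerate(protocol.sweeps):
        t, y, _ = _segment_window(trace, protocol, si, tail_segment)
        sel = t >= blank_ms
        if not np.any(sel):
            raise BiomarkerError("blanking window consumes the whole tail segment")
        k = int(np.argmax(np.abs(y[sel])))
        peaks.append(float(y[sel][k]))
        volts.append(float(sweep.metadata.get("test_voltage_mV", np.nan)))
    peaks_arr = np.abs(np.array(peaks))
    if np.max(peaks_arr) <= 0:
        raise BiomarkerError("all tail currents are zero; cannot normalize")
    return pd.DataFrame(
        {
            "test_voltage_mV": volts,
            "peak_tail_nA": peaks,
            "g_norm": peaks_arr / np.max(peaks_arr),
        }
    )


@dataclass
class BoltzmannFitResult:
    """Fit of y = scale / (1 + exp((V1/2 - V)/k)).  Positive k describes
    activation (y rises with depolarization); negative k describes
    inactivation/availability curves."""

    v_half_mV: float
    k_mV: float
    scale: float = 1.0
    transition_in_range: bool = True

    def value_at(self, v: float | np.ndarray) -> np.ndarray:
        return self.scale / (1.0 + np.exp((self.v_half_mV - np.asarray(v)) / self.k_mV))


def fit_boltzmann(
    voltages: Sequence[float], y: Sequence[float], fit_scale: bool = True
) -> BoltzmannFitResult:
    """Least-squares Boltzmann fit of a normalized (in)activation curve."""
    v = np.asarray(voltages, dtype=float)
    yy = np.asarray(y, dtype=float)
    if len(v) < 5:
        raise BiomarkerError("Boltzmann fit needs >= 5 points")
    # initial guesses: midpoint from the half-maximum crossing, slope sign
    # from the direction of change
    y_lo, y_hi = float(yy[np.argmin(v)]), float(yy[np.argmax(v)])
    rising = y_hi >= y_lo
    half = 0.5 * (np.min(yy) + np.max(yy))
    order = np.argsort(v)
    vs, ys = v[order], yy[order]
    crossings = np.where(np.diff(np.sign(ys - half)) != 0)[0]
    v_half0 = float(vs[crossings[0]]) if len(crossings) else float(np.median(v))
    k0 = (np.ptp(v) / 8.0) * (1 if rising else -1)

    def model(vv, v_half, k, scale):
        return scale / (1.0 + np.exp((v_half - vv) / k))

    p0 = [v_half0, k0, float(np.max(np.abs(yy))) or 1.0]
    if not fit_scale:
        p0 = p0[:2]
        model_fn = lambda vv, v_half, k: model(vv, v_half, k, 1.0)
    else:
        model_fn = model
    try:
        popt, _ = curve_fit(model_fn, v, yy, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise BiomarkerError(f"Boltzmann fit did not converge: {exc}") from exc
    v_half, k = float(popt[0]), float(popt[1])
    scale = float(popt[2]) if fit_scale else 1.0
    in_range = bool(np.min(v) <= v_half <= np.max(v))
    return BoltzmannFitResult(v_half, k, scale, transition_in_range=in_range)


# ---------------------------------------------------------------------------
# fully activated I-V, whole-cell conductance, rectification
# ---------------------------------------------------------------------------


def fully_activated_iv(
    trace: CurrentTrace,
    protocol: VoltageProtocol,
    tail_segment: int = 1,
    blank_ms: float = DEFAULT_BLANK_MS,
) -> pd.DataFrame:
    """Maximal (signed, largest-magnitude) current during each repolarizing
    step of the deactivation protocol vs tail voltage."""
    volts, peaks = [], []
    for si, sweep in enumerate(protocol.sweeps):
        t, y, _ = _segment_window(trace, protocol, si, tail_segment)
        sel = t >= blank_ms
        k = int(np.argmax(np.abs(y[sel])))
        peaks.append(float(y[sel][k]))
        volts.append(float(sweep.metadata.get("tail_voltage_mV",
                                              sweep.metadata.get("test_voltage_mV"))))
    return pd.DataFrame({"voltage_mV": volts, "current_nA": peaks})


def estimate_linear_conductance(
    voltages: Sequence[float],
    currents: Sequence[float],
    v_range: tuple[float, float] = (-140.0, -110.0),
) -> tuple[float, float]:
    """Whole-cell conductance: ordinary least-squares slope (uS) and
    intercept (nA) of the fully activated I-V over the linear region at
    strongly hyperpolarized voltages."""
    v = np.asarray(voltages, dtype=float)
    i = np.asarray(currents, dtype=float)
    sel = (v >= v_range[0]) & (v <= v_range[1])
    if np.count_nonzero(sel) < 3:
        raise BiomarkerError(
            f"need >= 3 I-V points in [{v_range[0]}, {v_range[1]}] mV"
        )
    slope, intercept = np.polyfit(v[sel], i[sel], 1)
    return float(slope), float(intercept)


@dataclass
class RectificationCurve:
    """Rectification factor R(V) = I / [G * n * (V_t - E_rev)]; points within
    ``mask_mV`` of the reversal potential are masked (NaN) to avoid division
    blow-up."""

    voltages_mV: np.ndarray
    r: np.ndarray
    conductance_uS: float
    n_at_plus40: float
    e_rev_mV: float


def compute_rectification(
    voltages: Sequence[float],
    currents: Sequence[float],
    conductance_uS: float,
    n_at_plus40: float,
    e_rev_mV: float,
    mask_mV: float = 5.0,
) -> RectificationCurve:
    if conductance_uS <= 0:
        raise BiomarkerError("conductance must be > 0")
    if not (0 < n_at_plus40 <= 1):
        raise BiomarkerError("activation variable n must lie in (0, 1]")
    v = np.asarray(voltages, dtype=float)
    i = np.asarray(currents, dtype=float)
    driving = v - e_rev_mV
    r = np.where(
        np.abs(driving) < mask_mV,
        np.nan,
        i / (conductance_uS * n_at_plus40 * driving),
    )
    return RectificationCurve(v, r, conductance_uS, n_at_plus40, e_rev_mV)


# ---------------------------------------------------------------------------
# protective currents
# ---------------------------------------------------------------------------


@dataclass
class ProtectiveCurrentCurve:
    """Protective-current amplitudes vs coupling interval.

    ``amplitudes_nA`` are the exponential-fit amplitudes extrapolated to the
    premature-step onset; ``normalized`` divides by the whole-cell
    conductance (nA/uS = mV).  ``fallback_used`` marks sweeps where the
    decaying-exponential fit was invalid and the in-step maximum was used.
    """

    coupling_intervals_ms: np.ndarray
    amplitudes_nA: np.ndarray
    normalized: np.ndarray
    peak_amplitude: float
    peak_interval_ms: float
    fallback_used: np.ndarray

    def amplitude_at(self, interval_ms: float) -> float:
        """Normalized amplitude at (the grid point nearest to) a coupling
        interval."""
        k = int(np.argmin(np.abs(self.coupling_intervals_ms - interval_ms)))
        return float(self.normalized[k])


def measure_protective_currents(
    trace: CurrentTrace,
    protocol: VoltageProtocol,
    conductance_uS: float,
    blank_ms: float = DEFAULT_BLANK_MS,
    extrapolate_to: str = "onset",
) -> ProtectiveCurrentCurve:
    """Measure protective currents on a premature-stimulation protocol.

    For each sweep, a single exponential is fitted to the decaying current
    during the 40-ms step (after the blanking window) and extrapolated back
    to the step onset (``extrapolate_to="blank_end"`` extrapolates to the end
    of the blanking window instead).  Amplitudes are normalized to the
    supplied whole-cell conductance.
    """
    if conductance_uS <= 0:
        raise BiomarkerError("conductance must be > 0")
    offsets = protocol.sweep_offsets()
    intervals, amps, fallback = [], [], []
    for si, sweep in enumerate(protocol.sweeps):
        meta = sweep.metadata
        if "coupling_interval_ms" not in meta:
            raise BiomarkerError("sweep lacks coupling-interval metadata")
        onset = offsets[si] + float(meta["step_onset_ms"])
        width = float(meta.get("step_duration_ms", 40.0))
        t = trace.times_ms
        sel = (t >= onset + blank_ms) & (t < onset + width)
        y = trace.current_nA[sel]
        ts = t[sel] - (onset if extrapolate_to == "onset" else onset + blank_ms)
        used_fallback = False
        try:
            fit = fit_exponential_decay(y, n_terms=1, t=ts, seed=si)
            # the fit's time axis starts at ts[0]; extrapolate to ts = 0

            amp = float(fit.offset_nA + fit.amp_fast_nA * np.exp(ts[0] / fit.tau_fast_ms))
            decaying = fit.amp_fast_nA > 0 and not fit.degenerate
        except BiomarkerError:
            decaying = False
            amp = float("nan")
        if not decaying or not np.isfinite(amp):
            amp = float(np.max(y))
            used_fallback = True
        intervals.append(float(meta["coupling_interval_ms"]))
        amps.append(amp)
        fallback.append(used_fallback)
    intervals_arr = np.array(intervals)
    amps_arr = np.array(amps)
    order = np.argsort(intervals_arr)
    intervals_arr, amps_arr = intervals_arr[order], amps_arr[order]
    fallback_arr = np.array(fallback)[order]
    normalized = amps_arr / conductance_uS
    k = int(np.argmax(amps_arr))
    return ProtectiveCurrentCurve(
        intervals_arr, amps_arr, normalized,
        peak_amplitude=float(normalized[k]),
        peak_interval_ms=float(intervals_arr[k]),
        fallback_used=fallback_arr,
    )


# ---------------------------------------------------------------------------
# AP-clamp metrics
# ---------------------------------------------------------------------------


@dataclass
class APClampMetrics:
    """Peak early transient current, peak resurgent current (both in nA, or
    normalized when a normalization was supplied) and the command voltage at
    the resurgent peak."""

    peak_transient: float
    peak_resurgent: float
    peak_voltage_mV: float
    normalization: str = "none"


def measure_ap_clamp_metrics(
    trace: CurrentTrace,
    protocol: VoltageProtocol,
    normalization: str = "none",
    normalization_value: float | None = None,
    transient_window_ms: float = 20.0,
    beat: int = -1,
) -> APClampMetrics:
    """AP-clamp metrics on one beat of an action-potential train.

    ``peak_transient`` is the maximum outward current within the first
    ``transient_window_ms`` after the upstroke of the selected beat (default:
    the last, rate-adapted beat); ``peak_resurgent`` is the maximum outward
    current during the remainder of the waveform; ``peak_voltage`` is the
    command voltage at the resurgent peak (ties broken toward earlier times).
    ``normalization`` is ``"none"``, ``"conductance"`` (divide by whole-cell
    conductance, uS) or ``"peak_tail"`` (divide by a peak tail current, nA).
    """
    meta = protocol.sweeps[0].metadata
    if "beat_onsets_ms" not in meta:
        raise BiomarkerError("protocol lacks beat-onset metadata")
    onsets = list(meta["beat_onsets_ms"])
    ap_dur = float(meta["ap_duration_ms"])
    onset = float(onsets[beat])
    t = trace.times_ms
    if onset + ap_dur > t[-1] + trace.dt_ms:
        raise BiomarkerError("analysis window extends past the trace")
    trans = (t >= onset) & (t < onset + transient_window_ms)
    resurg = (t >= onset + transient_window_ms) & (t < onset + ap_dur)
    if not np.any(trans) or not np.any(resurg):
        raise BiomarkerError("analysis windows are empty at this sampling")
    peak_trans = float(np.max(trace.current_nA[trans]))
    k = int(np.argmax(trace.current_nA[resurg]))
    peak_res = float(trace.current_nA[resurg][k])
    t_peak = float(t[resurg][k])
    if trace.voltage_mV is not None:
        v_peak = float(trace.voltage_mV[np.searchsorted(t, t_peak)])
    else:
        v_peak = protocol.voltage_at(t_peak)

    if normalization == "none":
        denom = 1.0
    elif normalization in ("conductance", "peak_tail"):
        if not normalization_value or normalization_value <= 0:
            raise BiomarkerError("normalization value must be > 0")
        denom = float(normalization_value)
    else:
        raise BiomarkerError(f"unknown normalization {normalization!r}")
    return APClampMetrics(
        peak_transient=peak_trans / denom,
        peak_resurgent=peak_res / denom,
        peak_voltage_mV=v_peak,
        normalization=normalization,
    )


# ---------------------------------------------------------------------------
# reversal potential
# ---------------------------------------------------------------------------


def instantaneous_tail_iv(
    trace: CurrentTrace,
    protocol: VoltageProtocol,
    tail_segment: int = 1,
    blank_ms: float = DEFAULT_BLANK_MS,
) -> pd.DataFrame:
    """Instantaneous tail current (first sample after the blanking window of
    each repolarizing step) vs tail voltage."""
    volts, inst = [], []
    for si, sweep in enumerate(protocol.sweeps):
        t, y, _ = _segment_window(trace, protocol, si, tail_segment)
        sel = np.where(t >= blank_ms)[0]
        if len(sel) == 0:
            raise BiomarkerError("blanking window consumes the tail segment")
        inst.append(float(y[sel[0]]))
        volts.append(float(sweep.metadata.get("tail_voltage_mV",
                                              sweep.metadata.get("test_voltage_mV"))))
    return pd.DataFrame({"voltage_mV": volts, "current_nA": inst})


def estimate_reversal_potential(
    voltages: Sequence[float], currents: Sequence[float]
) -> float:
    """Reversal potential (mV) by linear interpolation of the zero crossing
    of an instantaneous tail I-V; raises :class:`NoReversalError` when the
    currents do not change sign."""
    v = np.asarray(voltages, dtype=float)
    i = np.asarray(currents, dtype=float)
    order = np.argsort(v)
    v, i = v[order], i[order]
    sign = np.sign(i)
    crossings = np.where(np.diff(sign) != 0)[0]
    if len(crossings) == 0:
        raise NoReversalError("tail currents do not span a sign change")
    k = int(crossings[0])
    if i[k] == i[k + 1]:
        return float(0.5 * (v[k] + v[k + 1]))
    return float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]))
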