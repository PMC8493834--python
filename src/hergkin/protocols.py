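"""Voltage-clamp command protocols.

A :class:`VoltageProtocol` is an ordered list of sweeps, each an ordered list
of piecewise segments (``step``, ``ramp`` or ``sampled``).  Time is measured
in ms from the start of the protocol, sweeps are concatenated, and segment
intervals follow the half-open convention ``[t_start, t_end)`` — the command
voltage exactly at a boundary is that of the later segment.  Sampled segments
hold each sample for one sampling interval (piecewise-constant, as delivered
by a D/A converter).

Builders cover the protocol suite used to characterize hERG gating:

* square activation protocols (250-ms steps at 21 deg C in oocytes; shortened
  1,500-ms steps at 37 deg C in HEK cells),
* the deactivation/fully-activated-IV protocol (+40 mV step, 750-ms tails),
* the 37 deg C inactivation protocol (+20 mV prepulse, 800-ms repolarizing steps),
* a premature-stimulation protocol (stylized action potential followed by
  40-ms depolarizing steps to 0 mV at a grid of coupling intervals relative
  to 90% repolarization),
* action-potential-clamp trains of the stylized waveform,
* the ~19-s calibration "staircase" (bundled step table, configurable),
* arbitrary sampled waveforms loaded from two-column CSV, including a bundled
  synthetic complex action-potential train.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ProtocolError",
    "ProtocolSegment",
    "Sweep",
    "VoltageProtocol",
    "StylizedAPSpec",
    "voltage_at",
    "build_activation_protocol",
    "build_deactivation_protocol",
    "build_inactivation_protocol_37C",
    "build_premature_stimulation_protocol",
    "build_ap_clamp_protocol",
    "build_staircase_protocol",
    "build_complex_ap_train",
    "load_sampled_protocol",
    "save_sampled_protocol",
    "load_bundled_complex_ap",
]

_TIME_TOL = 1e-9


class ProtocolError(ValueError):
    """Malformed protocol definition or out-of-range query."""


@dataclass
class ProtocolSegment:
    """One piece of a voltage command.

    ``kind`` is ``"step"`` (constant ``v_start == v_end``), ``"ramp"`` (linear
    from ``v_start`` to ``v_end``) or ``"sampled"`` (``samples`` held for
    ``dt_ms`` each; ``duration_ms == len(samples) * dt_ms``).
    """

    kind: str
    duration_ms: float
    v_start: float
    v_end: float
    samples: np.ndarray | None = None
    dt_ms: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ramp", "sampled"):
            raise ProtocolError(f"unknown segment kind {self.kind!r}")
        if not (self.duration_ms > 0):
            raise ProtocolError("segment duration must be > 0")
        if self.kind == "step" and self.v_start != self.v_end:
            raise ProtocolError("step segment requires v_start == v_end")
        if self.kind == "sampled":
            if self.samples is None or self.dt_ms is None or self.dt_ms <= 0:
                raise ProtocolError("sampled segment requires samples and dt_ms > 0")
            self.samples = np.asarray(self.samples, dtype=float)
            n = len(self.samples)
            if n < 1 or abs(n * self.dt_ms - self.duration_ms) > _TIME_TOL * max(1.0, self.duration_ms):
                raise ProtocolError(
                    "sampled segment sampling interval must divide its duration "
                    f"(n*dt = {n * self.dt_ms} != duration {self.duration_ms})"
                )

    def voltage(self, t_rel: float) -> float:
        """Command voltage at time ``t_rel`` in [0, duration) from segment start."""
        if t_rel < -_TIME_TOL or t_rel >= self.duration_ms:
            raise ProtocolError(f"time {t_rel} outside segment [0, {self.duration_ms})")
        if self.kind == "step":
            return self.v_start
        if self.kind == "ramp":
            return self.v_start + (self.v_end - self.v_start) * t_rel / self.duration_ms
        i = min(int(math.floor(t_rel / self.dt_ms + _TIME_TOL)), len(self.samples) - 1)
        return float(self.samples[i])

    def to_json(self) -> dict:
        d = {
            "kind": self.kind,
            "duration_ms": self.duration_ms,
            "v_start": self.v_start,
            "v_end": self.v_end,
        }
        if self.kind == "sampled":
            d["dt_ms"] = self.dt_ms
            d["samples"] = [float(v) for v in self.samples]
        return d

    @classmethod
    def from_json(cls, d: dict) -> "ProtocolSegment":
        return cls(
            kind=d["kind"],
            duration_ms=float(d["duration_ms"]),
            v_start=float(d["v_start"]),
            v_end=float(d["v_end"]),
            samples=np.asarray(d["samples"], dtype=float) if "samples" in d else None,
            dt_ms=float(d["dt_ms"]) if "dt_ms" in d else None,
        )


def step(v: float, duration_ms: float) -> ProtocolSegment:
    """Convenience constructor for a constant-voltage segment."""
    return ProtocolSegment("step", duration_ms, v, v)


def ramp(v_start: float, v_end: float, duration_ms: float) -> ProtocolSegment:
    return ProtocolSegment("ramp", duration_ms, v_start, v_end)


@dataclass
class Sweep:
    segments: list[ProtocolSegment]
    metadata: dict = field(default_factory=dict)

    @property
    def duration_ms(self) -> float:
        return float(sum(s.duration_ms for s in self.segments))

    def to_json(self) -> dict:
        return {
            "segments": [s.to_json() for s in self.segments],
            "metadata": self.metadata,
        }

    @classmethod
    def from_json(cls, d: dict) -> "Sweep":
        return cls(
            segments=[ProtocolSegment.from_json(s) for s in d["segments"]],
            metadata=dict(d.get("metadata", {})),
        )


@dataclass
class VoltageProtocol:
    """An ordered set of sweeps with a holding potential and output sampling
    interval.  Each simulated sweep starts from the steady state at the
    holding potential (the limit of a long inter-sweep hold)."""

    holding_mV: float
    sweeps: list[Sweep]
    sampling_ms: float = 0.1
    name: str = ""

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ProtocolError("protocol needs at least one sweep")
        if self.sampling_ms <= 0:
            raise ProtocolError("sampling interval must be > 0")

    @property
    def duration_ms(self) -> float:
        return float(sum(sw.duration_ms for sw in self.sweeps))

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    def sweep_offsets(self) -> np.ndarray:
        """Start time of each sweep in protocol time."""
        durs = [sw.duration_ms for sw in self.sweeps]
        return np.concatenate([[0.0], np.cumsum(durs)[:-1]])

    def voltage_at(self, t: float) -> float:
        return voltage_at(self, t)

    def render_samples(self, dt_ms: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Sample the command voltage at ``k * dt`` over [0, duration)."""
        dt = dt_ms or self.sampling_ms
        n = int(round(self.duration_ms / dt))
        t = np.arange(n) * dt
        v = np.empty(n)
        i = 0
        offset = 0.0
        for sw in self.sweeps:
            for seg in sw.segments:
                end = offset + seg.duration_ms
                j = min(int(math.ceil(end / dt - 1e-9)), n)
                tt = t[i:j] - offset
                if seg.kind == "step":
                    v[i:j] = seg.v_start
                elif seg.kind == "ramp":
                    v[i:j] = seg.v_start + (seg.v_end - seg.v_start) * tt / seg.duration_ms
                else:
                    idx = np.minimum(
                        np.floor(tt / seg.dt_ms + _TIME_TOL).astype(int),
                        len(seg.samples) - 1,
                    )
                    v[i:j] = seg.samples[idx]
                i = j
                offset = end
        return t, v

    # -- serialization ------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "holding": self.holding_mV,
            "sampling_ms": self.sampling_ms,
            "name": self.name,
            "sweeps": [sw.to_json() for sw in self.sweeps],
        }

    @classmethod
    def from_json(cls, d: dict) -> "VoltageProtocol":
        return cls(
            holding_mV=float(d["holding"]),
            sweeps=[Sweep.from_json(s) for s in d["sweeps"]],
            sampling_ms=float(d.get("sampling_ms", 0.1)),
            name=str(d.get("name", "")),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "VoltageProtocol":
        return cls.from_json(json.loads(Path(path).read_text()))


def voltage_at(protocol: VoltageProtocol, t: float) -> float:
    """Command voltage at protocol time ``t`` in [0, total duration).

    Half-open segment convention: at an internal boundary the voltage of the
    *later* segment is returned.
    """
    if t < 0 or t >= protocol.duration_ms:
        raise ProtocolError(f"time {t} outside protocol [0, {protocol.duration_ms})")
    rem = t
    for sw in protocol.sweeps:
        for seg in sw.segments:
            if rem < seg.duration_ms:
                return seg.voltage(rem)
            rem -= seg.duration_ms
    # accumulated rounding pushed t past the last boundary by a float ulp
    last = protocol.sweeps[-1].segments[-1]
    return last.voltage(last.duration_ms * (1 - 1e-12))


# ---------------------------------------------------------------------------
# built-in protocols
# ---------------------------------------------------------------------------


def build_activation_protocol(
    variant: str = "oocyte_21C", sampling_ms: float = 0.5
) -> VoltageProtocol:
    """Square activation protocol.

    ``oocyte_21C``: holding -100 mV; 17 sweeps of a 250-ms test step from
    -100 to +60 mV in 10-mV increments followed by a 750-ms tail at -110 mV.

    ``hek_37C`` (shortened, physiological temperature): holding -80 mV; 7
    sweeps of a 1,500-ms test step from -50 to +40 mV in 15-mV increments,
    an 800-ms tail at -40 mV, and 200 ms back at holding.
    """
    if variant == "oocyte_21C":
        sweeps = [
            Sweep([step(v, 250.0), step(-110.0, 750.0)], {"test_voltage_mV": float(v)})
            for v in range(-100, 70, 10)
        ]
        return VoltageProtocol(-100.0, sweeps, sampling_ms, name="activation_oocyte_21C")
    if variant == "hek_37C":
        sweeps = [
            Sweep(
                [step(float(v), 1500.0), step(-40.0, 800.0), step(-80.0, 200.0)],
                {"test_voltage_mV": float(v)},
            )
            for v in range(-50, 55, 15)
        ]
        return VoltageProtocol(-80.0, sweeps, sampling_ms, name="activation_hek_37C")
    raise ProtocolError(f"unknown activation variant {variant!r}")


def build_deactivation_protocol(
    tail_voltages: Sequence[float] | None = None, sampling_ms: float = 0.5
) -> VoltageProtocol:
    """Deactivation / fully-activated-IV protocol: holding -100 mV; per sweep
    a 250-ms activating step to +40 mV then a 750-ms repolarizing step to the
    sweep's tail voltage.  The default tail grid (-140 to +40 mV in 10-mV
    increments) covers the linear-conductance region (-140 to -110 mV) used
    for whole-cell conductance normalization."""
    if tail_voltages is None:
        tail_voltages = [float(v) for v in range(-140, 50, 10)]
    tails = [float(v) for v in tail_voltages]
    if not tails:
        raise ProtocolError("tail voltage list is empty")
    if len(set(tails)) != len(tails):
        raise ProtocolError("duplicate tail voltages")
    for v in tails:
        if not (-150.0 <= v <= 60.0):
            raise ProtocolError(f"tail voltage {v} outside [-150, +60] mV")
    sweeps = [
        Sweep([step(40.0, 250.0), step(v, 750.0)], {"tail_voltage_mV": v})
        for v in tails
    ]
    return VoltageProtocol(-100.0, sweeps, sampling_ms, name="deactivation")


def build_inactivation_protocol_37C(sampling_ms: float = 0.5) -> VoltageProtocol:
    """Inactivation protocol at 37 deg C: a 500-ms depolarizing prepulse to
    +20 mV followed by 800-ms repolarizing steps from -140 to +40 mV in 30-mV
    increments (7 sweeps), from a holding potential of -80 mV."""
    sweeps = [
        Sweep(
            [step(20.0, 500.0), step(float(v), 800.0)],
            {"test_voltage_mV": float(v)},
        )
        for v in range(-140, 70, 30)
    ]
    return VoltageProtocol(-80.0, sweeps, sampling_ms, name="inactivation_37C")


# -- stylized action potential ----------------------------------------------


@dataclass
class StylizedAPSpec:
    """Stylized ventricular action potential waveform.

    An instantaneous upstroke to ``upstroke_mV``, a brief near-plateau ramp
    from ``plateau_start_mV`` to ``plateau_end_mV``, and a linear
    repolarizing ramp back to ``post_hold_mV``.  The time of 90%
    repolarization (measured from the upstroke, by analogy with APD90) is the
    reference point for premature-stimulation coupling intervals.
    """

    upstroke_mV: float = 40.0
    plateau_start_mV: float = 40.0
    plateau_end_mV: float = 20.0
    plateau_duration_ms: float = 50.0
    repol_ramp_ms: float = 300.0
    pre_hold_mV: float = -100.0
    post_hold_mV: float = -100.0

    def __post_init__(self) -> None:
        if self.plateau_duration_ms <= 0 or self.repol_ramp_ms <= 0:
            raise ProtocolError("AP segment durations must be > 0")
        if self.plateau_end_mV <= self.post_hold_mV:
            raise ProtocolError("repolarization ramp must be monotonically decreasing")
        if not (0 < self.t90_ms < self.duration_ms):
            raise ProtocolError("90% repolarization time must lie within the waveform")

    @property
    def duration_ms(self) -> float:
        """APD-like total duration from upstroke to full repolarization."""
        return self.plateau_duration_ms + self.repol_ramp_ms

    @property
    def t90_ms(self) -> float:
        """Time of 90% repolarization after the upstroke (0.9 x duration)."""
        return 0.9 * self.duration_ms

    def segments(self) -> list[ProtocolSegment]:
        return [
            ramp(self.plateau_start_mV, self.plateau_end_mV, self.plateau_duration_ms),
            ramp(self.plateau_end_mV, self.post_hold_mV, self.repol_ramp_ms),
        ]

    def voltage(self, t: float) -> float:
        """Waveform voltage at time t (ms) from the upstroke."""
        if t < self.plateau_duration_ms:
            return self.plateau_start_mV + (
                self.plateau_end_mV - self.plateau_start_mV
            ) * t / self.plateau_duration_ms
        t2 = t - self.plateau_duration_ms
        if t2 < self.repol_ramp_ms:
            return self.plateau_end_mV + (
                self.post_hold_mV - self.plateau_end_mV
            ) * t2 / self.repol_ramp_ms
        return self.post_hold_mV


def default_coupling_intervals() -> list[float]:
    """Coupling-interval grid: -80 to 0 ms at 10-ms spacing, then up to
    380 ms at 20-ms spacing."""
    return [float(v) for v in range(-80, 0, 10)] + [float(v) for v in range(0, 400, 20)]


def build_premature_stimulation_protocol(
    ap: StylizedAPSpec | None = None,
    intervals: Sequence[float] | None = None,
    pre_hold_ms: float = 100.0,
    post_hold_ms: float = 200.0,
    sampling_ms: float = 0.5,
) -> VoltageProtocol:
    """Premature-stimulation (protective-current) protocol.

    Each sweep delivers the stylized action potential and then a 40-ms
    depolarizing step to 0 mV whose onset is ``t90 + coupling_interval``
    (coupling interval measured from 90% repolarization; negative intervals
    truncate the repolarizing ramp).  Sweep metadata records the coupling
    interval and the step onset time within the sweep.
    """
    ap = ap or StylizedAPSpec()
    if intervals is None:
        intervals = default_coupling_intervals()
    intervals = [float(x) for x in intervals]
    if not intervals:
        raise ProtocolError("empty coupling-interval list")
    sweeps = []
    for ci in intervals:
        if not (-80.0 <= ci <= 380.0):
            raise ProtocolError(f"coupling interval {ci} outside [-80, 380] ms")
        onset = ap.t90_ms + ci  # relative to upstroke
        if onset <= 0:
            raise ProtocolError(
                f"coupling interval {ci} places the step before the AP upstroke"
            )
        segs: list[ProtocolSegment] = [step(ap.pre_hold_mV, pre_hold_ms)]
        if onset < ap.plateau_duration_ms:
            segs.append(
                ramp(ap.plateau_start_mV, ap.voltage(onset), onset)
            )
        elif onset < ap.duration_ms:
            segs.extend(
                [
                    ramp(ap.plateau_start_mV, ap.plateau_end_mV, ap.plateau_duration_ms),
                    ramp(ap.plateau_end_mV, ap.voltage(onset), onset - ap.plateau_duration_ms),
                ]
            )
        else:
            segs.extend(ap.segments())
            if onset > ap.duration_ms:
                segs.append(step(ap.post_hold_mV, onset - ap.duration_ms))
        step_onset = pre_hold_ms + onset
        segs.append(step(0.0, 40.0))
        segs.append(step(ap.post_hold_mV, post_hold_ms))
        sweeps.append(
            Sweep(
                segs,
                {
                    "coupling_interval_ms": ci,
                    "step_onset_ms": step_onset,
                    "step_duration_ms": 40.0,
                    "upstroke_ms": pre_hold_ms,
                },
            )
        )
    return VoltageProtocol(ap.pre_hold_mV, sweeps, sampling_ms, name="premature_stimulation")


def build_ap_clamp_protocol(
    ap: StylizedAPSpec | None = None,
    n_beats: int = 3,
    period_ms: float = 1000.0,
    pre_hold_ms: float = 100.0,
    sampling_ms: float = 0.5,
) -> VoltageProtocol:
    """Train of stylized action potentials at a fixed pacing period (1 Hz by
    default), as a single sweep.  Sweep metadata records the onset of each
    beat so that clamp metrics can be measured on the final (rate-adapted)
    beat."""
    ap = ap or StylizedAPSpec()
    if period_ms <= ap.duration_ms:
        raise ProtocolError("pacing period must exceed the AP duration")
    segs: list[ProtocolSegment] = [step(ap.pre_hold_mV, pre_hold_ms)]
    onsets = []
    t = pre_hold_ms
    for _ in range(n_beats):
        onsets.append(t)
        segs.extend(ap.segments())
        segs.append(step(ap.post_hold_mV, period_ms - ap.duration_ms))
        t += period_ms
    sweep = Sweep(
        segs,
        {
            "beat_onsets_ms": onsets,
            "ap_duration_ms": ap.duration_ms,
            "period_ms": period_ms,
        },
    )
    return VoltageProtocol(ap.pre_hold_mV, [sweep], sampling_ms, name="ap_clamp")


def build_staircase_protocol(
    config: dict | None = None, sampling_ms: float = 1.0
) -> VoltageProtocol:
    """The ~19-s calibration staircase: ascending then descending 500-ms
    steps, bracketed by reference steps (activating +40 mV pulse, -120 mV
    recovery pulses).  The step table is configuration: the bundled default
    is used unless ``config`` supplies ``{"holding_mV": ..., "steps":
    [[voltage_mV, duration_ms], ...]}``."""
    if config is None:
        config = json.loads(
            resources.files("hergkin.data").joinpath("staircase_default.json").read_text()
        )
    try:
        holding = float(config["holding_mV"])
        table = list(config["steps"])
    except (KeyError, TypeError) as exc:
        raise ProtocolError(f"malformed staircase config: {exc}") from exc
    segs = []
    for entry in table:
        try:
            v, dur = float(entry[0]), float(entry[1])
        except (TypeError, ValueError, IndexError) as exc:
            raise ProtocolError(f"malformed staircase step {entry!r}") from exc
        if dur <= 0:
            raise ProtocolError(f"staircase step {entry!r} has non-positive duration")
        segs.append(step(v, dur))
    if not segs:
        raise ProtocolError("staircase step table is empty")
    return VoltageProtocol(holding, [Sweep(segs)], sampling_ms, name="staircase")


# -- sampled waveforms -------------------------------------------------------


def build_complex_ap_train(dt_ms: float = 2.0) -> VoltageProtocol:
    """Synthetic complex action-potential train (validation waveform).

    A deterministic ~6-s sequence of stylized action potentials of varying
    duration and morphology, a premature depolarization delivered during late
    repolarization, an EAD-like secondary depolarization, and a rapid-pacing
    burst.  This is a synthetic stand-in with the same character as the
    experimentally used waveform (whose sample values are not published), not
    a reproduction of it.
    """
    parts: list[np.ndarray] = []

    def hold(v: float, dur: float) -> None:
        parts.append(np.full(int(round(dur / dt_ms)), float(v)))

    def lin(v0: float, v1: float, dur: float) -> None:
        n = int(round(dur / dt_ms))
        parts.append(v0 + (v1 - v0) * np.arange(n) / n)

    def ap(upstroke: float, plateau_end: float, plateau_ms: float,
           repol_ms: float, dias: float = -85.0) -> None:
        lin(upstroke, plateau_end, plateau_ms)
        lin(plateau_end, dias, repol_ms)

    hold(-80.0, 500.0)
    # ventricular-like AP
    ap(40.0, 20.0, 50.0, 300.0)
    hold(-85.0, 250.0)
    # short, triangular AP
    ap(30.0, -10.0, 30.0, 150.0)
    hold(-85.0, 250.0)
    # AP with a premature depolarization during late repolarization
    lin(40.0, 20.0, 50.0)
    lin(20.0, -70.0, 240.0)
    hold(0.0, 40.0)
    lin(0.0, -85.0, 60.0)
    hold(-85.0, 250.0)
    # AP with an EAD-like secondary depolarization
    lin(40.0, 20.0, 50.0)
    lin(20.0, -40.0, 150.0)
    lin(-40.0, 0.0, 80.0)
    lin(0.0, -85.0, 180.0)
    hold(-85.0, 300.0)
    # long AP
    ap(35.0, 15.0, 100.0, 350.0)
    hold(-85.0, 300.0)
    # rapid-pacing burst (period 400 ms)
    for _ in range(4):
        ap(40.0, 15.0, 40.0, 210.0)
        hold(-85.0, 150.0)
    hold(-80.0, 690.0)

    samples = np.concatenate(parts)
    seg = ProtocolSegment(
        "sampled", len(samples) * dt_ms, float(samples[0]), float(samples[-1]),
        samples=samples, dt_ms=dt_ms,
    )
    return VoltageProtocol(-80.0, [Sweep([seg])], dt_ms, name="complex_ap_train")


def save_sampled_protocol(protocol: VoltageProtocol, path: str | Path,
                          dt_ms: float | None = None) -> None:
    """Render a protocol to samples and write a two-column CSV
    (time_ms, voltage_mV)."""
    t, v = protocol.render_samples(dt_ms)
    with open(path, "w") as f:
        f.write("time_ms,voltage_mV\n")
        for ti, vi in zip(t, v):
            f.write(f"{ti:.10g},{vi:.12g}\n")


def load_sampled_protocol(path: str | Path, name: str = "") -> VoltageProtocol:
    """Load a uniformly sampled waveform from a two-column CSV
    (time_ms, voltage_mV); raises on non-uniform or non-monotone time."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 2 or data.shape[0] < 2:
        raise ProtocolError("expected two-column time/voltage CSV with >= 2 rows")
    t, v = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ProtocolError("time column is not strictly increasing")
    if np.max(np.abs(dt - dt[0])) > 1e-6 * max(abs(dt[0]), 1.0):
        raise ProtocolError("non-uniform sampling interval")
    dt0 = float(dt[0])
    seg = ProtocolSegment(
        "sampled", len(v) * dt0, float(v[0]), float(v[-1]), samples=v, dt_ms=dt0
    )
    return VoltageProtocol(
        float(v[0]), [Sweep([seg])], dt0, name=name or Path(path).stem
    )


def load_bundled_complex_ap() -> VoltageProtocol:
    """The bundled synthetic complex-AP waveform (see
    :func:`build_complex_ap_train`) as shipped in the package data."""
    with resources.as_file(
        resources.files("hergkin.data").joinpath("complex_ap_synthetic.csv")
    ) as p:
        return load_sampled_protocol(p, name="complex_ap_train")
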