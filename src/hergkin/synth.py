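"""Synthetic three-sweep patch-clamp recordings with ground truth.

Emulates the experimental design used to isolate hERG current from leak and
endogenous currents: each synthetic cell is recorded three times over the
same protocol suite — sweep 1 under control conditions (channel + leak +
noise), sweep 2 after wash-in of the activator RPR260243 (activator kinetics
+ leak + noise), and sweep 3 after wash-in of the blocker dofetilide, which
is modeled as complete channel block so the third sweep contains only leak
and noise.  Subtracting sweep 3 from sweeps 1 and 2 yields control and
activator channel currents free of leak (exactly so when rundown is off).

Noise is iid Gaussian, N(0, sigma^2), white at the output sampling rate.
Cell-to-cell variability enters through the maximal conductance and a
command-voltage offset; kinetics are shared across cells.  Optional rundown
scales the conductance continuously with elapsed recording time and is off
by default; with rundown on, the leak subtraction is no longer exact, which
reproduces a known limitation of the subtraction design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .model import KineticParameterSet
from .protocols import (
    VoltageProtocol,
    build_activation_protocol,
    build_complex_ap_train,
    build_inactivation_protocol_37C,
    build_staircase_protocol,
)
from .simulate import CellConfig, CurrentTrace, SimulationSettings, simulate_current

__all__ = [
    "SyntheticCellSpec",
    "SweepSet",
    "default_protocol_suite",
    "generate_cell_recording",
    "subtract_sweeps",
    "generate_cohort",
    "peak_staircase_current",
    "save_sweepset",
    "load_sweepset",
]

SWEEP_CONDITIONS = ("control", "activator", "blocker")


@dataclass
class SyntheticCellSpec:
    """Ground-truth description of one synthetic cell.

    ``noise_sd_nA`` is the per-sample Gaussian noise sigma; ``rundown_per_min``
    is the fractional conductance loss per minute of recording (0 disables
    rundown; values above 0.2/min are rejected as unphysiological).  The
    reported (measured) reversal potential is E_K + v_off, as an experimenter
    reading the zero-crossing of tail currents against command voltage would
    obtain it.
    """

    kinetics_control: KineticParameterSet
    kinetics_rpr: KineticParameterSet
    g_kr_uS: float = 0.1
    v_off_mV: float = 0.0
    noise_sd_nA: float = 0.0
    leak: tuple[float, float] | None = None
    rundown_per_min: float = 0.0
    seed: int = 0
    k_out_mM: float = 4.0
    k_in_mM: float = 130.0
    temperature_K: float = 310.15
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        if self.noise_sd_nA < 0:
            raise ValueError("noise sd must be >= 0")
        if not (0.0 <= self.rundown_per_min <= 0.2):
            raise ValueError("rundown must lie in [0, 0.2] per minute")
        if self.g_kr_uS < 0:
            raise ValueError("g_kr must be >= 0")

    def cell_config(self, with_leak: bool = True) -> CellConfig:
        return CellConfig(
            g_kr_uS=self.g_kr_uS,
            k_out_mM=self.k_out_mM,
            k_in_mM=self.k_in_mM,
            temperature_K=self.temperature_K,
            v_off_mV=self.v_off_mV,
            leak=self.leak if with_leak else None,
            cell_id=self.cell_id,
        )

    @property
    def e_k_mV(self) -> float:
        return self.cell_config().e_k

    @property
    def e_k_measured_mV(self) -> float:
        """Reversal potential as measured against the command voltage."""
        return self.e_k_mV + self.v_off_mV

    def to_json(self) -> dict:
        return {
            "kinetics_control": self.kinetics_control.to_json(),
            "kinetics_rpr": self.kinetics_rpr.to_json(),
            "g_kr_uS": self.g_kr_uS,
            "v_off_mV": self.v_off_mV,
            "noise_sd_nA": self.noise_sd_nA,
            "leak": list(self.leak) if self.leak else None,
            "rundown_per_min": self.rundown_per_min,
            "seed": self.seed,
            "k_out_mM": self.k_out_mM,
            "k_in_mM": self.k_in_mM,
            "temperature_K": self.temperature_K,
            "cell_id": self.cell_id,
        }

    @classmethod
    def from_json(cls, d: dict) -> "SyntheticCellSpec":
        return cls(
            kinetics_control=KineticParameterSet.from_json(d["kinetics_control"]),
            kinetics_rpr=KineticParameterSet.from_json(d["kinetics_rpr"]),
            g_kr_uS=float(d["g_kr_uS"]),
            v_off_mV=float(d["v_off_mV"]),
            noise_sd_nA=float(d["noise_sd_nA"]),
            leak=tuple(d["leak"]) if d.get("leak") else None,
            rundown_per_min=float(d.get("rundown_per_min", 0.0)),
            seed=int(d.get("seed", 0)),
            k_out_mM=float(d.get("k_out_mM", 4.0)),
            k_in_mM=float(d.get("k_in_mM", 130.0)),
            temperature_K=float(d.get("temperature_K", 310.15)),
            cell_id=str(d.get("cell_id", "cell")),
        )


@dataclass
class SweepSet:
    """A synthetic cell's three-sweep recording over a protocol suite, plus
    its embedded ground truth."""

    protocols: dict[str, VoltageProtocol]
    sweep_control: dict[str, CurrentTrace]
    sweep_activator: dict[str, CurrentTrace]
    sweep_blocker: dict[str, CurrentTrace]
    truth: SyntheticCellSpec

    def sweep(self, condition: str) -> dict[str, CurrentTrace]:
        return {
            "control": self.sweep_control,
            "activator": self.sweep_activator,
            "blocker": self.sweep_blocker,
        }[condition]


def default_protocol_suite() -> dict[str, VoltageProtocol]:
    """The full recording sequence: calibration staircase (C), activation
    (V1) and inactivation (V2) validation steps, the complex AP train (V3),
    and a repeat of the staircase (C2) for quality control."""
    return {
        "C": build_staircase_protocol(sampling_ms=0.1),
        "V1": build_activation_protocol("hek_37C", sampling_ms=1.0),
        "V2": build_inactivation_protocol_37C(sampling_ms=1.0),
        "V3": build_complex_ap_train(),
        "C2": build_staircase_protocol(sampling_ms=0.1),
    }


def generate_cell_recording(
    spec: SyntheticCellSpec,
    protocols: Mapping[str, VoltageProtocol] | None = None,
    settings: SimulationSettings | None = None,
) -> SweepSet:
    """Generate the three-sweep recording of one synthetic cell.

    The recording clock runs continuously through sweep 1 (all protocols in
    order), then sweep 2, then sweep 3; rundown, when enabled, scales the
    channel conductance by ``1 - rate * elapsed_minutes`` along that clock.
    Identical seeds produce identical output.
    """
    protocols = dict(protocols or default_protocol_suite())
    if not protocols:
        raise ValueError("protocol list must be non-empty")
    settings = settings or SimulationSettings()
    rng = np.random.default_rng(spec.seed)
    rate_per_ms = spec.rundown_per_min / 60000.0

    sweeps: list[dict[str, CurrentTrace]] = []
    elapsed = 0.0
    for condition in SWEEP_CONDITIONS:
        traces: dict[str, CurrentTrace] = {}
        for pid, proto in protocols.items():
            start = elapsed
            if condition == "blocker":
                # complete channel block: leak only
                dt = settings.sampling_ms or proto.sampling_ms
                _, v_cmd = proto.render_samples(dt)
                if spec.leak is not None:
                    g_leak, e_leak = spec.leak
                    current = g_leak * (v_cmd - e_leak)
                else:
                    current = np.zeros_like(v_cmd)
                trace = CurrentTrace(0.0, dt, current, v_cmd,
                                     {"protocol": pid, "cell_id": spec.cell_id})
            else:
                params = (
                    spec.kinetics_control if condition == "control"
                    else spec.kinetics_rpr
                )
                g_scale = None
                if rate_per_ms > 0:
                    g_scale = lambda t, s=start: np.maximum(
                        1.0 - rate_per_ms * (s + t), 0.0
                    )
                trace = simulate_current(
                    params, proto, spec.cell_config(), settings,
                    g_scale_of_t=g_scale,
                )
            if spec.noise_sd_nA > 0:
                trace.current_nA = trace.current_nA + rng.normal(
                    0.0, spec.noise_sd_nA, size=len(trace)
                )
            trace.metadata.update(
                {"condition": condition, "protocol": pid, "cell_id": spec.cell_id}
            )
            traces[pid] = trace
            elapsed += proto.duration_ms
        sweeps.append(traces)

    return SweepSet(
        protocols=protocols,
        sweep_control=sweeps[0],
        sweep_activator=sweeps[1],
        sweep_blocker=sweeps[2],
        truth=spec,
    )


def subtract_sweeps(
    sweep_set: SweepSet,
) -> tuple[dict[str, CurrentTrace], dict[str, CurrentTrace]]:
    """Blocker subtraction: control = sweep1 - sweep3 and activator =
    sweep2 - sweep3, per protocol, pointwise.  Raises on misaligned grids."""

    def _sub(a: CurrentTrace, b: CurrentTrace, condition: str) -> CurrentTrace:
        if len(a) != len(b) or abs(a.dt_ms - b.dt_ms) > 1e-12:
            raise ValueError("sweep grids are misaligned")
        return CurrentTrace(
            a.t0_ms, a.dt_ms, a.current_nA - b.current_nA, a.voltage_mV,
            {**a.metadata, "condition": condition, "subtracted": True},
        )

    control = {
        pid: _sub(tr, sweep_set.sweep_blocker[pid], "control")
        for pid, tr in sweep_set.sweep_control.items()
    }
    activator = {
        pid: _sub(tr, sweep_set.sweep_blocker[pid], "activator")
        for pid, tr in sweep_set.sweep_activator.items()
    }
    return control, activator


def peak_staircase_current(
    spec: SyntheticCellSpec,
    protocol: VoltageProtocol | None = None,
    settings: SimulationSettings | None = None,
) -> float:
    """Peak absolute noise-free channel current (nA) on the calibration
    staircase, used to set noise levels as a fraction of signal."""
    proto = protocol or build_staircase_protocol()
    trace = simulate_current(
        spec.kinetics_control, proto, spec.cell_config(with_leak=False), settings
    )
    return float(np.max(np.abs(trace.current_nA)))


def generate_cohort(
    n_cells: int,
    base_spec: SyntheticCellSpec,
    variability: Mapping[str, object] | None = None,
    seed: int = 0,
    protocols: Mapping[str, VoltageProtocol] | None = None,
    noise_frac_of_peak: float | None = None,
    settings: SimulationSettings | None = None,
) -> list[SweepSet]:
    """Generate a cohort of cells sharing kinetics, with per-cell conductance
    and voltage offset.

    ``variability`` keys (all optional):

    * ``"g_kr_values"`` — explicit per-cell conductances (uS; overrides any
      spread),
    * ``"g_kr_cv"`` — lognormal coefficient of variation around the base
      conductance,
    * ``"v_off_sd"`` — Gaussian sd of the per-cell voltage offset (mV),
    * ``"v_off_limit"`` — uniform offset in [-limit, +limit] mV instead.

    ``noise_frac_of_peak``, when given, sets each cell's noise sd to that
    fraction of its own peak noise-free staircase current.  Child seeds are
    derived deterministically from ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    variability = dict(variability or {})
    g_values = variability.get("g_kr_values")
    if g_values is not None and len(g_values) != n_cells:
        raise ValueError("g_kr_values length must equal n_cells")
    g_cv = float(variability.get("g_kr_cv", 0.0) or 0.0)
    v_off_sd = float(variability.get("v_off_sd", 0.0) or 0.0)
    v_off_limit = variability.get("v_off_limit")
    if g_cv < 0 or v_off_sd < 0:
        raise ValueError("variability spreads must be >= 0")

    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_cells):
        child_seed = int(rng.integers(0, 2**31 - 1))
        if g_values is not None:
            g = float(g_values[i])
        elif g_cv > 0:
            sigma = np.sqrt(np.log(1.0 + g_cv**2))
            g = float(base_spec.g_kr_uS * rng.lognormal(-0.5 * sigma**2, sigma))
        else:
            g = base_spec.g_kr_uS
        if v_off_limit is not None:
            v_off = float(rng.uniform(-float(v_off_limit), float(v_off_limit)))
        elif v_off_sd > 0:
            v_off = float(rng.normal(0.0, v_off_sd))
        else:
            v_off = base_spec.v_off_mV
        spec = replace(
            base_spec, g_kr_uS=g, v_off_mV=v_off, seed=child_seed,
            cell_id=f"{base_spec.cell_id}-{i + 1}",
        )
        if noise_frac_of_peak is not None:
            peak = peak_staircase_current(spec, (protocols or {}).get("C"), settings)
            spec = replace(spec, noise_sd_nA=noise_frac_of_peak * peak)
        cohort.append(generate_cell_recording(spec, protocols, settings))
    return cohort


# ---------------------------------------------------------------------------
# on-disk container: one directory per cell (traces as CSV + truth JSON)
# ---------------------------------------------------------------------------


def save_sweepset(sweep_set: SweepSet, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for pid, proto in sweep_set.protocols.items():
        proto.save(d / f"protocol_{pid}.json")
    for condition in SWEEP_CONDITIONS:
        for pid, trace in sweep_set.sweep(condition).items():
            trace.to_csv(d / f"{condition}_{pid}.csv")
    (d / "truth.json").write_text(
        json.dumps(sweep_set.truth.to_json(), indent=2) + "\n"
    )


def load_sweepset(directory: str | Path) -> SweepSet:
    d = Path(directory)
    truth = SyntheticCellSpec.from_json(json.loads((d / "truth.json").read_text()))
    protocols = {
        p.stem.removeprefix("protocol_"): VoltageProtocol.load(p)
        for p in sorted(d.glob("protocol_*.json"))
    }
    sweeps = {}
    for condition in SWEEP_CONDITIONS:
        sweeps[condition] = {
            pid: CurrentTrace.from_csv(
                d / f"{condition}_{pid}.csv",
                {"condition": condition, "protocol": pid, "cell_id": truth.cell_id},
            )
            for pid in protocols
        }
    return SweepSet(
        protocols=protocols,
        sweep_control=sweeps["control"],
        sweep_activator=sweeps["activator"],
        sweep_blocker=sweeps["blocker"],
        truth=truth,
    )
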