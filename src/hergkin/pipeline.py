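"""End-to-end characterization pipeline on synthetic cohorts.

``run_characterization`` reproduces the computational arc of a rapid
channel-characterization study entirely on synthetic data: generate a
three-sweep cohort for each construct, blocker-subtract, fit the joint model
to the calibration staircase only, predict the held-out validation protocols
(activation V1, inactivation V2, complex AP train V3), and phenotype the
fitted kinetics with gating biomarkers (deactivation time constants, G-V
midpoints, protective-current curves, AP-clamp metrics) at equal
conductance.  Outputs are plain CSV tables plus a human-readable summary;
reports embed the config hash and seeds, so a saved config re-runs to
identical outputs.

``export_model`` writes a fitted (or bundled) parameter set together with
the six rate expressions as a self-contained machine-readable model
description for embedding in external action-potential simulators;
``import_model`` round-trips it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import biomarkers as bm
from .inference import FitSettings, InferenceResult, dataset_from_sweepsets, fit_joint
from .model import KineticParameterSet, load_parameters
from .protocols import (
    StylizedAPSpec,
    build_ap_clamp_protocol,
    build_deactivation_protocol,
    build_premature_stimulation_protocol,
)
from .simulate import CellConfig, SimulationSettings, simulate_current
from .synth import (
    SweepSet,
    SyntheticCellSpec,
    default_protocol_suite,
    generate_cohort,
    subtract_sweeps,
)

__all__ = [
    "PipelineConfig",
    "run_characterization",
    "export_model",
    "import_model",
    "prediction_errors",
    "phenotype_report",
    "RATE_EXPRESSIONS",
]

#: The six transition-rate expressions of the model, in a plain-text form
#: suitable for embedding in external simulators (V in mV, rates in ms^-1).
RATE_EXPRESSIONS = {
    "a1": "p1 * exp(+p2 * V)",
    "b1": "p3 * exp(-p4 * V)",
    "bh": "p5 * exp(+p6 * V)",
    "ah": "p7 * exp(-p8 * V)",
    "a2": "p9 * exp(+p10 * V)",
    "b2": "p11 * exp(-p12 * V)",
}

#: Per-cell maximal conductances (uS) reported for the three calibration
#: cells of each construct; used as the default cohort conductances.
DEFAULT_COHORT_G = {
    "WT": [8.47e-2, 7.05e-2, 1.23e-1],
    "R56Q": [7.96e-2, 1.03e-1, 4.33e-2],
}


@dataclass
class PipelineConfig:
    """Fully serializable configuration of one characterization run."""

    constructs: tuple[str, ...] = ("WT",)
    n_cells: int = 3
    seed: int = 1
    noise_frac_of_peak: float = 0.02
    v_off_limit_mV: float = 2.0
    g_kr_values: dict | None = None  # construct -> list of uS
    leak: tuple[float, float] | None = (0.005, 0.0)
    rundown_per_min: float = 0.0
    n_starts: int = 10
    staircase_dt_ms: float = 0.1
    fit_overrides: dict | None = None
    protective_intervals: tuple[float, ...] | None = None
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["constructs"] = list(self.constructs)
        if self.protective_intervals is not None:
            d["protective_intervals"] = list(self.protective_intervals)
        if self.leak is not None:
            d["leak"] = list(self.leak)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "constructs" in d:
            d["constructs"] = tuple(d["constructs"])
        if d.get("leak"):
            d["leak"] = tuple(d["leak"])
        if d.get("protective_intervals"):
            d["protective_intervals"] = tuple(d["protective_intervals"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _construct_kinetics(construct: str) -> tuple[KineticParameterSet, KineticParameterSet]:
    return load_parameters(construct), load_parameters(f"{construct}+RPR")


def prediction_errors(
    sweep_set: SweepSet,
    result: InferenceResult,
    cell_index: int,
    protocol_ids: Sequence[str] = ("V1", "V2", "V3"),
) -> pd.DataFrame:
    """Held-out prediction check: simulate the fitted model on each
    validation protocol and compare with the cell's blocker-subtracted
    traces.

    Returns one row per (protocol, condition) with the prediction RMSE, the
    noise floor of the subtracted trace (sigma * sqrt(2): two independent
    noisy sweeps enter each subtraction) and their ratio.
    """
    control, activator = subtract_sweeps(sweep_set)
    truth = sweep_set.truth
    noise_floor = truth.noise_sd_nA * math.sqrt(2.0)
    g = result.g_kr_uS[cell_index]
    v_off = result.v_off_mV[cell_index]
    rows = []
    for pid in protocol_ids:
        proto = sweep_set.protocols[pid]
        for condition, params, data in (
            ("control", result.theta_control, control[pid]),
            ("activator", result.theta_rpr, activator[pid]),
        ):
            cfg = CellConfig(g_kr_uS=g, e_k_mV=truth.e_k_mV, v_off_mV=v_off)
            pred = simulate_current(
                params, proto, cfg,
                SimulationSettings(sampling_ms=data.dt_ms), store_voltage=False,
            )
            rmse = float(np.sqrt(np.mean((pred.current_nA - data.current_nA) ** 2)))
            rows.append(
                {
                    "protocol": pid,
                    "condition": condition,
                    "rmse_nA": rmse,
                    "noise_floor_nA": noise_floor,
                    "rmse_over_noise": rmse / noise_floor if noise_floor > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def phenotype_report(
    kinetics: Mapping[str, KineticParameterSet],
    g_kr_uS: float = 0.1,
    e_k_mV: float = -93.04,
    protective_intervals: Sequence[float] | None = None,
    deactivation_voltage: float = -60.0,
    sampling_ms: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Model-based phenotype comparison at equal maximal conductance.

    For each named kinetics set, computes deactivation time constants (tail
    at ``deactivation_voltage``), the G-V midpoint, the protective-current
    curve over the coupling-interval grid (normalized to whole-cell
    conductance) and AP-clamp metrics on the final beat of a 1-Hz stylized
    AP train.  Returns tidy DataFrames keyed by analysis name.
    """
    cfg = CellConfig(g_kr_uS=g_kr_uS, e_k_mV=e_k_mV)
    settings = SimulationSettings(sampling_ms=sampling_ms)
    ap = StylizedAPSpec()
    protective = build_premature_stimulation_protocol(
        ap, protective_intervals, sampling_ms=sampling_ms
    )
    ap_train = build_ap_clamp_protocol(ap, n_beats=3, period_ms=1000.0,
                                       sampling_ms=sampling_ms)
    deact = build_deactivation_protocol([deactivation_voltage], sampling_ms=sampling_ms)
    from .protocols import build_activation_protocol

    act = build_activation_protocol("hek_37C", sampling_ms=1.0)

    deact_rows, gv_rows, prot_rows, ap_rows = [], [], [], []
    for name, params in kinetics.items():
        tr = simulate_current(params, deact, cfg, settings)
        fit = bm.fit_exponential_decay(tr, window=(251.0, 1000.0), n_terms=2)
        deact_rows.append(
            {
                "kinetics": name,
                "tau_fast_ms": fit.tau_fast_ms,
                "tau_slow_ms": fit.tau_slow_ms,
                "fast_fraction": fit.fast_fraction,
            }
        )
        tr_act = simulate_current(params, act, cfg, SimulationSettings(sampling_ms=1.0))
        gv = bm.build_gv_from_tails(tr_act, act)
        bfit = bm.fit_boltzmann(gv.test_voltage_mV, gv.g_norm)
        gv_rows.append(
            {"kinetics": name, "v_half_mV": bfit.v_half_mV, "k_mV": bfit.k_mV}
        )
        tr_prot = simulate_current(params, protective, cfg, settings)
        curve = bm.measure_protective_currents(tr_prot, protective, g_kr_uS)
        for ci, amp in zip(curve.coupling_intervals_ms, curve.normalized):
            prot_rows.append(
                {"kinetics": name, "coupling_interval_ms": ci, "normalized_amplitude": amp}
            )
        tr_ap = simulate_current(params, ap_train, cfg, settings)
        met = bm.measure_ap_clamp_metrics(
            tr_ap, ap_train, normalization="conductance", normalization_value=g_kr_uS
        )
        ap_rows.append(
            {
                "kinetics": name,
                "peak_transient": met.peak_transient,
                "peak_resurgent": met.peak_resurgent,
                "peak_voltage_mV": met.peak_voltage_mV,
            }
        )
    return {
        "deactivation": pd.DataFrame(deact_rows),
        "gv": pd.DataFrame(gv_rows),
        "protective": pd.DataFrame(prot_rows),
        "ap_clamp": pd.DataFrame(ap_rows),
    }


def run_characterization(config: PipelineConfig) -> dict:
    """Run the full synthetic characterization pipeline.

    Per construct: generate cohort -> subtract -> fit (staircase only) ->
    predict V1-V3 -> biomarker phenotyping.  Returns a report dict; when
    ``config.out_dir`` is set, also writes CSV tables, a summary text file
    and a manifest with the config hash.  Stage failures are reported with
    the stage name; completed stages are preserved in the report.
    """
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "constructs": {},
    }
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    phenotype_sets: dict[str, KineticParameterSet] = {}
    for ci, construct in enumerate(config.constructs):
        cres: dict = {}
        stage = "generate"
        try:
            ctrl, rpr = _construct_kinetics(construct)
            g_values = (config.g_kr_values or DEFAULT_COHORT_G).get(construct)
            base = SyntheticCellSpec(
                kinetics_control=ctrl, kinetics_rpr=rpr,
                leak=config.leak, rundown_per_min=config.rundown_per_min,
                cell_id=construct,
            )
            suite = default_protocol_suite()
            if config.staircase_dt_ms != 0.1:
                from .protocols import build_staircase_protocol

                suite["C"] = build_staircase_protocol(
                    sampling_ms=config.staircase_dt_ms
                )
                suite["C2"] = build_staircase_protocol(
                    sampling_ms=config.staircase_dt_ms
                )
            cohort = generate_cohort(
                config.n_cells, base,
                variability={
                    "g_kr_values": g_values[: config.n_cells] if g_values else None,
                    "v_off_limit": config.v_off_limit_mV,
                },
                seed=config.seed + 1000 * ci,
                protocols=suite,
                noise_frac_of_peak=config.noise_frac_of_peak,
            )

            stage = "fit"
            dataset = dataset_from_sweepsets(cohort, "C")
            result = fit_joint(
                dataset,
                FitSettings(n_starts=config.n_starts, **(config.fit_overrides or {})),
                seed=config.seed + 1000 * ci,
            )
            truth_g = [ss.truth.g_kr_uS for ss in cohort]
            recovery = pd.DataFrame(
                {
                    "parameter": [f"p{i}" for i in range(1, 13)] * 2
                    + [f"g_cell{i+1}" for i in range(len(truth_g))],
                    "condition": ["control"] * 12 + ["activator"] * 12
                    + ["conductance"] * len(truth_g),
                    "truth": np.concatenate(
                        [ctrl.values, rpr.values, truth_g]
                    ),
                    "fitted": np.concatenate(
                        [
                            result.theta_control.values,
                            result.theta_rpr.values,
                            result.g_kr_uS,
                        ]
                    ),
                }
            )
            recovery["rel_error"] = recovery.fitted / recovery.truth - 1.0
            cres["n_parameters"] = result.n_parameters
            cres["sse"] = result.sse
            cres["sigma_hat_nA"] = result.sigma_hat_nA

            stage = "predict"
            pred = pd.concat(
                [
                    prediction_errors(ss, result, i).assign(cell=ss.truth.cell_id)
                    for i, ss in enumerate(cohort)
                ],
                ignore_index=True,
            )

            stage = "qc"
            qc_rows = []
            for ss in cohort:
                ok, drift = _qc(ss)
                qc_rows.append({"cell": ss.truth.cell_id, "pass": ok, "drift": drift})
            qc = pd.DataFrame(qc_rows)

            phenotype_sets[f"{construct}-control"] = result.theta_control
            phenotype_sets[f"{construct}-RPR"] = result.theta_rpr

            cres["recovery"] = recovery
            cres["predictions"] = pred
            cres["qc"] = qc
            if out:
                recovery.to_csv(out / f"recovery_{construct}.csv", index=False)
                pred.to_csv(out / f"predictions_{construct}.csv", index=False)
                qc.to_csv(out / f"qc_{construct}.csv", index=False)
                export_model(result.theta_control, out / f"model_{construct}_control.json")
                export_model(result.theta_rpr, out / f"model_{construct}_rpr.json")
        except Exception as exc:
            cres["failed_stage"] = stage
            cres["error"] = f"{type(exc).__name__}: {exc}"
        report["constructs"][construct] = cres

    try:
        pheno = phenotype_report(
            phenotype_sets, protective_intervals=config.protective_intervals
        )
        report["phenotype"] = pheno
        if out:
            for name, df in pheno.items():
                df.to_csv(out / f"phenotype_{name}.csv", index=False)
    except Exception as exc:
        report["phenotype_error"] = f"{type(exc).__name__}: {exc}"

    if out:
        (out / "manifest.json").write_text(
            json.dumps(
                {
                    "config": config.to_dict(),
                    "config_hash": config.config_hash(),
                    "outputs": sorted(p.name for p in out.iterdir()),
                },
                indent=2,
            )
            + "\n"
        )
        (out / "summary.txt").write_text(_summary_text(report))
    return report


def _qc(sweep_set: SweepSet) -> tuple[bool, float]:
    from .inference import staircase_qc_check

    control, _ = subtract_sweeps(sweep_set)
    if "C2" not in control:
        return True, 0.0
    # each blocker-subtracted trace carries noise sd sigma*sqrt(2)
    noise = 2.0 * sweep_set.truth.noise_sd_nA
    return staircase_qc_check(control["C"], control["C2"], expected_noise_sd=noise)


def _summary_text(report: dict) -> str:
    lines = [
        "Synthetic hERG characterization report",
        f"config hash: {report['config_hash']}",
        "",
    ]
    for construct, cres in report["constructs"].items():
        lines.append(f"[{construct}]")
        if "error" in cres:
            lines.append(
                f"  FAILED at stage {cres['failed_stage']}: {cres['error']}"
            )
            continue
        rec = cres["recovery"]
        kin = rec[rec.condition != "conductance"]
        lines.append(f"  joint parameters: {cres['n_parameters']}")
        lines.append(
            f"  kinetic recovery |rel err|: median "
            f"{np.median(np.abs(kin.rel_error)):.3g}, max {np.max(np.abs(kin.rel_error)):.3g}"
        )
        gs = rec[rec.condition == "conductance"]
        lines.append(
            f"  conductance recovery |rel err| max: {np.max(np.abs(gs.rel_error)):.3g}"
        )
        pred = cres["predictions"]
        lines.append(
            f"  prediction RMSE / noise floor: max {pred.rmse_over_noise.max():.3g}"
        )
        lines.append(
            f"  staircase QC pass: {int(cres['qc']['pass'].sum())}/{len(cres['qc'])}"
        )
    if "phenotype" in report:
        ap = report["phenotype"]["ap_clamp"]
        lines.append("")
        lines.append("phenotype (equal conductance):")
        for _, row in ap.iterrows():
            lines.append(
                f"  {row.kinetics}: peak transient {row.peak_transient:.3g}, "
                f"peak resurgent {row.peak_resurgent:.3g} (per uS), "
                f"peak voltage {row.peak_voltage_mV:.1f} mV"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# model export
# ---------------------------------------------------------------------------


def export_model(
    params: KineticParameterSet, path: str | Path, fmt: str | None = None
) -> None:
    """Write a self-contained model description (12 parameters + 6 rate
    expressions + current equation) for embedding in external simulators.
    ``fmt`` is ``"json"`` or ``"txt"`` (inferred from the extension when
    omitted)."""
    path = Path(path)
    fmt = fmt or (path.suffix.lstrip(".") or "json")
    if fmt == "json":
        payload = {
            "model": "hERG IKr, 6-state Markov (HH-factorizable)",
            "current": "I_Kr = g_Kr * Oa * h * (V - E_K)  [uS * mV = nA]",
            "states": "C2a <-> C1a <-> Oa (activation chain); h availability gate",
            "rates": RATE_EXPRESSIONS,
            "units": {"V": "mV", "rates": "ms^-1", "prefactors": "ms^-1",
                      "slopes": "mV^-1"},
            "parameters": params.to_json(),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif fmt == "txt":
        lines = [
            f"# hERG IKr model parameters ({params.label})",
            "# I_Kr = g_Kr * Oa * h * (V - E_K)   [uS * mV = nA]",
            "# dOa/dt  = a2*C1a - b2*Oa",
            "# dC1a/dt = b2*Oa + a1*C2a - (a2 + b1)*C1a",
            "# C2a     = 1 - Oa - C1a",
            "# dh/dt   = (h_inf - h)/tau_h;  h_inf = ah/(ah+bh);  tau_h = 1/(ah+bh)",
        ]
        lines += [f"{name} = {expr}" for name, expr in RATE_EXPRESSIONS.items()]
        lines += [f"p{i} = {float(v)!r}" for i, v in enumerate(params.values, start=1)]
        lines += [f"label = {params.label}"]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_model(path: str | Path) -> KineticParameterSet:
    """Read back a model description written by :func:`export_model`."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return KineticParameterSet.from_json(payload["parameters"])
    values = [None] * 12
    label = ""
    for line in path.read_text().splitlines():
        line = line.strip()
        if line.startswith("label"):
            label = line.split("=", 1)[1].strip()
        elif line.startswith("p") and "=" in line and not line.startswith("#"):
            key, val = (s.strip() for s in line.split("=", 1))
            if key[1:].isdigit():
                values[int(key[1:]) - 1] = float(val)
    if any(v is None for v in values):
        raise ValueError("model description lacks a full parameter set")
    return KineticParameterSet.from_values(values, label=label)
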