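"""Kinetic model of the hERG (Kv11.1) channel carrying the rapid delayed-rectifier
current I_Kr.

The model factorizes gating into a three-state activation chain
``C2a <-> C1a <-> Oa`` (slow, voltage-dependent activation/deactivation) and an
independent Hodgkin-Huxley availability gate ``h`` (fast C-type inactivation).
Open probability is ``O = Oa * h``.  The factorized system is exactly
equivalent to a six-state Markov chain on ``{C2, C1, O} x {available,
inactivated}`` in which the horizontal transitions carry the activation rates
and every vertical transition carries the inactivation rates ``bh`` (X -> IX)
and ``ah`` (IX -> X).

Six voltage-dependent transition rates are parameterized by twelve kinetic
parameters ``p1..p12`` (odd-indexed: prefactors, ms^-1; even-indexed: voltage
slopes, mV^-1)::

    a1 = p1 * exp(+p2 * V)     C2a -> C1a
    b1 = p3 * exp(-p4 * V)     C1a -> C2a
    bh = p5 * exp(+p6 * V)     inactivation (X -> IX)
    ah = p7 * exp(-p8 * V)     recovery from inactivation (IX -> X)
    a2 = p9 * exp(+p10 * V)    C1a -> Oa
    b2 = p11 * exp(-p12 * V)   Oa -> C1a

Forward (activating) rates grow with depolarization, backward and recovery
rates grow with hyperpolarization.  Four fitted parameter sets (WT and the
LQTS2-associated R56Q variant, each without and with the type I activator
RPR260243) ship with the package; see :func:`load_parameters`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "RATE_BAND",
    "V_PLAUSIBILITY_RANGE",
    "ModelError",
    "RateOverflowError",
    "DegenerateChainError",
    "InvalidStateError",
    "KineticParameterSet",
    "RateValues",
    "GateState",
    "MarkovOccupancy",
    "MARKOV_STATE_NAMES",
    "evaluate_rates",
    "rate_extrema",
    "gate_steady_state",
    "gate_derivatives",
    "open_probability",
    "expand_to_markov",
    "collapse_from_markov",
    "markov_rate_matrix",
    "markov_derivatives",
    "load_parameters",
    "BUNDLED_PARAMETER_SETS",
]

#: Plausibility band for every transition rate (ms^-1), checked over
#: :data:`V_PLAUSIBILITY_RANGE` during validation and parameter inference.
RATE_BAND: tuple[float, float] = (1e-7, 1e3)

#: Voltage range (mV) over which the plausibility band is enforced.
V_PLAUSIBILITY_RANGE: tuple[float, float] = (-120.0, 60.0)

# exp() overflows at ~709.8; guard well before that.
_EXP_ARG_MAX = 700.0

_PREFACTOR_IDX = (0, 2, 4, 6, 8, 10)  # p1, p3, p5, p7, p9, p11
_SLOPE_IDX = (1, 3, 5, 7, 9, 11)  # p2, p4, p6, p8, p10, p12

#: Sign of the voltage slope in ``exp(sign * slope * V)`` for each rate, in
#: parameter-pair order (a1, b1, bh, ah, a2, b2).
_RATE_SIGNS = (+1, -1, +1, -1, +1, -1)
_RATE_NAMES = ("a1", "b1", "bh", "ah", "a2", "b2")


class ModelError(ValueError):
    """Base error for model-level failures."""


class RateOverflowError(ModelError):
    """A transition rate overflowed (exponent beyond the guard) at some voltage."""


class DegenerateChainError(ModelError):
    """Both directions of one transition are zero; the stationary point is not unique."""


class InvalidStateError(ModelError):
    """A gating state lies outside the unit simplex beyond tolerance."""


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticParameterSet:
    """The twelve rate parameters of the channel model.

    Odd-indexed parameters (p1, p3, p5, p7, p9, p11) are rate prefactors in
    ms^-1 and must be strictly positive; even-indexed parameters (p2, p4, p6,
    p8, p10, p12) are voltage slopes in mV^-1 and must be >= 0.
    """

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float
    p7: float
    p8: float
    p9: float
    p10: float
    p11: float
    p12: float
    label: str = ""

    @property
    def values(self) -> np.ndarray:
        """Parameters as a length-12 array (p1..p12)."""
        return np.array(
            [self.p1, self.p2, self.p3, self.p4, self.p5, self.p6,
             self.p7, self.p8, self.p9, self.p10, self.p11, self.p12],
            dtype=float,
        )

    @classmethod
    def from_values(cls, values: Sequence[float], label: str = "") -> "KineticParameterSet":
        vals = [float(v) for v in values]
        if len(vals) != 12:
            raise ModelError(f"expected 12 parameters, got {len(vals)}")
        return cls(*vals, label=label)

    def with_label(self, label: str) -> "KineticParameterSet":
        return replace(self, label=label)

    # -- validation ---------------------------------------------------------

    def validate(
        self,
        band: tuple[float, float] = RATE_BAND,
        v_range: tuple[float, float] = V_PLAUSIBILITY_RANGE,
        on_band_violation: str = "raise",
    ) -> "KineticParameterSet":
        """Check structural invariants and the rate plausibility band.

        ``on_band_violation`` is ``"raise"``, ``"warn"`` or ``"ignore"`` and
        governs only the band check; structural violations (non-finite values,
        non-positive prefactors, negative slopes) always raise.
        """
        vals = self.values
        if not np.all(np.isfinite(vals)):
            raise ModelError(f"non-finite parameter in {self.label or 'parameter set'}")
        if np.any(vals[list(_PREFACTOR_IDX)] <= 0):
            raise ModelError("prefactors p1,p3,p5,p7,p9,p11 must be strictly positive")
        if np.any(vals[list(_SLOPE_IDX)] < 0):
            raise ModelError("voltage slopes p2,p4,p6,p8,p10,p12 must be >= 0")
        lo, hi = band
        extrema = rate_extrema(self, v_range)
        for name, (rmin, rmax) in extrema.items():
            if rmax > hi or rmin < lo:
                msg = (
                    f"rate {name} spans [{rmin:.3g}, {rmax:.3g}] ms^-1 over "
                    f"{v_range} mV, outside the plausibility band [{lo:g}, {hi:g}]"
                )
                if on_band_violation == "raise":
                    raise ModelError(msg)
                if on_band_violation == "warn":
                    warnings.warn(msg, stacklevel=2)
        return self

    # -- serialization ------------------------------------------------------

    def to_json(self) -> dict:
        d = {f"p{i+1}": float(v) for i, v in enumerate(self.values)}
        d["label"] = self.label
        return d

    @classmethod
    def from_json(cls, obj: dict) -> "KineticParameterSet":
        vals = [float(obj[f"p{i}"]) for i in range(1, 13)]
        return cls.from_values(vals, label=str(obj.get("label", "")))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "KineticParameterSet":
        return cls.from_json(json.loads(Path(path).read_text()))


#: Names of the bundled fitted parameter sets.
BUNDLED_PARAMETER_SETS = ("WT", "WT+RPR", "R56Q", "R56Q+RPR")

_BUNDLED_FILES = {
    "WT": "params_wt.json",
    "WT+RPR": "params_wt_rpr.json",
    "R56Q": "params_r56q.json",
    "R56Q+RPR": "params_r56q_rpr.json",
}


def load_parameters(name: str) -> KineticParameterSet:
    """Load one of the bundled fitted parameter sets.

    ``name`` is one of ``"WT"``, ``"WT+RPR"``, ``"R56Q"``, ``"R56Q+RPR"``.
    Bundled sets are validated with a warning (not an error) on plausibility
    band violations so that user-adjusted copies remain loadable.
    """
    if name not in _BUNDLED_FILES:
        raise ModelError(
            f"unknown parameter set {name!r}; available: {BUNDLED_PARAMETER_SETS}"
        )
    text = resources.files("hergkin.data").joinpath(_BUNDLED_FILES[name]).read_text()
    params = KineticParameterSet.from_json(json.loads(text))
    return params.validate(on_band_violation="warn")


# ---------------------------------------------------------------------------
# transition rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateValues:
    """The six transition rates (ms^-1) at one voltage, plus the derived
    inactivation-gate steady state ``h_inf = ah/(ah+bh)`` and time constant
    ``tau_h = 1/(ah+bh)`` (ms)."""

    a1: float
    b1: float
    a2: float
    b2: float
    ah: float
    bh: float

    @property
    def h_inf(self) -> float:
        return self.ah / (self.ah + self.bh)

    @property
    def tau_h(self) -> float:
        return 1.0 / (self.ah + self.bh)


def _raw_rates(values: np.ndarray, v: float) -> tuple[float, ...]:
    """(a1, b1, bh, ah, a2, b2) without overflow guarding, scalar voltage."""
    p = values
    return (
        p[0] * math.exp(p[1] * v),
        p[2] * math.exp(-p[3] * v),
        p[4] * math.exp(p[5] * v),
        p[6] * math.exp(-p[7] * v),
        p[8] * math.exp(p[9] * v),
        p[10] * math.exp(-p[11] * v),
    )


def evaluate_rates(params: KineticParameterSet, v: float) -> RateValues:
    """Evaluate the six transition rates at membrane voltage ``v`` (mV).

    Raises :class:`RateOverflowError`, naming the offending rate, if any
    exponent magnitude exceeds the overflow guard (|arg| > 700).
    """
    p = params.values
    args = [s * p[i] * v for s, i in zip(_RATE_SIGNS, _SLOPE_IDX)]
    for name, arg in zip(_RATE_NAMES, args):
        if not math.isfinite(arg) or abs(arg) > _EXP_ARG_MAX:
            raise RateOverflowError(
                f"rate {name}: exponent {arg:.3g} at V={v:g} mV exceeds overflow guard"
            )
    a1, b1, bh, ah, a2, b2 = _raw_rates(p, v)
    return RateValues(a1=a1, b1=b1, a2=a2, b2=b2, ah=ah, bh=bh)


def rate_extrema(
    params: KineticParameterSet,
    v_range: tuple[float, float] = V_PLAUSIBILITY_RANGE,
) -> dict[str, tuple[float, float]]:
    """Min/max of each rate over a voltage interval.

    Each rate is monotone in voltage (single exponential), so the extrema sit
    at the interval endpoints.
    """
    p = params.values
    lo = _raw_rates(p, v_range[0])
    hi = _raw_rates(p, v_range[1])
    return {
        name: (min(a, b), max(a, b))
        for name, a, b in zip(_RATE_NAMES, lo, hi)
    }


# ---------------------------------------------------------------------------
# gating states
# ---------------------------------------------------------------------------

_SIMPLEX_TOL = 1e-10


@dataclass(frozen=True)
class GateState:
    """Factorized gating state: activation-chain occupancies (Oa, C1a, C2a)
    summing to one, and the availability gate h in [0, 1]."""

    Oa: float
    C1a: float
    C2a: float
    h: float

    def validate(self, tol: float = 1e-6) -> "GateState":
        comps = (self.Oa, self.C1a, self.C2a, self.h)
        if any(not math.isfinite(c) for c in comps):
            raise InvalidStateError(f"non-finite gate state {self}")
        if any(c < -tol or c > 1 + tol for c in comps):
            raise InvalidStateError(f"gate state outside [0, 1]: {self}")
        if abs(self.Oa + self.C1a + self.C2a - 1.0) > max(tol, _SIMPLEX_TOL):
            raise InvalidStateError(f"activation chain does not sum to 1: {self}")
        return self

    def as_array(self) -> np.ndarray:
        return np.array([self.Oa, self.C1a, self.C2a, self.h], dtype=float)


#: Order of states in :class:`MarkovOccupancy` vectors and the rate matrix.
MARKOV_STATE_NAMES = ("O", "IO", "C1", "IC1", "C2", "IC2")


@dataclass(frozen=True)
class MarkovOccupancy:
    """Occupancies of the equivalent six-state Markov model (sum to one)."""

    O: float
    IO: float
    C1: float
    IC1: float
    C2: float
    IC2: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.O, self.IO, self.C1, self.IC1, self.C2, self.IC2], dtype=float
        )

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "MarkovOccupancy":
        return cls(*(float(x) for x in arr))

    def validate(self, tol: float = 1e-6) -> "MarkovOccupancy":
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise InvalidStateError(f"non-finite occupancy {self}")
        if np.any(arr < -tol) or np.any(arr > 1 + tol):
            raise InvalidStateError(f"occupancy outside [0, 1]: {self}")
        if abs(float(arr.sum()) - 1.0) > max(tol, _SIMPLEX_TOL):
            raise InvalidStateError(f"occupancies do not sum to 1: {self}")
        return self


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def gate_steady_state(params: KineticParameterSet, v: float) -> GateState:
    """Stationary point of the gating system at fixed voltage.

    The activation chain is a reversible birth-death chain, so its stationary
    distribution follows from the detailed-balance ratios C1a/C2a = a1/b1 and
    Oa/C1a = a2/b2; h relaxes to h_inf = ah/(ah+bh).
    """
    r = evaluate_rates(params, v)
    for fwd, bwd, name in ((r.a1, r.b1, "C2a<->C1a"), (r.a2, r.b2, "C1a<->Oa"),
                           (r.ah, r.bh, "h")):
        if fwd == 0.0 and bwd == 0.0:
            raise DegenerateChainError(
                f"both rates of transition {name} are zero at V={v:g} mV"
            )
    # unnormalized weights, written as products to stay finite when a single
    # backward rate vanishes
    w_c2 = r.b1 * r.b2
    w_c1 = r.a1 * r.b2
    w_o = r.a1 * r.a2
    total = w_c2 + w_c1 + w_o
    if total == 0.0 or not math.isfinite(total):
        raise DegenerateChainError(
            f"activation chain has no normalizable stationary point at V={v:g} mV"
        )
    return GateState(
        Oa=w_o / total, C1a=w_c1 / total, C2a=w_c2 / total, h=r.h_inf
    )


def gate_derivatives(
    params: KineticParameterSet, v: float, s: GateState
) -> tuple[float, float, float]:
    """Time derivatives (dC1a/dt, dOa/dt, dh/dt) in ms^-1.

    C2a is algebraic (1 - Oa - C1a) and its implied derivative is
    -(dC1a/dt + dOa/dt).
    """
    s.validate()
    r = evaluate_rates(params, v)
    c2a = 1.0 - s.Oa - s.C1a
    dc1a = r.b2 * s.Oa + r.a1 * c2a - (r.a2 + r.b1) * s.C1a
    doa = r.a2 * s.C1a - r.b2 * s.Oa
    dh = (r.h_inf - s.h) / r.tau_h
    return dc1a, doa, dh


def open_probability(s: GateState) -> float:
    """Open probability O = Oa * h."""
    return s.Oa * s.h


def expand_to_markov(s: GateState) -> MarkovOccupancy:
    """Map a factorized gate state onto the six-state occupancy vector."""
    return MarkovOccupancy(
        O=s.Oa * s.h,
        IO=s.Oa * (1.0 - s.h),
        C1=s.C1a * s.h,
        IC1=s.C1a * (1.0 - s.h),
        C2=s.C2a * s.h,
        IC2=s.C2a * (1.0 - s.h),
    )


def collapse_from_markov(m: MarkovOccupancy) -> GateState:
    """Inverse of :func:`expand_to_markov` (h undefined when the chain is fully
    inactivated; it is then taken from the open pair if possible, else 0)."""
    oa = m.O + m.IO
    c1a = m.C1 + m.IC1
    c2a = m.C2 + m.IC2
    avail = m.O + m.C1 + m.C2
    h = m.O / oa if oa > 0 else avail
    return GateState(Oa=oa, C1a=c1a, C2a=c2a, h=h)


def markov_rate_matrix(params: KineticParameterSet, v: float) -> np.ndarray:
    """Generator matrix Q of the six-state model, dm/dt = Q @ m.

    State order is :data:`MARKOV_STATE_NAMES`.  Horizontal transitions
    (C2<->C1<->O, and the same in the inactivated layer) carry the activation
    rates; every vertical transition X <-> IX carries (bh, ah).  Columns sum
    to zero, so total occupancy is conserved.
    """
    r = evaluate_rates(params, v)
    q = np.zeros((6, 6))
    idx = {name: i for i, name in enumerate(MARKOV_STATE_NAMES)}

    def add(src: str, dst: str, rate: float) -> None:
        q[idx[dst], idx[src]] += rate
        q[idx[src], idx[src]] -= rate

    for layer in ("", "I"):
        add(layer + "C2" if layer else "C2", layer + "C1", r.a1)
        add(layer + "C1", layer + "C2", r.b1)
        add(layer + "C1", layer + "O", r.a2)
        add(layer + "O", layer + "C1", r.b2)
    for base in ("O", "C1", "C2"):
        add(base, "I" + base, r.bh)
        add("I" + base, base, r.ah)
    return q


def markov_derivatives(
    params: KineticParameterSet, v: float, m: MarkovOccupancy
) -> np.ndarray:
    """Master-equation time derivatives of the six occupancies (ms^-1)."""
    m.validate()
    return markov_rate_matrix(params, v) @ m.as_array()
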