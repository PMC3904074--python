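"""Membrane mechanisms: leak, alpha/beta-gated channels, synaptic receptors.

Gated channels use the five-parameter rate form

    rate(V) = (A + B*V) / (C + exp((V + D) / E))

with A in ms^-1, B in ms^-1 mV^-1, D and E in mV and C dimensionless. The
removable singularity that occurs when C < 0 and the denominator vanishes
(the classic linoid rates) is handled by the analytic limit B*E/(-C) rather
than numerical nudging, so e.g. the squid axon m-gate activation rate is
exactly 1 ms^-1 at V = -40 mV.

Every channel exposes ``get_variables()`` and ``get_defaults()`` so the
distribution machinery can apply per-region parameter overrides uniformly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, NumericError, StateError
from .units import (
    CONDUCTANCE,
    CONDUCTANCE_DENSITY,
    VOLTAGE,
    Quantity,
    ensure_quantity,
)

__all__ = [
    "Channel",
    "LeakChannel",
    "GatedChannel",
    "GateSpec",
    "PSRSpec",
    "eval_rate",
    "gate_steady_state_and_tau",
    "channel_current_density",
    "psr_conductance",
    "psr_peak_time",
    "psr_normalisation",
    "hh_sodium",
    "hh_potassium",
    "make_leak",
    "channel_to_json",
    "channel_from_json",
]

_SINGULARITY_TOL = 1e-9


def eval_rate(params: Sequence[float], v_mV) -> float | np.ndarray:
    """Evaluate (A + B*V)/(C + exp((V+D)/E)) in ms^-1 at V in mV.

    Scalar or array ``v_mV``. At a removable singularity (denominator zero
    with vanishing numerator, possible only for C < 0) the analytic limit
    ``B*E/(-C)`` is returned; a non-removable zero denominator raises
    :class:`NumericError`.
    """
    a, b, c, d, e = (float(p) for p in params)
    if e == 0.0:
        raise DomainError("rate parameter E must be nonzero")
    v = np.asarray(v_mV, dtype=float)
    num = np.asarray(a + b * v, dtype=float)
    den = np.asarray(c + np.exp((v + d) / e), dtype=float)
    near = np.abs(den) < _SINGULARITY_TOL
    if np.any(near):
        if c >= 0.0 or np.any(np.abs(np.where(near, num, 0.0)) > 1e-6):
            raise NumericError(
                f"non-removable zero denominator in rate {tuple(params)}"
            )
        limit = b * e / (-c)
        out = np.where(near, limit, num / np.where(near, 1.0, den))
    else:
        out = num / den
    if v.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin-Huxley-style gating particle.

    ``alpha_params``/``beta_params`` are (A, B, C, D, E) tuples of the
    standard rate form; ``exponent`` is the power the gate enters the
    conductance with (e.g. 3 for m^3).
    """

    name: str
    exponent: int
    alpha_params: tuple[float, float, float, float, float]
    beta_params: tuple[float, float, float, float, float]

    def __post_init__(self):
        if self.exponent < 1:
            raise DomainError(f"gate {self.name!r}: exponent must be >= 1")
        for label, p in (("alpha", self.alpha_params), ("beta", self.beta_params)):
            if len(p) != 5:
                raise DomainError(
                    f"gate {self.name!r}: {label}_params must be a 5-tuple"
                )
            if p[4] == 0:
                raise DomainError(f"gate {self.name!r}: E must be nonzero")

    def alpha(self, v_mV):
        return eval_rate(self.alpha_params, v_mV)

    def beta(self, v_mV):
        return eval_rate(self.beta_params, v_mV)


def gate_steady_state_and_tau(gate: GateSpec, v_mV):
    """Return (inf, tau_ms) at voltage ``v_mV`` (scalar or array)."""
    a = gate.alpha(v_mV)
    b = gate.beta(v_mV)
    total = a + b
    if np.any(np.asarray(total) <= 0):
        raise NumericError(
            f"gate {gate.name!r}: alpha+beta not positive at V={v_mV} mV"
        )
    return a / total, 1.0 / total


class Channel:
    """Base class: a named mechanism with a uniform parameter interface."""

    mechanism_kind = "abstract"

    def __init__(self, name: str, defaults: Mapping[str, Quantity]):
        self.name = name
        self._defaults = dict(defaults)

    def get_variables(self) -> list[str]:
        """Ordered parameter names; keys of :meth:`get_defaults`."""
        return list(self._defaults.keys())

    def get_defaults(self) -> dict[str, Quantity]:
        return dict(self._defaults)

    # subclasses implement the current law
    def current_density(self, state, v_mV: float, params) -> float:
        raise NotImplementedError

    def __repr__(self):
        return f"{type(self).__name__}({self.name!r})"


class LeakChannel(Channel):
    """Ohmic leak: i = gbar * (V - erev), positive outward."""

    mechanism_kind = "leak"

    def __init__(self, name: str, gbar, erev):
        gbar = ensure_quantity(gbar, default_unit="mS/cm2",
                               expect_dim=CONDUCTANCE_DENSITY)
        erev = ensure_quantity(erev, default_unit="mV", expect_dim=VOLTAGE)
        super().__init__(name, {"gbar": gbar, "erev": erev})

    @property
    def gates(self) -> list[GateSpec]:
        return []

    def current_density(self, state, v_mV, params=None) -> float:
        """Current density in mA/cm2 (positive outward)."""
        params = params or self.get_defaults()
        g = params["gbar"].magnitude_in("mS/cm2")
        e = params["erev"].magnitude_in("mV")
        return g * (v_mV - e) * 1e-3  # mS/cm2 * mV = uA/cm2 -> mA/cm2


class GatedChannel(Channel):
    """Voltage-gated channel: i = gbar * prod(gate^exp) * (V - erev)."""

    mechanism_kind = "alpha_beta_gated"

    def __init__(self, name: str, gbar, erev, gates: Sequence[GateSpec]):
        gbar = ensure_quantity(gbar, default_unit="mS/cm2",
                               expect_dim=CONDUCTANCE_DENSITY)
        erev = ensure_quantity(erev, default_unit="mV", expect_dim=VOLTAGE)
        super().__init__(name, {"gbar": gbar, "erev": erev})
        self.gates = list(gates)
        if not self.gates:
            raise DomainError(f"gated channel {name!r} needs >= 1 gate")

    def open_fraction(self, state: Mapping[str, float]) -> float:
        frac = 1.0
        for g in self.gates:
            x = state[g.name]
            if not (0.0 <= np.min(x) and np.max(x) <= 1.0):
                raise StateError(
                    f"gate {g.name!r} value {x} outside [0, 1]"
                )
            frac = frac * x**g.exponent
        return frac

    def current_density(self, state, v_mV, params=None) -> float:
        """Current density in mA/cm2 (positive outward)."""
        params = params or self.get_defaults()
        g = params["gbar"].magnitude_in("mS/cm2")
        e = params["erev"].magnitude_in("mV")
        return g * self.open_fraction(state) * (v_mV - e) * 1e-3


def channel_current_density(chl: Channel, state, v_mV, params=None) -> Quantity:
    """Membrane current density of ``chl`` at voltage ``v_mV`` (mV).

    Positive sign = outward current. ``state`` maps gate names to values in
    [0, 1] (ignored for leak channels).
    """
    return Quantity(chl.current_density(state, v_mV, params), "mA/cm2")


# ---------------------------------------------------------------------------
# Double-exponential postsynaptic receptor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSRSpec:
    """Double-exponential postsynaptic conductance template.

    The waveform is peak-normalised: the conductance transient following a
    single event reaches exactly ``gbar`` at
    ``t_p = tau_d*tau_r/(tau_d - tau_r) * ln(tau_d/tau_r)``.
    """

    tau_rise: Quantity
    tau_decay: Quantity
    gbar: Quantity
    erev: Quantity
    delay: Quantity

    def __init__(self, tau_rise, tau_decay, gbar, erev, delay="0 ms"):
        object.__setattr__(
            self, "tau_rise", ensure_quantity(tau_rise, default_unit="ms"))
        object.__setattr__(
            self, "tau_decay", ensure_quantity(tau_decay, default_unit="ms"))
        object.__setattr__(
            self, "gbar",
            ensure_quantity(gbar, default_unit="nS", expect_dim=CONDUCTANCE))
        object.__setattr__(
            self, "erev",
            ensure_quantity(erev, default_unit="mV", expect_dim=VOLTAGE))
        object.__setattr__(
            self, "delay", ensure_quantity(delay, default_unit="ms"))
        tr = self.tau_rise.magnitude_in("ms")
        td = self.tau_decay.magnitude_in("ms")
        if not (0.0 < tr < td):
            raise DomainError(
                f"require 0 < tau_rise < tau_decay, got {tr} / {td} ms"
            )
        if self.gbar.si < 0:
            raise DomainError("gbar must be >= 0")
        if self.delay.si < 0:
            raise DomainError("delay must be >= 0")


def psr_peak_time(p: PSRSpec) -> float:
    """Time to peak after an event, in ms."""
    tr = p.tau_rise.magnitude_in("ms")
    td = p.tau_decay.magnitude_in("ms")
    return td * tr / (td - tr) * math.log(td / tr)


def psr_normalisation(p: PSRSpec) -> float:
    """Factor N making gbar the literal peak conductance."""
    tr = p.tau_rise.magnitude_in("ms")
    td = p.tau_decay.magnitude_in("ms")
    tp = psr_peak_time(p)
    return 1.0 / (math.exp(-tp / td) - math.exp(-tp / tr))


def psr_conductance(p: PSRSpec, t_since_event_ms) -> Quantity:
    """Conductance (nS) at time ``t_since_event_ms`` after one event.

    Zero before the event; contributions of multiple events add linearly
    (handled upstream by the solver).
    """
    t = np.asarray(t_since_event_ms, dtype=float)
    if np.any(t < 0):
        raise DomainError("t_since_event must be >= 0")
    tr = p.tau_rise.magnitude_in("ms")
    td = p.tau_decay.magnitude_in("ms")
    g = (
        p.gbar.magnitude_in("nS")
        * psr_normalisation(p)
        * (np.exp(-t / td) - np.exp(-t / tr))
    )
    return Quantity(float(g) if t.ndim == 0 else g, "nS")


# ---------------------------------------------------------------------------
# Library fixtures: the classic squid-axon channels
# ---------------------------------------------------------------------------

def hh_sodium(name: str = "hh_na", gbar="120 mS/cm2", erev="50 mV") -> GatedChannel:
    """Classic squid-axon sodium channel (m^3 h)."""
    m_gate = GateSpec(
        name="m", exponent=3,
        alpha_params=(-4.0, -0.1, -1.0, 40.0, -10.0),
        beta_params=(4.0, 0.0, 0.0, 65.0, 18.0),
    )
    h_gate = GateSpec(
        name="h", exponent=1,
        alpha_params=(0.07, 0.0, 0.0, 65.0, 20.0),
        beta_params=(1.0, 0.0, 1.0, 35.0, -10.0),
    )
    return GatedChannel(name, gbar, erev, [m_gate, h_gate])


def hh_potassium(name: str = "hh_k", gbar="36 mS/cm2", erev="-77 mV") -> GatedChannel:
    """Classic squid-axon delayed-rectifier potassium channel (n^4)."""
    n_gate = GateSpec(
        name="n", exponent=4,
        alpha_params=(-0.55, -0.01, -1.0, 55.0, -10.0),
        beta_params=(0.125, 0.0, 0.0, 65.0, 80.0),
    )
    return GatedChannel(name, gbar, erev, [n_gate])


def make_leak(name: str = "leak", gbar="0.3 mS/cm2", erev="-54.3 mV") -> LeakChannel:
    return LeakChannel(name, gbar, erev)


# ---------------------------------------------------------------------------
# JSON serialisation
# ---------------------------------------------------------------------------

def channel_to_json(chl: Channel) -> dict:
    doc = {
        "name": chl.name,
        "kind": chl.mechanism_kind,
        "parameters": {
            k: {"value": float(q.magnitude), "unit": q.unit_label}
            for k, q in chl.get_defaults().items()
        },
    }
    if isinstance(chl, GatedChannel):
        doc["gates"] = [
            {
                "name": g.name,
                "exponent": g.exponent,
                "alpha": list(g.alpha_params),
                "beta": list(g.beta_params),
            }
            for g in chl.gates
        ]
    return doc


def channel_from_json(doc: dict) -> Channel:
    params = {
        k: Quantity(v["value"], v["unit"])
        for k, v in doc["parameters"].items()
    }
    kind = doc["kind"]
    if kind == "leak":
        return LeakChannel(doc["name"], params["gbar"], params["erev"])
    if kind == "alpha_beta_gated":
        gates = [
            GateSpec(g["name"], g["exponent"], tuple(g["alpha"]),
                     tuple(g["beta"]))
            for g in doc["gates"]
        ]
        return GatedChannel(doc["name"], params["gbar"], params["erev"], gates)
    raise ValueError(f"unknown channel kind {kind!r}")


def channel_json_text(chl: Channel) -> str:
    return json.dumps(channel_to_json(chl), indent=2, sort_keys=True)
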