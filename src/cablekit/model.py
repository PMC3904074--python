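"""The declarative simulation object graph.

A :class:`Simulation` collects cells, stimuli, synapses, gap junctions and
recording requests; constructing the graph performs no numerics. Calling
:meth:`Simulation.run` validates the graph and hands it to the internal
cable solver, returning a :class:`~cablekit.traces.SimulationResults` with
exactly one output per recording request.

Component libraries let builders for cells/channels/morphologies/receptors
be registered once and instantiated by name with keyword arguments
forwarded to the builder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .channels import Channel, PSRSpec
from .distribution import Applicator, ChannelApplication, Targeter, \
    resolve_distribution
from .errors import ReferenceError_, ValidationError
from .morphology import MorphLocation, Morphology
from .units import (
    CAPACITANCE_DENSITY,
    CURRENT,
    FREQUENCY,
    RESISTIVITY,
    TIME,
    VOLTAGE,
    Quantity,
    ensure_quantity,
)

__all__ = [
    "Cell",
    "Simulation",
    "CurrentClampStep",
    "CurrentClampRamp",
    "CurrentClampSine",
    "VoltageClampStep",
    "SynapseTemplate",
    "Synapse",
    "GapJunction",
    "RecordingRequest",
    "ComponentLibrary",
]


class Cell:
    """A neuron: morphology + channel applications + passive properties."""

    def __init__(
        self,
        name: str,
        morphology: Morphology,
        capacitance="1.0 uF/cm2",
        axial_resistivity="100 Ohm*cm",
        initial_voltage=None,
        nseg_map: Optional[dict[str, int]] = None,
    ):
        self.name = name
        self.morphology = morphology
        self.capacitance = ensure_quantity(
            capacitance, default_unit="uF/cm2", expect_dim=CAPACITANCE_DENSITY)
        self.axial_resistivity = ensure_quantity(
            axial_resistivity, default_unit="Ohm*cm", expect_dim=RESISTIVITY)
        self.initial_voltage = (
            None if initial_voltage is None
            else ensure_quantity(initial_voltage, default_unit="mV",
                                 expect_dim=VOLTAGE)
        )
        self.nseg_map = dict(nseg_map or {})
        self.applications: list[ChannelApplication] = []
        if self.capacitance.si <= 0:
            raise ValidationError("capacitance must be positive")
        if self.axial_resistivity.si <= 0:
            raise ValidationError("axial resistivity must be positive")

    def apply_channel(
        self,
        channel: Channel,
        applicator: Applicator | None = None,
        targeter: Targeter | None = None,
    ) -> ChannelApplication:
        app = ChannelApplication(
            channel=channel,
            applicator=applicator or Applicator(),
            targeter=targeter or Targeter.everywhere(),
        )
        self.applications.append(app)
        return app

    def soma_location(self, fraction: float = 0.5) -> MorphLocation:
        return MorphLocation(self.morphology.root, fraction)

    def resolve_channels(self):
        return resolve_distribution(self.applications, self.morphology)

    def location(self, section_id: str, fraction: float = 0.5) -> MorphLocation:
        return MorphLocation(self.morphology[section_id], fraction)

    def __repr__(self):
        return f"Cell({self.name!r}, {len(self.morphology)} sections)"


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

class Stimulus:
    kind = "abstract"

    def __init__(self, name: str, cell: Cell, location: MorphLocation):
        self.name = name
        self.cell = cell
        self.location = location


class _CurrentClamp(Stimulus):
    def current_nA(self, t_ms: float) -> float:  # pragma: no cover
        raise NotImplementedError


class CurrentClampStep(_CurrentClamp):
    """Constant current ``amp`` for delay <= t < delay + duration."""

    kind = "step"

    def __init__(self, name, cell, location, amp, delay="0 ms",
                 duration=None):
        super().__init__(name, cell, location)
        self.amp = ensure_quantity(amp, default_unit="pA", expect_dim=CURRENT)
        self.delay = ensure_quantity(delay, default_unit="ms", expect_dim=TIME)
        self.duration = (
            None if duration is None
            else ensure_quantity(duration, default_unit="ms", expect_dim=TIME)
        )
        _check_timing(self.delay, self.duration)

    def current_nA(self, t_ms):
        d = self.delay.magnitude_in("ms")
        end = math.inf if self.duration is None else d + self.duration.magnitude_in("ms")
        amp = self.amp.magnitude_in("nA")
        return np.where((t_ms >= d) & (t_ms < end), amp, 0.0)


class CurrentClampRamp(_CurrentClamp):
    """Linear ramp from amp0 to amp1 over the stimulus window."""

    kind = "ramp"

    def __init__(self, name, cell, location, amp0, amp1, delay="0 ms",
                 duration="100 ms"):
        super().__init__(name, cell, location)
        self.amp0 = ensure_quantity(amp0, default_unit="pA", expect_dim=CURRENT)
        self.amp1 = ensure_quantity(amp1, default_unit="pA", expect_dim=CURRENT)
        self.delay = ensure_quantity(delay, default_unit="ms", expect_dim=TIME)
        self.duration = ensure_quantity(duration, default_unit="ms",
                                        expect_dim=TIME)
        _check_timing(self.delay, self.duration)

    def current_nA(self, t_ms):
        d = self.delay.magnitude_in("ms")
        dur = self.duration.magnitude_in("ms")
        a0 = self.amp0.magnitude_in("nA")
        a1 = self.amp1.magnitude_in("nA")
        frac = np.clip((np.asarray(t_ms, dtype=float) - d) / dur, 0.0, 1.0)
        inside = (t_ms >= d) & (t_ms < d + dur)
        return np.where(inside, a0 + frac * (a1 - a0), 0.0)


class CurrentClampSine(_CurrentClamp):
    """Sinusoidal current amp*sin(2*pi*f*(t-delay) + phase) in the window."""

    kind = "sine"

    def __init__(self, name, cell, location, amp, frequency, delay="0 ms",
                 duration=None, phase=0.0):
        super().__init__(name, cell, location)
        self.amp = ensure_quantity(amp, default_unit="pA", expect_dim=CURRENT)
        self.frequency = ensure_quantity(frequency, default_unit="Hz",
                                         expect_dim=FREQUENCY)
        self.delay = ensure_quantity(delay, default_unit="ms", expect_dim=TIME)
        self.duration = (
            None if duration is None
            else ensure_quantity(duration, default_unit="ms", expect_dim=TIME)
        )
        self.phase = float(phase)
        _check_timing(self.delay, self.duration)

    def current_nA(self, t_ms):
        d = self.delay.magnitude_in("ms")
        end = math.inf if self.duration is None else d + self.duration.magnitude_in("ms")
        amp = self.amp.magnitude_in("nA")
        f_per_ms = self.frequency.magnitude_in("kHz")  # cycles per ms
        t = np.asarray(t_ms, dtype=float)
        wave = amp * np.sin(2 * math.pi * f_per_ms * (t - d) + self.phase)
        return np.where((t >= d) & (t < end), wave, 0.0)


class VoltageClampStep(Stimulus):
    """Step voltage clamp via a large series conductance (default 1 MOhm)."""

    kind = "vclamp"

    def __init__(self, name, cell, location, voltage, delay="0 ms",
                 duration=None, series_resistance="1 MOhm"):
        super().__init__(name, cell, location)
        self.voltage = ensure_quantity(voltage, default_unit="mV",
                                       expect_dim=VOLTAGE)
        self.delay = ensure_quantity(delay, default_unit="ms", expect_dim=TIME)
        self.duration = (
            None if duration is None
            else ensure_quantity(duration, default_unit="ms", expect_dim=TIME)
        )
        self.series_resistance = ensure_quantity(
            series_resistance, default_unit="MOhm")
        _check_timing(self.delay, self.duration)

    def series_conductance_uS(self) -> float:
        return 1.0 / self.series_resistance.magnitude_in("MOhm")

    def active(self, t_ms) -> bool:
        d = self.delay.magnitude_in("ms")
        end = math.inf if self.duration is None else d + self.duration.magnitude_in("ms")
        return (t_ms >= d) & (t_ms < end)

    def command_mV(self, t_ms) -> float:
        return self.voltage.magnitude_in("mV")


def _check_timing(delay, duration):
    if delay.si < 0:
        raise ValidationError("stimulus delay must be >= 0")
    if duration is not None and duration.si < 0:
        raise ValidationError("stimulus duration must be >= 0")


_PROTOCOLS = {
    "step": CurrentClampStep,
    "ramp": CurrentClampRamp,
    "sine": CurrentClampSine,
}


# ---------------------------------------------------------------------------
# Synapses and gap junctions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapseTemplate:
    """A named, reusable double-exponential PSR parameter set."""

    name: str
    psr: PSRSpec

    @classmethod
    def build(cls, name, tau_rise, tau_decay, gbar, erev, delay="0 ms"):
        return cls(name, PSRSpec(tau_rise, tau_decay, gbar, erev, delay))


class SpikeTimesTrigger:
    """Explicit presynaptic event times (ms)."""

    def __init__(self, times_ms: Sequence[float]):
        self.times = sorted(float(t) for t in times_ms)
        if any(t < 0 for t in self.times):
            raise ValidationError("spike times must be >= 0")


class ThresholdTrigger:
    """Trigger on upward threshold crossing at a presynaptic location."""

    def __init__(self, cell: Cell, location: MorphLocation, threshold="0 mV"):
        self.cell = cell
        self.location = location
        self.threshold = ensure_quantity(threshold, default_unit="mV",
                                         expect_dim=VOLTAGE)


class Synapse:
    def __init__(self, name, template: SynapseTemplate, post_cell: Cell,
                 post_location: MorphLocation, trigger, delay=None):
        self.name = name
        self.template = template
        self.post_cell = post_cell
        self.post_location = post_location
        self.trigger = trigger
        # per-instance delay overrides the template's
        self.delay = (template.psr.delay if delay is None
                      else ensure_quantity(delay, default_unit="ms"))
        if self.delay.si < 0:
            raise ValidationError("synaptic delay must be >= 0")

    @property
    def pre_cell(self) -> Cell | None:
        return self.trigger.cell if isinstance(self.trigger, ThresholdTrigger) else None


class GapJunction:
    def __init__(self, name, conductance, cell1: Cell, loc1: MorphLocation,
                 cell2: Cell, loc2: MorphLocation):
        self.name = name
        self.conductance = ensure_quantity(conductance, default_unit="nS")
        self.cell1, self.loc1 = cell1, loc1
        self.cell2, self.loc2 = cell2, loc2
        if self.conductance.si < 0:
            raise ValidationError("gap junction conductance must be >= 0")
        if cell1 is cell2 and loc1 == loc2:
            raise ValidationError("gap junction endpoints must be distinct")


# ---------------------------------------------------------------------------
# Recording requests
# ---------------------------------------------------------------------------

_MODALITIES = {
    "Voltage", "Current", "CurrentDensity", "Conductance",
    "ConductanceDensity", "Events",
}


@dataclass
class RecordingRequest:
    what: str
    target: object  # Cell | Stimulus | Synapse
    location: Optional[MorphLocation] = None
    channel: Optional[Channel] = None
    threshold: Optional[Quantity] = None  # Events only
    user_tags: frozenset = frozenset()
    name: str = ""


# ---------------------------------------------------------------------------
# Component libraries
# ---------------------------------------------------------------------------

class ComponentLibrary:
    """Registry mapping (model_src, component_type) -> builder function."""

    def __init__(self, kind: str):
        self.kind = kind
        self._registry: dict[tuple[str, str], Callable] = {}

    def register(self, model_src: str, component_type: str,
                 builder: Callable) -> None:
        key = (model_src, component_type)
        if key in self._registry:
            raise ValueError(
                f"{self.kind} library: duplicate registration for {key!r}"
            )
        if not callable(builder):
            raise TypeError("builder must be callable")
        self._registry[key] = builder

    def instantiate(self, model_src: str, component_type: str, **kwargs):
        key = (model_src, component_type)
        try:
            builder = self._registry[key]
        except KeyError:
            raise LookupError(
                f"{self.kind} library: no builder for {key!r}; known keys: "
                f"{sorted(self._registry)}"
            ) from None
        return builder(**kwargs)

    def __iter__(self):
        return iter(sorted(self._registry.items()))

    def __len__(self):
        return len(self._registry)

    def summary_table(self) -> list[tuple[str, str, str]]:
        """(model_src, component_type, builder name) per registration."""
        return [
            (src, ctype, getattr(fn, "__name__", repr(fn)))
            for (src, ctype), fn in self
        ]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

class Simulation:
    """Declarative container for one in-silico experiment.

    Building the graph is inert; all numerics happen in :meth:`run`.
    """

    def __init__(self, name="simulation", duration="200 ms", dt="0.025 ms",
                 seed: int = 0):
        self.name = name
        self.duration = ensure_quantity(duration, default_unit="ms",
                                        expect_dim=TIME)
        self.dt = ensure_quantity(dt, default_unit="ms", expect_dim=TIME)
        self.seed = int(seed)
        self.cells: list[Cell] = []
        self.stimuli: list[Stimulus] = []
        self.synapses: list[Synapse] = []
        self.gap_junctions: list[GapJunction] = []
        self.recordings: list[RecordingRequest] = []
        if self.duration.si <= 0:
            raise ValidationError("duration must be positive")
        if self.dt.si <= 0:
            raise ValidationError("dt must be positive")

    # -- builders ---------------------------------------------------------
    def create_cell(self, name, morphology, **kwargs) -> Cell:
        if any(c.name == name for c in self.cells):
            raise ValidationError(f"duplicate cell name {name!r}")
        cell = Cell(name, morphology, **kwargs)
        self.cells.append(cell)
        return cell

    def add_cell(self, cell: Cell) -> Cell:
        if any(c.name == cell.name for c in self.cells):
            raise ValidationError(f"duplicate cell name {cell.name!r}")
        self.cells.append(cell)
        return cell

    def create_currentclamp(self, cell, location=None, protocol="step",
                            name=None, **params) -> Stimulus:
        """Create and register a current clamp; ``protocol`` defaults to step."""
        if protocol not in _PROTOCOLS:
            raise ValidationError(
                f"unknown protocol {protocol!r}; choose from "
                f"{sorted(_PROTOCOLS)}"
            )
        location = location or cell.soma_location()
        name = name or f"cclamp{len(self.stimuli) + 1}"
        cls = _PROTOCOLS[protocol]
        try:
            stim = cls(name, cell, location, **params)
        except TypeError as exc:
            raise ValidationError(
                f"missing or invalid parameters for protocol {protocol!r}: "
                f"{exc}"
            ) from None
        self.stimuli.append(stim)
        return stim

    def create_voltageclamp(self, cell, location=None, name=None,
                            **params) -> VoltageClampStep:
        location = location or cell.soma_location()
        name = name or f"vclamp{len(self.stimuli) + 1}"
        stim = VoltageClampStep(name, cell, location, **params)
        self.stimuli.append(stim)
        return stim

    def create_synapse(self, template: SynapseTemplate, post_cell: Cell,
                       post_location=None, trigger=None, name=None,
                       delay=None) -> Synapse:
        if trigger is None:
            raise ValidationError("synapse needs a trigger")
        post_location = post_location or post_cell.soma_location()
        name = name or f"syn{len(self.synapses) + 1}"
        syn = Synapse(name, template, post_cell, post_location, trigger,
                      delay=delay)
        self.synapses.append(syn)
        return syn

    def create_gapjunction(self, conductance, cell1, loc1=None, cell2=None,
                           loc2=None, name=None) -> GapJunction:
        loc1 = loc1 or cell1.soma_location()
        loc2 = loc2 or cell2.soma_location()
        name = name or f"gj{len(self.gap_junctions) + 1}"
        gj = GapJunction(name, conductance, cell1, loc1, cell2, loc2)
        self.gap_junctions.append(gj)
        return gj

    # -- recording --------------------------------------------------------
    def record(self, target, what="Voltage", location=None, channel=None,
               threshold=None, user_tags: Iterable[str] = (),
               name=None) -> RecordingRequest:
        """Request that a value be recorded during the run.

        ``target`` is a Cell (Voltage / CurrentDensity / ConductanceDensity
        / Events), a current or voltage clamp (Current), or a Synapse
        (Conductance / Current).
        """
        if what not in _MODALITIES:
            raise ValidationError(
                f"unknown recordable {what!r}; choose from {sorted(_MODALITIES)}"
            )
        if isinstance(target, Cell):
            if target not in self.cells:
                raise ReferenceError_(
                    f"cell {target.name!r} is not part of simulation "
                    f"{self.name!r}"
                )
            location = location or target.soma_location()
            if what in ("CurrentDensity", "ConductanceDensity"):
                if channel is None:
                    raise ValidationError(f"{what} recording needs a channel")
                resolved = target.resolve_channels()
                if (location.section.id, channel.name) not in resolved:
                    raise ReferenceError_(
                        f"channel {channel.name!r} is not present on section "
                        f"{location.section.id!r} of cell {target.name!r}"
                    )
            elif what not in ("Voltage", "Events"):
                raise ValidationError(f"cannot record {what!r} from a cell")
        elif isinstance(target, Stimulus):
            if target not in self.stimuli:
                raise ReferenceError_(
                    f"stimulus {target.name!r} is not part of this simulation"
                )
            if what != "Current":
                raise ValidationError(
                    f"cannot record {what!r} from a stimulus"
                )
        elif isinstance(target, Synapse):
            if target not in self.synapses:
                raise ReferenceError_(
                    f"synapse {target.name!r} is not part of this simulation"
                )
            if what not in ("Conductance", "Current"):
                raise ValidationError(f"cannot record {what!r} from a synapse")
        else:
            raise ReferenceError_(f"cannot record from {target!r}")

        thr = (ensure_quantity(threshold, default_unit="mV")
               if threshold is not None else None)
        req = RecordingRequest(
            what=what, target=target, location=location, channel=channel,
            threshold=thr, user_tags=frozenset(user_tags),
            name=name or f"rec{len(self.recordings) + 1}",
        )
        self.recordings.append(req)
        return req

    # -- validation and execution -----------------------------------------
    def validate(self) -> None:
        problems: list[str] = []
        if not self.cells:
            problems.append("simulation has no cells")
        for cell in self.cells:
            try:
                cell.morphology.validate()
                cell.resolve_channels()
            except Exception as exc:
                problems.append(f"cell {cell.name!r}: {exc}")
        dur = self.duration.magnitude_in("ms")
        for syn in self.synapses:
            if isinstance(syn.trigger, SpikeTimesTrigger):
                late = [t for t in syn.trigger.times if t > dur]
                if late:
                    # silently dropped at run time; not a validation failure
                    pass
        for stim in self.stimuli:
            if stim.cell not in self.cells:
                problems.append(
                    f"stimulus {stim.name!r} targets a cell outside the "
                    "simulation"
                )
        if problems:
            raise ValidationError("; ".join(problems))

    def run(self, method: str = "backward_euler"):
        """Validate and integrate; returns SimulationResults."""
        from . import solver

        self.validate()
        return solver.simulate(self, method=method)

    def __repr__(self):
        return (
            f"Simulation({self.name!r}, {len(self.cells)} cells, "
            f"{len(self.recordings)} recordings)"
        )
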