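"""Internal numerical backend: branched-cable integration.

Each cell's morphology is discretized into segments (equal-arc splits of
each section); the membrane equation

    C dV/dt = -sum(ionic) - axial + I_inj + I_syn + I_gap

is advanced with an implicit theta-method (backward Euler by default,
Crank-Nicolson with ``method="crank_nicolson"``) solved in O(N) per cell
on the Hines-ordered segment tree. Gating variables use the Rush-Larsen
exponential update at the start-of-step voltage; double-exponential
synapses are integrated analytically between events (two decaying states);
gap junctions couple cells through a short fixed-point iteration so each
cell keeps its own tree solve.

Internal unit system: mV, ms, uS, nF, nA (so C dV/dt, g*V and I are all in
nA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .channels import GatedChannel, LeakChannel, gate_steady_state_and_tau, \
    psr_normalisation
from .errors import DiscretizationError, NumericError
from .model import (
    Cell,
    CurrentClampStep,
    Simulation,
    SpikeTimesTrigger,
    ThresholdTrigger,
    VoltageClampStep,
    _CurrentClamp,
)
from .morphology import MorphLocation, frustum_lateral_area, resolve_location
from .traces import EventSet, SimulationResults, Trace

__all__ = ["DiscretizedCell", "discretize", "simulate", "ThresholdDetector",
           "detect_events"]

_GJ_MAX_ITER = 5
_GJ_TOL_MV = 1e-9


# ---------------------------------------------------------------------------
# Spatial discretization
# ---------------------------------------------------------------------------

@dataclass
class _ChannelInstance:
    channel: object
    seg_idx: np.ndarray          # global segment indices within the cell
    g_dens_mS_cm2: np.ndarray    # per listed segment
    erev_mV: np.ndarray
    g_max_uS: np.ndarray         # g_dens * area
    gates: list = field(default_factory=list)   # GateSpec list (gated only)
    gate_state: dict = field(default_factory=dict)  # name -> array


class DiscretizedCell:
    """Segment arrays for one cell, in Hines (parents-first) order."""

    def __init__(self, cell: Cell, nseg_map: Optional[dict] = None):
        m = cell.morphology
        m.validate()
        nseg_map = dict(cell.nseg_map)
        if nseg_map is None:
            nseg_map = {}
        self.cell = cell
        ra = cell.axial_resistivity.magnitude_in("Ohm*cm")
        cap = cell.capacitance.magnitude_in("uF/cm2")

        areas: list[float] = []          # cm^2
        parents: list[int] = []
        g_ax: list[float] = []           # uS, to parent
        half_res: list[float] = []       # Ohm, half-segment axial resistance
        sec_ids: list[str] = []
        regions: list[str] = []
        self._section_offset: dict[str, int] = {}
        self._section_nseg: dict[str, int] = {}
        last_seg_of: dict[str, int] = {}

        for sec in m:
            n = int(nseg_map.get(sec.id, 1))
            if n < 1:
                raise DiscretizationError(
                    f"section {sec.id!r}: nseg must be >= 1, got {n}"
                )
            L = sec.length
            if L <= 0:
                raise DiscretizationError(
                    f"section {sec.id!r}: zero-length section"
                )
            self._section_offset[sec.id] = len(areas)
            self._section_nseg[sec.id] = n
            for k in range(n):
                f0, f1 = k / n, (k + 1) / n
                r1 = sec.radius_at(f0)
                r2 = sec.radius_at(f1)
                rc = sec.radius_at((k + 0.5) / n)
                area_um2 = frustum_lateral_area(r1, r2, L / n)
                areas.append(area_um2 * 1e-8)  # um^2 -> cm^2
                # half-segment axial resistance, Ohm (lengths in cm)
                hr = ra * (L / (2 * n) * 1e-4) / (math.pi * (rc * 1e-4) ** 2)
                half_res.append(hr)
                idx = len(areas) - 1
                if k == 0:
                    if sec.parent is None:
                        parents.append(-1)
                        g_ax.append(0.0)
                    else:
                        pidx = last_seg_of[sec.parent.id]
                        parents.append(pidx)
                        g_ax.append(
                            1e6 / (half_res[idx] + half_res[pidx])
                        )
                else:
                    parents.append(idx - 1)
                    g_ax.append(1e6 / (half_res[idx] + half_res[idx - 1]))
                sec_ids.append(sec.id)
                regions.append(sec.region)
            last_seg_of[sec.id] = len(areas) - 1

        self.n = len(areas)
        self.area_cm2 = np.array(areas)
        self.c_nF = cap * self.area_cm2 * 1e3  # uF/cm2 * cm2 -> uF -> nF
        self.parent = np.array(parents, dtype=int)
        self.g_axial_uS = np.array(g_ax)
        self.section_ids = sec_ids
        self.regions = regions

        # channel instances from the resolved distribution
        resolved = cell.resolve_channels()
        chl_by_name = {}
        for app in cell.applications:
            chl_by_name.setdefault(app.channel.name, app.channel)
        self.instances: dict[str, _ChannelInstance] = {}
        for chname, chl in chl_by_name.items():
            seg_idx, g_dens, erev = [], [], []
            for sec in m:
                params = resolved.get((sec.id, chname))
                if params is None:
                    continue
                g = params["gbar"].magnitude_in("mS/cm2")
                e = params["erev"].magnitude_in("mV")
                off = self._section_offset[sec.id]
                for k in range(self._section_nseg[sec.id]):
                    seg_idx.append(off + k)
                    g_dens.append(g)
                    erev.append(e)
            if not seg_idx:
                continue
            inst = _ChannelInstance(
                channel=chl,
                seg_idx=np.array(seg_idx, dtype=int),
                g_dens_mS_cm2=np.array(g_dens),
                erev_mV=np.array(erev),
                g_max_uS=np.array(g_dens) * self.area_cm2[seg_idx] * 1e3,
            )
            if isinstance(chl, GatedChannel):
                inst.gates = list(chl.gates)
            self.instances[chname] = inst

        self.hines_order = np.arange(self.n)  # construction order is valid

    def seg_index(self, loc: MorphLocation) -> int:
        """Global segment index for a MorphLocation on this cell."""
        nseg = self._section_nseg[loc.section.id]
        k, _ = resolve_location(loc, nseg)
        return self._section_offset[loc.section.id] + k

    def initial_voltage(self) -> np.ndarray:
        """Per-segment rest estimate: leak-conductance-weighted reversal."""
        if self.cell.initial_voltage is not None:
            return np.full(self.n, self.cell.initial_voltage.magnitude_in("mV"))
        num = np.zeros(self.n)
        den = np.zeros(self.n)
        for inst in self.instances.values():
            if isinstance(inst.channel, LeakChannel):
                num[inst.seg_idx] += inst.g_max_uS * inst.erev_mV
                den[inst.seg_idx] += inst.g_max_uS
        v0 = np.full(self.n, -65.0)
        ok = den > 0
        v0[ok] = num[ok] / den[ok]
        return v0


def discretize(cell: Cell, nseg_map: Optional[dict] = None) -> DiscretizedCell:
    """Discretize a cell; ``nseg_map`` overrides the cell's own map."""
    if nseg_map is not None:
        cell = _with_nseg(cell, nseg_map)
    return DiscretizedCell(cell)


def _with_nseg(cell: Cell, nseg_map: dict) -> Cell:
    clone = Cell(
        cell.name, cell.morphology, capacitance=cell.capacitance,
        axial_resistivity=cell.axial_resistivity,
        initial_voltage=cell.initial_voltage, nseg_map=nseg_map,
    )
    clone.applications = list(cell.applications)
    return clone


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

class ThresholdDetector:
    """Upward threshold crossing with hysteresis.

    Emits the (linearly interpolated) crossing time at the first step where
    V_prev < theta <= V_now; does not re-arm until V falls below theta.
    """

    def __init__(self, threshold_mV: float, initial_v_mV: float):
        self.theta = float(threshold_mV)
        self.armed = initial_v_mV < self.theta

    def update(self, t0: float, t1: float, v0: float, v1: float):
        if self.armed and v0 < self.theta <= v1:
            self.armed = False
            frac = (self.theta - v0) / (v1 - v0) if v1 > v0 else 0.0
            return t0 + frac * (t1 - t0)
        if v1 < self.theta:
            self.armed = True
        return None


def detect_events(detectors, t0, t1, v0_values, v1_values) -> list[tuple[int, float]]:
    """Run a list of detectors over one step; returns (index, time) pairs."""
    out = []
    for i, det in enumerate(detectors):
        t = det.update(t0, t1, v0_values[i], v1_values[i])
        if t is not None:
            out.append((i, t))
    return out


# ---------------------------------------------------------------------------
# Runtime wrappers
# ---------------------------------------------------------------------------

@dataclass
class _SynRuntime:
    syn: object
    cell_idx: int
    seg: int
    gbarN_uS: float
    erev: float
    decay_d: float
    decay_r: float
    s_d: float = 0.0
    s_r: float = 0.0
    pending: list = field(default_factory=list)  # delivery times, sorted

    def conductance_uS(self) -> float:
        return max(self.gbarN_uS * (self.s_d - self.s_r), 0.0)


class _Engine:
    """One simulation run; see :func:`simulate`."""

    def __init__(self, sim: Simulation, method: str):
        self.sim = sim
        if method in ("backward_euler", "be"):
            self.theta = 1.0
        elif method in ("crank_nicolson", "cn"):
            self.theta = 0.5
        else:
            raise ValueError(f"unknown method {method!r}")
        self.method = method
        self.dt = sim.dt.magnitude_in("ms")
        self.duration = sim.duration.magnitude_in("ms")
        self.nsteps = int(round(self.duration / self.dt))
        self.times = np.arange(self.nsteps + 1) * self.dt

        self.cells = sim.cells
        self.cell_index = {c.name: i for i, c in enumerate(self.cells)}
        self.disc = [DiscretizedCell(c) for c in self.cells]
        self.V = [d.initial_voltage() for d in self.disc]

        # gate states at steady state of the initial voltage
        for d, v in zip(self.disc, self.V):
            for inst in d.instances.values():
                for gate in inst.gates:
                    inf, _ = gate_steady_state_and_tau(gate, v[inst.seg_idx])
                    inst.gate_state[gate.name] = np.asarray(inf, dtype=float)

        # stimuli
        self.cclamps = []   # (cell_idx, seg, stim)
        self.vclamps = []
        for stim in sim.stimuli:
            ci = self.cell_index[stim.cell.name]
            seg = self.disc[ci].seg_index(stim.location)
            if isinstance(stim, VoltageClampStep):
                self.vclamps.append((ci, seg, stim))
            else:
                self.cclamps.append((ci, seg, stim))

        # synapses
        self.dropped_events = 0
        self.synapses: list[_SynRuntime] = []
        self.syn_by_name: dict[str, _SynRuntime] = {}
        self.detectors = []  # (detector, cell_idx, seg, kind, payload)
        for syn in sim.synapses:
            psr = syn.template.psr
            ci = self.cell_index[syn.post_cell.name]
            seg = self.disc[ci].seg_index(syn.post_location)
            rt = _SynRuntime(
                syn=syn,
                cell_idx=ci,
                seg=seg,
                gbarN_uS=psr.gbar.magnitude_in("uS") * psr_normalisation(psr),
                erev=psr.erev.magnitude_in("mV"),
                decay_d=math.exp(-self.dt / psr.tau_decay.magnitude_in("ms")),
                decay_r=math.exp(-self.dt / psr.tau_rise.magnitude_in("ms")),
            )
            delay = syn.delay.magnitude_in("ms")
            if isinstance(syn.trigger, SpikeTimesTrigger):
                for t in syn.trigger.times:
                    self._enqueue(rt, t + delay)
            elif isinstance(syn.trigger, ThresholdTrigger):
                pci = self.cell_index[syn.trigger.cell.name]
                pseg = self.disc[pci].seg_index(syn.trigger.location)
                det = ThresholdDetector(
                    syn.trigger.threshold.magnitude_in("mV"),
                    self.V[pci][pseg],
                )
                self.detectors.append((det, pci, pseg, "synapse", (rt, delay)))
            self.synapses.append(rt)
            self.syn_by_name[syn.name] = rt

        # gap junctions
        self.gjs = []
        for gj in sim.gap_junctions:
            c1 = self.cell_index[gj.cell1.name]
            c2 = self.cell_index[gj.cell2.name]
            self.gjs.append((
                c1, self.disc[c1].seg_index(gj.loc1),
                c2, self.disc[c2].seg_index(gj.loc2),
                gj.conductance.magnitude_in("uS"),
            ))

        self.gap_iterations = 0
        self._setup_recorders()

    # -- events -----------------------------------------------------------
    def _fold_to_boundary(self, t: float) -> float:
        """Delivery times land on the next step boundary."""
        return math.ceil(t / self.dt - 1e-9) * self.dt

    def _enqueue(self, rt: _SynRuntime, t: float):
        td = self._fold_to_boundary(t)
        if td > self.duration + 1e-9:
            self.dropped_events += 1
            return
        rt.pending.append(td)
        rt.pending.sort()

    # -- recording --------------------------------------------------------
    def _setup_recorders(self):
        n = self.nsteps + 1
        self.recorders = []      # (req, array, sampler)
        self.event_recorders = []  # (req, list)
        for req in self.sim.recordings:
            if req.what == "Events":
                ci = self.cell_index[req.target.name]
                seg = self.disc[ci].seg_index(req.location)
                thr = (req.threshold.magnitude_in("mV")
                       if req.threshold is not None else 0.0)
                det = ThresholdDetector(thr, self.V[ci][seg])
                collected: list[float] = []
                self.detectors.append((det, ci, seg, "record", collected))
                self.event_recorders.append((req, collected))
                continue
            arr = np.empty(n)
            sampler = self._make_sampler(req)
            self.recorders.append((req, arr, sampler))

    def _make_sampler(self, req):
        what = req.what
        if what == "Voltage":
            ci = self.cell_index[req.target.name]
            seg = self.disc[ci].seg_index(req.location)
            return lambda t: self.V[ci][seg]
        if what in ("CurrentDensity", "ConductanceDensity"):
            ci = self.cell_index[req.target.name]
            d = self.disc[ci]
            seg = d.seg_index(req.location)
            inst = d.instances[req.channel.name]
            pos = int(np.nonzero(inst.seg_idx == seg)[0][0])

            def open_frac():
                f = 1.0
                for gate in inst.gates:
                    f *= inst.gate_state[gate.name][pos] ** gate.exponent
                return f

            if what == "ConductanceDensity":
                return lambda t: inst.g_dens_mS_cm2[pos] * open_frac()
            return lambda t: (
                inst.g_dens_mS_cm2[pos] * open_frac()
                * (self.V[ci][seg] - inst.erev_mV[pos]) * 1e-3
            )
        if what == "Current":
            target = req.target
            if isinstance(target, _CurrentClamp):
                return lambda t: float(np.asarray(target.current_nA(t)))
            if isinstance(target, VoltageClampStep):
                ci = self.cell_index[target.cell.name]
                seg = self.disc[ci].seg_index(target.location)
                gs = target.series_conductance_uS()
                return lambda t: (
                    gs * (target.command_mV(t) - self.V[ci][seg])
                    if target.active(t) else 0.0
                )
            rt = self.syn_by_name[target.name]
            return lambda t: rt.conductance_uS() * (
                self.V[rt.cell_idx][rt.seg] - rt.erev)
        if what == "Conductance":
            rt = self.syn_by_name[req.target.name]
            return lambda t: rt.conductance_uS() * 1e3  # uS -> nS
        raise ValueError(f"unhandled recordable {what!r}")

    def _sample(self, step: int, t: float):
        for _, arr, sampler in self.recorders:
            arr[step] = sampler(t)

    # -- one implicit step ------------------------------------------------
    def step(self, step_no: int):
        dt = self.dt
        theta = self.theta
        t0 = (step_no - 1) * dt
        t1 = step_no * dt
        t_stim = t1 if theta == 1.0 else t0 + 0.5 * dt

        V_old = [v.copy() for v in self.V]

        # 1. gating: Rush-Larsen at start-of-step voltage
        for d, v in zip(self.disc, V_old):
            for inst in d.instances.values():
                for gate in inst.gates:
                    inf, tau = gate_steady_state_and_tau(gate, v[inst.seg_idx])
                    x = inst.gate_state[gate.name]
                    inst.gate_state[gate.name] = inf + (x - inf) * np.exp(
                        -dt / tau)

        # 2. synapse states: analytic decay + boundary event delivery
        for rt in self.synapses:
            rt.s_d *= rt.decay_d
            rt.s_r *= rt.decay_r
            while rt.pending and rt.pending[0] <= t1 + 1e-9:
                rt.pending.pop(0)
                rt.s_d += 1.0
                rt.s_r += 1.0

        # 3. per-cell linear terms (independent of the gj iterate)
        G = []   # uS per segment, sums of conductances
        B = []   # nA per segment, g*e + injected currents
        for ci, d in enumerate(self.disc):
            g = np.zeros(d.n)
            b = np.zeros(d.n)
            for inst in d.instances.values():
                if inst.gates:
                    frac = np.ones(len(inst.seg_idx))
                    for gate in inst.gates:
                        frac *= inst.gate_state[gate.name] ** gate.exponent
                    gi = inst.g_max_uS * frac
                else:
                    gi = inst.g_max_uS
                np.add.at(g, inst.seg_idx, gi)
                np.add.at(b, inst.seg_idx, gi * inst.erev_mV)
            G.append(g)
            B.append(b)
        for ci, seg, stim in self.cclamps:
            B[ci][seg] += float(np.asarray(stim.current_nA(t_stim)))
        for ci, seg, stim in self.vclamps:
            if stim.active(t1):
                gs = stim.series_conductance_uS()
                G[ci][seg] += gs
                B[ci][seg] += gs * stim.command_mV(t_stim)
        for rt in self.synapses:
            gsyn = rt.conductance_uS()
            G[rt.cell_idx][rt.seg] += gsyn
            B[rt.cell_idx][rt.seg] += gsyn * rt.erev

        # 4. solve, iterating on gap-junction coupling if present
        n_iter = _GJ_MAX_ITER if self.gjs else 1
        V_guess = [v.copy() for v in V_old]
        for it in range(n_iter):
            V_new = []
            for ci, d in enumerate(self.disc):
                g_tot = G[ci].copy()
                b_tot = B[ci].copy()
                for (c1, s1, c2, s2, ggj) in self.gjs:
                    if ggj == 0.0:
                        continue
                    if c1 == ci:
                        g_tot[s1] += ggj
                        b_tot[s1] += ggj * V_guess[c2][s2]
                    if c2 == ci:
                        g_tot[s2] += ggj
                        b_tot[s2] += ggj * V_guess[c1][s1]
                V_new.append(self._solve_cell(d, V_old[ci], g_tot, b_tot))
            self.gap_iterations += 1 if self.gjs else 0
            if not self.gjs:
                V_guess = V_new
                break
            delta = max(
                float(np.max(np.abs(vn - vg)))
                for vn, vg in zip(V_new, V_guess)
            )
            V_guess = V_new
            if delta < _GJ_TOL_MV:
                break
        self.V = V_guess

        for v in self.V:
            if not np.all(np.isfinite(v)):
                raise NumericError(
                    f"solver diverged (non-finite voltage) at t={t1:.4f} ms"
                )

        # 5. event detection on the completed step
        for det, ci, seg, kind, payload in self.detectors:
            t_cross = det.update(t0, t1, V_old[ci][seg], self.V[ci][seg])
            if t_cross is None:
                continue
            if kind == "synapse":
                rt, delay = payload
                self._enqueue(rt, t_cross + delay)
            else:
                payload.append(t_cross)

    def _solve_cell(self, d: DiscretizedCell, v_old, g_lin, b) -> np.ndarray:
        """Theta-method solve of one cell's tree system (Hines O(N))."""
        dt = self.dt
        theta = self.theta
        n = d.n
        cdt = d.c_nF / dt
        ga = d.g_axial_uS
        parent = d.parent

        diag = cdt + theta * g_lin
        rhs = cdt * v_old + b
        if theta != 1.0:
            # explicit part: -(1-theta) * (G*v_old + A*v_old)
            ax = np.zeros(n)
            for i in range(1, n):
                p = parent[i]
                dv = v_old[i] - v_old[p]
                ax[i] += ga[i] * dv
                ax[p] -= ga[i] * dv
            rhs -= (1.0 - theta) * (g_lin * v_old + ax)

        a = theta * ga  # scaled axial conductances
        for i in range(1, n):
            diag[i] += a[i]
            diag[parent[i]] += a[i]

        # elimination, children into parents (reverse construction order)
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = a[i] / diag[i]
            diag[p] -= a[i] * f
            rhs[p] += f * rhs[i]
        v = np.empty(n)
        v[0] = rhs[0] / diag[0]
        for i in range(1, n):
            v[i] = (rhs[i] + a[i] * v[parent[i]]) / diag[i]
        return v

    # -- main loop --------------------------------------------------------
    def run(self) -> SimulationResults:
        self._sample(0, 0.0)
        for nstep in range(1, self.nsteps + 1):
            self.step(nstep)
            self._sample(nstep, nstep * self.dt)
        return self._collect()

    def _collect(self) -> SimulationResults:
        results = SimulationResults(metadata={
            "simulation": self.sim.name,
            "method": self.method,
            "dt_ms": self.dt,
            "duration_ms": self.duration,
            "steps": self.nsteps,
            "gap_junction_iterations": self.gap_iterations,
            "dropped_events": self.dropped_events,
            "seed": self.sim.seed,
        })
        units = {
            "Voltage": "mV", "Current": "nA", "CurrentDensity": "mA/cm2",
            "Conductance": "nS", "ConductanceDensity": "mS/cm2",
        }
        for req, arr, _ in self.recorders:
            results.traces.append(Trace(
                self.times, arr, units[req.what],
                tags=self._tags_for(req), name=req.name,
            ))
        for req, collected in self.event_recorders:
            results.events.append(EventSet(
                collected, tags=self._tags_for(req), name=req.name,
            ))
        return results

    def _tags_for(self, req) -> set[str]:
        tags = {req.what if req.what != "Events" else "Event"}
        tags |= set(req.user_tags)
        target = req.target
        if isinstance(target, Cell):
            tags.add(target.name)
            if req.location is not None:
                tags.add(f"loc:{req.location.section.id}")
            if req.channel is not None:
                tags.add(req.channel.name)
        elif isinstance(target, VoltageClampStep) or isinstance(
                target, _CurrentClamp):
            tags.add(target.name)
            tags.add(target.cell.name)
        else:  # synapse
            syn = target
            tags.add(syn.name)
            tags.add("SYNAPTIC")
            tags.add(f"POST:{syn.post_cell.name}")
            if syn.pre_cell is not None:
                tags.add(f"PRE:{syn.pre_cell.name}")
        return tags


def simulate(sim: Simulation, method: str = "backward_euler") -> SimulationResults:
    """Integrate a validated simulation graph; deterministic per (graph, dt)."""
    return _Engine(sim, method).run()
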