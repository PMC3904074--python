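"""Serialisation of the simulation object graph to a JSON document.

The document format (schema shipped in ``cablekit/schema/``) lets the CLI
run simulations described in plain text files. Quantities are written as
``"<value> <unit>"`` strings.
"""

from __future__ import annotations

import json
from pathlib import Path

from .channels import (
    GatedChannel,
    GateSpec,
    LeakChannel,
    channel_from_json,
    channel_to_json,
    hh_potassium,
    hh_sodium,
)
from .distribution import Applicator, Targeter
from .errors import ValidationError
from .model import (
    Cell,
    CurrentClampRamp,
    CurrentClampSine,
    CurrentClampStep,
    GapJunction,
    Simulation,
    SpikeTimesTrigger,
    Synapse,
    SynapseTemplate,
    ThresholdTrigger,
    VoltageClampStep,
)
from .morphology import Morphology, MorphLocation, build_soma_from_area, read_swc

__all__ = ["simulation_to_document", "simulation_from_document",
           "load_simulation", "save_simulation"]


def _q(quantity) -> str:
    return f"{quantity.magnitude:.12g} {quantity.unit_label}"


def _loc_doc(loc: MorphLocation) -> dict:
    return {"section": loc.section.id, "fraction": loc.fraction_along}


def _loc_from(cell: Cell, doc) -> MorphLocation:
    if doc is None:
        return cell.soma_location()
    return MorphLocation(cell.morphology[doc["section"]],
                         doc.get("fraction", 0.5))


def _morphology_doc(m: Morphology) -> dict:
    return {
        "name": m.name,
        "sections": [
            {
                "id": s.id,
                "proximal": list(map(float, s.proximal)),
                "distal": list(map(float, s.distal)),
                "proximal_radius": s.proximal_radius,
                "distal_radius": s.distal_radius,
                "region": s.region,
                "parent": s.parent.id if s.parent else None,
                "spherical": s.spherical,
            }
            for s in m
        ],
    }


def _morphology_from(doc) -> Morphology:
    if "swc" in doc:
        return read_swc(doc["swc"])
    if "builder" in doc:
        if doc["builder"] != "soma_area":
            raise ValidationError(f"unknown morphology builder {doc['builder']!r}")
        return build_soma_from_area(doc.get("area", "1000 um2"))
    m = Morphology(doc.get("name", "morphology"))
    for s in doc["sections"]:
        m.add_section(
            id=s["id"], proximal=s["proximal"], distal=s["distal"],
            proximal_radius=s["proximal_radius"],
            distal_radius=s["distal_radius"], region=s["region"],
            parent=s["parent"], spherical=s.get("spherical", False),
        )
    return m


def _targeter_doc(t: Targeter) -> dict:
    return {"kind": t.kind, "arg": t.arg, "priority": t.priority}


def _targeter_from(doc) -> Targeter:
    if doc is None or doc == "everywhere":
        return Targeter.everywhere()
    if isinstance(doc, str):
        raise ValidationError(f"unknown targeter {doc!r}")
    kind = doc["kind"]
    defaults = {"everywhere": 1, "region": 2, "section": 3}
    return Targeter(kind, doc.get("arg"),
                    doc.get("priority", defaults[kind]))


def simulation_to_document(sim: Simulation) -> dict:
    cells = []
    for cell in sim.cells:
        cells.append({
            "name": cell.name,
            "morphology": _morphology_doc(cell.morphology),
            "capacitance": _q(cell.capacitance),
            "axial_resistivity": _q(cell.axial_resistivity),
            "initial_voltage": (None if cell.initial_voltage is None
                                else _q(cell.initial_voltage)),
            "nseg_map": cell.nseg_map,
            "channels": [
                {
                    "channel": channel_to_json(app.channel),
                    "targeter": _targeter_doc(app.targeter),
                    "overrides": {
                        k: (_q(v) if hasattr(v, "unit_label") else v)
                        for k, v in app.applicator.overrides.items()
                    },
                    "multipliers": dict(app.applicator.multipliers),
                }
                for app in cell.applications
            ],
        })
    stimuli = []
    for stim in sim.stimuli:
        d = {"name": stim.name, "kind": stim.kind, "cell": stim.cell.name,
             "location": _loc_doc(stim.location)}
        if isinstance(stim, CurrentClampStep):
            d.update(amp=_q(stim.amp), delay=_q(stim.delay),
                     duration=None if stim.duration is None else _q(stim.duration))
        elif isinstance(stim, CurrentClampRamp):
            d.update(amp0=_q(stim.amp0), amp1=_q(stim.amp1),
                     delay=_q(stim.delay), duration=_q(stim.duration))
        elif isinstance(stim, CurrentClampSine):
            d.update(amp=_q(stim.amp), frequency=_q(stim.frequency),
                     delay=_q(stim.delay), phase=stim.phase,
                     duration=None if stim.duration is None else _q(stim.duration))
        elif isinstance(stim, VoltageClampStep):
            d.update(voltage=_q(stim.voltage), delay=_q(stim.delay),
                     duration=None if stim.duration is None else _q(stim.duration),
                     series_resistance=_q(stim.series_resistance))
        stimuli.append(d)
    synapses = []
    for syn in sim.synapses:
        psr = syn.template.psr
        d = {
            "name": syn.name,
            "template": {
                "name": syn.template.name,
                "tau_rise": _q(psr.tau_rise), "tau_decay": _q(psr.tau_decay),
                "gbar": _q(psr.gbar), "erev": _q(psr.erev),
            },
            "post_cell": syn.post_cell.name,
            "post_location": _loc_doc(syn.post_location),
            "delay": _q(syn.delay),
        }
        if isinstance(syn.trigger, SpikeTimesTrigger):
            d["trigger"] = {"kind": "times", "times": syn.trigger.times}
        else:
            d["trigger"] = {
                "kind": "threshold",
                "cell": syn.trigger.cell.name,
                "location": _loc_doc(syn.trigger.location),
                "threshold": _q(syn.trigger.threshold),
            }
        synapses.append(d)
    gap_junctions = [
        {
            "name": gj.name, "conductance": _q(gj.conductance),
            "cell1": gj.cell1.name, "loc1": _loc_doc(gj.loc1),
            "cell2": gj.cell2.name, "loc2": _loc_doc(gj.loc2),
        }
        for gj in sim.gap_junctions
    ]
    recordings = []
    for req in sim.recordings:
        d = {"name": req.name, "what": req.what,
             "user_tags": sorted(req.user_tags)}
        target = req.target
        d["target"] = target.name
        if req.location is not None:
            d["location"] = _loc_doc(req.location)
        if req.channel is not None:
            d["channel"] = req.channel.name
        if req.threshold is not None:
            d["threshold"] = _q(req.threshold)
        recordings.append(d)
    return {
        "format": "cablekit-simulation/1",
        "name": sim.name,
        "duration": _q(sim.duration),
        "dt": _q(sim.dt),
        "seed": sim.seed,
        "cells": cells,
        "stimuli": stimuli,
        "synapses": synapses,
        "gap_junctions": gap_junctions,
        "recordings": recordings,
    }


def simulation_from_document(doc: dict) -> Simulation:
    if doc.get("format") != "cablekit-simulation/1":
        raise ValidationError("not a cablekit simulation document")
    sim = Simulation(doc.get("name", "simulation"),
                     duration=doc["duration"], dt=doc["dt"],
                     seed=doc.get("seed", 0))
    for cdoc in doc["cells"]:
        cell = sim.create_cell(
            cdoc["name"], _morphology_from(cdoc["morphology"]),
            capacitance=cdoc.get("capacitance", "1.0 uF/cm2"),
            axial_resistivity=cdoc.get("axial_resistivity", "100 Ohm*cm"),
            initial_voltage=cdoc.get("initial_voltage"),
            nseg_map={k: int(v) for k, v in cdoc.get("nseg_map", {}).items()},
        )
        for chdoc in cdoc.get("channels", []):
            chl = channel_from_json(chdoc["channel"])
            cell.apply_channel(
                chl,
                applicator=Applicator(chdoc.get("overrides") or {},
                                      chdoc.get("multipliers") or {}),
                targeter=_targeter_from(chdoc.get("targeter")),
            )
    cells = {c.name: c for c in sim.cells}
    stim_by_name = {}
    for sdoc in doc.get("stimuli", []):
        cell = cells[sdoc["cell"]]
        loc = _loc_from(cell, sdoc.get("location"))
        kind = sdoc["kind"]
        common = dict(cell=cell, location=loc, name=sdoc["name"])
        if kind == "step":
            stim = sim.create_currentclamp(
                protocol="step", amp=sdoc["amp"], delay=sdoc.get("delay", "0 ms"),
                duration=sdoc.get("duration"), **common)
        elif kind == "ramp":
            stim = sim.create_currentclamp(
                protocol="ramp", amp0=sdoc["amp0"], amp1=sdoc["amp1"],
                delay=sdoc.get("delay", "0 ms"),
                duration=sdoc["duration"], **common)
        elif kind == "sine":
            stim = sim.create_currentclamp(
                protocol="sine", amp=sdoc["amp"], frequency=sdoc["frequency"],
                delay=sdoc.get("delay", "0 ms"), duration=sdoc.get("duration"),
                phase=sdoc.get("phase", 0.0), **common)
        elif kind == "vclamp":
            stim = sim.create_voltageclamp(
                voltage=sdoc["voltage"], delay=sdoc.get("delay", "0 ms"),
                duration=sdoc.get("duration"),
                series_resistance=sdoc.get("series_resistance", "1 MOhm"),
                **common)
        else:
            raise ValidationError(f"unknown stimulus kind {kind!r}")
        stim_by_name[stim.name] = stim
    syn_by_name = {}
    for sdoc in doc.get("synapses", []):
        tdoc = sdoc["template"]
        tmpl = SynapseTemplate.build(
            tdoc.get("name", "psr"), tdoc["tau_rise"], tdoc["tau_decay"],
            tdoc["gbar"], tdoc["erev"])
        trg_doc = sdoc["trigger"]
        if trg_doc["kind"] == "times":
            trigger = SpikeTimesTrigger(trg_doc["times"])
        else:
            pre = cells[trg_doc["cell"]]
            trigger = ThresholdTrigger(
                pre, _loc_from(pre, trg_doc.get("location")),
                trg_doc.get("threshold", "0 mV"))
        post = cells[sdoc["post_cell"]]
        syn = sim.create_synapse(
            tmpl, post_cell=post,
            post_location=_loc_from(post, sdoc.get("post_location")),
            trigger=trigger, name=sdoc["name"], delay=sdoc.get("delay"))
        syn_by_name[syn.name] = syn
    for gdoc in doc.get("gap_junctions", []):
        c1, c2 = cells[gdoc["cell1"]], cells[gdoc["cell2"]]
        sim.create_gapjunction(
            gdoc["conductance"], cell1=c1, loc1=_loc_from(c1, gdoc.get("loc1")),
            cell2=c2, loc2=_loc_from(c2, gdoc.get("loc2")), name=gdoc["name"])
    for rdoc in doc.get("recordings", []):
        tname = rdoc["target"]
        if tname in cells:
            target = cells[tname]
            loc = _loc_from(target, rdoc.get("location"))
            channel = None
            if rdoc.get("channel"):
                for app in target.applications:
                    if app.channel.name == rdoc["channel"]:
                        channel = app.channel
                        break
            sim.record(target, what=rdoc["what"], location=loc,
                       channel=channel, threshold=rdoc.get("threshold"),
                       user_tags=rdoc.get("user_tags", ()),
                       name=rdoc.get("name"))
        elif tname in stim_by_name:
            sim.record(stim_by_name[tname], what=rdoc["what"],
                       user_tags=rdoc.get("user_tags", ()),
                       name=rdoc.get("name"))
        elif tname in syn_by_name:
            sim.record(syn_by_name[tname], what=rdoc["what"],
                       user_tags=rdoc.get("user_tags", ()),
                       name=rdoc.get("name"))
        else:
            raise ValidationError(
                f"recording target {tname!r} not found in document")
    return sim


def save_simulation(sim: Simulation, path) -> None:
    Path(str(path)).write_text(
        json.dumps(simulation_to_document(sim), indent=2))


def load_simulation(path) -> Simulation:
    return simulation_from_document(json.loads(Path(str(path)).read_text()))
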