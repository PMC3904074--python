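{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "cablekit simulation document",
  "type": "object",
  "required": ["format", "duration", "dt", "cells"],
  "properties": {
    "format": {"const": "cablekit-simulation/1"},
    "name": {"type": "string"},
    "duration": {"type": "string", "description": "quantity string, e.g. '200 ms'"},
    "dt": {"type": "string"},
    "seed": {"type": "integer"},
    "cells": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "morphology"],
        "properties": {
          "name": {"type": "string"},
          "morphology": {
            "type": "object",
            "description": "one of: {builder: 'soma_area', area}, {swc: path}, {sections: [...]}"
          },
          "capacitance": {"type": "string"},
          "axial_resistivity": {"type": "string"},
          "initial_voltage": {"type": ["string", "null"]},
          "nseg_map": {"type": "object"},
          "channels": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["channel"],
              "properties": {
                "channel": {"type": "object"},
                "targeter": {"type": ["object", "string", "null"]},
                "overrides": {"type": "object"},
                "multipliers": {"type": "object"}
              }
            }
          }
        }
      }
    },
    "stimuli": {"type": "array"},
    "synapses": {"type": "array"},
    "gap_junctions": {"type": "array"},
    "recordings": {"type": "array"}
  }
}
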