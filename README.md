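# cablekit

A self-contained Python toolbox for building and running simulations of
small networks of multicompartmental, conductance-based model neurons. An
entire in-silico experiment — morphologies, channels, channel
distributions, stimuli, synapses, gap junctions, recording, analysis and
plotting — is declared in one short script against a high-level object
model, then integrated by an internal branched-cable solver (no external
simulator required).

Features:

- **Units everywhere.** All parameters and results carry explicit physical
  units (`0.3 mS/cm2`, `300 MOhm`, ...) over a fixed, auditable unit
  whitelist; conversions are exact (SI value is stored once).
- **Morphologies** as trees of conical-frustum sections with region
  labels; SWC import/export; programmatic builders.
- **Channels**: leak, Hodgkin-Huxley-style gated channels defined by
  five-parameter alpha/beta rate equations (classic squid-axon Na/K ship as
  library fixtures), and double-exponential postsynaptic receptors with
  peak-normalised conductance.
- **Channel distribution notation**: `(Channel, Applicator, Targeter)`
  triplets with priority-based resolution (section > region > everywhere;
  equal-priority conflicts are hard errors).
- **Solver**: implicit theta-method (backward Euler default,
  Crank-Nicolson optional) on the Hines-ordered segment tree, Rush-Larsen
  gating updates, analytic synapse integration, fixed-point gap-junction
  coupling.
- **Tag-based results**: every recorded trace carries a set of tags; a
  small query language (`ALL{...}`, `ANY{...}`, `AND`, `OR`, `NOT`,
  parentheses) selects traces for analysis and plotting.
- **TagViewer** stacked-axis figures and **HTML/Markdown simulation
  summaries** (cell tables, morphology projections, channel kinetics
  curves, resolved distributions).
- **Scenario harness**: human/machine-readable scenario files with
  parameter sweeps and hand-calculated expectation tables verify the
  solver end to end; a fixture generator emits scenarios with closed-form
  expectations.

## Quick start

```python
from cablekit import (Simulation, LeakChannel, build_soma_from_area,
                      spike_count)
from cablekit.reporting import tagviewer_render, summarize_simulation

sim = Simulation("example", duration="200 ms")
cell = sim.create_cell("cell1", build_soma_from_area("1000 um2"))
leak = LeakChannel("lk", gbar="0.3 mS/cm2", erev="-51 mV")
cell.apply_channel(leak)
clamp = sim.create_currentclamp(cell, amp="100 pA", delay="100 ms",
                                duration="50 ms")
sim.record(cell, "Voltage")
sim.record(cell, "CurrentDensity", channel=leak)
sim.record(clamp, "Current")

results = sim.run()                      # 3 tagged traces
voltages = results.filter("ALL{Voltage}")
tagviewer_render(results, out_path="traces.svg")
summarize_simulation(sim, results, out_path="summary.html")
```

## Command line

A `cablekit` console script wraps the common operations:

```bash
cablekit run sim.json --out results.json     # run a JSON simulation document
cablekit query results.json "ALL{Voltage}"   # select traces by tag query
cablekit plot results.json -s "ALL{Voltage}" --out fig.svg
cablekit summarize sim.json --out summary.html
cablekit make-scenarios scenarios/ --seed 0  # emit built-in fixtures
cablekit run-scenarios scenarios/            # verify; nonzero exit on failure
```

The simulation document schema ships in `src/cablekit/schema/`.

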