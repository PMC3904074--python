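"""Scenario files: simulator verification against hand-calculated tables.

A scenario is a human- and machine-readable text file describing a small
simulation with ``<PARAM>`` placeholders, the units of every parameter and
recorded symbol, a table of parameter sweeps and a table of expected
values whose column headers use slice notation, e.g. ``$V[95:100].mean``
(window in ms, half-open, statistic suffix ``.mean``/``.max``/``.min``).

File grammar (``#`` starts a comment; tables are pipe-delimited)::

    SCENARIO <name>
    DESCRIPTION
        DURATION 200
        DT 0.025
        CELL cell1 AREA <A> CAPACITANCE <C> INITIAL <VS>
        CHANNEL leak lk ON cell1 GBAR <GLK> EREV <EREV>
        STIMULUS step stim1 INTO cell1 AMP <I> FROM 0
        ...
    END
    UNITS
        | A | um2 |
        | $V | mV |
    RECORD
        | $V | cell1 | Voltage |
    VALUES
        | A | C | VS | GLK | EREV | I |
        | 1000 | 1 | -51 | 0.3 | -51 | 100 |
    EXPECTED
        | A | C | VS | GLK | EREV | I | $V[95:100].mean |
        | 1000 | 1 | -51 | 0.3 | -51 | 100 | -17.6667 |
    TOLERANCE 0.01

Description statements: DURATION/DT (ms); CELL with AREA/CAPACITANCE/
INITIAL; CHANNEL of kind ``leak``/``hh_na``/``hh_k`` with GBAR/EREV;
STIMULUS of kind ``step`` (AMP FROM [FOR]) or ``ramp`` (AMP0 AMP1 FROM
FOR); VCLAMP (TO FROM [FOR]); GAPJUNCTION (BETWEEN c1 c2 G); SYNAPSE
(ONTO cell GBAR EREV TAU_RISE TAU_DECAY AT t1,t2,... [DELAY]). Literal
numbers use canonical units: ms for times, um2/uF-per-cm2/mV/mS-per-cm2/
pA/nS as appropriate per keyword; placeholders take their unit from the
UNITS block.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .channels import LeakChannel, hh_potassium, hh_sodium
from .errors import ComparisonError, ScenarioError
from .model import Simulation, SpikeTimesTrigger, SynapseTemplate
from .morphology import build_soma_from_area
from .traces import window_stat
from .units import Quantity

__all__ = [
    "Scenario",
    "ComparisonReport",
    "parse_scenario",
    "write_scenario",
    "run_scenario",
    "generate_fixture_scenarios",
    "compare_backends",
]

#: absolute comparison floor, in the declared unit of each symbol
ABS_FLOOR = 0.01

_PLACEHOLDER_RE = re.compile(r"<([A-Za-z_][A-Za-z0-9_]*)>")
_COLUMN_RE = re.compile(
    r"^\$([A-Za-z_][A-Za-z0-9_]*)\[([0-9.eE+-]+):([0-9.eE+-]+)\]"
    r"(?:\.(mean|max|min))?$"
)

# canonical units for literal numbers per description keyword
_KEYWORD_UNITS = {
    "AREA": "um2", "CAPACITANCE": "uF/cm2", "INITIAL": "mV",
    "GBAR": "mS/cm2", "EREV": "mV", "AMP": "pA", "AMP0": "pA", "AMP1": "pA",
    "FROM": "ms", "FOR": "ms", "TO": "mV", "G": "nS",
    "TAU_RISE": "ms", "TAU_DECAY": "ms", "DELAY": "ms",
    "DURATION": "ms", "DT": "ms",
}


@dataclass
class ExpectedColumn:
    symbol: str
    t0: float
    t1: float
    stat: str  # mean | max | min

    @property
    def header(self) -> str:
        return f"${self.symbol}[{self.t0:g}:{self.t1:g}].{self.stat}"


@dataclass
class Scenario:
    name: str
    description_lines: list[str]
    units: dict[str, str]                      # PARAM or $SYM -> unit string
    records: dict[str, tuple[str, str]]        # symbol -> (target, modality)
    parameter_names: list[str]
    parameter_sets: list[dict[str, float]]
    expected_columns: list[ExpectedColumn]
    expected: list[dict[str, float]]           # one per parameter set
    tolerance: float = 0.01
    source: str = "<memory>"

    def placeholders(self) -> set[str]:
        found: set[str] = set()
        for line in self.description_lines:
            found |= set(_PLACEHOLDER_RE.findall(line))
        return found


@dataclass
class CellResult:
    """One expected-table cell compared against the simulation."""

    set_index: int
    parameters: dict[str, float]
    column: str
    expected: float
    observed: Optional[float]
    error: float
    passed: bool
    note: str = ""


@dataclass
class ComparisonReport:
    scenario: str
    cells: list[CellResult] = field(default_factory=list)
    tolerance: float = 0.01

    @property
    def overall_pass(self) -> bool:
        return all(c.passed for c in self.cells)

    def to_markdown(self) -> str:
        lines = [
            f"## Scenario {self.scenario} "
            f"({'PASS' if self.overall_pass else 'FAIL'}, "
            f"tolerance {self.tolerance:g})",
            "",
            "| set | column | expected | observed | error | pass |",
            "|---|---|---|---|---|---|",
        ]
        for c in self.cells:
            obs = "-" if c.observed is None else f"{c.observed:.6g}"
            lines.append(
                f"| {c.set_index} | {c.column} | {c.expected:.6g} | {obs} "
                f"| {c.error:.3g} | {'yes' if c.passed else 'NO'} "
                f"{c.note} |"
            )
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "scenario": self.scenario,
            "tolerance": self.tolerance,
            "overall_pass": self.overall_pass,
            "cells": [
                {
                    "set": c.set_index, "column": c.column,
                    "expected": c.expected, "observed": c.observed,
                    "error": c.error, "pass": c.passed, "note": c.note,
                }
                for c in self.cells
            ],
        }


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _strip(line: str) -> str:
    return line.split("#", 1)[0].rstrip()


def _table_row(line: str, path, lineno) -> list[str]:
    body = line.strip()
    if not (body.startswith("|") and body.endswith("|")):
        raise ScenarioError(
            f"{path}:{lineno}: table rows must be pipe-delimited: {line!r}"
        )
    return [c.strip() for c in body[1:-1].split("|")]


def parse_scenario(path) -> Scenario:
    """Parse and cross-check a scenario file; errors carry line numbers."""
    text = Path(str(path)).read_text()
    lines = text.splitlines()
    name = None
    tolerance = 0.01
    description: list[str] = []
    units: dict[str, str] = {}
    records: dict[str, tuple[str, str]] = {}
    value_header: list[str] = []
    value_rows: list[tuple[int, list[str]]] = []
    expected_header: list[str] = []
    expected_rows: list[tuple[int, list[str]]] = []

    block = None
    for lineno, raw in enumerate(lines, start=1):
        line = _strip(raw)
        if not line.strip():
            continue
        word = line.strip().split()[0]
        if word == "SCENARIO":
            name = line.strip()[len("SCENARIO"):].strip()
            block = None
            continue
        if word == "TOLERANCE":
            try:
                tolerance = float(line.strip().split()[1])
            except (IndexError, ValueError):
                raise ScenarioError(f"{path}:{lineno}: malformed TOLERANCE")
            block = None
            continue
        if word in ("DESCRIPTION", "UNITS", "RECORD", "VALUES", "EXPECTED"):
            block = word
            continue
        if word == "END":
            block = None
            continue
        if block == "DESCRIPTION":
            description.append(line.strip())
        elif block == "UNITS":
            cells = _table_row(line, path, lineno)
            if len(cells) != 2:
                raise ScenarioError(
                    f"{path}:{lineno}: UNITS rows need 2 columns"
                )
            units[cells[0]] = cells[1]
        elif block == "RECORD":
            cells = _table_row(line, path, lineno)
            if len(cells) != 3:
                raise ScenarioError(
                    f"{path}:{lineno}: RECORD rows need 3 columns "
                    "($sym | target | modality)"
                )
            sym = cells[0]
            if not sym.startswith("$"):
                raise ScenarioError(
                    f"{path}:{lineno}: record symbol must start with '$'"
                )
            records[sym[1:]] = (cells[1], cells[2])
        elif block == "VALUES":
            cells = _table_row(line, path, lineno)
            if not value_header:
                value_header = cells
            else:
                value_rows.append((lineno, cells))
        elif block == "EXPECTED":
            cells = _table_row(line, path, lineno)
            if not expected_header:
                expected_header = cells
            else:
                expected_rows.append((lineno, cells))
        else:
            raise ScenarioError(
                f"{path}:{lineno}: statement outside any block: {line!r}"
            )

    if name is None:
        raise ScenarioError(f"{path}: missing SCENARIO header")
    if not value_header:
        raise ScenarioError(f"{path}: missing VALUES block")
    if not expected_header:
        raise ScenarioError(f"{path}: missing EXPECTED block")

    # expected header: parameter columns first, then slice columns
    exp_param_cols: list[str] = []
    expected_columns: list[ExpectedColumn] = []
    for col in expected_header:
        if col.startswith("$"):
            m = _COLUMN_RE.match(col)
            if not m:
                raise ScenarioError(
                    f"{path}: malformed slice column {col!r} in EXPECTED "
                    "header"
                )
            sym, t0, t1, stat = m.groups()
            expected_columns.append(
                ExpectedColumn(sym, float(t0), float(t1), stat or "mean")
            )
        else:
            if expected_columns:
                raise ScenarioError(
                    f"{path}: parameter column {col!r} after slice columns"
                )
            exp_param_cols.append(col)

    parameter_sets = []
    for lineno, cells in value_rows:
        if len(cells) != len(value_header):
            raise ScenarioError(
                f"{path}:{lineno}: VALUES row has {len(cells)} cells, "
                f"header has {len(value_header)}"
            )
        try:
            parameter_sets.append(
                {k: float(v) for k, v in zip(value_header, cells)}
            )
        except ValueError as exc:
            raise ScenarioError(f"{path}:{lineno}: {exc}") from None

    if len(expected_rows) != len(parameter_sets):
        raise ScenarioError(
            f"{path}: EXPECTED has {len(expected_rows)} rows but VALUES has "
            f"{len(parameter_sets)} parameter sets"
        )
    expected = []
    for (lineno, cells), pset in zip(expected_rows, parameter_sets):
        if len(cells) != len(expected_header):
            raise ScenarioError(
                f"{path}:{lineno}: EXPECTED row width mismatch"
            )
        for col, cell in zip(exp_param_cols, cells):
            if col not in pset or float(cell) != pset[col]:
                raise ScenarioError(
                    f"{path}:{lineno}: EXPECTED parameter column {col!r} "
                    f"does not match the VALUES row ({cell!r} vs "
                    f"{pset.get(col)!r})"
                )
        row = {}
        for ecol, cell in zip(expected_columns,
                              cells[len(exp_param_cols):]):
            try:
                row[ecol.header] = float(cell)
            except ValueError:
                raise ScenarioError(
                    f"{path}:{lineno}: non-numeric expected value {cell!r}"
                ) from None
        expected.append(row)

    s = Scenario(
        name=name, description_lines=description, units=units,
        records=records, parameter_names=value_header,
        parameter_sets=parameter_sets, expected_columns=expected_columns,
        expected=expected, tolerance=tolerance, source=str(path),
    )
    _cross_check(s, path)
    return s


def _cross_check(s: Scenario, path) -> None:
    placeholders = s.placeholders()
    for p in placeholders:
        if p not in s.units:
            raise ScenarioError(
                f"{path}: placeholder <{p}> has no entry in UNITS"
            )
        if p not in s.parameter_names:
            raise ScenarioError(
                f"{path}: placeholder <{p}> missing from VALUES header"
            )
    for p in s.parameter_names:
        if p not in placeholders:
            raise ScenarioError(
                f"{path}: VALUES column {p!r} is not used as a placeholder"
            )
    for ecol in s.expected_columns:
        if ecol.symbol not in s.records:
            raise ScenarioError(
                f"{path}: expected column uses ${ecol.symbol} which is not "
                "declared in RECORD"
            )
        if ecol.t0 >= ecol.t1:
            raise ScenarioError(
                f"{path}: malformed slice [{ecol.t0}:{ecol.t1}]"
            )
    for sym in s.records:
        if f"${sym}" not in s.units:
            raise ScenarioError(
                f"{path}: recorded symbol ${sym} has no entry in UNITS"
            )


def write_scenario(s: Scenario, path) -> None:
    """Serialise a Scenario back to its file format."""
    out = [f"SCENARIO {s.name}", "", "DESCRIPTION"]
    out += [f"    {line}" for line in s.description_lines]
    out += ["END", "", "UNITS"]
    for k, v in s.units.items():
        out.append(f"    | {k} | {v} |")
    out += ["", "RECORD"]
    for sym, (target, modality) in s.records.items():
        out.append(f"    | ${sym} | {target} | {modality} |")
    out += ["", "VALUES"]
    out.append("    | " + " | ".join(s.parameter_names) + " |")
    for pset in s.parameter_sets:
        out.append(
            "    | " + " | ".join(f"{pset[k]:g}" for k in s.parameter_names)
            + " |"
        )
    out += ["", "EXPECTED"]
    headers = list(s.parameter_names) + [c.header for c in s.expected_columns]
    out.append("    | " + " | ".join(headers) + " |")
    for pset, row in zip(s.parameter_sets, s.expected):
        cells = [f"{pset[k]:g}" for k in s.parameter_names]
        cells += [f"{row[c.header]:.10g}" for c in s.expected_columns]
        out.append("    | " + " | ".join(cells) + " |")
    out += ["", f"TOLERANCE {s.tolerance:g}", ""]
    Path(str(path)).write_text("\n".join(out))


# ---------------------------------------------------------------------------
# Building and running simulations from scenarios
# ---------------------------------------------------------------------------

def _substitute(token: str, s: Scenario, values: dict[str, float],
                keyword: str) -> Quantity:
    m = _PLACEHOLDER_RE.fullmatch(token)
    if m:
        pname = m.group(1)
        return Quantity(values[pname], s.units[pname])
    try:
        v = float(token)
    except ValueError:
        raise ScenarioError(
            f"scenario {s.name!r}: cannot interpret {token!r} for "
            f"{keyword}"
        ) from None
    return Quantity(v, _KEYWORD_UNITS[keyword])


def _kwargs_of(tokens: list[str]) -> dict[str, str]:
    """Parse trailing 'KEY value KEY value ...' pairs."""
    if len(tokens) % 2 != 0:
        raise ScenarioError(f"unbalanced key/value tokens: {tokens!r}")
    return {tokens[i]: tokens[i + 1] for i in range(0, len(tokens), 2)}


def build_simulation(s: Scenario, values: dict[str, float],
                     dt_override: Optional[float] = None) -> tuple[Simulation, dict]:
    """Instantiate the scenario's simulation for one parameter set.

    Returns (simulation, symbol -> recording-request name).
    """
    duration = Quantity(200.0, "ms")
    dt = Quantity(0.025, "ms")
    statements = []
    for line in s.description_lines:
        tokens = line.split()
        if not tokens:
            continue
        if tokens[0] == "DURATION":
            duration = _substitute(tokens[1], s, values, "DURATION")
        elif tokens[0] == "DT":
            dt = _substitute(tokens[1], s, values, "DT")
        else:
            statements.append(tokens)
    if dt_override is not None:
        dt = Quantity(dt_override, "ms")

    sim = Simulation(s.name, duration=duration, dt=dt)
    cells: dict[str, object] = {}
    named: dict[str, object] = {}

    def q(tok, kw):
        return _substitute(tok, s, values, kw)

    for tokens in statements:
        kind = tokens[0]
        if kind == "CELL":
            cname = tokens[1]
            kw = _kwargs_of(tokens[2:])
            cell = sim.create_cell(
                cname,
                build_soma_from_area(q(kw["AREA"], "AREA")),
                capacitance=q(kw["CAPACITANCE"], "CAPACITANCE"),
                initial_voltage=(q(kw["INITIAL"], "INITIAL")
                                 if "INITIAL" in kw else None),
            )
            cells[cname] = cell
        elif kind == "CHANNEL":
            chkind, chname = tokens[1], tokens[2]
            if tokens[3] != "ON":
                raise ScenarioError(
                    f"scenario {s.name!r}: CHANNEL syntax: CHANNEL <kind> "
                    "<name> ON <cell> ..."
                )
            cell = cells[tokens[4]]
            kw = _kwargs_of(tokens[5:])
            if chkind == "leak":
                chl = LeakChannel(chname, q(kw["GBAR"], "GBAR"),
                                  q(kw["EREV"], "EREV"))
            elif chkind == "hh_na":
                chl = hh_sodium(chname, **_opt_ge(kw, q))
            elif chkind == "hh_k":
                chl = hh_potassium(chname, **_opt_ge(kw, q))
            else:
                raise ScenarioError(
                    f"scenario {s.name!r}: unknown channel kind {chkind!r}"
                )
            cell.apply_channel(chl)
        elif kind == "STIMULUS":
            proto, sname = tokens[1], tokens[2]
            if tokens[3] != "INTO":
                raise ScenarioError(
                    f"scenario {s.name!r}: STIMULUS syntax error"
                )
            cell = cells[tokens[4]]
            kw = _kwargs_of(tokens[5:])
            if proto == "step":
                stim = sim.create_currentclamp(
                    cell, protocol="step", name=sname,
                    amp=q(kw["AMP"], "AMP"),
                    delay=q(kw.get("FROM", "0"), "FROM"),
                    duration=(q(kw["FOR"], "FOR") if "FOR" in kw else None),
                )
            elif proto == "ramp":
                stim = sim.create_currentclamp(
                    cell, protocol="ramp", name=sname,
                    amp0=q(kw.get("AMP0", "0"), "AMP0"),
                    amp1=q(kw["AMP1"], "AMP1"),
                    delay=q(kw.get("FROM", "0"), "FROM"),
                    duration=q(kw["FOR"], "FOR"),
                )
            else:
                raise ScenarioError(
                    f"scenario {s.name!r}: unknown stimulus kind {proto!r}"
                )
            named[sname] = stim
        elif kind == "VCLAMP":
            sname = tokens[1]
            cell = cells[tokens[3]]
            kw = _kwargs_of(tokens[4:])
            stim = sim.create_voltageclamp(
                cell, name=sname, voltage=q(kw["TO"], "TO"),
                delay=q(kw.get("FROM", "0"), "FROM"),
                duration=(q(kw["FOR"], "FOR") if "FOR" in kw else None),
            )
            named[sname] = stim
        elif kind == "GAPJUNCTION":
            gname = tokens[1]
            c1, c2 = cells[tokens[3]], cells[tokens[4]]
            kw = _kwargs_of(tokens[5:])
            named[gname] = sim.create_gapjunction(
                q(kw["G"], "G"), cell1=c1, cell2=c2, name=gname)
        elif kind == "SYNAPSE":
            sname = tokens[1]
            cell = cells[tokens[3]]
            kw = _kwargs_of(tokens[4:])
            psr_gbar = q(kw["GBAR"], "G")  # synaptic gbar in nS
            tmpl = SynapseTemplate.build(
                f"{sname}_tmpl", q(kw["TAU_RISE"], "TAU_RISE"),
                q(kw["TAU_DECAY"], "TAU_DECAY"), psr_gbar,
                q(kw["EREV"], "EREV"))
            times = [float(t) for t in kw["AT"].split(",")]
            named[sname] = sim.create_synapse(
                tmpl, post_cell=cell, trigger=SpikeTimesTrigger(times),
                name=sname,
                delay=(q(kw["DELAY"], "DELAY") if "DELAY" in kw else None),
            )
        else:
            raise ScenarioError(
                f"scenario {s.name!r}: unknown statement {kind!r}"
            )

    symbol_to_rec: dict[str, str] = {}
    for sym, (target_name, modality) in s.records.items():
        if target_name in cells:
            req = sim.record(cells[target_name], what=modality,
                             user_tags={f"sym:{sym}"})
        elif target_name in named:
            req = sim.record(named[target_name], what=modality,
                             user_tags={f"sym:{sym}"})
        else:
            raise ScenarioError(
                f"scenario {s.name!r}: record target {target_name!r} not "
                "declared in the description"
            )
        symbol_to_rec[sym] = req.name
    return sim, symbol_to_rec


def run_scenario(s: Scenario, backend_config: Optional[dict] = None) -> ComparisonReport:
    """Run every parameter set and compare recorded values to the table.

    ``backend_config`` may carry ``method`` (solver scheme) and ``dt``
    (ms, overriding the scenario's DT). A failing simulation marks all of
    that row's cells failed and the run continues.
    """
    cfg = backend_config or {}
    report = ComparisonReport(scenario=s.name, tolerance=s.tolerance)
    for i, (pset, exp_row) in enumerate(zip(s.parameter_sets, s.expected)):
        try:
            sim, sym_rec = build_simulation(s, pset, dt_override=cfg.get("dt"))
            results = sim.run(method=cfg.get("method", "backward_euler"))
        except Exception as exc:  # recorded, not raised
            for ecol in s.expected_columns:
                report.cells.append(CellResult(
                    set_index=i, parameters=pset, column=ecol.header,
                    expected=exp_row[ecol.header], observed=None,
                    error=math.inf, passed=False,
                    note=f"simulation failed: {exc}",
                ))
            continue
        by_name = {tr.name: tr for tr in results.traces}
        for ecol in s.expected_columns:
            tr = by_name[sym_rec[ecol.symbol]]
            unit = s.units[f"${ecol.symbol}"]
            obs = window_stat(tr, ecol.t0, ecol.t1,
                              ecol.stat).magnitude_in(unit)
            exp = exp_row[ecol.header]
            tol_abs = max(s.tolerance * abs(exp), ABS_FLOOR)
            err = abs(obs - exp)
            report.cells.append(CellResult(
                set_index=i, parameters=pset, column=ecol.header,
                expected=exp, observed=obs,
                error=err / abs(exp) if exp else err,
                passed=err <= tol_abs,
            ))
    return report


def compare_backends(s: Scenario, configs: list[dict]) -> dict:
    """Pairwise max relative trace discrepancies per recorded symbol.

    Each config is a dict for :func:`run_scenario`'s ``backend_config``.
    """
    if len(configs) < 2:
        raise ComparisonError("need at least 2 backend configurations")
    runs = []  # per config: list over parameter sets of {sym: trace}
    for cfg in configs:
        per_set = []
        for pset in s.parameter_sets:
            sim, sym_rec = build_simulation(s, pset, dt_override=cfg.get("dt"))
            results = sim.run(method=cfg.get("method", "backward_euler"))
            by_name = {tr.name: tr for tr in results.traces}
            per_set.append({sym: by_name[rec] for sym, rec in sym_rec.items()})
        runs.append(per_set)
    for per_set in runs[1:]:
        for a, b in zip(runs[0], per_set):
            if set(a) != set(b):
                raise ComparisonError("mismatched recording sets")
    out: dict[tuple[int, int], dict[str, float]] = {}
    for i in range(len(configs)):
        for j in range(i + 1, len(configs)):
            per_sym: dict[str, float] = {}
            for set_a, set_b in zip(runs[i], runs[j]):
                for sym in set_a:
                    ta, tb = set_a[sym], set_b[sym]
                    if len(ta.times) != len(tb.times):
                        # different dt: compare on the coarser grid
                        vb = np.interp(ta.times, tb.times, tb.values)
                    else:
                        vb = tb.values
                    scale = max(np.max(np.abs(ta.values)),
                                np.max(np.abs(vb)), ABS_FLOOR)
                    disc = float(np.max(np.abs(ta.values - vb)) / scale)
                    per_sym[sym] = max(per_sym.get(sym, 0.0), disc)
            out[(i, j)] = per_sym
    return out


def _opt_ge(kw, q):
    opts = {}
    if "GBAR" in kw:
        opts["gbar"] = q(kw["GBAR"], "GBAR")
    if "EREV" in kw:
        opts["erev"] = q(kw["EREV"], "EREV")
    return opts


# ---------------------------------------------------------------------------
# Fixture generation with closed-form expectations
# ---------------------------------------------------------------------------

def _grid(duration: float, dt: float) -> np.ndarray:
    return np.arange(int(round(duration / dt)) + 1) * dt


def _window_vals(t: np.ndarray, v: np.ndarray, t0: float, t1: float):
    mask = (t >= t0) & (t < t1)
    return v[mask]


def _passive_G_C(area_um2, gbar, cap):
    """(G uS, C nF) of a soma of ``area_um2`` with gbar mS/cm2, cap uF/cm2."""
    area_cm2 = area_um2 * 1e-8
    return gbar * area_cm2 * 1e3, cap * area_cm2 * 1e3


def _fmt_rows(rows):
    return rows


def generate_fixture_scenarios(out_dir, seed: int = 0) -> list[Path]:
    """Write >= 5 scenario files whose expectations come from closed forms.

    All expectations are computed analytically (no solver involvement) on
    the same sampling grid the simulator records on, so shipped fixtures
    pass at 1% tolerance. Same seed -> byte-identical files.
    """
    import random

    rng = random.Random(seed)
    out_dir = Path(str(out_dir))
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    dt = 0.025
    area, cap, erev = 1000.0, 1.0, -51.0

    # 1. passive step: late-window mean over a sweep of amplitudes --------
    gbar = 0.3
    G, C = _passive_G_C(area, gbar, cap)
    tau = C / G
    duration, ton, t0w, t1w = 200.0, 0.0, 150.0, 200.0
    t = _grid(duration, dt)
    amps = [0.0, rng.choice([50.0, 80.0]), 100.0, rng.choice([150.0, 200.0])]
    psets, exps = [], []
    for amp in amps:
        v = erev + (amp * 1e-3 / G) * (1 - np.exp(-np.maximum(t - ton, 0) / tau))
        psets.append({"I": amp})
        exps.append({"col": float(np.mean(_window_vals(t, v, t0w, t1w)))})
    s = Scenario(
        name="passive_step",
        description_lines=[
            f"DURATION {duration:g}", f"DT {dt:g}",
            f"CELL cell1 AREA {area:g} CAPACITANCE {cap:g} INITIAL {erev:g}",
            f"CHANNEL leak lk ON cell1 GBAR {gbar:g} EREV {erev:g}",
            f"STIMULUS step stim1 INTO cell1 AMP <I> FROM {ton:g}",
        ],
        units={"I": "pA", "$V": "mV"},
        records={"V": ("cell1", "Voltage")},
        parameter_names=["I"],
        parameter_sets=psets,
        expected_columns=[ExpectedColumn("V", t0w, t1w, "mean")],
        expected=[{f"$V[{t0w:g}:{t1w:g}].mean": e["col"]} for e in exps],
    )
    paths.append(_emit(s, out_dir))

    # 2. input resistance: late-window mean over a sweep of leak densities -
    amp = 100.0
    gl_values = [0.1, 0.3, rng.choice([0.5, 0.6]), 1.0]
    psets, exps = [], []
    for gl in gl_values:
        Gx, Cx = _passive_G_C(area, gl, cap)
        taux = Cx / Gx
        v = erev + (amp * 1e-3 / Gx) * (1 - np.exp(-t / taux))
        psets.append({"GLK": gl})
        exps.append(float(np.mean(_window_vals(t, v, t0w, t1w))))
    s = Scenario(
        name="input_resistance",
        description_lines=[
            f"DURATION {duration:g}", f"DT {dt:g}",
            f"CELL cell1 AREA {area:g} CAPACITANCE {cap:g} INITIAL {erev:g}",
            "CHANNEL leak lk ON cell1 GBAR <GLK> EREV " + f"{erev:g}",
            f"STIMULUS step stim1 INTO cell1 AMP {amp:g} FROM 0",
        ],
        units={"GLK": "mS/cm2", "$V": "mV"},
        records={"V": ("cell1", "Voltage")},
        parameter_names=["GLK"],
        parameter_sets=psets,
        expected_columns=[ExpectedColumn("V", t0w, t1w, "mean")],
        expected=[{f"$V[{t0w:g}:{t1w:g}].mean": e} for e in exps],
    )
    paths.append(_emit(s, out_dir))

    # 3. membrane time constant: early-window mean is tau-sensitive -------
    caps = [0.5, 1.0, rng.choice([1.5, 2.0])]
    w0, w1 = 1.0, 5.0
    psets, exps = [], []
    for cx in caps:
        Gx, Cx = _passive_G_C(area, gbar, cx)
        taux = Cx / Gx
        v = erev + (amp * 1e-3 / Gx) * (1 - np.exp(-t / taux))
        psets.append({"C": cx})
        exps.append(float(np.mean(_window_vals(t, v, w0, w1))))
    s = Scenario(
        name="time_constant",
        description_lines=[
            f"DURATION {duration:g}", f"DT {dt:g}",
            f"CELL cell1 AREA {area:g} CAPACITANCE <C> INITIAL {erev:g}",
            f"CHANNEL leak lk ON cell1 GBAR {gbar:g} EREV {erev:g}",
            f"STIMULUS step stim1 INTO cell1 AMP {amp:g} FROM 0",
        ],
        units={"C": "uF/cm2", "$V": "mV"},
        records={"V": ("cell1", "Voltage")},
        parameter_names=["C"],
        parameter_sets=psets,
        expected_columns=[ExpectedColumn("V", w0, w1, "mean")],
        expected=[{f"$V[{w0:g}:{w1:g}].mean": e} for e in exps],
    )
    paths.append(_emit(s, out_dir))

    # 4. passive ramp: mid-ramp window from the exact ramp response -------
    ramp_amp = rng.choice([100.0, 200.0])
    rdur = 150.0
    k = ramp_amp * 1e-3 / rdur  # nA per ms
    w0, w1 = 120.0, 150.0
    vramp = erev + (k / G) * (
        (t - tau * (1 - np.exp(-t / tau))) * (t < rdur)
    )
    exp_ramp = float(np.mean(_window_vals(t, vramp, w0, w1)))
    s = Scenario(
        name="passive_ramp",
        description_lines=[
            f"DURATION {duration:g}", f"DT {dt:g}",
            f"CELL cell1 AREA {area:g} CAPACITANCE {cap:g} INITIAL {erev:g}",
            f"CHANNEL leak lk ON cell1 GBAR {gbar:g} EREV {erev:g}",
            f"STIMULUS ramp stim1 INTO cell1 AMP0 0 AMP1 <I> FROM 0 "
            f"FOR {rdur:g}",
        ],
        units={"I": "pA", "$V": "mV"},
        records={"V": ("cell1", "Voltage")},
        parameter_names=["I"],
        parameter_sets=[{"I": ramp_amp}],
        expected_columns=[ExpectedColumn("V", w0, w1, "mean")],
        expected=[{f"$V[{w0:g}:{w1:g}].mean": exp_ramp}],
    )
    paths.append(_emit(s, out_dir))

    # 5. gap-junction coupling coefficient --------------------------------
    ggj_values = [1.0, rng.choice([2.0, 3.0])]
    psets, exps = [], []
    for ggj_nS in ggj_values:
        ggj = ggj_nS * 1e-3  # uS
        inj = amp * 1e-3     # nA
        v1 = erev + inj * (G + ggj) / (G * (G + 2 * ggj))
        v2 = erev + inj * ggj / (G * (G + 2 * ggj))
        psets.append({"GJ": ggj_nS})
        exps.append((v1, v2))
    s = Scenario(
        name="gap_junction_coupling",
        description_lines=[
            f"DURATION {duration:g}", f"DT {dt:g}",
            f"CELL cell1 AREA {area:g} CAPACITANCE {cap:g} INITIAL {erev:g}",
            f"CELL cell2 AREA {area:g} CAPACITANCE {cap:g} INITIAL {erev:g}",
            f"CHANNEL leak lk1 ON cell1 GBAR {gbar:g} EREV {erev:g}",
            f"CHANNEL leak lk2 ON cell2 GBAR {gbar:g} EREV {erev:g}",
            "GAPJUNCTION gj1 BETWEEN cell1 cell2 G <GJ>",
            f"STIMULUS step stim1 INTO cell1 AMP {amp:g} FROM 0",
        ],
        units={"GJ": "nS", "$V1": "mV", "$V2": "mV"},
        records={"V1": ("cell1", "Voltage"), "V2": ("cell2", "Voltage")},
        parameter_names=["GJ"],
        parameter_sets=psets,
        expected_columns=[
            ExpectedColumn("V1", t0w, t1w, "mean"),
            ExpectedColumn("V2", t0w, t1w, "mean"),
        ],
        expected=[
            {
                f"$V1[{t0w:g}:{t1w:g}].mean": v1,
                f"$V2[{t0w:g}:{t1w:g}].mean": v2,
            }
            for v1, v2 in exps
        ],
    )
    paths.append(_emit(s, out_dir))

    # 6. PSR peak under voltage clamp -------------------------------------
    t_event = 20.0
    tr_ms, td_ms = 0.5, 5.0
    gs_values = [1.0, rng.choice([2.0, 4.0])]
    tp = td_ms * tr_ms / (td_ms - tr_ms) * math.log(td_ms / tr_ms)
    norm = 1.0 / (math.exp(-tp / td_ms) - math.exp(-tp / tr_ms))
    t_short = _grid(60.0, dt)
    rel = np.maximum(t_short - t_event, 0.0)
    wave = norm * (np.exp(-rel / td_ms) - np.exp(-rel / tr_ms)) * (
        t_short >= t_event)
    psets, exps = [], []
    for gs in gs_values:
        g = gs * wave
        psets.append({"GS": gs})
        exps.append(float(np.max(_window_vals(t_short, g, t_event, 40.0))))
    s = Scenario(
        name="psr_vclamp_peak",
        description_lines=[
            "DURATION 60", f"DT {dt:g}",
            f"CELL cell1 AREA {area:g} CAPACITANCE {cap:g} INITIAL {erev:g}",
            f"CHANNEL leak lk ON cell1 GBAR {gbar:g} EREV {erev:g}",
            f"VCLAMP vc1 ON cell1 TO {erev:g} FROM 0",
            f"SYNAPSE syn1 ONTO cell1 GBAR <GS> EREV 0 TAU_RISE {tr_ms:g} "
            f"TAU_DECAY {td_ms:g} AT {t_event:g}",
        ],
        units={"GS": "nS", "$G": "nS"},
        records={"G": ("syn1", "Conductance")},
        parameter_names=["GS"],
        parameter_sets=psets,
        expected_columns=[ExpectedColumn("G", t_event, 40.0, "max")],
        expected=[{f"$G[{t_event:g}:40].max": e} for e in exps],
    )
    paths.append(_emit(s, out_dir))

    return paths


def _emit(s: Scenario, out_dir: Path) -> Path:
    path = out_dir / f"{s.name}.scn"
    write_scenario(s, path)
    parse_scenario(path)  # self-check: generated files must round-trip
    return path
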