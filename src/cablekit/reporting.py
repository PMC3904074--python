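"""Figure generation (TagViewer) and HTML/Markdown simulation summaries.

:func:`tagviewer_render` draws a single figure of stacked axes sharing one
time base; which traces land on which axis is decided by tag-selection
queries held in :class:`PlotSpec` objects. When no specs are given a
default list (Voltage, Current, CurrentDensity, Conductance,
ConductanceDensity, Events) is used.

:func:`summarize_simulation` generates a standalone HTML or Markdown
document describing a simulation: per-cell tables, a 2D morphology
projection, channel parameter tables with rate/steady-state/time-constant
curves, the resolved channel distribution, stimulus/synapse/gap-junction
tables and (optionally) the default results figure. Rendering is a pure
function of its inputs: no timestamps or environment data are embedded.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .channels import GatedChannel, gate_steady_state_and_tau
from .distribution import distribution_table
from .errors import DimensionError
from .model import Cell, ComponentLibrary, Simulation, VoltageClampStep, \
    _CurrentClamp
from .traces import SimulationResults, parse_query
from .units import parse_unit

__all__ = ["PlotSpec", "DEFAULT_PLOT_SPECS", "tagviewer_render",
           "summarize_simulation", "SummaryDocument"]


@dataclass(frozen=True)
class PlotSpec:
    """One axis of a TagViewer figure."""

    selector: str
    ylabel: str = ""
    yunit: str = ""
    yrange: Optional[tuple[float, float]] = None

    def __post_init__(self):
        parse_query(self.selector)  # validates
        if self.yunit:
            parse_unit(self.yunit)


DEFAULT_PLOT_SPECS: tuple[PlotSpec, ...] = (
    PlotSpec("ALL{Voltage}", ylabel="Voltage", yunit="mV"),
    PlotSpec("ALL{Current}", ylabel="Current", yunit="pA"),
    PlotSpec("ALL{CurrentDensity}", ylabel="Current density", yunit="mA/cm2"),
    PlotSpec("ALL{Conductance}", ylabel="Conductance", yunit="nS"),
    PlotSpec("ALL{ConductanceDensity}", ylabel="Conductance density",
             yunit="mS/cm2"),
    PlotSpec("ALL{Event}", ylabel="Events"),
)


def tagviewer_render(
    results: SimulationResults,
    plot_specs: Optional[Sequence[PlotSpec]] = None,
    out_path=None,
):
    """Render stacked axes, one per matching PlotSpec, sharing the time axis.

    Returns the matplotlib figure; saves it to ``out_path`` if given.
    Raises :class:`DimensionError` if a spec's unit is incompatible with a
    matched trace, and ``LookupError`` (listing the available tags) if no
    spec matches anything.
    """
    specs = list(plot_specs) if plot_specs is not None else list(
        DEFAULT_PLOT_SPECS)
    panels = []
    for spec in specs:
        q = parse_query(spec.selector)
        traces = [tr for tr in results.traces if q.matches(tr.tags)]
        events = [ev for ev in results.events if q.matches(ev.tags)]
        if traces or events:
            panels.append((spec, traces, events))
    if not panels:
        raise LookupError(
            "no trace matches any plot spec; available tags: "
            f"{sorted(results.all_tags)}"
        )
    fig, axes = plt.subplots(
        len(panels), 1, sharex=True, squeeze=False,
        figsize=(8.0, 2.2 * len(panels)),
    )
    for ax, (spec, traces, events) in zip(axes[:, 0], panels):
        for tr in traces:
            if spec.yunit:
                try:
                    tr = tr.to_unit(spec.yunit)
                except DimensionError as exc:
                    raise DimensionError(
                        f"plot spec {spec.selector!r} (unit {spec.yunit!r}) "
                        f"matched incompatible trace {tr.name!r} "
                        f"({tr.unit!r}): {exc}"
                    ) from None
            ax.plot(tr.times, tr.values, label=tr.name or None, lw=1.0)
        for i, ev in enumerate(events):
            ax.eventplot(ev.times, lineoffsets=i + 1, colors="k")
        label = spec.ylabel or spec.selector
        if spec.yunit:
            label = f"{label} ({spec.yunit})"
        ax.set_ylabel(label, fontsize=8)
        if spec.yrange:
            ax.set_ylim(*spec.yrange)
        if traces and len(traces) > 1:
            ax.legend(fontsize=6, loc="upper right")
    axes[-1, 0].set_xlabel("time (ms)")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(str(out_path))
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# Summary documents
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    kind: str  # "heading" | "table" | "figure" | "text" | "code"
    payload: object
    title: str = ""


class SummaryDocument:
    """Ordered blocks renderable to HTML or Markdown."""

    def __init__(self, title: str):
        self.title = title
        self.blocks: list[_Block] = []

    def heading(self, text: str, level: int = 2):
        self.blocks.append(_Block("heading", (level, text)))

    def table(self, header: Sequence[str], rows: Sequence[Sequence], title=""):
        self.blocks.append(_Block("table", (list(header), [list(r) for r in rows]),
                                  title))

    def figure(self, path: str, title=""):
        self.blocks.append(_Block("figure", path, title))

    def text(self, body: str):
        self.blocks.append(_Block("text", body))

    def code(self, body: str):
        self.blocks.append(_Block("code", body))

    # -- renderers --------------------------------------------------------
    def to_markdown(self) -> str:
        out = [f"# {self.title}", ""]
        for b in self.blocks:
            if b.kind == "heading":
                level, text = b.payload
                out += ["#" * level + " " + text, ""]
            elif b.kind == "table":
                header, rows = b.payload
                if b.title:
                    out.append(f"**{b.title}**\n")
                out.append("| " + " | ".join(map(str, header)) + " |")
                out.append("|" + "---|" * len(header))
                for r in rows:
                    out.append("| " + " | ".join(str(c) for c in r) + " |")
                out.append("")
            elif b.kind == "figure":
                out += [f"![{b.title}]({b.payload})", ""]
            elif b.kind == "code":
                out += ["```", b.payload, "```", ""]
            else:
                out += [str(b.payload), ""]
        return "\n".join(out)

    def to_html(self) -> str:
        esc = _html.escape
        parts = [
            "<!DOCTYPE html><html><head><meta charset='utf-8'>",
            f"<title>{esc(self.title)}</title>",
            "<style>body{font-family:sans-serif;margin:2em;}"
            "table{border-collapse:collapse;margin:1em 0;}"
            "td,th{border:1px solid #999;padding:0.3em 0.6em;"
            "font-size:0.9em;}</style>",
            "</head><body>",
            f"<h1>{esc(self.title)}</h1>",
        ]
        for b in self.blocks:
            if b.kind == "heading":
                level, text = b.payload
                parts.append(f"<h{level}>{esc(text)}</h{level}>")
            elif b.kind == "table":
                header, rows = b.payload
                if b.title:
                    parts.append(f"<p><b>{esc(b.title)}</b></p>")
                parts.append("<table><tr>" + "".join(
                    f"<th>{esc(str(h))}</th>" for h in header) + "</tr>")
                for r in rows:
                    parts.append("<tr>" + "".join(
                        f"<td>{esc(str(c))}</td>" for c in r) + "</tr>")
                parts.append("</table>")
            elif b.kind == "figure":
                parts.append(
                    f"<figure><img src='{b.payload}' style='max-width:100%'/>"
                    f"<figcaption>{esc(b.title)}</figcaption></figure>")
            elif b.kind == "code":
                parts.append(f"<pre>{esc(b.payload)}</pre>")
            else:
                parts.append(f"<p>{esc(str(b.payload))}</p>")
        parts.append("</body></html>")
        return "\n".join(parts)


def _morphology_figure(cell: Cell, path: Path):
    """XY orthographic projection, line width proportional to diameter."""
    fig, ax = plt.subplots(figsize=(4, 4))
    for sec in cell.morphology:
        x = [sec.proximal[0], sec.distal[0]]
        y = [sec.proximal[1], sec.distal[1]]
        mean_d = sec.proximal_radius + sec.distal_radius  # = mean diameter
        ax.plot(x, y, lw=max(0.5, mean_d * 0.5), color="C0",
                solid_capstyle="round")
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(cell.name, fontsize=9)
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)


def _channel_figure(chl: GatedChannel, path: Path):
    """alpha/beta, steady state and time constant over [-100, 60] mV."""
    v = np.arange(-100.0, 60.0 + 1e-9, 0.1)
    fig, axes = plt.subplots(2, 2, figsize=(7, 5))
    for gate in chl.gates:
        a = gate.alpha(v)
        b = gate.beta(v)
        inf, tau = gate_steady_state_and_tau(gate, v)
        axes[0, 0].plot(v, a, label=f"alpha_{gate.name}")
        axes[0, 1].plot(v, b, label=f"beta_{gate.name}")
        axes[1, 0].plot(v, inf, label=f"{gate.name}_inf")
        axes[1, 1].plot(v, tau, label=f"tau_{gate.name}")
    for ax, ylab in zip(axes.flat, ("rate (ms^-1)", "rate (ms^-1)",
                                    "steady state", "tau (ms)")):
        ax.set_xlabel("V (mV)")
        ax.set_ylabel(ylab, fontsize=8)
        ax.legend(fontsize=6)
    fig.suptitle(chl.name, fontsize=10)
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)


def summarize_simulation(
    sim: Simulation,
    results: Optional[SimulationResults] = None,
    out_path="summary.html",
    format: str = "html",
) -> SummaryDocument:
    """Write an HTML/Markdown summary of ``sim``; returns the document.

    Figures (SVG) are written next to ``out_path`` using its stem as a
    prefix.
    """
    if format not in ("html", "md"):
        raise ValueError(f"format must be 'html' or 'md', got {format!r}")
    sim.validate()
    out_path = Path(str(out_path))
    out_path.parent.mkdir(parents=True, exist_ok=True)
    stem = out_path.stem

    doc = SummaryDocument(f"Simulation summary: {sim.name}")
    doc.text(
        f"duration {sim.duration.magnitude_in('ms'):g} ms, "
        f"dt {sim.dt.magnitude_in('ms'):g} ms, seed {sim.seed}."
    )

    doc.heading("Cells")
    doc.table(
        ["name", "sections", "total area (um2)", "capacitance",
         "axial resistivity"],
        [
            [
                c.name,
                len(c.morphology),
                f"{c.morphology.surface_area().magnitude_in('um2'):.2f}",
                str(c.capacitance),
                str(c.axial_resistivity),
            ]
            for c in sim.cells
        ],
    )
    for cell in sim.cells:
        fig_path = out_path.parent / f"{stem}_morph_{cell.name}.svg"
        _morphology_figure(cell, fig_path)
        doc.figure(fig_path.name, title=f"morphology of {cell.name}")

    doc.heading("Channels")
    seen: dict[str, object] = {}
    for cell in sim.cells:
        for app in cell.applications:
            seen.setdefault(app.channel.name, app.channel)
    for name, chl in sorted(seen.items()):
        doc.table(
            ["parameter", "default value"],
            [[k, str(v)] for k, v in chl.get_defaults().items()],
            title=f"{name} ({chl.mechanism_kind})",
        )
        if isinstance(chl, GatedChannel):
            fig_path = out_path.parent / f"{stem}_chl_{name}.svg"
            _channel_figure(chl, fig_path)
            doc.figure(fig_path.name, title=f"kinetics of {name}")

    doc.heading("Channel distribution")
    rows = []
    for cell in sim.cells:
        resolved = cell.resolve_channels()
        for sid, region, chname, pname, value, unit in distribution_table(
                resolved, cell.morphology):
            rows.append([cell.name, sid, region, chname, pname,
                         f"{value:g}", unit])
    doc.table(["cell", "section", "region", "channel", "parameter",
               "value", "unit"], rows)

    doc.heading("Stimuli")
    stim_rows = []
    for stim in sim.stimuli:
        if isinstance(stim, VoltageClampStep):
            desc = f"clamp to {stim.voltage}"
        elif isinstance(stim, _CurrentClamp):
            parts = []
            for attr in ("amp", "amp0", "amp1", "frequency"):
                if hasattr(stim, attr):
                    parts.append(f"{attr}={getattr(stim, attr)}")
            desc = ", ".join(parts)
        stim_rows.append([
            stim.name, stim.kind, stim.cell.name,
            f"{stim.location.section.id}:{stim.location.fraction_along:g}",
            desc,
        ])
    doc.table(["name", "kind", "cell", "location", "parameters"], stim_rows)

    if sim.synapses:
        doc.heading("Synapses")
        doc.table(
            ["name", "template", "post cell", "gbar", "erev", "tau_rise",
             "tau_decay", "delay", "trigger"],
            [
                [
                    s.name, s.template.name, s.post_cell.name,
                    str(s.template.psr.gbar), str(s.template.psr.erev),
                    str(s.template.psr.tau_rise), str(s.template.psr.tau_decay),
                    str(s.delay),
                    ("times" if s.pre_cell is None
                     else f"spike in {s.pre_cell.name}"),
                ]
                for s in sim.synapses
            ],
        )
    if sim.gap_junctions:
        doc.heading("Gap junctions")
        doc.table(
            ["name", "conductance", "cell1", "cell2"],
            [[g.name, str(g.conductance), g.cell1.name, g.cell2.name]
             for g in sim.gap_junctions],
        )

    if results is not None:
        doc.heading("Results")
        fig_path = out_path.parent / f"{stem}_results.svg"
        tagviewer_render(results, out_path=fig_path)
        doc.figure(fig_path.name, title="recorded traces")

    text = doc.to_html() if format == "html" else doc.to_markdown()
    out_path.write_text(text)
    return doc


def library_summary(library: ComponentLibrary) -> list[tuple[str, str, str]]:
    """Rows of a component library's summary_table()."""
    return library.summary_table()
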