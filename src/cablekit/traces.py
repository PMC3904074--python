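"""Tagged result objects, the tag-selection query language, trace analysis.

Every recorded waveform is a :class:`Trace`: time stamps (ms), values, a
unit string and a set of tags. Spike detections are :class:`EventSet`
objects. Queries over tags use a small boolean language::

    expr   := term (OR term)*
    term   := factor (AND factor)*
    factor := NOT factor | '(' expr ')' | ('ALL'|'ANY') '{' tag (',' tag)* '}'

``ALL{A,B}`` is a subset test, ``ANY{X,Y}`` a nonempty-intersection test.
Tag comparison is case-insensitive. NOT binds tightest, then AND, then OR.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import DimensionError, QueryParseError, WindowError
from .units import VOLTAGE, Quantity, ensure_quantity, parse_unit

__all__ = [
    "Trace",
    "EventSet",
    "TagQuery",
    "parse_query",
    "filter_traces",
    "spike_count",
    "spike_times",
    "window_stat",
    "SimulationResults",
    "save_results",
    "load_results",
]


class Trace:
    """A time-stamped analog signal with a unit and a set of string tags."""

    def __init__(self, times, values, unit: str, tags: Iterable[str] = (),
                 name: str = ""):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.unit = unit
        self.tags = set(tags)
        self.name = name
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if len(self.times) != len(self.values):
            raise ValueError(
                f"times ({len(self.times)}) and values ({len(self.values)}) "
                "differ in length"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        parse_unit(unit)  # validates

    def to_unit(self, unit: str) -> "Trace":
        """Return a copy with values converted to ``unit``."""
        factor = Quantity(1.0, self.unit).magnitude_in(unit)
        return Trace(self.times, self.values * factor, unit, self.tags,
                     self.name)

    def __repr__(self):
        return (
            f"Trace({self.name!r}, n={len(self.times)}, unit={self.unit!r}, "
            f"tags={sorted(self.tags)})"
        )


class EventSet:
    """A sorted collection of time stamps (ms) with tags."""

    def __init__(self, times, tags: Iterable[str] = (), name: str = ""):
        self.times = np.sort(np.asarray(times, dtype=float))
        self.tags = set(tags)
        self.name = name

    def __len__(self):
        return len(self.times)

    def __repr__(self):
        return f"EventSet({self.name!r}, n={len(self)}, tags={sorted(self.tags)})"


# ---------------------------------------------------------------------------
# Tag query language
# ---------------------------------------------------------------------------

class TagQuery:
    """Parsed query expression; evaluate with :meth:`matches`."""

    def matches(self, tags: Iterable[str]) -> bool:
        folded = {t.lower() for t in tags}
        return self._eval(folded)

    def _eval(self, folded: set[str]) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def __str__(self):
        raise NotImplementedError


@dataclass(frozen=True)
class _Pred(TagQuery):
    kind: str  # "ALL" | "ANY"
    tags: tuple[str, ...]

    def _eval(self, folded):
        wanted = {t.lower() for t in self.tags}
        if self.kind == "ALL":
            return wanted <= folded
        return bool(wanted & folded)

    def __str__(self):
        return f"{self.kind}{{{','.join(self.tags)}}}"


@dataclass(frozen=True)
class _Not(TagQuery):
    operand: TagQuery

    def _eval(self, folded):
        return not self.operand._eval(folded)

    def __str__(self):
        return f"NOT {self.operand}"


@dataclass(frozen=True)
class _And(TagQuery):
    left: TagQuery
    right: TagQuery

    def _eval(self, folded):
        return self.left._eval(folded) and self.right._eval(folded)

    def __str__(self):
        return f"({self.left} AND {self.right})"


@dataclass(frozen=True)
class _Or(TagQuery):
    left: TagQuery
    right: TagQuery

    def _eval(self, folded):
        return self.left._eval(folded) or self.right._eval(folded)

    def __str__(self):
        return f"({self.left} OR {self.right})"


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<kw>ALL|ANY|AND|OR|NOT)\b|(?P<lbrace>\{)|(?P<rbrace>\})"
    r"|(?P<lparen>\()|(?P<rparen>\))|(?P<comma>,)|(?P<tag>[A-Za-z0-9_:]+))"
)


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.tokens: list[tuple[str, str, int]] = []
        self._tokenize()
        self.idx = 0

    def _tokenize(self):
        pos = 0
        while pos < len(self.text):
            if self.text[pos].isspace():
                pos += 1
                continue
            m = _TOKEN_RE.match(self.text, pos)
            if not m:
                raise QueryParseError(
                    f"unexpected character {self.text[pos]!r} at position {pos}"
                )
            kind = m.lastgroup
            self.tokens.append((kind, m.group(), pos))
            pos = m.end()

    def _peek(self):
        return self.tokens[self.idx] if self.idx < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise QueryParseError(
                f"unexpected end of query at position {len(self.text)}"
            )
        self.idx += 1
        return tok

    def parse(self) -> TagQuery:
        expr = self._expr()
        tok = self._peek()
        if tok is not None:
            raise QueryParseError(
                f"unexpected token {tok[1].strip()!r} at position {tok[2]}"
            )
        return expr

    def _expr(self) -> TagQuery:
        node = self._term()
        while self._peek() and self._peek()[1].strip() == "OR":
            self._next()
            node = _Or(node, self._term())
        return node

    def _term(self) -> TagQuery:
        node = self._factor()
        while self._peek() and self._peek()[1].strip() == "AND":
            self._next()
            node = _And(node, self._factor())
        return node

    def _factor(self) -> TagQuery:
        tok = self._next()
        kind, text, pos = tok
        word = text.strip()
        if word == "NOT":
            return _Not(self._factor())
        if kind == "lparen":
            node = self._expr()
            closing = self._next()
            if closing[0] != "rparen":
                raise QueryParseError(
                    f"expected ')' at position {closing[2]}, got "
                    f"{closing[1].strip()!r}"
                )
            return node
        if word in ("ALL", "ANY"):
            lb = self._next()
            if lb[0] != "lbrace":
                raise QueryParseError(
                    f"expected '{{' after {word} at position {lb[2]}"
                )
            tags: list[str] = []
            while True:
                t = self._next()
                if t[0] == "rbrace" and not tags:
                    raise QueryParseError(
                        f"empty predicate {word}{{}} at position {t[2]}"
                    )
                if t[0] != "tag":
                    raise QueryParseError(
                        f"expected tag at position {t[2]}, got "
                        f"{t[1].strip()!r}"
                    )
                tags.append(t[1].strip())
                sep = self._next()
                if sep[0] == "rbrace":
                    break
                if sep[0] != "comma":
                    raise QueryParseError(
                        f"expected ',' or '}}' at position {sep[2]}, got "
                        f"{sep[1].strip()!r}"
                    )
            return _Pred(word, tuple(tags))
        raise QueryParseError(
            f"unexpected token {word!r} at position {pos}"
        )


def parse_query(text: str) -> TagQuery:
    """Parse a tag-selection string into a :class:`TagQuery`."""
    if not text or not text.strip():
        raise QueryParseError("empty query")
    return _Parser(text).parse()


def match(query: TagQuery | str, tags: Iterable[str]) -> bool:
    """Evaluate ``query`` (parsing it first if a string) against ``tags``."""
    if isinstance(query, str):
        query = parse_query(query)
    return query.matches(tags)


def filter_traces(results, query_text: str | TagQuery) -> list[Trace]:
    """Select traces whose tags match the query, in recording order."""
    q = parse_query(query_text) if isinstance(query_text, str) else query_text
    traces = results.traces if hasattr(results, "traces") else list(results)
    return [tr for tr in traces if q.matches(tr.tags)]


# ---------------------------------------------------------------------------
# Trace analysis
# ---------------------------------------------------------------------------

def _require_voltage(tr: Trace):
    _, dim = parse_unit(tr.unit)
    if dim != VOLTAGE:
        raise DimensionError(
            f"trace {tr.name!r} has unit {tr.unit!r}; spike analysis needs a "
            "voltage trace"
        )


def _threshold_mV(threshold) -> float:
    return ensure_quantity(threshold, default_unit="mV",
                           expect_dim=VOLTAGE).magnitude_in("mV")


def _crossing_indices(values: np.ndarray, theta: float) -> np.ndarray:
    prev = values[:-1]
    curr = values[1:]
    return np.nonzero((prev < theta) & (curr >= theta))[0]


def spike_count(tr: Trace, threshold="0 mV") -> int:
    """Count strict upward threshold crossings (v[i-1] < theta <= v[i])."""
    _require_voltage(tr)
    theta = _threshold_mV(threshold)
    v = tr.to_unit("mV").values
    return int(len(_crossing_indices(v, theta)))


def spike_times(tr: Trace, threshold="0 mV") -> EventSet:
    """Upward-crossing times, linearly interpolated between samples."""
    _require_voltage(tr)
    theta = _threshold_mV(threshold)
    v = tr.to_unit("mV").values
    idx = _crossing_indices(v, theta)
    t0 = tr.times[idx]
    t1 = tr.times[idx + 1]
    v0 = v[idx]
    v1 = v[idx + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(v1 > v0, (theta - v0) / (v1 - v0), 0.0)
    times = t0 + frac * (t1 - t0)
    return EventSet(times, tags=tr.tags | {"Event"}, name=f"{tr.name}.spikes")


_STATS = {
    "mean": np.mean,
    "max": np.max,
    "min": np.min,
}


def window_stat(tr: Trace, t0: float, t1: float, stat: str = "mean") -> Quantity:
    """Statistic over samples with t0 <= t < t1 (ms), in the trace's unit."""
    if stat not in _STATS:
        raise ValueError(f"unknown stat {stat!r}; choose from {sorted(_STATS)}")
    if not (t0 < t1):
        raise WindowError(f"require t0 < t1, got [{t0}, {t1})")
    mask = (tr.times >= t0) & (tr.times < t1)
    if not np.any(mask):
        raise WindowError(
            f"window [{t0}, {t1}) ms contains no samples of trace "
            f"{tr.name!r} (domain [{tr.times[0]}, {tr.times[-1]}])"
        )
    return Quantity(float(_STATS[stat](tr.values[mask])), tr.unit)


# ---------------------------------------------------------------------------
# Results container and archive
# ---------------------------------------------------------------------------

@dataclass
class SimulationResults:
    """Outputs of one simulation run: traces, event sets, metadata."""

    traces: list[Trace] = field(default_factory=list)
    events: list[EventSet] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def filter(self, query_text: str | TagQuery) -> list[Trace]:
        return filter_traces(self, query_text)

    def filter_events(self, query_text: str | TagQuery) -> list[EventSet]:
        q = (parse_query(query_text) if isinstance(query_text, str)
             else query_text)
        return [ev for ev in self.events if q.matches(ev.tags)]

    def get_one(self, query_text: str | TagQuery) -> Trace:
        hits = self.filter(query_text)
        if len(hits) != 1:
            raise LookupError(
                f"query {query_text!r} matched {len(hits)} traces, expected 1"
            )
        return hits[0]

    @property
    def all_tags(self) -> set[str]:
        tags: set[str] = set()
        for tr in self.traces:
            tags |= tr.tags
        for ev in self.events:
            tags |= ev.tags
        return tags


def save_results(results: SimulationResults, path) -> None:
    """Write results to a single-file JSON archive (arrays + metadata)."""
    doc = {
        "format": "cablekit-results/1",
        "metadata": results.metadata,
        "traces": [
            {
                "name": tr.name,
                "unit": tr.unit,
                "tags": sorted(tr.tags),
                "times": tr.times.tolist(),
                "values": tr.values.tolist(),
            }
            for tr in results.traces
        ],
        "events": [
            {
                "name": ev.name,
                "tags": sorted(ev.tags),
                "times": ev.times.tolist(),
            }
            for ev in results.events
        ],
    }
    Path(str(path)).write_text(json.dumps(doc))


def load_results(path) -> SimulationResults:
    doc = json.loads(Path(str(path)).read_text())
    if doc.get("format") != "cablekit-results/1":
        raise ValueError(f"{path}: not a cablekit results archive")
    return SimulationResults(
        traces=[
            Trace(d["times"], d["values"], d["unit"], d["tags"], d["name"])
            for d in doc["traces"]
        ],
        events=[
            EventSet(d["times"], d["tags"], d["name"]) for d in doc["events"]
        ],
        metadata=doc.get("metadata", {}),
    )
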