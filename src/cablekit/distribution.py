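"""Channel distribution over morphologies via (Channel, Applicator, Targeter).

A cell's channel complement is declared as a list of triplets. Each
Targeter selects sections (everywhere / by region / by section id) and
carries an integer priority (defaults 1 / 2 / 3). For each (section,
channel) pair exactly one triplet applies: the matching one with the
highest priority. Equal-priority matches are a hard error rather than
last-wins, since silent shadowing is a correctness hazard.

Parameters are resolved per section by starting from the channel defaults,
then applying the winning applicator's overrides, then its multipliers.
Multipliers never stack across triplets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .channels import Channel
from .errors import AmbiguityError, DomainError
from .morphology import Morphology, Section
from .units import Quantity, ensure_quantity

__all__ = [
    "Targeter",
    "Applicator",
    "ChannelApplication",
    "resolve_distribution",
    "distribution_table",
]


@dataclass(frozen=True)
class Targeter:
    """Selects the sections a channel application applies to."""

    kind: str  # "everywhere" | "region" | "section"
    arg: str | None = None
    priority: int = 1

    _DEFAULT_PRIORITY = {"everywhere": 1, "region": 2, "section": 3}

    def __post_init__(self):
        if self.kind not in self._DEFAULT_PRIORITY:
            raise DomainError(f"unknown targeter kind {self.kind!r}")
        if self.kind != "everywhere" and not self.arg:
            raise DomainError(f"targeter kind {self.kind!r} needs an argument")
        if self.priority < 1:
            raise DomainError("targeter priority must be >= 1")

    @classmethod
    def everywhere(cls, priority: int = 1) -> "Targeter":
        return cls("everywhere", None, priority)

    @classmethod
    def region(cls, name: str, priority: int = 2) -> "Targeter":
        return cls("region", name, priority)

    @classmethod
    def section(cls, section_id: str, priority: int = 3) -> "Targeter":
        return cls("section", section_id, priority)

    def matches(self, section: Section) -> bool:
        if self.kind == "everywhere":
            return True
        if self.kind == "region":
            return section.region == self.arg
        return section.id == self.arg

    def describe(self) -> str:
        if self.kind == "everywhere":
            return "everywhere"
        return f"{self.kind}:{self.arg}"


class Applicator:
    """Parameter overrides and multipliers applied on top of defaults.

    A parameter may not appear in both maps. Override values must be
    Quantities (or parseable strings) with the same dimensions as the
    channel default they replace; that check happens at resolution time.
    """

    def __init__(
        self,
        overrides: Mapping[str, object] | None = None,
        multipliers: Mapping[str, float] | None = None,
    ):
        self.overrides = {
            k: ensure_quantity(v) if not isinstance(v, (int, float)) else v
            for k, v in (overrides or {}).items()
        }
        self.multipliers = {k: float(v) for k, v in (multipliers or {}).items()}
        both = set(self.overrides) & set(self.multipliers)
        if both:
            raise DomainError(
                f"parameters {sorted(both)} appear in both overrides and "
                "multipliers"
            )

    @classmethod
    def uniform(cls, **overrides) -> "Applicator":
        return cls(overrides=overrides)

    def __repr__(self):
        return (
            f"Applicator(overrides={self.overrides!r}, "
            f"multipliers={self.multipliers!r})"
        )


@dataclass
class ChannelApplication:
    """One (Channel, Applicator, Targeter) triplet."""

    channel: Channel
    applicator: Applicator = field(default_factory=Applicator)
    targeter: Targeter = field(default_factory=Targeter.everywhere)

    def __post_init__(self):
        known = set(self.channel.get_variables())
        bad = (set(self.applicator.overrides) | set(self.applicator.multipliers)) - known
        if bad:
            raise DomainError(
                f"unknown parameter(s) {sorted(bad)} for channel "
                f"{self.channel.name!r}; known: {sorted(known)}"
            )

    def resolved_params(self) -> dict[str, Quantity]:
        params = self.channel.get_defaults()
        for k, v in self.applicator.overrides.items():
            if isinstance(v, Quantity):
                if v.dimensions != params[k].dimensions:
                    from .errors import DimensionError

                    raise DimensionError(
                        f"override {k!r} for channel {self.channel.name!r}: "
                        f"dims {v.dimensions} != default dims "
                        f"{params[k].dimensions}"
                    )
                params[k] = v
            else:
                # bare number: interpreted in the default's display unit
                params[k] = Quantity(float(v), params[k].unit_label)
        for k, mult in self.applicator.multipliers.items():
            params[k] = params[k] * mult
        return params


def resolve_distribution(
    applications: list[ChannelApplication], m: Morphology
) -> dict[tuple[str, str], dict[str, Quantity]]:
    """Resolve triplets into a map (section id, channel name) -> parameters.

    Raises
    ------
    KeyError
        If a region targeter names a region absent from the morphology.
    AmbiguityError
        If two matching triplets for the same (section, channel) share the
        highest priority.
    """
    regions = m.regions
    for app in applications:
        t = app.targeter
        if t.kind == "region" and t.arg not in regions:
            raise KeyError(
                f"targeter references unknown region {t.arg!r}; known "
                f"regions: {sorted(regions)}"
            )
        if t.kind == "section" and t.arg not in m:
            raise KeyError(
                f"targeter references unknown section {t.arg!r}"
            )

    resolved: dict[tuple[str, str], dict[str, Quantity]] = {}
    channel_names = sorted({a.channel.name for a in applications})
    for sec in m:
        for chname in channel_names:
            matching = [
                a
                for a in applications
                if a.channel.name == chname and a.targeter.matches(sec)
            ]
            if not matching:
                continue
            best_priority = max(a.targeter.priority for a in matching)
            best = [a for a in matching if a.targeter.priority == best_priority]
            if len(best) > 1:
                descr = ", ".join(a.targeter.describe() for a in best)
                raise AmbiguityError(
                    f"section {sec.id!r}: {len(best)} triplets for channel "
                    f"{chname!r} at equal priority {best_priority} ({descr})"
                )
            resolved[(sec.id, chname)] = best[0].resolved_params()
    return resolved


def distribution_table(
    resolved: Mapping[tuple[str, str], Mapping[str, Quantity]], m: Morphology
) -> list[tuple[str, str, str, str, float, str]]:
    """Flatten a resolved distribution into (section, region, channel,
    parameter, value, unit) rows for summaries."""
    rows = []
    for sec in m:
        for (sid, chname), params in resolved.items():
            if sid != sec.id:
                continue
            for pname, q in params.items():
                rows.append(
                    (sid, sec.region, chname, pname, float(q.magnitude),
                     q.unit_label)
                )
    return rows
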