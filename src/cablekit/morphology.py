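"""Neuronal morphologies as trees of conical frusta with region labels.

A :class:`Morphology` is an ordered tree of :class:`Section` objects. Each
section is an unbranched piece of membrane between two 3D points with a
radius at either end (a conical frustum); sections carry a string region
label (``soma``, ``dendrite``, ...) used by the channel-distribution rules.

SWC import/export is supported for the standard 7-column format. See
:func:`read_swc` for the mapping of sample chains onto sections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import DimensionError, DomainError, MorphologyError
from .units import AREA, Quantity, ensure_quantity

__all__ = [
    "Section",
    "Morphology",
    "MorphLocation",
    "build_soma_from_area",
    "surface_area",
    "frustum_lateral_area",
    "read_swc",
    "write_swc",
    "resolve_location",
]

# SWC type code <-> region name
_SWC_REGIONS = {1: "soma", 2: "axon", 3: "dendrite", 4: "apicaldendrite"}
_REGION_CODES = {v: k for k, v in _SWC_REGIONS.items()}


def _region_for_code(code: int) -> str:
    return _SWC_REGIONS.get(code, f"region{code}")


def _code_for_region(region: str) -> int:
    if region in _REGION_CODES:
        return _REGION_CODES[region]
    if region.startswith("region"):
        try:
            return int(region[len("region"):])
        except ValueError:
            pass
    return 5  # custom


def frustum_lateral_area(r1: float, r2: float, length: float) -> float:
    """Lateral surface area pi*(r1+r2)*sqrt(L^2 + (r2-r1)^2), all in um."""
    return math.pi * (r1 + r2) * math.hypot(length, r2 - r1)


class Section:
    """An unbranched conical frustum between two 3D points (um).

    ``spherical`` marks sections synthesised from a single SWC sample
    (sphere-of-equal-area convention: cylinder with L = d = 2r); it only
    affects how the section is written back to SWC.
    """

    __slots__ = (
        "id", "proximal", "distal", "proximal_radius", "distal_radius",
        "region", "parent", "spherical",
    )

    def __init__(
        self,
        id: str,
        proximal,
        distal,
        proximal_radius: float,
        distal_radius: float,
        region: str,
        parent: Optional["Section"] = None,
        spherical: bool = False,
    ):
        self.id = str(id)
        self.proximal = np.asarray(proximal, dtype=float)
        self.distal = np.asarray(distal, dtype=float)
        self.proximal_radius = float(proximal_radius)
        self.distal_radius = float(distal_radius)
        self.region = str(region)
        self.parent = parent
        self.spherical = bool(spherical)
        if self.proximal.shape != (3,) or self.distal.shape != (3,):
            raise MorphologyError(f"section {id!r}: endpoints must be 3-vectors")
        if self.proximal_radius <= 0 or self.distal_radius <= 0:
            raise MorphologyError(f"section {id!r}: radii must be positive")
        if self.length <= 0:
            raise MorphologyError(f"section {id!r}: axial length must be > 0")

    @property
    def length(self) -> float:
        """Euclidean distance between endpoints (um)."""
        return float(np.linalg.norm(self.distal - self.proximal))

    @property
    def lateral_area(self) -> float:
        """Frustum lateral surface area (um^2)."""
        return frustum_lateral_area(
            self.proximal_radius, self.distal_radius, self.length
        )

    def radius_at(self, fraction: float) -> float:
        """Linearly interpolated radius at ``fraction`` along the section."""
        return self.proximal_radius + fraction * (
            self.distal_radius - self.proximal_radius
        )

    def __repr__(self):
        return (
            f"Section({self.id!r}, region={self.region!r}, "
            f"L={self.length:.3g}um)"
        )


class Morphology:
    """An ordered tree of sections; parents always precede children."""

    def __init__(self, name: str = "morphology"):
        self.name = name
        self._sections: list[Section] = []
        self._by_id: dict[str, Section] = {}

    # -- construction -----------------------------------------------------
    def add_section(
        self,
        id: str,
        proximal,
        distal,
        proximal_radius: float,
        distal_radius: float,
        region: str,
        parent: Optional[Section | str] = None,
        spherical: bool = False,
    ) -> Section:
        if id in self._by_id:
            raise MorphologyError(f"duplicate section id {id!r}")
        if isinstance(parent, str):
            parent = self[parent]
        if parent is not None and parent.id not in self._by_id:
            raise MorphologyError(
                f"parent {parent.id!r} of section {id!r} is not in this "
                "morphology"
            )
        if parent is None and any(s.parent is None for s in self._sections):
            raise MorphologyError(
                "morphology already has a root section; every other section "
                "needs a parent"
            )
        sec = Section(
            id, proximal, distal, proximal_radius, distal_radius, region,
            parent=parent, spherical=spherical,
        )
        self._sections.append(sec)
        self._by_id[sec.id] = sec
        return sec

    # -- access -----------------------------------------------------------
    @property
    def sections(self) -> list[Section]:
        return list(self._sections)

    def __getitem__(self, section_id: str) -> Section:
        try:
            return self._by_id[section_id]
        except KeyError:
            raise KeyError(
                f"no section {section_id!r} in morphology {self.name!r}"
            ) from None

    def __contains__(self, section_id: str) -> bool:
        return section_id in self._by_id

    def __len__(self) -> int:
        return len(self._sections)

    def __iter__(self):
        return iter(self._sections)

    @property
    def root(self) -> Section:
        roots = [s for s in self._sections if s.parent is None]
        if len(roots) != 1:
            raise MorphologyError(
                f"morphology {self.name!r} has {len(roots)} roots, expected 1"
            )
        return roots[0]

    @property
    def regions(self) -> set[str]:
        return {s.region for s in self._sections}

    def children_of(self, section: Section) -> list[Section]:
        return [s for s in self._sections if s.parent is section]

    def validate(self) -> None:
        """Check tree invariants; raise MorphologyError on violation."""
        if not self._sections:
            raise MorphologyError(f"morphology {self.name!r} has no sections")
        _ = self.root
        for s in self._sections:
            if s.parent is not None and s.parent.id not in self._by_id:
                raise MorphologyError(
                    f"section {s.id!r} has a parent outside the morphology"
                )
        # parents-first ordering implies acyclicity; verify anyway
        seen: set[str] = set()
        for s in self._sections:
            if s.parent is not None and s.parent.id not in seen:
                raise MorphologyError(
                    f"section {s.id!r} appears before its parent"
                )
            seen.add(s.id)

    def surface_area(self, region_filter: str | None = None) -> Quantity:
        return surface_area(self, region_filter)

    def __repr__(self):
        return f"Morphology({self.name!r}, {len(self._sections)} sections)"


@dataclass(frozen=True)
class MorphLocation:
    """A point on a morphology: a section plus a fraction along it."""

    section: Section
    fraction_along: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.fraction_along <= 1.0):
            raise DomainError(
                f"fraction_along must be in [0, 1], got {self.fraction_along}"
            )


def build_soma_from_area(
    area, region: str = "soma", name: str = "soma"
) -> Morphology:
    """Single-cylinder morphology with the requested lateral surface area.

    The cylinder has length equal to diameter, so ``pi * d^2 == area``.
    ``area`` may be a Quantity, a string like ``"1000 um2"``, or a bare
    number interpreted in um^2.
    """
    q = ensure_quantity(area, default_unit="um2")
    if q.dimensions != AREA:
        raise DimensionError(
            f"soma area must have area dimensions, got {q.unit_label!r}"
        )
    area_um2 = q.magnitude_in("um2")
    if area_um2 <= 0:
        raise DomainError(f"soma area must be positive, got {area_um2} um2")
    d = math.sqrt(area_um2 / math.pi)
    m = Morphology(name=name)
    m.add_section(
        id="soma",
        proximal=(0.0, 0.0, 0.0),
        distal=(d, 0.0, 0.0),
        proximal_radius=d / 2,
        distal_radius=d / 2,
        region=region,
    )
    return m


def surface_area(m: Morphology, region_filter: str | None = None) -> Quantity:
    """Total frustum lateral area, optionally restricted to one region.

    Raises ``KeyError`` for a region name not present in the morphology.
    """
    if region_filter is not None and region_filter not in m.regions:
        raise KeyError(
            f"no region {region_filter!r} in morphology {m.name!r}; "
            f"known regions: {sorted(m.regions)}"
        )
    total = sum(
        s.lateral_area
        for s in m
        if region_filter is None or s.region == region_filter
    )
    return Quantity(total, "um2")


def resolve_location(loc: MorphLocation, nseg: int) -> tuple[int, float]:
    """Map a MorphLocation onto (segment index, local fraction within it).

    Segment i covers the half-open arc interval [i/nseg, (i+1)/nseg);
    fraction 1.0 folds into the last segment.
    """
    if nseg < 1:
        raise DomainError(f"nseg must be >= 1, got {nseg}")
    f = loc.fraction_along
    idx = min(int(f * nseg), nseg - 1)
    local = f * nseg - idx
    return idx, local


# ---------------------------------------------------------------------------
# SWC import / export
# ---------------------------------------------------------------------------

@dataclass
class _Sample:
    id: int
    type: int
    xyz: np.ndarray
    radius: float
    parent: int
    line: int
    children: list[int] = field(default_factory=list)


def _parse_swc_samples(path) -> dict[int, _Sample]:
    samples: dict[int, _Sample] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 7:
                raise MorphologyError(
                    f"{path}:{lineno}: expected 7 columns, got {len(fields)}"
                )
            try:
                sid = int(fields[0])
                stype = int(fields[1])
                xyz = np.array([float(v) for v in fields[2:5]])
                radius = float(fields[5])
                parent = int(fields[6])
            except ValueError as exc:
                raise MorphologyError(f"{path}:{lineno}: {exc}") from None
            if radius <= 0:
                raise MorphologyError(
                    f"{path}:{lineno}: non-positive radius {radius}"
                )
            if sid in samples:
                raise MorphologyError(f"{path}:{lineno}: duplicate id {sid}")
            samples[sid] = _Sample(sid, stype, xyz, radius, parent, lineno)
    if not samples:
        raise MorphologyError(f"{path}: no samples")
    roots = [s for s in samples.values() if s.parent == -1]
    if len(roots) != 1:
        raise MorphologyError(
            f"{path}: expected exactly one root (parent -1), found "
            f"{len(roots)}"
        )
    for s in samples.values():
        if s.parent != -1:
            if s.parent not in samples:
                raise MorphologyError(
                    f"{path}:{s.line}: parent id {s.parent} references a "
                    "missing sample"
                )
            samples[s.parent].children.append(s.id)
    return samples


def _sphere_section(
    m: Morphology, sid: str, sample: _Sample, parent: Section | None
) -> Section:
    r = sample.radius
    c = sample.xyz
    return m.add_section(
        id=sid,
        proximal=c - np.array([r, 0.0, 0.0]),
        distal=c + np.array([r, 0.0, 0.0]),
        proximal_radius=r,
        distal_radius=r,
        region=_region_for_code(sample.type),
        parent=parent,
        spherical=True,
    )


def read_swc(path) -> Morphology:
    """Read a 7-column SWC file into a Morphology.

    Sample chains are split into sections at branch points and at type
    changes. An edge between samples of the same type becomes one frustum
    section whose region is that type's name. A cross-type edge is treated
    as a non-membrane attachment: the child sample starts a new subtree
    whose sections begin at its own coordinates. A sample with no same-type
    neighbour on either side (including a single-sample file) becomes a
    sphere-equivalent cylinder with L = d = 2r.
    """
    samples = _parse_swc_samples(path)
    root = next(s for s in samples.values() if s.parent == -1)
    m = Morphology(name=Path(str(path)).stem)

    section_of: dict[int, Section | None] = {}

    def same_type_children(s: _Sample) -> list[_Sample]:
        return [samples[c] for c in s.children if samples[c].type == s.type]

    # Root sample: fold into the first edge when it has exactly one child
    # of its own type, otherwise synthesise a sphere so the tree keeps a
    # single root.
    if len(root.children) == 1 and same_type_children(root):
        section_of[root.id] = None  # the same-type edge becomes the root
    else:
        section_of[root.id] = _sphere_section(m, f"sec{root.id}", root, None)

    # BFS, parents before children.
    queue = list(root.children)
    while queue:
        sid = queue.pop(0)
        s = samples[sid]
        queue.extend(s.children)
        p = samples[s.parent]
        if s.type == p.type:
            parent_section = section_of[p.id]
            section_of[s.id] = m.add_section(
                id=f"sec{s.id}",
                proximal=p.xyz,
                distal=s.xyz,
                proximal_radius=p.radius,
                distal_radius=s.radius,
                region=_region_for_code(s.type),
                parent=parent_section,
            )
        else:
            # cross-type attachment: this sample starts a new run
            if same_type_children(s):
                # its same-type edges will carry the geometry (with this
                # sample's coordinates as proximal endpoint); the run hangs
                # off the section owning the parent sample
                section_of[s.id] = section_of[p.id]
            else:
                section_of[s.id] = _sphere_section(
                    m, f"sec{s.id}", s, section_of[p.id]
                )
    m.validate()
    return m


def write_swc(m: Morphology, path) -> None:
    """Write a Morphology to SWC (inverse of :func:`read_swc`).

    Spherical sections are emitted as a single sample; frustum sections
    emit their distal endpoint, inserting a junction sample when their
    proximal endpoint does not coincide with the parent's emitted sample.
    """
    m.validate()
    lines = ["# written by cablekit"]
    next_id = 1
    distal_sample: dict[str, int] = {}
    sample_info: dict[int, tuple[np.ndarray, float]] = {}

    def emit(stype, xyz, radius, parent) -> int:
        nonlocal next_id
        sid = next_id
        next_id += 1
        lines.append(
            f"{sid} {stype} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f} "
            f"{radius:.6f} {parent}"
        )
        sample_info[sid] = (np.asarray(xyz, dtype=float), float(radius))
        return sid

    for sec in m:
        code = _code_for_region(sec.region)
        if sec.parent is None:
            if sec.spherical:
                centre = (sec.proximal + sec.distal) / 2.0
                distal_sample[sec.id] = emit(
                    code, centre, sec.proximal_radius, -1
                )
                continue
            prox_id = emit(code, sec.proximal, sec.proximal_radius, -1)
        else:
            parent_id = distal_sample[sec.parent.id]
            pxyz, prad = sample_info[parent_id]
            if sec.spherical:
                centre = (sec.proximal + sec.distal) / 2.0
                distal_sample[sec.id] = emit(
                    code, centre, sec.proximal_radius, parent_id
                )
                continue
            coincides = (
                np.allclose(pxyz, sec.proximal, atol=1e-9)
                and abs(prad - sec.proximal_radius) < 1e-9
            )
            if coincides:
                prox_id = parent_id
            else:
                prox_id = emit(
                    code, sec.proximal, sec.proximal_radius, parent_id
                )
        distal_sample[sec.id] = emit(
            code, sec.distal, sec.distal_radius, prox_id
        )
    Path(str(path)).write_text("\n".join(lines) + "\n")
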