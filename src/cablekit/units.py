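"""Dimensioned quantities with a fixed unit whitelist.

Every model parameter and recorded value in cablekit carries explicit
physical dimensions. Internally a :class:`Quantity` stores its value in SI
base units together with an exponent vector over the base dimensions
``(length, mass, time, current, amount)``; the display unit is kept only as
a label, so converting between compatible units never touches the stored
value and round-trips are exact.

The accepted unit tokens are a documented whitelist (see ``UNIT_TABLE``)
combined with ``*``/``/`` products and integer powers, e.g. ``mS/cm2``,
``pA``, ``ms^-1``. The Unicode characters ``μ`` (and ``µ``), ``Ω`` and
superscript digits are accepted as aliases for ``u``, ``Ohm`` and plain
digits.

Examples
--------
>>> q = parse_quantity("0.3 mS/cm2")
>>> q.to("S/cm2").magnitude
0.0003
>>> area_specific_conductance(parse_quantity("300 MOhm"),
...                           parse_quantity("1200 um2")).magnitude
0.2777...
"""

from __future__ import annotations

import re
from typing import Union

import numpy as np

from .errors import DimensionError, DomainError, UnitParseError

__all__ = [
    "Quantity",
    "parse_quantity",
    "convert",
    "area_specific_conductance",
    "ensure_quantity",
    "UNIT_TABLE",
]

# Exponent vectors over (m, kg, s, A, mol).
Dim = tuple  # 5-tuple of ints

DIMLESS: Dim = (0, 0, 0, 0, 0)
LENGTH: Dim = (1, 0, 0, 0, 0)
AREA: Dim = (2, 0, 0, 0, 0)
TIME: Dim = (0, 0, 1, 0, 0)
CURRENT: Dim = (0, 0, 0, 1, 0)
FREQUENCY: Dim = (0, 0, -1, 0, 0)
VOLTAGE: Dim = (2, 1, -3, -1, 0)
RESISTANCE: Dim = (2, 1, -3, -2, 0)
CONDUCTANCE: Dim = (-2, -1, 3, 2, 0)
CAPACITANCE: Dim = (-2, -1, 4, 2, 0)


def _dim_add(a: Dim, b: Dim) -> Dim:
    return tuple(x + y for x, y in zip(a, b))


def _dim_sub(a: Dim, b: Dim) -> Dim:
    return tuple(x - y for x, y in zip(a, b))


def _dim_mul(a: Dim, n: int) -> Dim:
    return tuple(x * n for x in a)


CONDUCTANCE_DENSITY: Dim = _dim_sub(CONDUCTANCE, AREA)
CAPACITANCE_DENSITY: Dim = _dim_sub(CAPACITANCE, AREA)
CURRENT_DENSITY: Dim = _dim_sub(CURRENT, AREA)
RESISTIVITY: Dim = _dim_add(RESISTANCE, LENGTH)

#: token -> (scale to SI, dimension vector)
UNIT_TABLE: dict[str, tuple[float, Dim]] = {
    "1": (1.0, DIMLESS),
    # voltage
    "V": (1.0, VOLTAGE),
    "mV": (1e-3, VOLTAGE),
    "uV": (1e-6, VOLTAGE),
    # current
    "A": (1.0, CURRENT),
    "mA": (1e-3, CURRENT),
    "uA": (1e-6, CURRENT),
    "nA": (1e-9, CURRENT),
    "pA": (1e-12, CURRENT),
    # time
    "s": (1.0, TIME),
    "ms": (1e-3, TIME),
    "us": (1e-6, TIME),
    # length
    "m": (1.0, LENGTH),
    "cm": (1e-2, LENGTH),
    "mm": (1e-3, LENGTH),
    "um": (1e-6, LENGTH),
    "nm": (1e-9, LENGTH),
    # area (plain tokens; "um^2" also works via the power syntax)
    "m2": (1.0, AREA),
    "cm2": (1e-4, AREA),
    "mm2": (1e-6, AREA),
    "um2": (1e-12, AREA),
    # capacitance
    "F": (1.0, CAPACITANCE),
    "mF": (1e-3, CAPACITANCE),
    "uF": (1e-6, CAPACITANCE),
    "nF": (1e-9, CAPACITANCE),
    "pF": (1e-12, CAPACITANCE),
    # conductance
    "S": (1.0, CONDUCTANCE),
    "mS": (1e-3, CONDUCTANCE),
    "uS": (1e-6, CONDUCTANCE),
    "nS": (1e-9, CONDUCTANCE),
    "pS": (1e-12, CONDUCTANCE),
    # resistance
    "Ohm": (1.0, RESISTANCE),
    "kOhm": (1e3, RESISTANCE),
    "MOhm": (1e6, RESISTANCE),
    "GOhm": (1e9, RESISTANCE),
    # frequency
    "Hz": (1.0, FREQUENCY),
    "kHz": (1e3, FREQUENCY),
}

_SUPERSCRIPTS = {"²": "2", "³": "3", "¹": "1", "⁻": "-"}


def _normalise_unit_text(text: str) -> str:
    for mu in ("μ", "µ"):
        text = text.replace(mu, "u")
    text = text.replace("Ω", "Ohm").replace("Ω", "Ohm")
    for sup, plain in _SUPERSCRIPTS.items():
        text = text.replace(sup, "^" + plain)
    text = text.replace("·", "*").replace("⋅", "*")
    return text.strip()


_TOKEN_RE = re.compile(r"([A-Za-z]+[0-9]*)(?:\^(-?\d+))?$")


def _lookup_token(name: str, expstr: str | None, sign: int) -> tuple[float, Dim, int]:
    """Resolve one unit token to (scale, dim, signed power)."""
    if name in UNIT_TABLE:
        scale, dim = UNIT_TABLE[name]
        return scale, dim, (int(expstr) if expstr else 1) * sign
    # trailing-digit power for names not themselves whitelisted, e.g. "ms2"
    m = re.match(r"^([A-Za-z]+)(\d+)$", name)
    if m and m.group(1) in UNIT_TABLE:
        if expstr:
            raise UnitParseError(
                f"cannot combine trailing digits and '^' in {name!r}"
            )
        scale, dim = UNIT_TABLE[m.group(1)]
        return scale, dim, int(m.group(2)) * sign
    raise UnitParseError(f"unknown unit token: {name!r}")


def parse_unit(text: str) -> tuple[float, Dim]:
    """Parse a unit expression into (scale-to-SI, dimension vector).

    Grammar: ``unit := token (('*'|'/') token)*`` where each token is a
    whitelisted name with an optional integer power (``^n`` or trailing
    digits).
    """
    text = _normalise_unit_text(text)
    if not text:
        raise UnitParseError("empty unit expression")
    parts = re.split(r"([*/])", text.replace(" ", ""))
    scale = 1.0
    dim: Dim = DIMLESS
    sign = 1
    expect_token = True
    for part in parts:
        if part == "":
            raise UnitParseError(f"malformed unit expression: {text!r}")
        if part in ("*", "/"):
            if expect_token:
                raise UnitParseError(f"malformed unit expression: {text!r}")
            sign = -1 if part == "/" else 1
            expect_token = True
            continue
        m = _TOKEN_RE.match(part)
        if not m:
            raise UnitParseError(f"unknown unit token: {part!r}")
        base_scale, base_dim, power = _lookup_token(m.group(1), m.group(2), sign)
        scale *= base_scale**power
        dim = _dim_add(dim, _dim_mul(base_dim, power))
        expect_token = False
    if expect_token:
        raise UnitParseError(f"trailing operator in unit expression: {text!r}")
    return scale, dim


_BASE_NAMES = ("m", "kg", "s", "A", "mol")


def _canonical_label(dim: Dim) -> str:
    if dim == DIMLESS:
        return "1"
    parts = []
    for name, exp in zip(_BASE_NAMES, dim):
        if exp == 0:
            continue
        parts.append(name if exp == 1 else f"{name}^{exp}")
    return "*".join(parts)


Number = Union[int, float, np.ndarray]


class Quantity:
    """A number (or numeric array) with physical dimensions.

    The value is stored in SI base units; ``unit_label`` controls only how
    ``magnitude`` is reported. Use :meth:`to` to change the display unit.
    """

    __slots__ = ("_si", "_dim", "_label")

    def __init__(self, value: Number, unit: str | None = None):
        if unit is None:
            self._si = value
            self._dim = DIMLESS
            self._label = None
        else:
            scale, dim = parse_unit(unit)
            self._si = value * scale
            self._dim = dim
            self._label = _normalise_unit_text(unit)

    @classmethod
    def _from_si(cls, si: Number, dim: Dim, label: str | None = None) -> "Quantity":
        q = cls.__new__(cls)
        q._si = si
        q._dim = dim
        q._label = label
        return q

    # -- introspection ----------------------------------------------------
    @property
    def si(self) -> Number:
        """Value in SI base units."""
        return self._si

    @property
    def dimensions(self) -> Dim:
        return self._dim

    @property
    def unit_label(self) -> str:
        return self._label if self._label is not None else _canonical_label(self._dim)

    @property
    def magnitude(self) -> Number:
        """Value expressed in the display unit."""
        if self._label is None:
            return self._si
        scale, _ = parse_unit(self._label)
        return self._si / scale

    # -- conversion -------------------------------------------------------
    def to(self, unit: str) -> "Quantity":
        """Return an equal quantity displayed in ``unit``.

        Raises
        ------
        DimensionError
            If ``unit`` has different dimensions; the message lists both
            exponent vectors.
        """
        scale, dim = parse_unit(unit)
        if dim != self._dim:
            raise DimensionError(
                f"cannot convert {self.unit_label!r} (dims {self._dim}) "
                f"to {unit!r} (dims {dim})"
            )
        return Quantity._from_si(self._si, self._dim, _normalise_unit_text(unit))

    def magnitude_in(self, unit: str) -> Number:
        return self.to(unit).magnitude

    # -- arithmetic -------------------------------------------------------
    def _check_same_dim(self, other: "Quantity", op: str) -> None:
        if self._dim != other._dim:
            raise DimensionError(
                f"cannot {op} quantities with dims {self._dim} and {other._dim}"
            )

    def __add__(self, other):
        if not isinstance(other, Quantity):
            return NotImplemented
        self._check_same_dim(other, "add")
        return Quantity._from_si(self._si + other._si, self._dim, self._label)

    def __sub__(self, other):
        if not isinstance(other, Quantity):
            return NotImplemented
        self._check_same_dim(other, "subtract")
        return Quantity._from_si(self._si - other._si, self._dim, self._label)

    def __mul__(self, other):
        if isinstance(other, Quantity):
            return Quantity._from_si(
                self._si * other._si, _dim_add(self._dim, other._dim)
            )
        if isinstance(other, (int, float, np.ndarray, np.floating, np.integer)):
            return Quantity._from_si(self._si * other, self._dim, self._label)
        return NotImplemented

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Quantity):
            return Quantity._from_si(
                self._si / other._si, _dim_sub(self._dim, other._dim)
            )
        if isinstance(other, (int, float, np.ndarray, np.floating, np.integer)):
            return Quantity._from_si(self._si / other, self._dim, self._label)
        return NotImplemented

    def __rtruediv__(self, other):
        if isinstance(other, (int, float, np.ndarray, np.floating, np.integer)):
            return Quantity._from_si(other / self._si, _dim_mul(self._dim, -1))
        return NotImplemented

    def __pow__(self, n):
        if not isinstance(n, int):
            return NotImplemented
        return Quantity._from_si(self._si**n, _dim_mul(self._dim, n))

    def __neg__(self):
        return Quantity._from_si(-self._si, self._dim, self._label)

    def __abs__(self):
        return Quantity._from_si(abs(self._si), self._dim, self._label)

    # -- comparison -------------------------------------------------------
    def __eq__(self, other):
        if not isinstance(other, Quantity):
            return NotImplemented
        return self._dim == other._dim and np.all(self._si == other._si)

    def __lt__(self, other):
        self._check_same_dim(other, "compare")
        return self._si < other._si

    def __le__(self, other):
        self._check_same_dim(other, "compare")
        return self._si <= other._si

    def __gt__(self, other):
        self._check_same_dim(other, "compare")
        return self._si > other._si

    def __ge__(self, other):
        self._check_same_dim(other, "compare")
        return self._si >= other._si

    def __hash__(self):
        return hash((float(self._si), self._dim))

    def is_close(self, other: "Quantity", rel: float = 1e-12) -> bool:
        self._check_same_dim(other, "compare")
        return bool(
            np.all(np.abs(self._si - other._si) <= rel * np.maximum(
                np.abs(self._si), np.abs(other._si)))
        )

    def __repr__(self):
        return f"Quantity({self.magnitude!r}, {self.unit_label!r})"

    def __str__(self):
        return f"{self.magnitude:g} {self.unit_label}"


_NUMBER_RE = re.compile(
    r"^\s*([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*(.*)$"
)


def parse_quantity(text: str) -> Quantity:
    """Parse ``"<number> <unit-expression>"`` into a :class:`Quantity`.

    >>> parse_quantity("300 MOhm").si
    300000000.0
    """
    if not isinstance(text, str):
        raise UnitParseError(f"expected a string, got {type(text).__name__}")
    m = _NUMBER_RE.match(text)
    if not m:
        raise UnitParseError(f"missing magnitude in quantity {text!r}")
    value = float(m.group(1))
    unit = m.group(2).strip()
    if not unit:
        raise UnitParseError(f"missing unit in quantity {text!r}")
    return Quantity(value, unit)


def convert(q: Union[Quantity, str], target_unit: str) -> Quantity:
    """Convert ``q`` (a Quantity or parseable string) to ``target_unit``."""
    if isinstance(q, str):
        q = parse_quantity(q)
    return q.to(target_unit)


def ensure_quantity(
    value, default_unit: str | None = None, expect_dim: Dim | None = None
) -> Quantity:
    """Coerce strings / bare numbers into a Quantity, with a dimension check.

    Bare numbers are interpreted in ``default_unit`` (an error if none is
    given, to keep unit handling explicit at API boundaries).
    """
    if isinstance(value, Quantity):
        q = value
    elif isinstance(value, str):
        q = parse_quantity(value)
    elif isinstance(value, (int, float, np.floating, np.integer)):
        if default_unit is None:
            raise UnitParseError(
                f"bare number {value!r} given where a unit-bearing quantity "
                "is required"
            )
        q = Quantity(float(value), default_unit)
    else:
        raise UnitParseError(f"cannot interpret {value!r} as a quantity")
    if expect_dim is not None and q.dimensions != expect_dim:
        raise DimensionError(
            f"expected dims {expect_dim}, got {q.dimensions} "
            f"({q.unit_label!r})"
        )
    return q


def area_specific_conductance(
    input_resistance: Union[Quantity, str], area: Union[Quantity, str]
) -> Quantity:
    """Specific membrane conductance 1/(R_in * A), displayed in mS/cm2.

    >>> area_specific_conductance("300 MOhm", "1200 um2").magnitude
    0.2777...
    """
    r = ensure_quantity(input_resistance, expect_dim=RESISTANCE)
    a = ensure_quantity(area, expect_dim=AREA)
    if not (r.si > 0):
        raise DomainError(f"input resistance must be positive, got {r}")
    if not (a.si > 0):
        raise DomainError(f"area must be positive, got {a}")
    return (1.0 / (r * a)).to("mS/cm2")
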