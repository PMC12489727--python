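"""Elemental-formula arithmetic and exact m/z computation for singly charged ions.

All mass bookkeeping in the package goes through :class:`ElementalFormula`.
Monoisotopic masses are pinned IUPAC values for the most abundant isotope of
each supported element, so computed ion masses are bit-stable across platforms.
Only singly charged (de)protonated species are modelled: ``[M-H]-`` in negative
mode and ``[M+H]+`` in positive mode, with the electron mass included in the
ion m/z (required to reproduce Orbitrap "calcd" values at four decimals).
"""

from __future__ import annotations

import math
import re
from collections.abc import Mapping
from typing import Iterator

__all__ = [
    "ElementalFormula",
    "ELECTRON_MASS",
    "ISOTOPE_MASS",
    "monoisotopic_mass",
    "mz_ion",
    "nominal_mz",
    "ppm_error",
    "formula_subtract",
    "round_half_up",
]

#: Monoisotopic mass (Da) of the most abundant isotope, IUPAC 2021 values.
ISOTOPE_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.00307400443,
    "O": 15.99491461957,
    "S": 31.97207117354,
}

#: Electron rest mass in Da.
ELECTRON_MASS: float = 0.000548579909

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalFormula(Mapping):
    """Immutable element -> count mapping with count-wise arithmetic.

    Accepts a Hill-notation string (``"C28H26O15"``), a mapping, or keyword
    counts. Zero counts are dropped; negative counts are rejected.

    >>> ElementalFormula("C28H26O15")["C"]
    28
    >>> str(ElementalFormula(H=2, O=1))
    'H2O'
    """

    __slots__ = ("_counts",)

    def __init__(self, source: str | Mapping[str, int] | None = None, **counts: int):
        merged: dict[str, int] = {}
        if isinstance(source, str):
            merged.update(_parse_hill(source))
        elif source is not None:
            merged.update(source)
        for element, n in counts.items():
            merged[element] = merged.get(element, 0) + n
        for element, n in merged.items():
            if not isinstance(n, int):
                raise TypeError(f"count for {element} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for element {element}: {n}")
        self._counts: dict[str, int] = {e: n for e, n in merged.items() if n > 0}

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, element: object) -> bool:
        return element in self._counts

    # Equality is count-wise, so C1H0O2 == CO2.
    def __eq__(self, other: object) -> bool:
        if isinstance(other, str):
            other = ElementalFormula(other)
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {e: n for e, n in other.items() if n}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    # Arithmetic -----------------------------------------------------------
    def __add__(self, other: "ElementalFormula | str") -> "ElementalFormula":
        other = _coerce(other)
        counts = dict(self._counts)
        for e, n in other._counts.items():
            counts[e] = counts.get(e, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula | str") -> "ElementalFormula":
        return formula_subtract(self, _coerce(other))

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            raise ValueError(f"multiplier must be a non-negative integer, got {k!r}")
        return ElementalFormula({e: n * k for e, n in self._counts.items()})

    __rmul__ = __mul__

    def __str__(self) -> str:
        return _hill_string(self._counts)

    def __repr__(self) -> str:
        return f"ElementalFormula({_hill_string(self._counts)!r})"

    def __bool__(self) -> bool:
        return bool(self._counts)


def _coerce(f: ElementalFormula | str | Mapping[str, int]) -> ElementalFormula:
    return f if isinstance(f, ElementalFormula) else ElementalFormula(f)


def _parse_hill(text: str) -> dict[str, int]:
    """Parse ``C28H26O15``-style strings (Hill order not enforced on input)."""
    counts: dict[str, int] = {}
    pos = 0
    stripped = text.strip()
    for match in _TOKEN.finditer(stripped):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        if not match.group(0):
            break
        element, digits = match.group(1), match.group(2)
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(stripped) or (stripped and not counts):
        raise ValueError(f"cannot parse formula {text!r}")
    return counts


def _hill_string(counts: Mapping[str, int]) -> str:
    """Hill order: C first, H second, then remaining elements alphabetically."""

    def render(element: str) -> str:
        n = counts[element]
        return element if n == 1 else f"{element}{n}"

    parts: list[str] = []
    if "C" in counts:
        parts.append(render("C"))
        if "H" in counts:
            parts.append(render("H"))
        parts.extend(render(e) for e in sorted(counts) if e not in ("C", "H"))
    else:
        parts.extend(render(e) for e in sorted(counts))
    return "".join(parts)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used for reported m/z)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def monoisotopic_mass(f: ElementalFormula | str) -> float:
    """Monoisotopic mass in Da: sum of most-abundant-isotope masses.

    Raises ``KeyError`` naming the offending symbol for unsupported elements.
    """
    f = _coerce(f)
    total = 0.0
    for element, n in f.items():
        try:
            total += ISOTOPE_MASS[element] * n
        except KeyError:
            raise KeyError(f"unknown element symbol: {element!r}") from None
    return total


def mz_ion(f: ElementalFormula | str, polarity: str = "negative") -> float:
    """m/z of the singly charged (de)protonated ion of neutral formula *f*.

    Negative mode gives ``[M-H]-`` (minus one H atom, plus one electron);
    positive mode gives ``[M+H]+`` (plus one H atom, minus one electron).
    """
    f = _coerce(f)
    m = monoisotopic_mass(f)
    if polarity == "negative":
        if f["H"] < 1:
            raise ValueError(
                f"cannot deprotonate {f}: no hydrogen in the neutral formula"
            )
        return m - ISOTOPE_MASS["H"] + ELECTRON_MASS
    if polarity == "positive":
        return m + ISOTOPE_MASS["H"] - ELECTRON_MASS
    raise ValueError(f"polarity must be 'negative' or 'positive', got {polarity!r}")


def nominal_mz(f: ElementalFormula | str, polarity: str = "negative") -> int:
    """Integer (nominal) m/z: exact ion m/z rounded half-up."""
    return int(round_half_up(mz_ion(f, polarity)))


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


def formula_subtract(
    a: ElementalFormula | str, b: ElementalFormula | str
) -> ElementalFormula:
    """Count-wise difference ``a - b``; raises if any count would go negative."""
    a, b = _coerce(a), _coerce(b)
    counts: dict[str, int] = dict(a)
    for element, n in b.items():
        remaining = counts.get(element, 0) - n
        if remaining < 0:
            raise ValueError(
                f"loss not contained: subtracting {b} from {a} leaves "
                f"negative {element} count"
            )
        counts[element] = remaining
    return ElementalFormula(counts)
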