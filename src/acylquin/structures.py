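"""Structural descriptors for acyl-quinic acids and flavonoid malonyl-glucosides.

Two compound families are modelled:

* :class:`AcylQuinate` — a quinic-acid (or *epi*-quinic) core, i.e.
  1,3,4,5-tetrahydroxycyclohexanecarboxylic acid, whose four hydroxyl
  positions {1, 3, 4, 5} may each carry one caffeoyl or malonyl ester.
* :class:`FlavonoidGlycoside` — a flavonoid aglycone (quercetin, luteolin or
  kaempferol) bearing one O-glucosyl unit, itself optionally malonylated at
  the sugar 2'' and/or 6'' hydroxyls.

Formulas follow ester bookkeeping: each ester or glycosidic bond condenses
out one H2O. Regiochemistry never changes the molecular formula, which is why
regioisomers are indistinguishable by exact mass and need the fragmentation
and NMR keys elsewhere in this package.

Descriptor strings give a compact round-trippable notation::

    QA[1:caf,3:mal,5:caf]      1,5-dicaffeoyl-3-malonylquinic acid
    eQA[3:caf,4:mal,5:caf]     the epi-quinic analogue
    LUT-7-Glc[2'':mal,6'':mal] luteolin-7-O-(2'',6''-di-O-malonyl)-glucoside
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field

from .formula import ElementalFormula

__all__ = [
    "AcylQuinate",
    "FlavonoidGlycoside",
    "neutral_formula",
    "enumerate_regioisomers",
    "catechol_count",
    "parse_descriptor",
    "CAFFEIC_ACID",
    "MALONIC_ACID",
    "QUINIC_ACID",
    "GLUCOSE",
    "AGLYCONES",
    "WATER",
]

WATER = ElementalFormula("H2O")
QUINIC_ACID = ElementalFormula("C7H12O6")
CAFFEIC_ACID = ElementalFormula("C9H8O4")
MALONIC_ACID = ElementalFormula("C3H4O4")
GLUCOSE = ElementalFormula("C6H12O6")

#: Parent acids of the supported acyl groups.
ACYL_PARENT_ACID: dict[str, ElementalFormula] = {
    "caffeoyl": CAFFEIC_ACID,
    "malonyl": MALONIC_ACID,
}

AGLYCONES: dict[str, ElementalFormula] = {
    "quercetin": ElementalFormula("C15H10O7"),
    "luteolin": ElementalFormula("C15H10O6"),
    "kaempferol": ElementalFormula("C15H10O6"),
}

#: Aglycones whose B ring is an ortho-dihydroxybenzene (catechol) unit.
#: Kaempferol carries a single 4'-OH instead.
_CATECHOL_AGLYCONES = frozenset({"quercetin", "luteolin"})

_QUINATE_POSITIONS = (1, 3, 4, 5)
_SUGAR_POSITIONS = ("2''", "6''")


@dataclass(frozen=True)
class AcylQuinate:
    """Quinic or epi-quinic core with an acyl-substituent map over {1,3,4,5}.

    The core stereo label ({'quinic', 'epi-quinic'}) is metadata for the NMR
    key; it never affects the formula or the fragment grammar.
    """

    substituents: dict[int, str] = field(default_factory=dict)
    core: str = "quinic"

    def __post_init__(self) -> None:
        if self.core not in ("quinic", "epi-quinic"):
            raise ValueError(f"unknown core label {self.core!r}")
        for pos, label in self.substituents.items():
            if pos not in _QUINATE_POSITIONS:
                raise ValueError(f"invalid acylation position {pos}; allowed: 1,3,4,5")
            if label not in ACYL_PARENT_ACID:
                raise ValueError(f"unknown acyl group {label!r}")
        # freeze for hashability
        object.__setattr__(self, "substituents", dict(sorted(self.substituents.items())))

    def __hash__(self) -> int:
        return hash((self.core, tuple(self.substituents.items())))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AcylQuinate):
            return NotImplemented
        return self.core == other.core and self.substituents == other.substituents

    def count(self, label: str) -> int:
        return sum(1 for v in self.substituents.values() if v == label)

    @property
    def n_caffeoyl(self) -> int:
        return self.count("caffeoyl")

    @property
    def n_malonyl(self) -> int:
        return self.count("malonyl")

    def neutral_formula(self) -> ElementalFormula:
        f = QUINIC_ACID
        for label in self.substituents.values():
            f = f + ACYL_PARENT_ACID[label] - WATER
        return f

    def descriptor(self) -> str:
        prefix = "QA" if self.core == "quinic" else "eQA"
        inner = ",".join(
            f"{pos}:{label[:3]}" for pos, label in sorted(self.substituents.items())
        )
        return f"{prefix}[{inner}]"

    def __str__(self) -> str:
        return self.descriptor()


@dataclass(frozen=True)
class FlavonoidGlycoside:
    """Flavonoid O-glucoside with 0-2 malonyl esters on the sugar.

    ``anomeric`` is metadata (beta assumed, set by the NMR key); it does not
    affect the formula.
    """

    aglycone: str
    glycosylation_position: int = 3
    malonyl_positions: frozenset = frozenset()
    anomeric: str = "beta"

    def __post_init__(self) -> None:
        if self.aglycone not in AGLYCONES:
            raise ValueError(
                f"unknown aglycone {self.aglycone!r}; supported: {sorted(AGLYCONES)}"
            )
        if self.glycosylation_position not in (3, 7):
            raise ValueError("glycosylation position must be 3 or 7")
        positions = frozenset(self.malonyl_positions)
        if not positions <= frozenset(_SUGAR_POSITIONS):
            raise ValueError(
                f"malonyl positions must be a subset of {_SUGAR_POSITIONS}"
            )
        object.__setattr__(self, "malonyl_positions", positions)

    @property
    def n_malonyl(self) -> int:
        return len(self.malonyl_positions)

    def neutral_formula(self) -> ElementalFormula:
        f = AGLYCONES[self.aglycone] + GLUCOSE - WATER  # glycosidic bond
        for _ in self.malonyl_positions:
            f = f + MALONIC_ACID - WATER
        return f

    def descriptor(self) -> str:
        tag = {"quercetin": "QUE", "luteolin": "LUT", "kaempferol": "KMP"}[self.aglycone]
        inner = ",".join(f"{p}:mal" for p in sorted(self.malonyl_positions))
        return f"{tag}-{self.glycosylation_position}-Glc[{inner}]"

    def __str__(self) -> str:
        return self.descriptor()


Structure = AcylQuinate | FlavonoidGlycoside


def neutral_formula(s: Structure) -> ElementalFormula:
    """Molecular formula of the neutral compound described by *s*."""
    return s.neutral_formula()


def enumerate_regioisomers(
    n_caffeoyl: int, n_malonyl: int, core: str = "quinic"
) -> list[AcylQuinate]:
    """All distinct assignments of the given acyl groups over positions {1,3,4,5}.

    Returned in deterministic lexicographic order (by occupied positions, then
    labels). The count equals the multinomial 4!/(a! b! (4-a-b)!); two caffeoyl
    plus one malonyl gives the twelve regioisomeric MDiCQAs.
    """
    if n_caffeoyl < 0 or n_malonyl < 0:
        raise ValueError("acyl counts must be non-negative")
    if n_caffeoyl + n_malonyl > len(_QUINATE_POSITIONS):
        raise ValueError(
            f"{n_caffeoyl}+{n_malonyl} acyl groups exceed the 4 acylatable positions"
        )
    labels = ["caffeoyl"] * n_caffeoyl + ["malonyl"] * n_malonyl
    seen: set[tuple] = set()
    out: list[AcylQuinate] = []
    for positions in itertools.combinations(_QUINATE_POSITIONS, len(labels)):
        for perm in sorted(set(itertools.permutations(labels))):
            key = tuple(zip(positions, perm))
            if key not in seen:
                seen.add(key)
                out.append(AcylQuinate(dict(key), core=core))
    out.sort(key=lambda s: tuple(sorted(s.substituents.items())))
    expected = math.factorial(4) // (
        math.factorial(n_caffeoyl)
        * math.factorial(n_malonyl)
        * math.factorial(4 - n_caffeoyl - n_malonyl)
    )
    assert len(out) == expected
    return out


def catechol_count(s: Structure) -> int:
    """Number of ortho-dihydroxybenzene (catechol) units in the structure.

    Each caffeoyl ester contributes one; quercetin and luteolin B rings
    contribute one; kaempferol and the bare quinic core contribute none.
    The count bounds the in-source oxidation series (-2H per catechol).
    """
    if isinstance(s, AcylQuinate):
        return s.n_caffeoyl
    if isinstance(s, FlavonoidGlycoside):
        return 1 if s.aglycone in _CATECHOL_AGLYCONES else 0
    raise TypeError(f"unsupported structure type: {type(s).__name__}")


_QA_RE = re.compile(r"^(e?QA)\[([^\]]*)\]$")
_GLC_RE = re.compile(r"^(QUE|LUT|KMP)-([37])-Glc\[([^\]]*)\]$")
_ACYL_SHORT = {"caf": "caffeoyl", "mal": "malonyl"}
_AGLYCONE_TAG = {"QUE": "quercetin", "LUT": "luteolin", "KMP": "kaempferol"}


def parse_descriptor(text: str) -> Structure:
    """Parse a compact descriptor string back into a structure object.

    Inverse of ``str(structure)``; see module docstring for the syntax.
    """
    text = text.strip()
    m = _QA_RE.match(text)
    if m:
        core = "quinic" if m.group(1) == "QA" else "epi-quinic"
        subs: dict[int, str] = {}
        if m.group(2):
            for item in m.group(2).split(","):
                pos_s, _, label_s = item.partition(":")
                try:
                    pos = int(pos_s)
                    label = _ACYL_SHORT[label_s.strip()]
                except (ValueError, KeyError):
                    raise ValueError(f"bad substituent {item!r} in {text!r}") from None
                if pos in subs:
                    raise ValueError(f"duplicate position {pos} in {text!r}")
                subs[pos] = label
        return AcylQuinate(subs, core=core)
    m = _GLC_RE.match(text)
    if m:
        positions = set()
        if m.group(3):
            for item in m.group(3).split(","):
                pos_s, _, label_s = item.partition(":")
                if label_s.strip() != "mal" or pos_s not in _SUGAR_POSITIONS:
                    raise ValueError(f"bad sugar substituent {item!r} in {text!r}")
                positions.add(pos_s)
        return FlavonoidGlycoside(
            aglycone=_AGLYCONE_TAG[m.group(1)],
            glycosylation_position=int(m.group(2)),
            malonyl_positions=frozenset(positions),
        )
    raise ValueError(f"cannot parse structure descriptor {text!r}")
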