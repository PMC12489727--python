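"""Coupling-constant keys: quinic vs epi-quinic core, solvent shift, anomeric J.

Acyl-quinates adopt chair-like conformations whose proton-proton couplings
report relative configuration. In DMSO-d6 the largest H-4 coupling (the
trans-diaxial 3J(4,5) candidate) separates the two cores: a quinic core keeps
H-4 and H-5 diaxial (J near 9 Hz), while an epi-quinic core equilibrates
between chairs and averages the coupling below 8 Hz. Between 8.0 and 8.3 Hz
the key deliberately refuses to decide: the quinic floor sits at the smallest
coupling actually observed for a quinic core (8.3 Hz), and the gap below it
down to the 8 Hz epi-quinic ceiling is unobserved territory left to human
review.

D2O shifts the conformational equilibrium further toward the diaxial chair,
so the diagnostic coupling must *increase* on going DMSO -> D2O — for a
quinic core via 3J(4,5), for an epi-quinic core via 3J(3,4). That provides an
independent consistency check, never the primary assignment.

For glucosides, an anomeric-proton doublet of >= 7 Hz indicates the
trans-diaxial H-1''/H-2'' arrangement of a beta-glycosidic bond.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "QUINIC_MIN_J",
    "EPI_QUINIC_MAX_J",
    "BETA_ANOMERIC_MIN_J",
    "CouplingObservation",
    "CoreAssignment",
    "assign_core",
    "solvent_shift_check",
    "check_anomeric",
]

#: DMSO 3J(4,5) at or above this is a quinic core ("~9 Hz" rule; the smallest
#: coupling observed on a confirmed quinic core is 8.3 Hz).
QUINIC_MIN_J: float = 8.3
#: DMSO 3J(4,5) below this is an epi-quinic core ("< 8 Hz" rule).
EPI_QUINIC_MAX_J: float = 8.0
#: Anomeric doublet at or above this indicates a beta-glycoside.
BETA_ANOMERIC_MIN_J: float = 7.0


@dataclass(frozen=True)
class CouplingObservation:
    """One proton's coupling constants as extracted from a 1D spectrum."""

    proton: str  # e.g. "H-4", "H-1''"
    J_values: tuple[float, ...]
    solvent: str = "DMSO"

    def __post_init__(self) -> None:
        if any(j < 0 for j in self.J_values):
            raise ValueError("coupling constants must be non-negative")
        if self.solvent not in ("DMSO", "D2O"):
            raise ValueError(f"unknown solvent {self.solvent!r}")

    @property
    def largest_J(self) -> float:
        """The trans-diaxial candidate: the largest coupling of the multiplet."""
        if not self.J_values:
            raise ValueError(f"no J values recorded for {self.proton}")
        return max(self.J_values)


@dataclass(frozen=True)
class CoreAssignment:
    core: str  # quinic | epi-quinic | indeterminate
    J_used: float
    solvent: str = "DMSO"


def assign_core(J45_dmso: float) -> CoreAssignment:
    """Assign the core stereochemistry from the DMSO-d6 H-4 trans-diaxial J.

    >= 8.3 Hz -> quinic; < 8.0 Hz -> epi-quinic; the 8.0-8.3 Hz gap is
    returned as indeterminate and left to human review.
    """
    if J45_dmso < 0:
        raise ValueError(f"coupling constant must be non-negative, got {J45_dmso}")
    if J45_dmso >= QUINIC_MIN_J:
        core = "quinic"
    elif J45_dmso < EPI_QUINIC_MAX_J:
        core = "epi-quinic"
    else:
        core = "indeterminate"
    return CoreAssignment(core=core, J_used=J45_dmso, solvent="DMSO")


def solvent_shift_check(J_dmso: float, J_d2o: float, core: str) -> str:
    """Consistency check: the diagnostic coupling must increase in D2O.

    For a quinic core the compared coupling is 3J(4,5); for an epi-quinic
    core it is 3J(3,4). Returns ``"consistent"`` or ``"inconsistent"``.
    """
    if J_dmso < 0 or J_d2o < 0:
        raise ValueError("coupling constants must be non-negative")
    if core not in ("quinic", "epi-quinic"):
        raise ValueError(f"unknown core label {core!r}")
    return "consistent" if J_d2o > J_dmso else "inconsistent"


def check_anomeric(J: float) -> str:
    """Beta/alpha call from the anomeric doublet: >= 7 Hz -> ``"beta"``."""
    if J < 0:
        raise ValueError(f"coupling constant must be non-negative, got {J}")
    return "beta" if J >= BETA_ANOMERIC_MIN_J else "not_beta"
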