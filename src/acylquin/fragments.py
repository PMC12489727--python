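"""Neutral-loss fragmentation grammar for acyl-quinates and malonyl-glucosides.

Negative-mode CID of these ester metabolites is dominated by sequential
eliminations of whole residues rather than ring cleavages, so a small neutral
loss grammar reproduces the observed fragment series:

* ``malonyl_residue``  C3H2O3, 86.0004 Da (ketene-type ester cleavage; the
  104 Da malonic-acid loss is not observed and not generated)
* ``caffeoyl_residue`` C9H6O3, 162.0317 Da
* ``glucosyl_residue`` C6H10O5, 162.0528 Da (glycosidic cleavage; only after
  every malonyl ester on the sugar has been lost — demalonylation-first)
* ``CO2``              43.9898 Da (from the free carboxyl; once per molecule,
  acyl-quinates only)
* ``H2O``              18.0106 Da (once)

For acyl-quinates the tree is completed with the terminal marker ions seen at
the low-mass end of every spectrum: deprotonated quinic acid (nominal 191),
caffeic acid (179) and dehydrated quinic acid (173).
"""

from __future__ import annotations

import itertools
from collections import Counter, deque
from dataclasses import dataclass

from .formula import ElementalFormula, monoisotopic_mass, mz_ion, ppm_error, round_half_up
from .spectra import Spectrum
from .structures import AcylQuinate, FlavonoidGlycoside, Structure, neutral_formula

__all__ = [
    "NEUTRAL_LOSSES",
    "TERMINAL_IONS",
    "FragmentNode",
    "PeakAnnotation",
    "generate_fragments",
    "annotate_peaks",
    "explain_loss",
]

#: Loss label -> neutral formula eliminated.
NEUTRAL_LOSSES: dict[str, ElementalFormula] = {
    "malonyl_residue": ElementalFormula("C3H2O3"),
    "caffeoyl_residue": ElementalFormula("C9H6O3"),
    "glucosyl_residue": ElementalFormula("C6H10O5"),
    "CO2": ElementalFormula("CO2"),
    "H2O": ElementalFormula("H2O"),
}

#: Terminal marker ions emitted by acyl-quinate spectra regardless of the
#: acylation pattern: (path tag, neutral formula of the corresponding acid).
TERMINAL_IONS: tuple[tuple[str, ElementalFormula], ...] = (
    ("terminal:quinic_acid", ElementalFormula("C7H12O6")),       # nominal 191
    ("terminal:caffeic_acid", ElementalFormula("C9H8O4")),       # nominal 179
    ("terminal:quinic_acid-H2O", ElementalFormula("C7H10O5")),   # nominal 173
)


@dataclass(frozen=True)
class FragmentNode:
    """One theoretical fragment: remaining neutral formula plus its loss path."""

    remaining: ElementalFormula
    path: tuple[str, ...]
    mz: float
    nominal: int

    @property
    def is_terminal_marker(self) -> bool:
        return any(p.startswith("terminal:") for p in self.path)

    def __str__(self) -> str:
        route = ">".join(self.path) if self.path else "precursor"
        return f"{self.mz:.4f} ({self.nominal}) [{route}]"


@dataclass(frozen=True)
class PeakAnnotation:
    """Observed peak with its best matching theoretical node (or none)."""

    peak_mz: float
    peak_intensity: float
    matched_node: FragmentNode | None
    ppm: float | None

    @property
    def matched(self) -> bool:
        return self.matched_node is not None


def _loss_budget(s: Structure) -> dict[str, int]:
    """Per-structure multiplicity budget for each loss type."""
    if isinstance(s, AcylQuinate):
        return {
            "malonyl_residue": s.n_malonyl,
            "caffeoyl_residue": s.n_caffeoyl,
            "glucosyl_residue": 0,
            "CO2": 1,  # the free C-1 carboxyl
            "H2O": 1,
        }
    if isinstance(s, FlavonoidGlycoside):
        return {
            "malonyl_residue": s.n_malonyl,
            "caffeoyl_residue": 0,
            "glucosyl_residue": 1,
            "CO2": 0,  # no free carboxyl on the flavonoid glycosides
            "H2O": 1,
        }
    raise TypeError(f"unsupported structure type: {type(s).__name__}")


def _node(remaining: ElementalFormula, path: tuple[str, ...]) -> FragmentNode:
    mz = mz_ion(remaining, "negative")
    return FragmentNode(remaining, path, mz, int(round_half_up(mz)))


def generate_fragments(s: Structure, max_depth: int = 3) -> set[FragmentNode]:
    """Breadth-first fragment tree of the deprotonated molecule of *s*.

    Each available loss is applied at most its multiplicity along a path; the
    glucosyl residue may only leave after all sugar malonyls are gone. Nodes
    are deduplicated by remaining formula (the shortest path is kept), so
    different elimination orders of the same residues collapse to one node.
    ``max_depth`` = 0 returns the precursor alone; any positive depth also
    emits the acyl-quinate terminal marker ions.
    """
    if max_depth < 0:
        raise ValueError(f"max_depth must be >= 0, got {max_depth}")
    precursor = neutral_formula(s)
    budget = _loss_budget(s)
    sugar_malonyls = s.n_malonyl if isinstance(s, FlavonoidGlycoside) else 0

    best: dict[ElementalFormula, FragmentNode] = {precursor: _node(precursor, ())}
    queue: deque[FragmentNode] = deque([best[precursor]])
    while queue:
        node = queue.popleft()
        if len(node.path) >= max_depth:
            continue
        used = Counter(node.path)
        for label, loss in NEUTRAL_LOSSES.items():
            if used[label] >= budget[label]:
                continue
            if label == "glucosyl_residue" and used["malonyl_residue"] < sugar_malonyls:
                continue  # demalonylation must precede glycosidic cleavage
            try:
                remaining = node.remaining - loss
            except ValueError:
                continue
            if remaining["H"] < 1:  # must still be deprotonatable
                continue
            if remaining in best:
                continue
            child = _node(remaining, node.path + (label,))
            best[remaining] = child
            queue.append(child)

    nodes = set(best.values())
    if max_depth >= 1 and isinstance(s, AcylQuinate):
        for tag, acid in TERMINAL_IONS:
            nodes.add(_node(acid, (tag,)))
    return nodes


def annotate_peaks(
    spec: Spectrum, nodes: set[FragmentNode], tol_ppm: float = 5.0
) -> list[PeakAnnotation]:
    """Match every peak to the nearest theoretical node within *tol_ppm*.

    One node may annotate several peaks; peaks with no node in tolerance are
    returned unmatched. An empty node set yields an all-unmatched report.
    """
    if spec.polarity != "negative":
        raise ValueError("fragment annotation is defined for negative-mode spectra")
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be positive, got {tol_ppm}")
    ordered = sorted(nodes, key=lambda n: n.mz)
    out: list[PeakAnnotation] = []
    for mz, intensity in spec.peaks:
        match: FragmentNode | None = None
        best_ppm: float | None = None
        for node in ordered:
            err = ppm_error(mz, node.mz)
            if abs(err) <= tol_ppm and (best_ppm is None or abs(err) < abs(best_ppm)):
                match, best_ppm = node, err
        out.append(PeakAnnotation(mz, intensity, match, best_ppm))
    return out


def explain_loss(
    parent_mz: float, fragment_mz: float, tol_mDa: float = 10.0
) -> list[tuple[str, ...]]:
    """All multisets of at most three neutral losses matching a mass difference.

    Returns the candidate loss combinations (possibly including the empty
    combination when parent and fragment coincide) sorted by absolute mass
    error. Tolerance is in milli-Dalton, suited to neutral-loss deltas.
    """
    if parent_mz < fragment_mz:
        raise ValueError(
            f"parent m/z {parent_mz} is below fragment m/z {fragment_mz}"
        )
    delta = parent_mz - fragment_mz
    tol = tol_mDa / 1000.0
    labels = list(NEUTRAL_LOSSES)
    masses = {lab: monoisotopic_mass(f) for lab, f in NEUTRAL_LOSSES.items()}
    candidates: list[tuple[float, tuple[str, ...]]] = []
    for size in range(4):
        for combo in itertools.combinations_with_replacement(labels, size):
            err = abs(sum(masses[lab] for lab in combo) - delta)
            if err <= tol:
                candidates.append((err, combo))
    candidates.sort(key=lambda item: (item[0], len(item[1]), item[1]))
    return [combo for _, combo in candidates]
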