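"""End-to-end identification pipeline over an MGF file of MS/MS spectra.

Per precursor the pipeline (1) matches the precursor m/z against the built-in
candidate formulas (MDiCQA, DiMDiCQA and the three flavonoid malonyl-glucoside
compositions), (2) annotates the fragment peaks against the candidate's
theoretical loss tree, and (3) for MDiCQA precursors runs the two-stage
isomer key on the paired 25/45 eV spectra. Stage failures are recorded per
spectrum and never abort the run. Reports are deterministic: fixed key order,
m/z printed at 4 decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .formula import mz_ion, ppm_error
from .fragments import annotate_peaks, generate_fragments
from .isomer_key import classify
from .spectra import Spectrum
from .structures import Structure, parse_descriptor

__all__ = ["RunConfig", "CANDIDATES", "pair_spectra", "run_pipeline", "report_json"]

#: Candidate compound classes searched for each precursor.
CANDIDATES: dict[str, str] = {
    "MDiCQA": "QA[1:caf,3:mal,5:caf]",
    "DiMDiCQA": "QA[1:caf,3:mal,4:mal,5:caf]",
    "quercetin malonyl-glucoside": "QUE-3-Glc[6'':mal]",
    "luteolin/kaempferol malonyl-glucoside": "LUT-7-Glc[6'':mal]",
    "luteolin dimalonyl-glucoside": "LUT-7-Glc[2'':mal,6'':mal]",
}


@dataclass
class RunConfig:
    """Pipeline settings; defaults are the package's documented choices."""

    tol_ppm: float = 5.0          # fragment annotation tolerance
    precursor_tol_ppm: float = 10.0  # formula check & spectrum pairing
    tol_mda: float = 10.0         # neutral-loss explanation tolerance
    max_depth: int = 4
    eluent_preset: str = "formic_0.1"
    seed: int = 0
    input_path: str | None = None
    output_path: str | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})


def _title_stem(title: str) -> str:
    """Title without a trailing collision-energy tag, for pairing."""
    stem = title.strip()
    for sep in (" 25eV", " 45eV", " ce=25", " ce=45"):
        if stem.endswith(sep):
            stem = stem[: -len(sep)]
    return stem


def pair_spectra(
    spectra: list[Spectrum], precursor_tol_ppm: float = 10.0
) -> list[tuple[Spectrum, Spectrum | None]]:
    """Group spectra into (25 eV, optional 45 eV companion) pairs.

    Companions must share the precursor m/z within tolerance and the title
    stem. Unpairable 45 eV spectra are returned as their own entries so the
    caller can warn about them.
    """
    primaries = [s for s in spectra if s.collision_energy == 25]
    secondaries = [s for s in spectra if s.collision_energy == 45]
    others = [s for s in spectra if s.collision_energy not in (25, 45)]
    used: set[int] = set()
    pairs: list[tuple[Spectrum, Spectrum | None]] = []
    for spec in primaries:
        companion = None
        for j, cand in enumerate(secondaries):
            if j in used:
                continue
            if spec.precursor_mz and cand.precursor_mz:
                if abs(ppm_error(cand.precursor_mz, spec.precursor_mz)) > precursor_tol_ppm:
                    continue
            if _title_stem(cand.title) != _title_stem(spec.title):
                continue
            companion = cand
            used.add(j)
            break
        pairs.append((spec, companion))
    for j, cand in enumerate(secondaries):
        if j not in used:
            pairs.append((cand, None))
    pairs.extend((s, None) for s in others)
    return pairs


def _match_candidate(
    precursor_mz: float, tol_ppm: float
) -> tuple[str, Structure, float] | None:
    best: tuple[float, str, Structure] | None = None
    for name, descriptor in CANDIDATES.items():
        structure = parse_descriptor(descriptor)
        theo = mz_ion(structure.neutral_formula(), "negative")
        err = ppm_error(precursor_mz, theo)
        if abs(err) <= tol_ppm and (best is None or abs(err) < abs(best[0])):
            best = (err, name, structure)
    if best is None:
        return None
    return best[1], best[2], best[0]


def run_pipeline(config: RunConfig, spectra: list[Spectrum]) -> dict:
    """Run the identification stages over already-loaded spectra.

    Returns a JSON-serializable report with one entry per processed spectrum
    pair; failures are recorded in the entry's ``errors`` list.
    """
    results = []
    for spec25, spec45 in pair_spectra(spectra, config.precursor_tol_ppm):
        entry: dict = {
            "title": spec25.title,
            "precursor_mz": _fmt(spec25.precursor_mz),
            "collision_energy": spec25.collision_energy,
            "errors": [],
        }
        if spec25.precursor_mz is None:
            entry["errors"].append("no precursor m/z; stages skipped")
            results.append(entry)
            continue
        match = _match_candidate(spec25.precursor_mz, config.precursor_tol_ppm)
        if match is None:
            entry["formula_check"] = {"matched": False}
            entry["errors"].append(
                "precursor matches no candidate formula; downstream stages skipped"
            )
            results.append(entry)
            continue
        name, structure, err = match
        entry["formula_check"] = {
            "matched": True,
            "candidate": name,
            "descriptor": str(structure),
            "formula": str(structure.neutral_formula()),
            "ppm": round(err, 2),
        }
        nodes = generate_fragments(structure, max_depth=config.max_depth)
        annotations = annotate_peaks(spec25, nodes, config.tol_ppm)
        entry["annotation"] = {
            "n_peaks": len(annotations),
            "n_matched": sum(a.matched for a in annotations),
            "matched": [
                {
                    "mz": _fmt(a.peak_mz),
                    "nominal": a.matched_node.nominal,
                    "path": ">".join(a.matched_node.path) or "precursor",
                    "ppm": round(a.ppm, 2),
                }
                for a in annotations
                if a.matched
            ],
        }
        if name == "MDiCQA" and spec25.collision_energy == 25:
            try:
                call = classify(spec25, spec45)
                entry["isomer_call"] = {
                    "label": call.label,
                    "confidence": call.confidence,
                    "I233": round(call.stage1_evidence[0], 4),
                    "I395": round(call.stage1_evidence[1], 4),
                    "stage2_ratio": (
                        round(call.stage2_ratio, 4) if call.stage2_ratio is not None else None
                    ),
                }
            except ValueError as exc:
                entry["errors"].append(f"isomer key: {exc}")
        results.append(entry)
    return {"config": RunConfig.to_dict(config), "n_spectra": len(spectra),
            "results": results}


def _fmt(mz: float | None) -> str | None:
    return None if mz is None else f"{mz:.4f}"


def report_json(report: dict) -> str:
    """Deterministic serialization: sorted keys, fixed float formatting."""
    return json.dumps(report, indent=2, sort_keys=True)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(report_json(report) + "\n")
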