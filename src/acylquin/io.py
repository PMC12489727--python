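"""File formats: MGF spectra (via pyteomics), CSV peak lists and tables.

MGF conventions used here: ``PEPMASS`` holds the precursor m/z, ``CHARGE``
``1-``/``1+`` encodes the polarity, and the collision energy travels in a
``COLLISION_ENERGY=<eV>`` header line (also recognised as ``ce=<eV>`` inside
the title for files produced elsewhere).
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from pyteomics import mgf as _mgf

from .spectra import Spectrum

__all__ = ["read_mgf", "write_mgf", "read_peaks_csv", "write_peaks_csv"]

_CE_IN_TITLE = re.compile(r"\bce\s*[=:]\s*([0-9.]+)", re.IGNORECASE)


def _polarity_from_charge(charge) -> str:
    if charge is None:
        return "negative"
    text = str(charge)
    return "negative" if "-" in text else "positive"


def _collision_energy(params: dict) -> float | None:
    for key in ("collision_energy", "collisionenergy", "energy"):
        if key in params:
            try:
                return float(str(params[key]).split()[0])
            except ValueError:
                return None
    m = _CE_IN_TITLE.search(str(params.get("title", "")))
    return float(m.group(1)) if m else None


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read all ``BEGIN IONS`` blocks of an MGF file into Spectrum objects.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` when
    the file contains no valid blocks; individual malformed blocks are
    reported with their block index in the error message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    errors: list[str] = []
    with _mgf.MGF(str(path)) as reader:
        for index, entry in enumerate(reader):
            try:
                params = entry.get("params", {})
                pepmass = params.get("pepmass", (None,))
                precursor = float(pepmass[0]) if pepmass and pepmass[0] else None
                peaks = list(
                    zip(
                        (float(m) for m in entry["m/z array"]),
                        (float(i) for i in entry["intensity array"]),
                    )
                )
                spectra.append(
                    Spectrum(
                        polarity=_polarity_from_charge(params.get("charge")),
                        precursor_mz=precursor,
                        collision_energy=_collision_energy(params),
                        peaks=peaks,
                        title=str(params.get("title", "")),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                errors.append(f"block {index + 1}: {exc}")
    if not spectra:
        detail = "; ".join(errors) if errors else "no BEGIN IONS blocks found"
        raise ValueError(f"no valid blocks in {path}: {detail}")
    return spectra


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; round-trips peaks through :func:`read_mgf`."""
    path = Path(path)
    entries = []
    for spec in spectra:
        params = {
            "title": spec.title,
            "charge": "1-" if spec.polarity == "negative" else "1+",
        }
        if spec.precursor_mz is not None:
            params["pepmass"] = spec.precursor_mz
        if spec.collision_energy is not None:
            params["collision_energy"] = f"{spec.collision_energy:g}"
        entries.append(
            {
                "params": params,
                "m/z array": [mz for mz, _ in spec.peaks],
                "intensity array": [i for _, i in spec.peaks],
            }
        )
    with open(path, "w") as handle:
        _mgf.write(entries, handle)


def read_peaks_csv(path: str | Path) -> list[tuple[float, float]]:
    """Read an ``mz,intensity`` CSV peak list."""
    df = pd.read_csv(path)
    missing = {"mz", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return list(zip(df["mz"].astype(float), df["intensity"].astype(float)))


def write_peaks_csv(peaks: list[tuple[float, float]], path: str | Path) -> None:
    pd.DataFrame(peaks, columns=["mz", "intensity"]).to_csv(path, index=False)
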