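"""Seeded generators for every input the analysis pipeline consumes.

Everything here is a pure function of its parameters and a seed, so tests and
the acceptance script can exercise the full pipeline offline:

* MS/MS spectra of the four MDiCQA isomers from intensity templates that
  encode the study conditions of the diagnostic key (25 eV: m/z 233 at ~70%
  of TIC for compounds 4/7, m/z 395 at ~35% for 5, 35%/30% for 6; 45 eV:
  173/233 at 40%/30% for 7 and 8%/30% for 4). Whatever template mass the key
  ions do not carry is spread uniformly over the co-occurring background
  fragments (557/515/439/377/353/191/179) — their true proportions are
  energy-dependent and not modelled.
* MS1 peak lists with in-source oxidation satellites under three eluent
  presets (0.1% formic acid, 0.3% formic acid, water-only).
* 4PL dose-response curves with Gaussian noise.
* Organ x phase tissue-concentration tables with lognormal scatter.

Noise model: Gaussian m/z jitter (ppm), lognormal intensity scatter (CV),
and uniform decoy peaks that are kept at least 0.5 Da away from the key ions
so that robustness measurements are attributable to intensity noise alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioassay import DoseResponse, four_pl
from .formula import mz_ion
from .fragments import generate_fragments
from .isomer_key import KEY_IONS
from .oxidation import H2_MASS
from .spectra import Spectrum
from .structures import Structure, catechol_count, parse_descriptor

__all__ = [
    "SpectrumTemplate",
    "NoiseModel",
    "MDICQA_TEMPLATES",
    "ELUENT_PRESETS",
    "reference_mdicqa",
    "gen_msms",
    "gen_ms1_oxidation",
    "gen_dose_response",
    "gen_tissue_table",
]

#: The isolated reference regioisomer used for theoretical fragment masses
#: (1,5-dicaffeoyl-3-malonylquinic acid); every MDiCQA regioisomer shares the
#: same fragment m/z set, so the choice does not matter for m/z purposes.
_REFERENCE_DESCRIPTOR = "QA[1:caf,3:mal,5:caf]"


def reference_mdicqa():
    return parse_descriptor(_REFERENCE_DESCRIPTOR)


def _exact_mz_by_nominal() -> dict[int, float]:
    nodes = generate_fragments(reference_mdicqa(), max_depth=4)
    table: dict[int, float] = {}
    for node in sorted(nodes, key=lambda n: len(n.path)):
        table.setdefault(node.nominal, node.mz)
    return table


#: Nominal -> exact negative-mode m/z for the MDiCQA fragment series.
_EXACT_MZ: dict[int, float] = _exact_mz_by_nominal()

#: Background fragments shared by all MDiCQA spectra (never key ions).
_BACKGROUND_IONS: tuple[int, ...] = (557, 515, 439, 377, 353, 191, 179)


@dataclass(frozen=True)
class SpectrumTemplate:
    """Isomer label, collision energy, and key-ion TIC fractions.

    ``key_fractions`` maps nominal m/z to the TIC fraction the template
    assigns; the remaining mass is distributed uniformly over
    ``background_ions``.
    """

    label: str
    collision_energy: float
    key_fractions: dict[int, float]
    background_ions: tuple[int, ...] = _BACKGROUND_IONS

    def __post_init__(self) -> None:
        total = sum(self.key_fractions.values())
        if not 0 <= total <= 1:
            raise ValueError(f"key fractions sum to {total}, must lie in [0, 1]")

    def peak_fractions(self) -> dict[int, float]:
        """Full nominal -> fraction table (keys plus uniform background)."""
        out = dict(self.key_fractions)
        residual = 1.0 - sum(out.values())
        share = residual / len(self.background_ions)
        for ion in self.background_ions:
            out[ion] = out.get(ion, 0.0) + share
        return out


#: The study-condition templates for the four isomers at the two key energies.
MDICQA_TEMPLATES: dict[tuple[str, int], SpectrumTemplate] = {
    ("cpd4", 25): SpectrumTemplate("cpd4", 25, {233: 0.70, 395: 0.02}),
    ("cpd7", 25): SpectrumTemplate("cpd7", 25, {233: 0.70, 395: 0.02}),
    ("cpd5", 25): SpectrumTemplate("cpd5", 25, {395: 0.35, 233: 0.01}),
    ("cpd6", 25): SpectrumTemplate("cpd6", 25, {233: 0.35, 395: 0.30}),
    ("cpd4", 45): SpectrumTemplate("cpd4", 45, {173: 0.08, 233: 0.30}),
    ("cpd7", 45): SpectrumTemplate("cpd7", 45, {173: 0.40, 233: 0.30}),
}


@dataclass(frozen=True)
class NoiseModel:
    """Reproducible spectral noise: same seed, same output."""

    mz_jitter_ppm: float = 0.0
    intensity_cv: float = 0.0
    n_decoy_peaks: int = 0
    decoy_rel_intensity: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mz_jitter_ppm < 0 or self.intensity_cv < 0 or self.n_decoy_peaks < 0:
            raise ValueError("noise parameters must be non-negative")


def _perturb(
    peaks: list[tuple[float, float]],
    noise: NoiseModel,
    rng: np.random.Generator,
    decoy_range: tuple[float, float] | None = None,
    protected: tuple[int, ...] = (),
) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for mz, intensity in peaks:
        if noise.mz_jitter_ppm > 0:
            mz = mz * (1.0 + rng.normal(0.0, noise.mz_jitter_ppm) * 1e-6)
        if noise.intensity_cv > 0:
            sigma = np.sqrt(np.log1p(noise.intensity_cv**2))
            intensity = intensity * rng.lognormal(-0.5 * sigma**2, sigma)
        out.append((float(mz), float(intensity)))
    if decoy_range is not None and noise.n_decoy_peaks > 0:
        total = sum(i for _, i in out)
        placed = 0
        while placed < noise.n_decoy_peaks:
            mz = float(rng.uniform(*decoy_range))
            # decoys stay clear of the diagnostic ions
            if any(abs(mz - k) < 0.5 for k in protected):
                continue
            out.append((mz, float(rng.uniform(0.0, noise.decoy_rel_intensity) * total)))
            placed += 1
    return sorted(out)


def gen_msms(template: SpectrumTemplate, noise: NoiseModel | None = None) -> Spectrum:
    """Synthesize one negative-mode MS/MS spectrum from an intensity template.

    With a zero-noise model the peak TIC fractions equal the template exactly.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    precursor = mz_ion(reference_mdicqa().neutral_formula(), "negative")
    peaks = [
        (_EXACT_MZ[nominal], fraction)
        for nominal, fraction in sorted(template.peak_fractions().items())
        if fraction > 0
    ]
    peaks = _perturb(
        peaks, noise, rng, decoy_range=(150.0, precursor), protected=KEY_IONS
    )
    return Spectrum(
        polarity="negative",
        precursor_mz=precursor,
        collision_energy=template.collision_energy,
        peaks=peaks,
        title=f"synthetic {template.label} {template.collision_energy:g}eV",
    )


#: Relative member intensities (state 0, -2H, -4H) under each eluent, scaled
#: to base 100 for the most intense member of the full 2-catechol pattern.
ELUENT_PRESETS: dict[str, dict[int, float]] = {
    # 0.1% formic acid: intact ion dominant; satellites at the midpoints of
    # the observed ranges (singly oxidized 30-90% -> 60; doubly 5-10% -> 7.5)
    "formic_0.1": {0: 100.0, 1: 60.0, 2: 7.5},
    # water-only: doubly oxidized dominant, intact reduced to ~10%
    "water": {0: 10.0, 1: 30.0, 2: 100.0},
    # 0.3% formic acid: oxidation markedly suppressed relative to 0.1%
    "formic_0.3": {0: 100.0, 1: 15.0, 2: 2.0},
}


def gen_ms1_oxidation(
    structure: Structure | str,
    eluent_preset: str,
    noise: NoiseModel | None = None,
) -> list[tuple[float, float]]:
    """MS1 peak list with in-source oxidation satellites for one compound.

    Satellites appear only up to the structure's catechol count; a
    catechol-free compound yields the intact ion alone whatever the eluent.
    """
    if isinstance(structure, str):
        structure = parse_descriptor(structure)
    try:
        preset = ELUENT_PRESETS[eluent_preset]
    except KeyError:
        raise ValueError(
            f"unknown eluent preset {eluent_preset!r}; "
            f"available: {sorted(ELUENT_PRESETS)}"
        ) from None
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    base = mz_ion(structure.neutral_formula(), "negative")
    n_cat = catechol_count(structure)
    peaks = [
        (base - k * H2_MASS, intensity)
        for k, intensity in sorted(preset.items())
        if k <= n_cat
    ]
    return _perturb(peaks, noise, rng)


def gen_dose_response(
    ic50: float,
    hill: float = 1.0,
    bottom: float = 0.0,
    top: float = 100.0,
    doses: tuple[float, ...] | None = None,
    sigma: float = 0.0,
    seed: int = 0,
    n_parallel: int = 4,
    replicate: str = "",
) -> DoseResponse:
    """4PL mean curve plus Gaussian noise (sd *sigma*, in % response units).

    Default doses are eight three-fold steps centred on *ic50*, each measured
    in *n_parallel* parallel wells (four, the assay design emulated here);
    noise draws are independent across wells. With ``sigma = 0`` every
    response equals the 4PL closed form.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if n_parallel < 1:
        raise ValueError("n_parallel must be >= 1")
    if doses is None:
        doses = tuple(ic50 * 3.0 ** k for k in range(-4, 4))
    doses = tuple(sorted(doses)) * 1
    all_doses = tuple(sorted(d for d in doses for _ in range(n_parallel)))
    rng = np.random.default_rng(seed)
    mean = four_pl(all_doses, bottom, top, np.log(ic50), hill)
    resp = mean + (rng.normal(0.0, sigma, size=len(all_doses)) if sigma > 0 else 0.0)
    return DoseResponse(doses=all_doses, responses=tuple(float(r) for r in resp),
                        replicate=replicate)


def gen_tissue_table(
    profile: dict[tuple[str, str], float],
    compound: str,
    species: str = "synthetic",
    n_per_cell: int = 3,
    cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tissue-concentration table with lognormal scatter around cell means.

    *profile* maps ``(organ, phase)`` to the mean concentration (mg/g dry
    tissue); each cell receives *n_per_cell* records. With ``cv = 0`` every
    record equals its cell mean exactly.
    """
    if any(m < 0 for m in profile.values()):
        raise ValueError("profile means must be non-negative")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for (organ, phase), mean in sorted(profile.items()):
        for r in range(n_per_cell):
            value = mean
            if cv > 0 and mean > 0:
                sigma = np.sqrt(np.log1p(cv**2))
                value = mean * rng.lognormal(-0.5 * sigma**2, sigma)
            rows.append(
                {
                    "species": species,
                    "organ": organ,
                    "phase": phase,
                    "compound": compound,
                    "mg_per_g": float(value),
                    "sample": f"{species}-{organ}-{phase}-{r + 1}",
                }
            )
    return pd.DataFrame(rows, columns=["species", "organ", "phase", "compound",
                                       "mg_per_g", "sample"])
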