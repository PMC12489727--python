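"""Lightweight peak-list container shared by the MS modules."""

from __future__ import annotations

from dataclasses import dataclass, field

from .formula import round_half_up

__all__ = ["Spectrum"]


@dataclass
class Spectrum:
    """A single MS or MS/MS scan: polarity, precursor, collision energy, peaks.

    ``peaks`` is a list of ``(mz, intensity)`` tuples. Intensities may be raw
    counts or fractions; consumers that need total-ion-current fractions call
    :meth:`tic_fraction`, which is invariant to the intensity unit.
    """

    polarity: str = "negative"
    precursor_mz: float | None = None
    collision_energy: float | None = None
    peaks: list[tuple[float, float]] = field(default_factory=list)
    title: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"polarity must be negative/positive, got {self.polarity!r}")
        for mz, intensity in self.peaks:
            if intensity < 0:
                raise ValueError(f"negative intensity {intensity} at m/z {mz}")

    @property
    def tic(self) -> float:
        """Total ion current: sum of all peak intensities."""
        return float(sum(i for _, i in self.peaks))

    def tic_fraction(self, nominal: int) -> float:
        """Summed TIC fraction of peaks whose half-up-rounded m/z equals *nominal*."""
        total = self.tic
        if total <= 0:
            return 0.0
        hit = sum(i for mz, i in self.peaks if int(round_half_up(mz)) == nominal)
        return hit / total

    def sorted_by_mz(self) -> "Spectrum":
        return Spectrum(
            polarity=self.polarity,
            precursor_mz=self.precursor_mz,
            collision_energy=self.collision_energy,
            peaks=sorted(self.peaks),
            title=self.title,
        )
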