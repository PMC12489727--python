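"""Two-stage CID intensity-ratio key for the four malonyl-dicaffeoylquinic acids.

The four MDiCQA regioisomers (here ``cpd4`` = 1,5-dicaffeoyl-3-malonyl,
``cpd5`` = 3,5-dicaffeoyl-1-malonyl, ``cpd6`` = 3,5-dicaffeoyl-4-malonyl on an
epi-quinic core, ``cpd7`` = 1,5-dicaffeoyl-4-malonyl) give identical fragment
m/z sets, but the relative intensities of three key ions are diagnostic:

Stage 1 — 25 eV spectrum, TIC fractions of m/z 233 and m/z 395:
  * 233 dominant (≈70%) with 395 in traces  → compound 4 or 7 (unresolved)
  * 395 dominant (≈35%) with 233 in traces  → compound 5
  * 233 and 395 comparably high (≈35%/30%)  → compound 6

Stage 2 — 45 eV spectrum, ratio R = I(173)/I(233):
  * R ≈ 1.3 (40%/30%) → compound 7
  * R ≈ 0.3 (8%/30%)  → compound 4

All intensities are fractions of the total ion current (TIC), never of the
base peak, so every rule is invariant to the raw intensity unit. Key ions are
matched at nominal (integer) m/z — high-resolution matching adds nothing to
the key itself.
"""

from __future__ import annotations

from dataclasses import dataclass

from .spectra import Spectrum

__all__ = [
    "KEY_IONS",
    "TRACE_THRESHOLD",
    "STAGE2_LOWER",
    "STAGE2_UPPER",
    "IsomerCall",
    "key_intensity",
    "classify_stage1",
    "classify_stage2",
    "classify",
]

#: Nominal m/z of the diagnostic ions.
KEY_IONS: tuple[int, ...] = (173, 233, 395)

#: TIC fraction below which a key ion counts as "trace".
TRACE_THRESHOLD: float = 0.05

#: Stage-2 dead band on R = I173/I233: below -> cpd4, above -> cpd7.
STAGE2_LOWER: float = 0.5
STAGE2_UPPER: float = 0.7

#: Stage-1 rule floors (TIC fractions).
_S1_GROUP_I233 = 0.5     # 233 dominant -> {4, 7}
_S1_CPD5_I395 = 0.25     # 395 dominant -> 5
_S1_CPD6_FLOOR = 0.2     # both high -> 6
_S1_CPD6_RATIO = (0.5, 2.0)  # "comparably high" band for I233/I395

#: Relative margin a rule must clear for a high-confidence call.
_MARGIN = 0.2


@dataclass(frozen=True)
class IsomerCall:
    """Decision-key verdict with the evidence that produced it."""

    label: str  # cpd4 | cpd5 | cpd6 | cpd7 | group_4_or_7 | inconclusive
    stage1_evidence: tuple[float, float]  # (I233, I395) as TIC fractions
    stage2_ratio: float | None
    confidence: str  # high | low

    def __post_init__(self) -> None:
        if self.label in ("cpd4", "cpd7") and self.stage2_ratio is None:
            raise ValueError(f"label {self.label} requires stage-2 evidence")


def key_intensity(spec: Spectrum, nominal: int) -> float:
    """TIC fraction carried by peaks whose rounded m/z equals *nominal*."""
    return spec.tic_fraction(nominal)


def _require_energy(spec: Spectrum, expected: float, stage: str) -> None:
    if spec.collision_energy != expected:
        raise ValueError(
            f"{stage} requires a {expected:g} eV spectrum, "
            f"got collision energy {spec.collision_energy!r}"
        )


def classify_stage1(spec25: Spectrum) -> str:
    """First-stage call from the 25 eV spectrum: cpd5, cpd6, group_4_or_7 or inconclusive."""
    _require_energy(spec25, 25, "stage 1")
    i233 = key_intensity(spec25, 233)
    i395 = key_intensity(spec25, 395)
    if i233 >= _S1_GROUP_I233 and i395 < TRACE_THRESHOLD:
        return "group_4_or_7"
    if i395 >= _S1_CPD5_I395 and i233 < TRACE_THRESHOLD:
        return "cpd5"
    if (
        i233 >= _S1_CPD6_FLOOR
        and i395 >= _S1_CPD6_FLOOR
        and _S1_CPD6_RATIO[0] <= i233 / i395 <= _S1_CPD6_RATIO[1]
    ):
        return "cpd6"
    return "inconclusive"


def classify_stage2(spec45: Spectrum) -> str:
    """Second-stage call from the 45 eV spectrum: cpd4, cpd7 or inconclusive."""
    _require_energy(spec45, 45, "stage 2")
    i233 = key_intensity(spec45, 233)
    if i233 == 0:
        raise ValueError("diagnostic denominator absent: no m/z 233 ion at 45 eV")
    ratio = key_intensity(spec45, 173) / i233
    if ratio >= STAGE2_UPPER:
        return "cpd7"
    if ratio <= STAGE2_LOWER:
        return "cpd4"
    return "inconclusive"


def _stage1_margin_ok(label: str, i233: float, i395: float) -> bool:
    """Did every stage-1 rule fire with >= 20% margin on its threshold?"""
    lo, hi = _S1_CPD6_RATIO
    if label == "group_4_or_7":
        return i233 >= _S1_GROUP_I233 * (1 + _MARGIN) and i395 < TRACE_THRESHOLD * (1 - _MARGIN)
    if label == "cpd5":
        return i395 >= _S1_CPD5_I395 * (1 + _MARGIN) and i233 < TRACE_THRESHOLD * (1 - _MARGIN)
    if label == "cpd6":
        ratio = i233 / i395 if i395 > 0 else float("inf")
        return (
            i233 >= _S1_CPD6_FLOOR * (1 + _MARGIN)
            and i395 >= _S1_CPD6_FLOOR * (1 + _MARGIN)
            and lo * (1 + _MARGIN) <= ratio <= hi / (1 + _MARGIN)
        )
    return False


def _stage2_margin_ok(label: str, ratio: float) -> bool:
    if label == "cpd7":
        return ratio >= STAGE2_UPPER * (1 + _MARGIN)
    if label == "cpd4":
        return ratio <= STAGE2_LOWER * (1 - _MARGIN)
    return False


def classify(spec25: Spectrum, spec45: Spectrum | None = None) -> IsomerCall:
    """Full two-stage key.

    Stage 1 runs on the mandatory 25 eV spectrum; when it returns the
    unresolved {4, 7} group and a 45 eV spectrum is available, stage 2
    refines the call via R = I(173)/I(233). Confidence is ``high`` only when
    every rule that fired did so with at least a 20% margin on its threshold;
    an unrefined group call is always ``low``.
    """
    i233 = key_intensity(spec25, 233)
    i395 = key_intensity(spec25, 395)
    stage1 = classify_stage1(spec25)
    ratio: float | None = None

    if stage1 != "group_4_or_7":
        confidence = "high" if _stage1_margin_ok(stage1, i233, i395) else "low"
        return IsomerCall(stage1, (i233, i395), None, confidence)

    if spec45 is None:
        return IsomerCall("group_4_or_7", (i233, i395), None, "low")

    stage2 = classify_stage2(spec45)
    ratio = key_intensity(spec45, 173) / key_intensity(spec45, 233)
    if stage2 == "inconclusive":
        return IsomerCall("group_4_or_7", (i233, i395), ratio, "low")
    confident = _stage1_margin_ok("group_4_or_7", i233, i395) and _stage2_margin_ok(
        stage2, ratio
    )
    return IsomerCall(stage2, (i233, i395), ratio, "high" if confident else "low")
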