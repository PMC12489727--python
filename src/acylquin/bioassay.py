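"""Dose-response (IC50) fitting, activity flagging and tissue summaries.

IC50 estimation uses the four-parameter logistic (4PL)::

    f(d) = bottom + (top - bottom) / (1 + (ic50 / d) ** hill)

fitted by nonlinear least squares in log-IC50 parameterization (which keeps
the positivity constraint implicit and makes the standard error symmetric on
the scale where the likelihood is closest to quadratic). The same machinery
serves radical-scavenging data (% inhibition rising with dose) and viability
data (% viability falling with dose) via the ``direction`` flag; a falling
curve is simply a 4PL with top and bottom exchanged, so the fit is shared and
only the censoring rule reads the direction.

A linear-interpolation crossing estimate is provided as an independent
cross-check of the 4PL fit; it is never the default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .structures import Structure, catechol_count

__all__ = [
    "DoseResponse",
    "IC50Fit",
    "TissueSummary",
    "four_pl",
    "fit_ic50",
    "interpolate_ic50",
    "activity_flag",
    "summarize_tissues",
]


@dataclass(frozen=True)
class DoseResponse:
    """Dose series (concentration, ascending) with percent responses."""

    doses: tuple[float, ...]
    responses: tuple[float, ...]
    replicate: str = ""

    def __post_init__(self) -> None:
        if len(self.doses) != len(self.responses):
            raise ValueError("doses and responses must have equal length")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")
        if any(not math.isfinite(r) for r in self.responses):
            raise ValueError("responses must be finite")
        if list(self.doses) != sorted(self.doses):
            raise ValueError("doses must be ascending")


@dataclass(frozen=True)
class IC50Fit:
    ic50: float | None
    hill: float | None
    bottom: float | None
    top: float | None
    se_ic50: float | None
    se_log_ic50: float | None
    status: str  # ok | censored_above_max | failed
    message: str = ""


@dataclass(frozen=True)
class TissueSummary:
    compound: str
    mean_by_organ_phase: dict[tuple[str, str], float]
    organ_means: dict[str, float]
    argmax_record: dict
    fold_difference: float


def four_pl(dose, bottom: float, top: float, log_ic50: float, hill: float):
    """4PL response at *dose* (vectorized); log_ic50 is the natural log."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (log_ic50 - np.log(dose))))


def fit_ic50(dr: DoseResponse, direction: str = "inhibition") -> IC50Fit:
    """Least-squares 4PL fit; IC50 is the dose of half-maximal effect.

    Requires at least five dose levels. Returns ``censored_above_max`` when
    the observed effect never reaches 50% (for inhibition: max response
    below 50%; for viability: min response above 50%), and ``failed`` with a
    diagnostic message on non-convergence.
    """
    if direction not in ("inhibition", "viability"):
        raise ValueError(f"direction must be inhibition/viability, got {direction!r}")
    if len(dr.doses) < 5:
        raise ValueError(
            f"IC50 fitting needs >= 5 dose levels, got {len(dr.doses)}"
        )
    doses = np.asarray(dr.doses, dtype=float)
    resp = np.asarray(dr.responses, dtype=float)

    if direction == "inhibition" and resp.max() < 50.0:
        return IC50Fit(None, None, None, None, None, None, "censored_above_max",
                       f"max response {resp.max():.1f}% never reaches 50%")
    if direction == "viability" and resp.min() > 50.0:
        return IC50Fit(None, None, None, None, None, None, "censored_above_max",
                       f"min viability {resp.min():.1f}% never falls to 50%")

    rising = direction == "inhibition"
    b0 = float(resp.min()) if rising else float(resp.max())
    t0 = float(resp.max()) if rising else float(resp.min())
    # crossing of the half-effect level as the log-IC50 start value
    half = 0.5 * (b0 + t0)
    order = np.argsort(np.abs(resp - half))
    lg0 = float(np.log(doses[order[0]]))
    p0 = (b0, t0, lg0, 1.0 if rising else 1.0)
    # note: a falling curve is fitted with top < bottom and positive hill
    if not rising:
        p0 = (t0, b0, lg0, 1.0)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                four_pl, doses, resp, p0=p0, maxfev=20000,
                bounds=([-50.0, -50.0, np.log(doses.min()) - 5.0, 0.05],
                        [150.0, 150.0, np.log(doses.max()) + 5.0, 10.0]),
            )
    except (RuntimeError, ValueError) as exc:
        return IC50Fit(None, None, None, None, None, None, "failed", str(exc))

    bottom, top, log_ic50, hill = (float(v) for v in popt)
    var_log = float(pcov[2, 2])
    if not math.isfinite(var_log) or var_log < 0:
        return IC50Fit(None, None, None, None, None, None, "failed",
                       "singular covariance: IC50 standard error undefined")
    ic50 = math.exp(log_ic50)
    se_log = math.sqrt(var_log)
    lo, hi = sorted((bottom, top))
    return IC50Fit(
        ic50=ic50,
        hill=hill,
        bottom=lo,
        top=hi,
        se_ic50=ic50 * se_log,  # delta method
        se_log_ic50=se_log,
        status="ok",
    )


def interpolate_ic50(dr: DoseResponse, direction: str = "inhibition") -> float | None:
    """Model-free cross-check: log-linear interpolation at the 50% crossing.

    Returns None when the response never crosses 50%.
    """
    doses = np.asarray(dr.doses, dtype=float)
    resp = np.asarray(dr.responses, dtype=float)
    if direction == "viability":
        resp = 100.0 - resp
    above = resp >= 50.0
    if not above.any() or above.all():
        return None
    i = int(np.argmax(above))  # first dose at/above 50%
    if i == 0:
        return float(doses[0])
    x0, x1 = np.log(doses[i - 1]), np.log(doses[i])
    y0, y1 = resp[i - 1], resp[i]
    return float(np.exp(x0 + (50.0 - y0) * (x1 - x0) / (y1 - y0)))


def activity_flag(s: Structure) -> str:
    """Radical-scavenging structure flag: any catechol -> ``catechol_bearing``.

    The ortho-dihydroxy unit is the hydrogen donor behind strong DPPH
    activity; structures without one (kaempferol glycosides, bare quinic
    acid) are flagged ``catechol_free``.
    """
    return "catechol_bearing" if catechol_count(s) >= 1 else "catechol_free"


def summarize_tissues(records, compound: str) -> TissueSummary:
    """Organ x phase concentration summary for one compound.

    *records* is an iterable of mappings (or a DataFrame) with columns
    ``species, organ, phase, compound, mg_per_g``. Returns per-cell means,
    the single highest record, and the fold difference between the highest
    and lowest positive organ means (phases pooled). Order-invariant.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if df.empty or "compound" not in df.columns:
        raise ValueError(f"no records for compound {compound!r}")
    sub = df[df["compound"] == compound]
    if sub.empty:
        raise ValueError(f"no records for compound {compound!r}")
    if (sub["mg_per_g"] < 0).any():
        raise ValueError("concentrations must be non-negative")

    cell_means = (
        sub.groupby(["organ", "phase"], sort=True)["mg_per_g"].mean().to_dict()
    )
    organ_means = sub.groupby("organ", sort=True)["mg_per_g"].mean().to_dict()
    top = sub.loc[sub["mg_per_g"].idxmax()].to_dict()
    positive = [m for m in organ_means.values() if m > 0]
    fold = max(positive) / min(positive) if positive else float("nan")
    return TissueSummary(
        compound=compound,
        mean_by_organ_phase=cell_means,
        organ_means=organ_means,
        argmax_record=top,
        fold_difference=float(fold),
    )
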