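"""Detection of in-source catechol-oxidation ion series in MS1 spectra.

Catechol (ortho-dihydroxybenzene) moieties oxidize in the electrospray source
to ortho-quinones, losing two hydrogen atoms per catechol. A compound with
``n`` catechol units can therefore show satellite ions at −2.0157 Da (singly
oxidized) up to −n × 2.0157 Da below the intact (de)protonated species. The
satellite pattern depends on eluent acidity, not on the analyte, so flagging
the series — rather than treating satellites as distinct analytes — keeps
identification and quantitation robust.

Oxidation states are labelled ``"0"``, ``"-2H"``, ``"-4H"``, ... in reports;
internally they are integers k = 0, 1, 2 (number of oxidized catechols).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formula import ISOTOPE_MASS

__all__ = [
    "H2_MASS",
    "OxidationSeries",
    "state_label",
    "detect_series",
    "dominant_state",
    "merge_series_intensity",
]

#: Mass removed per oxidation event: two hydrogen atoms (exact, not nominal 2 Da).
H2_MASS: float = 2.0 * ISOTOPE_MASS["H"]  # 2.01565...


def state_label(k: int) -> str:
    """Human-readable oxidation-state label: 0 -> '0', 1 -> '-2H', 2 -> '-4H'."""
    return "0" if k == 0 else f"-{2 * k}H"


@dataclass
class OxidationSeries:
    """An intact ion plus its detected oxidation satellites.

    ``members`` maps oxidation state k (0 = intact) to the observed
    ``(mz, intensity)``. ``anomalies`` records satellite-like peaks that the
    catechol count cannot explain (e.g. a −2H peak next to a catechol-free
    compound) — these are never claimed as oxidation.
    """

    base_mz: float
    n_catechol: int
    members: dict[int, tuple[float, float]] = field(default_factory=dict)
    anomalies: list[str] = field(default_factory=list)
    tie: bool = False


def detect_series(
    peaks: list[tuple[float, float]],
    base_mz: float,
    n_catechol: int,
    tol_ppm: float = 10.0,
) -> OxidationSeries:
    """Locate the intact ion and its −2H/−4H satellites in an MS1 peak list.

    The intact species must be present within *tol_ppm* of *base_mz*
    (a missing base peak is an error distinct from "base present, no
    satellites"). Satellites are searched at base − k×2.01565 for
    k = 1..n_catechol; one extra position is probed only to raise an anomaly
    flag, guarding against isotope misassignment.
    """
    if n_catechol < 0:
        raise ValueError("n_catechol must be non-negative")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")

    def find(target: float) -> tuple[float, float] | None:
        tol = target * tol_ppm * 1e-6
        hits = [(abs(mz - target), mz, i) for mz, i in peaks if abs(mz - target) <= tol]
        if not hits:
            return None
        _, mz, i = min(hits)
        return mz, i

    base = find(base_mz)
    if base is None:
        raise ValueError(
            f"no base peak within {tol_ppm} ppm of m/z {base_mz:.4f}: "
            "cannot anchor an oxidation series (base absent, not merely no satellites)"
        )
    series = OxidationSeries(base_mz=base[0], n_catechol=n_catechol, members={0: base})
    for k in range(1, n_catechol + 1):
        hit = find(base_mz - k * H2_MASS)
        if hit is not None:
            series.members[k] = hit
    beyond = find(base_mz - (n_catechol + 1) * H2_MASS)
    if beyond is not None:
        series.anomalies.append(
            f"peak at m/z {beyond[0]:.4f} sits {2 * (n_catechol + 1)} H below the base "
            f"ion but only {n_catechol} catechol unit(s) are available; "
            "not assigned to oxidation"
        )
    return series


def dominant_state(series: OxidationSeries) -> str:
    """Oxidation-state label of the most intense series member.

    Ties resolve to the lower oxidation state and set ``series.tie``.
    """
    if not series.members:
        raise ValueError("empty oxidation series has no dominant state")
    best_intensity = max(i for _, i in series.members.values())
    winners = sorted(k for k, (_, i) in series.members.items() if i == best_intensity)
    series.tie = len(winners) > 1
    return state_label(winners[0])


def merge_series_intensity(series: OxidationSeries) -> tuple[float, float]:
    """Total series intensity attributed to the intact species.

    Returns ``(base_mz, summed intensity)``; summing over oxidation states
    makes quantitation insensitive to eluent-dependent in-source oxidation.
    """
    if not series.members:
        raise ValueError("empty oxidation series")
    return series.base_mz, float(sum(i for _, i in series.members.values()))
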