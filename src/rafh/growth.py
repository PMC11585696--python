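"""GA growth-rate metrics and baseline-area tertile stratification.

Three per-eye growth rates, each computed from the FIRST and LAST visits
only (intermediate visits do not enter the subtraction):

* area rate, mm^2/yr:        (A_last - A_first) / dt
* square-root rate, mm/yr:   (sqrt(A_last) - sqrt(A_first)) / dt
* perimeter-adjusted, mm/yr: area rate / mean(P_first, P_last)

The square-root transform reduces the dependence of the growth rate on the
baseline lesion size; the perimeter-adjusted rate approximates the mean
radial expansion speed of the lesion border (for a disc growing at constant
radial speed k it converges to k exactly, and the square-root rate to
sqrt(pi)*k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io import EyeSeries


@dataclass
class GrowthRates:
    """Per-eye growth summary; ``tertile`` is set by :func:`assign_tertiles`."""

    participant_id: str
    eye: str
    area_rate: float
    sqrt_rate: float
    perim_adj_rate: float
    dt_years: float
    baseline_area_mm2: float
    tertile: int | None = None


def _endpoints(series: EyeSeries) -> tuple[float, float, float]:
    if series.n_visits < 2:
        raise ValueError(
            f"eye ({series.participant_id}, {series.eye}) has {series.n_visits} visit(s); "
            "growth needs a baseline and at least one follow-up"
        )
    t = series.times
    dt = float(t[-1] - t[0])
    if dt <= 0:
        raise ValueError("zero or negative follow-up interval")
    return float(series.areas[0]), float(series.areas[-1]), dt


def area_growth_rate(series: EyeSeries) -> float:
    """(A_last - A_first) / dt in mm^2/yr."""
    a0, a1, dt = _endpoints(series)
    return (a1 - a0) / dt


def sqrt_growth_rate(series: EyeSeries) -> float:
    """(sqrt(A_last) - sqrt(A_first)) / dt in mm/yr; sqrt of the TOTAL area."""
    a0, a1, dt = _endpoints(series)
    if a0 < 0 or a1 < 0:
        raise ValueError("areas must be non-negative")
    return (math.sqrt(a1) - math.sqrt(a0)) / dt


def perimeter_adjusted_growth_rate(series: EyeSeries) -> float:
    """Area rate divided by the mean of first- and last-visit perimeters."""
    _, _, dt = _endpoints(series)
    p0 = float(series.perimeters[0])
    p1 = float(series.perimeters[-1])
    mean_p = 0.5 * (p0 + p1)
    if mean_p <= 0:
        raise ValueError("mean perimeter must be positive")
    return area_growth_rate(series) / mean_p


def growth_rates(series: EyeSeries) -> GrowthRates:
    """All three rates plus the baseline area for one eye."""
    a0, _, dt = _endpoints(series)
    return GrowthRates(
        participant_id=series.participant_id,
        eye=series.eye,
        area_rate=area_growth_rate(series),
        sqrt_rate=sqrt_growth_rate(series),
        perim_adj_rate=perimeter_adjusted_growth_rate(series),
        dt_years=dt,
        baseline_area_mm2=a0,
    )


def assign_tertiles(eyes: list[GrowthRates]) -> list[int]:
    """Split eyes into 3 near-equal groups by ascending baseline GA area.

    Stable sort with ties broken by (participant_id, eye); when n is not a
    multiple of 3 the remainder goes to the LOWER tertiles, so n=71 splits
    24/24/23.  Labels (1, 2, 3) are written back onto each GrowthRates and
    also returned in the input order.
    """
    n = len(eyes)
    if n < 3:
        raise ValueError(f"need at least 3 eyes to form tertiles, got {n}")
    order = sorted(
        range(n), key=lambda i: (eyes[i].baseline_area_mm2, eyes[i].participant_id, eyes[i].eye)
    )
    base, rem = divmod(n, 3)
    sizes = [base + (1 if t < rem else 0) for t in range(3)]
    labels = [0] * n
    pos = 0
    for tertile, size in enumerate(sizes, start=1):
        for i in order[pos : pos + size]:
            labels[i] = tertile
            eyes[i].tertile = tertile
        pos += size
    return labels
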