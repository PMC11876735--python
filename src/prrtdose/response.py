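"""Tumor response and toxicity reporting.

Size change is assessed on the product of the two CT diameters (area
L x W), as a percentage of the baseline area; the best change of a lesion
is its most favorable follow-up value (most negative, or the smallest
increase if it never shrank).  Dose-response association uses the Spearman
rank correlation of best change against cumulative absorbed dose.  Organ
doses are screened against the conventional conservative thresholds of
23 Gy to the kidneys and 2 Gy to the red marrow, and renal function series
against a decline of -20% per year from baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TumorMeasurement",
    "ToxicityThresholds",
    "CohortSummary",
    "size_change_pct",
    "best_change",
    "diameter_change_pct",
    "shrinkage_fraction",
    "dose_response_association",
    "renal_decline_rate",
    "threshold_flags",
    "incidence_proportion",
    "summarize_cohort",
]

ALLOWED_WEEKS = frozenset({0, 12, 24, 36, 48, 60, 72})


@dataclass(frozen=True)
class TumorMeasurement:
    """One bidimensional CT measurement of one lesion at one visit.

    ``L`` is the longest diameter and ``W`` the largest perpendicular
    diameter, both in mm; ``week`` is weeks from the first administration.
    """

    lesion_id: str
    week: int
    L: float
    W: float
    is_lymph_node: bool = False

    def __post_init__(self) -> None:
        if self.week not in ALLOWED_WEEKS:
            raise ValueError(f"week must be one of {sorted(ALLOWED_WEEKS)}, got {self.week}")
        if not (self.L >= self.W > 0):
            raise ValueError(f"need L >= W > 0, got L={self.L}, W={self.W}")

    @property
    def area(self) -> float:
        """Lesion area proxy L x W in mm^2."""
        return self.L * self.W


@dataclass(frozen=True)
class ToxicityThresholds:
    """Conservative organ-dose and renal-function screening thresholds."""

    kidney_course: float = 23.0  # Gy over the full course
    marrow_course: float = 2.0  # Gy over the full course
    renal_decline: float = -20.0  # percent per year

    def __post_init__(self) -> None:
        if self.kidney_course <= 0 or self.marrow_course <= 0:
            raise ValueError("kidney and marrow thresholds must be positive")


@dataclass(frozen=True)
class CohortSummary:
    """Mean (SD) and median (range) of one cohort metric."""

    mean: float
    sd: float
    median: float
    min: float
    max: float
    n: int
    single_value: bool = False

    def __post_init__(self) -> None:
        if not (self.min <= self.median <= self.max):
            raise ValueError("min <= median <= max violated")


def size_change_pct(area_t: float, area_baseline: float) -> float:
    """Percent area change from baseline: ((T_t / T_bl) - 1) x 100.

    Positive values are growth, negative values shrinkage.
    """
    if area_baseline <= 0:
        raise ValueError("baseline area must be positive")
    return (area_t / area_baseline - 1.0) * 100.0


def best_change(series: Iterable[tuple[float, float]]) -> float:
    """Best percent change of one lesion over its follow-up visits.

    ``series`` holds (week, percent-change) pairs for post-baseline visits.
    The best change is the greatest reduction, i.e. the minimum percent; for
    a lesion that never shrank it is the lowest increase.
    """
    changes = [pct for _, pct in series]
    if not changes:
        raise ValueError("best_change needs at least one post-baseline point")
    return min(changes)


def diameter_change_pct(at_time: TumorMeasurement, baseline: TumorMeasurement) -> float:
    """Percent change of a single diameter from baseline.

    Lymph node lesions are measured on the short axis (W), all others on the
    long axis (L).
    """
    if at_time.is_lymph_node != baseline.is_lymph_node:
        raise ValueError("lymph-node status must agree between visits")
    if baseline.is_lymph_node:
        return size_change_pct(at_time.W, baseline.W)
    return size_change_pct(at_time.L, baseline.L)


def shrinkage_fraction(
    lesions: Sequence[tuple[float, float]],
    dose_floor: float | None = None,
) -> tuple[int, int, float]:
    """Count lesions whose best change is negative.

    Parameters
    ----------
    lesions:
        (best_change_percent, cumulative_dose_Gy) per lesion.
    dose_floor:
        When given, only lesions with cumulative dose >= floor are counted.

    Returns
    -------
    (n_shrinking, n_total, percent) with the percent rounded to the nearest
    integer.
    """
    if dose_floor is not None:
        selected = [bc for bc, dose in lesions if dose >= dose_floor]
    else:
        selected = [bc for bc, _ in lesions]
    if not selected:
        raise ValueError("no lesions left after dose filtering")
    n_shrink = sum(1 for bc in selected if bc < 0)
    n_total = len(selected)
    return n_shrink, n_total, round(100.0 * n_shrink / n_total)


@dataclass(frozen=True)
class DoseResponseResult:
    rho: float
    p_value: float
    n: int
    undefined: bool
    table: pd.DataFrame = field(compare=False, repr=False, default=None)


def dose_response_association(
    pairs: Sequence[tuple[float, float]],
) -> DoseResponseResult:
    """Spearman rank correlation of best size change vs cumulative dose.

    Ties are mid-ranked.  A constant dose or change vector leaves the
    correlation undefined; the result is then flagged rather than raised,
    since a flat response is a legitimate cohort outcome.  The returned table
    (dose, best_change) is ready for a scatter plot.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (dose, change) pairs")
    doses = np.asarray([d for d, _ in pairs], dtype=float)
    changes = np.asarray([c for _, c in pairs], dtype=float)
    table = pd.DataFrame({"cumulative_dose_Gy": doses, "best_change_pct": changes})
    if np.ptp(doses) == 0 or np.ptp(changes) == 0:
        return DoseResponseResult(np.nan, np.nan, len(pairs), True, table)
    rho, p = stats.spearmanr(doses, changes)
    return DoseResponseResult(float(rho), float(p), len(pairs), False, table)


def renal_decline_rate(
    times_years: Sequence[float],
    clearance: Sequence[float],
    threshold_pct_per_year: float = -20.0,
) -> tuple[float, bool]:
    """Least-squares slope of percent creatinine-clearance change per year.

    The series is converted to percent change from its first (baseline)
    value; the unweighted least-squares slope against time in years is the
    decline rate.  The flag is set when the slope is at or below the
    impairment threshold (default -20 %/y).
    """
    t = np.asarray(times_years, dtype=float)
    y = np.asarray(clearance, dtype=float)
    if t.size < 2 or t.size != y.size:
        raise ValueError("need >=2 paired (time, clearance) points")
    if y[0] <= 0:
        raise ValueError("baseline clearance must be positive")
    pct = (y / y[0] - 1.0) * 100.0
    slope = float(np.polyfit(t, pct, 1)[0])
    # small absolute tolerance so a slope at exactly the threshold flags
    return slope, slope <= threshold_pct_per_year + 1e-9


def threshold_flags(
    kidney_course_dose: float,
    marrow_course_dose: float,
    thresholds: ToxicityThresholds = ToxicityThresholds(),
) -> dict[str, bool]:
    """Flag course doses strictly above the organ toxicity thresholds."""
    if kidney_course_dose < 0 or marrow_course_dose < 0:
        raise ValueError("doses must be non-negative")
    return {
        "kidney": kidney_course_dose > thresholds.kidney_course,
        "marrow": marrow_course_dose > thresholds.marrow_course,
    }


def incidence_proportion(events: int, n: int) -> float:
    """Percent incidence events/n, rounded to one decimal."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= events <= n:
        raise ValueError("need 0 <= events <= n")
    return round(100.0 * events / n, 1)


def summarize_cohort(values: Sequence[float]) -> CohortSummary:
    """Sample mean, SD (n-1), median, min and max of one metric.

    A single value yields SD 0 with the ``single_value`` flag set.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty metric")
    single = x.size == 1
    sd = 0.0 if single else float(np.std(x, ddof=1))
    return CohortSummary(
        mean=float(np.mean(x)),
        sd=sd,
        median=float(np.median(x)),
        min=float(np.min(x)),
        max=float(np.max(x)),
        n=int(x.size),
        single_value=single,
    )
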