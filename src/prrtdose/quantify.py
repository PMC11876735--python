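"""Conjugate-view (geometric-mean) planar activity quantification.

Given paired anterior/posterior count images and a set of region-of-interest
masks, each source's activity is

    A = sqrt(C_A * C_P / T) / (sensitivity * duration)

where C_A, C_P are background-corrected ROI counts and T = exp(-mu * d_body)
is the patient body transmission along the source axis.  The geometric mean
of the two views cancels the (unknown) source depth, which is what makes
planar quantification workable without tomography.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "PlanarScan",
    "RoiSet",
    "TimedActivitySample",
    "roi_counts",
    "conjugate_view_activity",
    "build_time_activity_series",
]

WHOLE_BODY = "whole_body"


@dataclass(frozen=True)
class PlanarScan:
    """One anterior/posterior planar acquisition."""

    anterior: np.ndarray
    posterior: np.ndarray
    time_post_injection: float  # h
    duration: float  # s
    sensitivity: float  # counts/(MBq*s)

    def __post_init__(self) -> None:
        if self.anterior.shape != self.posterior.shape:
            raise ValueError("anterior and posterior images must share shape")
        if np.any(np.asarray(self.anterior) < 0) or np.any(np.asarray(self.posterior) < 0):
            raise ValueError("count images must be non-negative")
        if self.time_post_injection <= 0 or self.duration <= 0:
            raise ValueError("time and duration must be positive")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")


@dataclass(frozen=True)
class RoiSet:
    """Source ROI masks, one background mask, and per-source transmissions.

    ``transmission`` holds exp(-mu * body_thickness) per source, in (0, 1].
    Source masks may not overlap each other (overlap disambiguation is out of
    scope and raises), and the background mask must be disjoint from every
    source.  The whole-body mask, when present under the key ``whole_body``,
    is exempt from the overlap rule since it contains the sources by design.
    """

    masks: Mapping[str, np.ndarray]
    background: np.ndarray
    transmission: Mapping[str, float]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()} | {self.background.shape}
        if len(shapes) != 1:
            raise ValueError("all ROI masks must share one shape")
        occupied = np.zeros(self.background.shape, dtype=bool)
        for name, mask in self.masks.items():
            if not mask.any():
                raise ValueError(f"ROI {name!r} is empty")
            if name == WHOLE_BODY:
                continue
            if (occupied & mask).any():
                raise ValueError(f"ROI {name!r} overlaps another source ROI")
            occupied |= mask
            if (mask & self.background).any():
                raise ValueError(f"background overlaps source ROI {name!r}")
        if not self.background.any():
            raise ValueError("background ROI is empty")
        for name in self.masks:
            tr = self.transmission.get(name)
            if tr is None:
                raise ConfigurationError(f"no transmission factor for source {name!r}")
            if not 0.0 < tr <= 1.0:
                raise ValueError(f"transmission for {name!r} must lie in (0, 1]")


@dataclass(frozen=True)
class TimedActivitySample:
    """One source activity estimate at one imaging time point."""

    source: str
    time: float  # h
    fraction_of_injected: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.fraction_of_injected < 0 or self.sd < 0:
            raise ValueError("fraction and sd must be non-negative")


def roi_counts(
    scan: PlanarScan,
    roiset: RoiSet,
    source: str,
    background_correction: bool = True,
) -> tuple[float, float, bool]:
    """Background-corrected anterior and posterior ROI counts for one source.

    Correction subtracts (background mean counts per pixel) x (ROI pixel
    count) per view, flooring at zero.  Returns (cA, cP, floored) where the
    flag marks a view whose correction exceeded its raw counts.
    """
    if source not in roiset.masks:
        raise KeyError(f"source {source!r} not in ROI set")
    mask = roiset.masks[source]
    floored = False
    out = []
    for img in (scan.anterior, scan.posterior):
        raw = float(np.asarray(img)[mask].sum())
        if background_correction:
            bg_mean = float(np.asarray(img)[roiset.background].mean())
            corrected = raw - bg_mean * int(mask.sum())
            if corrected < 0:
                corrected = 0.0
                floored = True
                warnings.warn(
                    f"background correction exceeded ROI counts for {source!r}; floored at 0",
                    stacklevel=2,
                )
        else:
            corrected = raw
        out.append(corrected)
    return out[0], out[1], floored


def conjugate_view_activity(
    counts_anterior: float,
    counts_posterior: float,
    transmission: float,
    scan: PlanarScan,
) -> float:
    """Source activity [MBq] from the geometric mean of the two views."""
    if counts_anterior < 0 or counts_posterior < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 < transmission <= 1.0:
        raise ValueError("transmission must lie in (0, 1]")
    geo = math.sqrt(counts_anterior * counts_posterior / transmission)
    return geo / (scan.sensitivity * scan.duration)


def _sample_sd(cA: float, cP: float, activity: float) -> float:
    # Poisson error propagation through sqrt(cA*cP): rel sd = 0.5*sqrt(1/cA+1/cP)
    if cA <= 0 or cP <= 0:
        return 0.0
    return 0.5 * math.sqrt(1.0 / cA + 1.0 / cP) * activity


def build_time_activity_series(
    scans: Sequence[PlanarScan],
    roiset: RoiSet,
    injected_activity: float,
    normalize_first_wholebody: bool = False,
    background_correction: bool = True,
) -> pd.DataFrame:
    """Quantify every source on every scan into a tidy time-activity table.

    Returns a DataFrame with columns (source, time_h, fraction_ia, sd).  With
    ``normalize_first_wholebody`` all fractions are rescaled so the
    whole-body estimate at the first time point equals 1.0 — a common
    calibration when the first scan precedes any excretion.
    """
    if len(scans) < 2:
        raise ValueError("need at least 2 scans")
    times = [s.time_post_injection for s in scans]
    if np.any(np.diff(times) <= 0):
        raise ValueError("scan times must be strictly increasing")
    if injected_activity <= 0:
        raise ValueError("injected activity must be positive")
    if normalize_first_wholebody and WHOLE_BODY not in roiset.masks:
        raise ConfigurationError(
            "normalize_first_wholebody requires a 'whole_body' ROI"
        )

    rows = []
    for scan in scans:
        for source in roiset.masks:
            cA, cP, _ = roi_counts(scan, roiset, source, background_correction)
            act = conjugate_view_activity(cA, cP, roiset.transmission[source], scan)
            rows.append(
                {
                    "source": source,
                    "time_h": scan.time_post_injection,
                    "fraction_ia": act / injected_activity,
                    "sd": _sample_sd(cA, cP, act) / injected_activity,
                }
            )
    table = pd.DataFrame(rows)
    if normalize_first_wholebody:
        first = table[
            (table.source == WHOLE_BODY)
            & (table.time_h == table.time_h.min())
        ].fraction_ia.iloc[0]
        if first <= 0:
            raise ConfigurationError("first whole-body estimate is zero; cannot normalize")
        table[["fraction_ia", "sd"]] /= first
    return table
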