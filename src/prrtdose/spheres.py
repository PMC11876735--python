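"""Unit-density-sphere tumor dosimetry.

A lesion is modeled as an isolated unit-density sphere with uniform
activity.  Its dose factor (absorbed dose per unit time-integrated
activity) is

    df(m) = N * [Delta_np + phi_p(m) * Delta_p] / m

with N the nuclear transformations per MBq·h, Delta_np the non-penetrating
(beta + conversion/Auger electron) energy per decay — fully absorbed in
spheres at these sizes — Delta_p the photon energy per decay, phi_p(m) the
mass-dependent photon absorbed fraction, and m the sphere mass.  Dose
factors are tabulated on a mass grid and interpolated log-log for each
lesion, which is exact in the electron-only limit where df is a pure
power law 1/m.

Lesion uptake is assumed proportional to mass across cycles, so the
absorbed dose per administration is constant for equal injected activity
and the cumulative course dose scales by total administered activity over
the reference-cycle activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .constants import LU177, PhysicalConstants
from .organs import AdministrationRecord

__all__ = [
    "RadionuclideEmissionData",
    "SphereDoseFactorTable",
    "Lesion",
    "LU177_EMISSION",
    "build_sphere_table",
    "default_sphere_table",
    "interp_df",
    "lesion_dose",
    "cumulative_lesion_dose",
    "fractions_at_thresholds",
]

LOCATION_CLASSES = ("liver", "lymph_node", "bone", "other")


@dataclass(frozen=True)
class RadionuclideEmissionData:
    """Per-decay emission energies and photon absorbed fractions.

    ``photon_absorbed_fraction`` maps sphere mass [g] to the fraction of
    emitted photon energy absorbed in the sphere; it must be non-decreasing
    in mass.  Queries between tabulated masses are interpolated linearly in
    log-mass.
    """

    delta_nonpenetrating: float  # J per decay
    delta_penetrating: float  # J per decay
    photon_absorbed_fraction: Mapping[float, float]

    def __post_init__(self) -> None:
        if self.delta_nonpenetrating <= 0 or self.delta_penetrating <= 0:
            raise ValueError("emission energies must be positive")
        masses = sorted(self.photon_absorbed_fraction)
        phis = [self.photon_absorbed_fraction[m] for m in masses]
        if any(not 0.0 <= p <= 1.0 for p in phis):
            raise ValueError("absorbed fractions must lie in [0, 1]")
        if any(b < a for a, b in zip(phis, phis[1:])):
            raise ValueError("photon absorbed fraction must be non-decreasing in mass")

    def phi(self, mass: float) -> float:
        masses = np.array(sorted(self.photon_absorbed_fraction), dtype=float)
        phis = np.array(
            [self.photon_absorbed_fraction[m] for m in masses], dtype=float
        )
        if not masses[0] <= mass <= masses[-1]:
            raise ValueError(
                f"mass {mass} g outside the tabulated absorbed-fraction range "
                f"[{masses[0]}, {masses[-1]}] g"
            )
        return float(np.interp(np.log(mass), np.log(masses), phis))


#: Lu-177 emission data: mean electron (beta + conversion/Auger) energy of
#: ~148 keV per decay and ~33 keV of photon energy per decay (113 and
#: 208 keV gammas weighted by yield).  The absorbed fractions are a smooth
#: synthetic table with the expected magnitude and monotonicity for soft
#: tissue spheres of 1-1000 g.
LU177_EMISSION = RadionuclideEmissionData(
    delta_nonpenetrating=2.37e-14,
    delta_penetrating=5.3e-15,
    photon_absorbed_fraction={1.0: 0.008, 10.0: 0.018, 100.0: 0.040, 1000.0: 0.085},
)


@dataclass(frozen=True)
class SphereDoseFactorTable:
    """Dose factors [Gy/(MBq·h)] on a strictly increasing mass grid [g]."""

    mass_grid: tuple[float, ...]
    df: tuple[float, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.mass_grid, dtype=float)
        d = np.asarray(self.df, dtype=float)
        if m.size != d.size or m.size < 2:
            raise ValueError("grid needs >=2 matching points")
        if np.any(m <= 0) or np.any(np.diff(m) <= 0):
            raise ValueError("mass grid must be positive and strictly increasing")
        if np.any(d <= 0) or np.any(np.diff(d) >= 0):
            raise ValueError("dose factors must be positive and strictly decreasing in mass")


@dataclass
class Lesion:
    """One target lesion and its dosimetry results."""

    lesion_id: str
    location_class: str
    mass: float  # g
    tiac: float  # h
    dose_per_admin: float | None = None  # Gy
    cumulative_dose: float | None = None  # Gy

    def __post_init__(self) -> None:
        if self.location_class not in LOCATION_CLASSES:
            raise ValueError(
                f"location_class must be one of {LOCATION_CLASSES}"
            )
        if self.mass <= 0:
            raise ValueError("lesion mass must be positive")
        if self.tiac < 0:
            raise ValueError("lesion TIAC must be non-negative")


def build_sphere_table(
    emission: RadionuclideEmissionData,
    mass_grid: Sequence[float],
    constants: PhysicalConstants = LU177,
    include_photons: bool = True,
) -> SphereDoseFactorTable:
    """Tabulate sphere dose factors df(m) on a mass grid [g].

    With ``include_photons=False`` the dose factor is exactly proportional
    to 1/m (electron-only limit).
    """
    m = np.asarray(mass_grid, dtype=float)
    if np.any(np.diff(m) <= 0):
        raise ValueError("mass grid must be strictly increasing")
    df = []
    for mass in m:
        energy = emission.delta_nonpenetrating
        if include_photons:
            energy = energy + emission.phi(mass) * emission.delta_penetrating
        df.append(constants.decays_per_MBq_hour * energy / (mass / 1000.0))
    return SphereDoseFactorTable(tuple(float(x) for x in m), tuple(df))


def default_sphere_table(
    n_per_decade: int = 10, constants: PhysicalConstants = LU177
) -> SphereDoseFactorTable:
    """Lu-177 sphere dose-factor table on a 1-1000 g logarithmic grid."""
    grid = np.logspace(0, 3, 3 * n_per_decade + 1)
    return build_sphere_table(LU177_EMISSION, grid, constants)


def interp_df(
    table: SphereDoseFactorTable, mass: float, extrapolate: bool = False
) -> float:
    """Log-log interpolated dose factor at a lesion mass [Gy/(MBq·h)].

    Masses outside the grid raise by default (a lesion below the smallest
    tabulated sphere is typically below camera resolution and should be
    excluded, not extrapolated silently); with ``extrapolate=True`` the
    nearest power-law segment is extended, with a warning.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    m = np.log(np.asarray(table.mass_grid))
    d = np.log(np.asarray(table.df))
    x = np.log(mass)
    if not m[0] <= x <= m[-1]:
        if not extrapolate:
            raise ValueError(
                f"mass {mass} g outside grid [{table.mass_grid[0]}, "
                f"{table.mass_grid[-1]}] g; pass extrapolate=True to extend"
            )
        warnings.warn(
            f"power-law extrapolation of sphere dose factor at {mass} g",
            stacklevel=2,
        )
        if x < m[0]:
            slope = (d[1] - d[0]) / (m[1] - m[0])
            return float(np.exp(d[0] + slope * (x - m[0])))
        slope = (d[-1] - d[-2]) / (m[-1] - m[-2])
        return float(np.exp(d[-1] + slope * (x - m[-1])))
    return float(np.exp(np.interp(x, m, d)))


def lesion_dose(
    tiac: float,
    mass: float,
    table: SphereDoseFactorTable,
    administered: float,
    extrapolate: bool = False,
) -> float:
    """Lesion absorbed dose for one administration [Gy].

    D = administered [MBq] x tiac [h] x df(mass) [Gy/(MBq·h)].
    """
    if administered <= 0:
        raise ValueError("administered activity must be positive")
    if tiac < 0:
        raise ValueError("TIAC must be non-negative")
    return administered * tiac * interp_df(table, mass, extrapolate)


def cumulative_lesion_dose(
    dose_per_admin: float, admin: AdministrationRecord
) -> float:
    """Cumulative course dose under the constant-uptake assumption [Gy].

    With uptake proportional to mass the per-cycle dose is constant for
    equal injected activity, so the cumulative dose scales the measured
    cycle by total administered over reference-cycle activity.
    """
    if dose_per_admin < 0:
        raise ValueError("dose per administration must be non-negative")
    ref = admin.cycle_activities[admin.reference_cycle]
    return dose_per_admin * admin.total_administered / ref


def fractions_at_thresholds(
    cumulative_doses: Sequence[float], thresholds: Sequence[float]
) -> dict[float, float]:
    """Percent of lesions at or above each dose threshold, to one decimal."""
    doses = np.asarray(cumulative_doses, dtype=float)
    if doses.size == 0:
        raise ValueError("cumulative dose list is empty")
    return {
        float(th): round(100.0 * float(np.mean(doses >= th)), 1)
        for th in thresholds
    }
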