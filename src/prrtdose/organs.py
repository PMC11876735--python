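"""MIRD-schema organ dosimetry from TIACs and S-value tables.

The absorbed dose to a target per unit administered activity is the
source-summed product D/A0 = sum_s tau_s * S(target <- source), with tau in
hours and S in Gy/(GBq·h) (numerically equal to mGy/(MBq·h)).  Activity not
assigned to an explicit source organ is carried by the remainder of body,
whose TIAC is the total-body TIAC minus the explicit sources and whose
S-value is the mass-weighted correction of the total-body S-value.

The red marrow is handled with the blood-based model: marrow activity
concentration is assumed proportional to blood activity concentration, so
the marrow TIAC is the cumulated blood concentration [h/kg] times the
marrow mass and the marrow-to-blood concentration ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConservationError
from .kinetics import KineticFit, tiac_analytic

__all__ = [
    "DoseFactorTable",
    "MarrowModelParams",
    "AdministrationRecord",
    "OrganDoseResult",
    "TOTAL_BODY",
    "REMAINDER",
    "remainder_tiac",
    "remainder_s_value",
    "organ_dose_per_unit",
    "red_marrow_tiac",
    "course_dose",
    "organ_doses",
]

TOTAL_BODY = "total_body"
REMAINDER = "remainder"

_S_COLUMNS = ("target", "source", "s_value_Gy_per_GBq_h")
_MASS_COLUMNS = ("organ", "mass_g")


@dataclass(frozen=True)
class DoseFactorTable:
    """Phantom S-values [Gy/(GBq·h)] and organ masses [g].

    ``s`` maps (target, source) pairs; every organ appearing in ``s`` must
    have a mass, and the total-body mass must be at least the sum of the
    explicit organ masses.
    """

    phantom_id: str
    organ_masses: Mapping[str, float]
    total_body_mass: float
    s: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        if self.total_body_mass <= 0:
            raise ValueError("total body mass must be positive")
        for organ, mass in self.organ_masses.items():
            if mass <= 0:
                raise ValueError(f"mass of {organ!r} must be positive")
        explicit = sum(
            m for o, m in self.organ_masses.items() if o != TOTAL_BODY
        )
        if explicit > self.total_body_mass:
            raise ValueError("organ masses exceed total body mass")
        for (tgt, src), val in self.s.items():
            if val < 0:
                raise ValueError(f"S({tgt}<-{src}) must be non-negative")
            for organ in (tgt, src):
                if organ != TOTAL_BODY and organ not in self.organ_masses:
                    raise ValueError(f"organ {organ!r} in S-table has no mass entry")

    def s_value(self, target: str, source: str) -> float:
        try:
            return self.s[(target, source)]
        except KeyError:
            raise ConfigurationError(
                f"no S-value for target {target!r} <- source {source!r}"
            ) from None

    @classmethod
    def from_csv(cls, s_path: str | Path, mass_path: str | Path, phantom_id: str = "") -> "DoseFactorTable":
        """Load S-values and organ masses from unit-annotated CSV files."""
        s_df = pd.read_csv(s_path)
        if tuple(s_df.columns[:3]) != _S_COLUMNS:
            raise ConfigurationError(
                f"S-value CSV must have columns {_S_COLUMNS}, got {tuple(s_df.columns)}"
            )
        m_df = pd.read_csv(mass_path)
        if tuple(m_df.columns[:2]) != _MASS_COLUMNS:
            raise ConfigurationError(
                f"mass CSV must have columns {_MASS_COLUMNS}, got {tuple(m_df.columns)}"
            )
        masses = dict(zip(m_df.organ, m_df.mass_g.astype(float)))
        if TOTAL_BODY not in masses:
            raise ConfigurationError("mass CSV must include a total_body row")
        total = masses.pop(TOTAL_BODY)
        s = {
            (row.target, row.source): float(row.s_value_Gy_per_GBq_h)
            for row in s_df.itertuples()
        }
        return cls(phantom_id or str(s_path), masses, total, s)


@dataclass(frozen=True)
class MarrowModelParams:
    """Blood-based red marrow model parameters."""

    marrow_mass: float = 1.17  # kg, adult reference
    marrow_to_blood_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.marrow_mass <= 0 or self.marrow_to_blood_ratio < 0:
            raise ValueError("marrow mass must be positive and ratio non-negative")


@dataclass(frozen=True)
class AdministrationRecord:
    """Administered cycle activities [GBq] and the planned full course."""

    cycle_activities: tuple[float, ...]
    planned_course: float = 29.6  # GBq: 4 x 7.4
    reference_cycle: int = 0

    def __post_init__(self) -> None:
        if not self.cycle_activities or any(a <= 0 for a in self.cycle_activities):
            raise ValueError("every cycle activity must be positive")
        if not 0 <= self.reference_cycle < len(self.cycle_activities):
            raise ValueError("reference_cycle out of range")
        if self.planned_course <= 0:
            raise ValueError("planned course activity must be positive")

    @property
    def total_administered(self) -> float:
        return float(sum(self.cycle_activities))


@dataclass(frozen=True)
class OrganDoseResult:
    """Per-organ dose per unit activity and projected course dose."""

    organ: str
    dose_per_unit_activity: float  # Gy/GBq
    course_dose: float  # Gy
    tiac: float  # h

    def __post_init__(self) -> None:
        if self.dose_per_unit_activity < 0 or self.course_dose < 0:
            raise ValueError("doses must be non-negative")


def remainder_tiac(
    total_body_tiac: float, source_tiacs: Mapping[str, float]
) -> float:
    """Remainder-of-body TIAC: tau_TB minus the explicit source TIACs [h].

    Raises :class:`ConservationError` if the sources exceed the total body —
    that indicates inconsistent quantification, which must not be clipped.
    """
    if total_body_tiac <= 0:
        raise ValueError("total-body TIAC must be positive")
    src_sum = float(sum(source_tiacs.values()))
    rob = total_body_tiac - src_sum
    if rob < 0:
        raise ConservationError(
            f"source TIACs ({src_sum:.6g} h) exceed total-body TIAC "
            f"({total_body_tiac:.6g} h)"
        )
    return rob


def remainder_s_value(
    table: DoseFactorTable, target: str, explicit_sources: Sequence[str]
) -> float:
    """Mass-weighted remainder-of-body S-value for one target [Gy/(GBq·h)].

    S(t<-RoB) = [S(t<-TB)·M_TB − sum_s S(t<-s)·M_s] / M_RoB with
    M_RoB = M_TB − sum_s M_s.  A negative correction (possible with
    inconsistent tables) is floored at zero with a warning.
    """
    sources = [s for s in explicit_sources if s != TOTAL_BODY]
    m_sources = 0.0
    for s in sources:
        if s not in table.organ_masses:
            raise ConfigurationError(f"source {s!r} has no mass in the table")
        m_sources += table.organ_masses[s]
    m_rob = table.total_body_mass - m_sources
    if m_rob <= 0:
        raise ConfigurationError("remainder mass is non-positive")
    if not sources:
        return table.s_value(target, TOTAL_BODY)
    num = table.s_value(target, TOTAL_BODY) * table.total_body_mass
    num -= sum(table.s_value(target, s) * table.organ_masses[s] for s in sources)
    if num < 0:
        warnings.warn(
            f"remainder S-value for {target!r} is negative; floored at 0",
            stacklevel=2,
        )
        return 0.0
    return num / m_rob


def organ_dose_per_unit(
    tiacs: Mapping[str, float], table: DoseFactorTable, target: str
) -> float:
    """Target dose per unit administered activity: sum_s tau_s·S(t<-s) [Gy/GBq].

    ``tiacs`` must include the remainder term under the key ``"remainder"``
    (its S-value is resolved with :func:`remainder_s_value` against the other
    sources in the map).
    """
    if REMAINDER not in tiacs:
        raise ConfigurationError("tiacs must include a 'remainder' entry")
    explicit = [s for s in tiacs if s != REMAINDER]
    dose = 0.0
    for source, tau in tiacs.items():
        if tau < 0:
            raise ValueError(f"TIAC of {source!r} must be non-negative")
        if source == REMAINDER:
            s_val = remainder_s_value(table, target, explicit)
        else:
            s_val = table.s_value(target, source)
        dose += tau * s_val
    return dose


def red_marrow_tiac(
    blood_fit: KineticFit, params: MarrowModelParams = MarrowModelParams()
) -> float:
    """Red marrow TIAC from the blood-based model [h].

    The blood fit is over activity concentration in fraction of injected
    activity per kg; its integral [h/kg] times marrow mass [kg] and the
    marrow-to-blood concentration ratio gives the marrow TIAC.
    """
    cumulated_conc = tiac_analytic(blood_fit)  # h per kg
    return cumulated_conc * params.marrow_mass * params.marrow_to_blood_ratio


def course_dose(
    dose_per_unit: float, admin: AdministrationRecord, mode: str = "planned"
) -> float:
    """Project a full-course absorbed dose [Gy].

    ``mode="planned"`` scales by the planned course activity (default
    29.6 GBq); ``mode="actual"`` by the activities actually administered.
    """
    if dose_per_unit < 0:
        raise ValueError("dose per unit activity must be non-negative")
    if mode == "planned":
        return dose_per_unit * admin.planned_course
    if mode == "actual":
        return dose_per_unit * admin.total_administered
    raise ConfigurationError(f"unknown course mode {mode!r}")


def organ_doses(
    source_tiacs: Mapping[str, float],
    total_body_tiac: float,
    table: DoseFactorTable,
    targets: Sequence[str],
    admin: AdministrationRecord,
    mode: str = "planned",
) -> list[OrganDoseResult]:
    """Convenience driver: remainder handling plus per-target dose results."""
    rob = remainder_tiac(total_body_tiac, source_tiacs)
    tiacs = dict(source_tiacs)
    tiacs[REMAINDER] = rob
    out = []
    for target in targets:
        dpu = organ_dose_per_unit(tiacs, table, target)
        out.append(
            OrganDoseResult(
                organ=target,
                dose_per_unit_activity=dpu,
                course_dose=course_dose(dpu, admin, mode),
                tiac=float(source_tiacs.get(target, 0.0)),
            )
        )
    return out
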