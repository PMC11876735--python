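"""Study-scale synthetic cohort generator.

Builds a full synthetic dosimetry cohort with the structure of a typical
Lu-177 PRRT dosimetry substudy: 20 imaging patients with
kidney/liver/spleen kinetics (a subset of kidneys showing an uptake phase
peaking near 24 h), 4-6 planar time points over up to 7 days, blood
sampling, per-patient administration records (most patients complete
4 x 7.4 GBq cycles); and 65 target lesions across 17 patients with masses
spanning ~1-1000 g whose ground-truth cumulative doses follow a fixed
count structure (17 below 50 Gy, 14 between 50 and 100 Gy, 34 at or above
100 Gy).  52 lesions carry 72-week CT size courses: 35 of the 38 lesions
at >=50 Gy shrink (plateau area changes up to about -56%), as do 12 of
the 14 below, so 47 of 52 shrink overall.

Those counts are fixed inputs of the generator; every percentage reported
downstream is recomputed by the analysis chain, never copied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import LU177, substream
from .organs import AdministrationRecord
from .phantom import PhantomLesionSpec, PhantomOrganSpec, PhantomSpec, simulate_lesion_course
from .response import TumorMeasurement
from .spheres import Lesion, SphereDoseFactorTable, default_sphere_table, interp_df

__all__ = ["OrganPatient", "StudyCohort", "make_study_cohort", "default_organ_patient"]

#: default clinical imaging schedule [h] (5 points over 7 days)
DEFAULT_SCAN_TIMES = (1.0, 4.0, 24.0, 48.0, 168.0)
DEFAULT_SCAN_DURATION = 300.0  # s

# lesion dose strata: (count, low Gy, high Gy) — the printed frequency
# structure of cumulative target-lesion doses
DOSE_STRATA = ((17, 7.0, 48.0), (14, 52.0, 98.0), (34, 102.0, 2218.0))
N_CT_HIGH = 38  # CT-course lesions at >= 50 Gy ...
N_CT_HIGH_SHRINK = 35  # ... of which shrink
N_CT_LOW = 14  # CT-course lesions below 50 Gy ...
N_CT_LOW_SHRINK = 12  # ... of which shrink


@dataclass(frozen=True)
class OrganPatient:
    """One synthetic imaging patient: phantom, schedule and administrations."""

    patient_id: str
    spec: PhantomSpec
    admin: AdministrationRecord
    scan_times: tuple[float, ...] = DEFAULT_SCAN_TIMES
    scan_duration: float = DEFAULT_SCAN_DURATION


@dataclass
class StudyCohort:
    """A complete synthetic study: imaging patients, lesions, CT courses."""

    seed: int
    organ_patients: list[OrganPatient]
    lesions: list[Lesion]
    lesion_truth: pd.DataFrame
    course_specs: dict[str, PhantomLesionSpec]
    measurements: list[TumorMeasurement]
    sphere_table: SphereDoseFactorTable = field(default_factory=default_sphere_table)


def _organ_layouts() -> dict[str, dict]:
    # base kinetics chosen to land TIACs near the reported organ means
    # (kidneys ~2.5 h, liver ~14 h, spleen ~1.9 h) with terminal effective
    # half-lives well inside 21-161 h
    return {
        "kidneys": {
            "amplitudes": (0.020, 0.015),
            "half_lives": (80.0, 8.0),
            "mass": 299.0,
            "footprint": (60, 76, 40, 62),
            "depth": 8.0,
        },
        "liver": {
            "amplitudes": (0.090, 0.050),
            "half_lives": (100.0, 15.0),
            "mass": 1910.0,
            "footprint": (28, 56, 30, 70),
            "depth": 6.0,
        },
        "spleen": {
            "amplitudes": (0.013, 0.008),
            "half_lives": (95.0, 12.0),
            "mass": 183.0,
            "footprint": (30, 44, 78, 96),
            "depth": 7.0,
        },
    }


def default_organ_patient(seed: int = 0, patient_id: str = "pt00") -> OrganPatient:
    """A single nominal imaging patient without inter-patient variability."""
    organs = tuple(
        PhantomOrganSpec(
            name=name,
            amplitudes=lay["amplitudes"],
            effective_rates=tuple(math.log(2) / t for t in lay["half_lives"]),
            mass=lay["mass"],
            footprint=lay["footprint"],
            depth=lay["depth"],
        )
        for name, lay in _organ_layouts().items()
    )
    spec = PhantomSpec(organs=organs, seed=seed)
    return OrganPatient(
        patient_id=patient_id,
        spec=spec,
        admin=AdministrationRecord(cycle_activities=(7.4,) * 4),
    )


def _vary_patient(rng: np.random.Generator, uptake_kidney: bool, seed: int) -> PhantomSpec:
    organs = []
    for name, lay in _organ_layouts().items():
        amp_f = rng.lognormal(0.0, 0.30)
        hl_f = rng.lognormal(0.0, 0.20)
        amps = tuple(a * amp_f for a in lay["amplitudes"])
        hls = [min(max(t * hl_f, 3.0), 150.0) for t in lay["half_lives"]]
        hls[0] = min(max(hls[0], 25.0), 150.0)  # terminal phase inside 21-161 h
        if name == "kidneys" and uptake_kidney:
            # uptake-washout: one negative term, activity peaking near 24 h
            a1 = 0.030 * amp_f
            amps = (a1, -0.4 * a1)
            hls = [min(max(90.0 * hl_f, 25.0), 150.0), 9.0]
        depth = float(rng.uniform(4.0, 12.0))
        organs.append(
            PhantomOrganSpec(
                name=name,
                amplitudes=amps,
                effective_rates=tuple(math.log(2) / t for t in hls),
                mass=lay["mass"],
                footprint=lay["footprint"],
                depth=depth,
            )
        )
    blood_f = rng.lognormal(0.0, 0.25)
    return PhantomSpec(
        organs=tuple(organs),
        seed=seed,
        blood_amplitudes=(0.05 * blood_f, 0.0012 * blood_f),
    )


def _admin_schedule(i: int) -> AdministrationRecord:
    # 15 patients complete 4 cycles; 3 stop after 3; 1 after 2; 1 after 1
    n_cycles = 4 if i < 15 else (3 if i < 18 else (2 if i < 19 else 1))
    ref = i % min(n_cycles, 3)  # dosimetry at cycle 1, 2 or 3
    return AdministrationRecord(
        cycle_activities=(7.4,) * n_cycles, reference_cycle=ref
    )


def _lesion_mass_bounds(dose: float) -> tuple[float, float]:
    # invert the (electron-dominated) sphere dose factor df ~ 85.3/m
    # [Gy/(GBq·h) per g] so the implied TIAC stays in a plausible 0.05-6 h
    c = 29.6e3 * 85.32e-3  # MBq total course x Gy/(MBq.h) at 1 g
    lo = max(1.0, c * 0.05 / dose)
    hi = min(1000.0, c * 6.0 / dose)
    return lo, max(hi, lo * 1.2)


def make_study_cohort(
    seed: int = 0,
    n_patients: int = 20,
    n_uptake_kidneys: int = 6,
) -> StudyCohort:
    """Generate the full synthetic study cohort for one global seed."""
    sphere_table = default_sphere_table()

    # --- imaging patients -------------------------------------------------
    rng_pat = substream(seed, "cohort/patients")
    organ_patients = []
    for i in range(n_patients):
        spec = _vary_patient(rng_pat, uptake_kidney=i < n_uptake_kidneys, seed=seed + 1000 + i)
        n_extra = int(rng_pat.integers(0, 3))  # 4-6 time points
        times = sorted({1.0, 24.0, 48.0, 168.0} | set((4.0, 96.0)[: n_extra]))
        organ_patients.append(
            OrganPatient(
                patient_id=f"pt{i:02d}",
                spec=spec,
                admin=_admin_schedule(i),
                scan_times=tuple(times),
            )
        )

    # --- target lesions ---------------------------------------------------
    rng_les = substream(seed, "cohort/lesions")
    location_pool = ["liver"] * 33 + ["lymph_node"] * 16 + ["bone"] * 2 + ["other"] * 14
    rng_les.shuffle(location_pool)
    lesions: list[Lesion] = []
    truth_rows = []
    idx = 0
    for count, lo, hi in DOSE_STRATA:
        doses = np.exp(rng_les.uniform(math.log(lo), math.log(hi), size=count))
        doses[0], doses[-1] = lo, hi  # pin the stratum range
        for dose in doses:
            m_lo, m_hi = _lesion_mass_bounds(float(dose))
            mass = float(np.exp(rng_les.uniform(math.log(m_lo), math.log(m_hi))))
            df = interp_df(sphere_table, mass)
            tiac = float(dose) / (29.6e3 * df)
            lesion_id = f"les{idx:02d}"
            patient = f"pt{idx % 17:02d}"
            lesions.append(
                Lesion(
                    lesion_id=lesion_id,
                    location_class=location_pool[idx],
                    mass=mass,
                    tiac=tiac,
                )
            )
            truth_rows.append(
                {
                    "lesion_id": lesion_id,
                    "patient": patient,
                    "location_class": location_pool[idx],
                    "mass_g": mass,
                    "tiac_h": tiac,
                    "true_cumulative_dose_Gy": float(dose),
                }
            )
            idx += 1
    truth = pd.DataFrame(truth_rows)

    # --- CT size courses --------------------------------------------------
    # 38 of the 48 lesions at >=50 Gy and 14 of the 17 below have CT series
    high_ids = truth.loc[truth.true_cumulative_dose_Gy >= 50, "lesion_id"].tolist()
    low_ids = truth.loc[truth.true_cumulative_dose_Gy < 50, "lesion_id"].tolist()
    ct_high = list(rng_les.choice(high_ids, size=N_CT_HIGH, replace=False))
    ct_low = list(rng_les.choice(low_ids, size=N_CT_LOW, replace=False))

    def _draw_shrinkages(n_total: int, n_shrink: int) -> list[float]:
        s = list(rng_les.uniform(0.04, 0.565, size=n_shrink))
        s += list(-rng_les.uniform(0.08, 0.25, size=n_total - n_shrink))
        rng_les.shuffle(s)
        return s

    course_specs: dict[str, PhantomLesionSpec] = {}
    measurements: list[TumorMeasurement] = []
    has_ct = set()
    for ids, n_shrink in ((ct_high, N_CT_HIGH_SHRINK), (ct_low, N_CT_LOW_SHRINK)):
        shrinkages = _draw_shrinkages(len(ids), n_shrink)
        for lesion_id, s in zip(ids, shrinkages):
            row = truth.loc[truth.lesion_id == lesion_id].iloc[0]
            L = float(rng_les.uniform(15.0, 80.0))
            W = L * float(rng_les.uniform(0.55, 0.9))
            # small plateau changes get longer follow-up so the sign of the
            # best change is determined by the kinetics, not the noise
            max_follow = 6
            min_follow = 1 if abs(s) >= 0.15 else 2
            n_follow = int(rng_les.integers(min_follow, max_follow + 1))
            weeks = [0] + list(range(12, 12 * n_follow + 1, 12))
            spec = PhantomLesionSpec(
                lesion_id=lesion_id,
                mass=float(row.mass_g),
                amplitudes=(float(row.tiac_h) * math.log(2) / 110.0,),
                effective_rates=(math.log(2) / 110.0,),
                location_class=str(row.location_class),
                baseline_L_mm=L,
                baseline_W_mm=W,
                shrinkage=float(s),
                shrink_tau_wk=float(rng_les.uniform(10.0, 24.0)),
            )
            course_specs[lesion_id] = spec
            measurements.extend(
                simulate_lesion_course(spec, weeks, noise_sd=0.005, seed=seed)
            )
            has_ct.add(lesion_id)
    truth["has_ct_course"] = truth.lesion_id.isin(has_ct)

    return StudyCohort(
        seed=seed,
        organ_patients=organ_patients,
        lesions=lesions,
        lesion_truth=truth,
        course_specs=course_specs,
        measurements=measurements,
        sphere_table=sphere_table,
    )
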