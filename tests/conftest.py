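import math

import numpy as np
import pytest

from prrtdose.cohort import default_organ_patient
from prrtdose.phantom import PhantomOrganSpec, PhantomSpec
from prrtdose.pipeline import toy_dose_factor_table
from prrtdose.spheres import default_sphere_table


@pytest.fixture(scope="session")
def sphere_table():
    return default_sphere_table()


@pytest.fixture(scope="session")
def s_table():
    return toy_dose_factor_table()


@pytest.fixture
def nominal_patient():
    return default_organ_patient(seed=7)


def make_single_organ_spec(
    depth: float = 6.931471805599453,  # ln2 / 0.1: anterior transmission 0.5
    amplitudes=(1.0,),
    rates=(math.log(2) / 159.53,),
    seed: int = 0,
    **kwargs,
) -> PhantomSpec:
    """One-organ slab phantom with round-number attenuation factors.

    mu = 0.1/cm and thickness = ln(6.25)/0.1 give exp(-mu*T) = 0.16, so the
    conjugate-view transmission correction is exactly sqrt(0.16) = 0.4.
    """
    organ = PhantomOrganSpec(
        name="organ",
        amplitudes=tuple(amplitudes),
        effective_rates=tuple(rates),
        mass=300.0,
        footprint=(40, 60, 40, 70),
        depth=depth,
    )
    defaults = dict(
        organs=(organ,),
        body_thickness=math.log(6.25) / 0.1,
        attenuation_coefficient=0.1,
        camera_sensitivity=10.0,
        injected_activity=100.0,
        background_fraction=0.0,
        seed=seed,
    )
    defaults.update(kwargs)
    return PhantomSpec(**defaults)
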