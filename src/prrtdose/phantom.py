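"""Synthetic planar-scintigraphy phantoms with known kinetics.

The phantom is a 2-D slab-body model: each source organ is a rectangular
pixel footprint at a known depth below the anterior surface, carrying a
sum-of-exponentials activity curve expressed as fractions of the injected
activity.  Anterior and posterior expected counts follow the narrow-beam
attenuation model

    C_A = sensitivity * duration * A(t) * exp(-mu * depth)
    C_P = sensitivity * duration * A(t) * exp(-mu * (thickness - depth))

so the geometric mean of the two views cancels the depth and leaves the
body transmission exp(-mu * thickness), exactly as the conjugate-view
quantification assumes.  Counts are Poisson draws around those means, and a
uniform background (a fixed fraction of the physically decaying injected
activity, spread over the body region at mid-depth) emulates circulating
and soft-tissue activity.

Because the generating kinetics are known in closed form, every downstream
stage — quantification, fitting, TIAC integration, dosimetry — can be
checked against exact ground truth without any patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import LU177, PhysicalConstants, substream
from .response import TumorMeasurement, ALLOWED_WEEKS

__all__ = [
    "PhantomOrganSpec",
    "PhantomLesionSpec",
    "PhantomSpec",
    "true_activity",
    "true_tiac",
    "render_planar_pair",
    "sample_blood",
    "simulate_lesion_course",
]


@dataclass(frozen=True)
class PhantomOrganSpec:
    """One source organ of the slab phantom.

    ``amplitudes`` are fractions of injected activity; one term may be
    negative to model a kidney-like uptake phase (rising to a peak around
    24 h before washing out).  ``effective_rates`` are the matching
    effective decay constants in 1/h (physical x biological).  ``footprint``
    is the (row0, row1, col0, col1) half-open pixel rectangle of the organ in
    the planar frame, and ``depth`` the distance in cm from the anterior body
    surface to the organ plane.
    """

    name: str
    amplitudes: tuple[float, ...]
    effective_rates: tuple[float, ...]
    mass: float  # g
    footprint: tuple[int, int, int, int]
    depth: float  # cm

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        lam = np.asarray(self.effective_rates, dtype=float)
        if a.size != lam.size or a.size == 0:
            raise ValueError("amplitudes and effective_rates must have equal, nonzero length")
        if np.any(lam <= 0):
            raise ValueError("effective rates must be strictly positive")
        if not 0.0 <= float(a.sum()) <= 1.0:
            raise ValueError("sum of amplitudes must lie in [0, 1]")
        if self.mass <= 0:
            raise ValueError("organ mass must be positive")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        r0, r1, c0, c1 = self.footprint
        if not (r0 < r1 and c0 < c1):
            raise ValueError("footprint rectangle must be non-empty")
        # activity curve must stay non-negative; checked on a dense grid
        t = np.linspace(0.0, 2000.0, 2001)
        if np.min(a @ np.exp(-np.outer(lam, t))) < -1e-12:
            raise ValueError(f"organ {self.name!r}: activity goes negative")

    @property
    def tiac(self) -> float:
        """Ground-truth time-integrated activity coefficient sum(a/lambda) [h]."""
        return float(
            np.sum(np.asarray(self.amplitudes) / np.asarray(self.effective_rates))
        )


@dataclass(frozen=True)
class PhantomLesionSpec:
    """One lesion: mass, kinetics, location, and an optional CT size course.

    ``shrinkage`` is defined on lesion AREA: the plateau area change is
    -shrinkage x 100%, approached with time constant ``shrink_tau_wk``.
    Negative shrinkage grows the lesion.  When ``footprint`` is given the
    lesion is also rendered into the planar images like an organ.
    """

    lesion_id: str
    mass: float  # g
    amplitudes: tuple[float, ...]
    effective_rates: tuple[float, ...]
    location_class: str = "liver"  # liver | lymph_node | bone | other
    baseline_L_mm: float = 30.0
    baseline_W_mm: float = 20.0
    shrinkage: float = 0.0
    shrink_tau_wk: float = 12.0
    footprint: tuple[int, int, int, int] | None = None
    depth: float = 0.0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("lesion mass must be positive")
        if not (self.baseline_L_mm > 0 and self.baseline_W_mm > 0):
            raise ValueError("baseline diameters must be positive")
        if self.shrinkage >= 1.0:
            raise ValueError("area shrinkage must be < 1")
        if len(self.amplitudes) != len(self.effective_rates):
            raise ValueError("amplitudes and effective_rates must match")

    @property
    def is_lymph_node(self) -> bool:
        return self.location_class == "lymph_node"

    @property
    def tiac(self) -> float:
        return float(
            np.sum(np.asarray(self.amplitudes) / np.asarray(self.effective_rates))
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom configuration for one synthetic patient."""

    organs: tuple[PhantomOrganSpec, ...]
    lesions: tuple[PhantomLesionSpec, ...] = ()
    body_thickness: float = 20.0  # cm
    attenuation_coefficient: float = 0.137  # 1/cm, effective mu at 208 keV
    camera_sensitivity: float = 10.0  # counts/(MBq*s)
    injected_activity: float = 7400.0  # MBq
    background_fraction: float = 0.05
    seed: int = 0
    image_shape: tuple[int, int] = (128, 128)
    body_region: tuple[int, int, int, int] = (8, 120, 24, 104)
    blood_amplitudes: tuple[float, ...] = (0.05, 0.0012)  # fraction IA per kg
    blood_rates: tuple[float, ...] = (math.log(2) / 2.0, math.log(2) / 60.0)  # 1/h
    constants: PhysicalConstants = LU177

    def __post_init__(self) -> None:
        if self.injected_activity <= 0:
            raise ValueError("injected_activity must be positive")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must lie in [0, 1)")
        if self.body_thickness <= 0 or self.attenuation_coefficient <= 0:
            raise ValueError("body thickness and attenuation must be positive")
        if self.camera_sensitivity <= 0:
            raise ValueError("camera sensitivity must be positive")
        nrows, ncols = self.image_shape
        br0, br1, bc0, bc1 = self.body_region
        if not (0 <= br0 < br1 <= nrows and 0 <= bc0 < bc1 <= ncols):
            raise ValueError("body region must lie within the image frame")
        occupied = np.zeros(self.image_shape, dtype=bool)
        for src in self._rendered_sources():
            r0, r1, c0, c1 = src.footprint
            if not (br0 <= r0 < r1 <= br1 and bc0 <= c0 < c1 <= bc1):
                raise ValueError(f"footprint of {self._src_name(src)!r} outside body region")
            if src.depth > self.body_thickness:
                raise ValueError(f"{self._src_name(src)!r}: depth exceeds body thickness")
            if occupied[r0:r1, c0:c1].any():
                raise ValueError(f"footprint of {self._src_name(src)!r} overlaps another source")
            occupied[r0:r1, c0:c1] = True

    @staticmethod
    def _src_name(src) -> str:
        return getattr(src, "name", None) or getattr(src, "lesion_id")

    def _rendered_sources(self):
        out = list(self.organs)
        out.extend(l for l in self.lesions if l.footprint is not None)
        return out


def true_activity(
    organ: PhantomOrganSpec | PhantomLesionSpec,
    t,
    injected_activity: float,
):
    """Ground-truth source activity A(t) = A0 * sum(a_i exp(-lambda_i t)) [MBq]."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    if injected_activity <= 0:
        raise ValueError("injected activity must be positive")
    a = np.asarray(organ.amplitudes, dtype=float)
    lam = np.asarray(organ.effective_rates, dtype=float)
    scalar = t_arr.ndim == 0
    val = injected_activity * (a @ np.exp(-np.outer(lam, np.atleast_1d(t_arr))))
    return float(val[0]) if scalar else val


def true_tiac(organ: PhantomOrganSpec | PhantomLesionSpec) -> float:
    """Analytic TIAC sum(a_i / lambda_i) of a phantom source [h]."""
    return organ.tiac


def _attenuation(spec: PhantomSpec, depth: float) -> tuple[float, float]:
    mu = spec.attenuation_coefficient
    return math.exp(-mu * depth), math.exp(-mu * (spec.body_thickness - depth))


def render_planar_pair(
    spec: PhantomSpec,
    t: float,
    duration: float,
    noise: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render one anterior/posterior planar pair at time ``t`` post-injection.

    Returns (anterior, posterior, truth) where the count matrices are int64
    Poisson draws when ``noise`` is on and exact float expected counts
    otherwise, and ``truth`` maps each
    source name to its true activity [MBq], fraction of injected activity,
    and ground-truth TIAC [h], plus a ``whole_body`` entry.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if duration <= 0:
        raise ValueError("acquisition duration must be positive")
    if rng is None:
        rng = substream(spec.seed, f"images/t={t:.6g}")

    mean_ant = np.zeros(spec.image_shape, dtype=float)
    mean_post = np.zeros(spec.image_shape, dtype=float)
    k = spec.camera_sensitivity * duration
    truth: dict[str, dict[str, float]] = {}

    total_activity = 0.0
    for src in spec._rendered_sources():
        name = spec._src_name(src)
        act = true_activity(src, t, spec.injected_activity)
        f_ant, f_post = _attenuation(spec, src.depth)
        r0, r1, c0, c1 = src.footprint
        npix = (r1 - r0) * (c1 - c0)
        mean_ant[r0:r1, c0:c1] += k * act * f_ant / npix
        mean_post[r0:r1, c0:c1] += k * act * f_post / npix
        truth[name] = {
            "activity_MBq": act,
            "fraction_ia": act / spec.injected_activity,
            "tiac_h": src.tiac,
        }
        total_activity += act

    # uniform circulating background over the body region, placed at
    # mid-depth so both views see the same transmission
    bg_act = (
        spec.background_fraction
        * spec.injected_activity
        * math.exp(-spec.constants.decay_constant * t)
    )
    br0, br1, bc0, bc1 = spec.body_region
    n_body = (br1 - br0) * (bc1 - bc0)
    f_mid, _ = _attenuation(spec, spec.body_thickness / 2.0)
    mean_ant[br0:br1, bc0:bc1] += k * bg_act * f_mid / n_body
    mean_post[br0:br1, bc0:bc1] += k * bg_act * f_mid / n_body

    truth["whole_body"] = {
        "activity_MBq": total_activity + bg_act,
        "fraction_ia": (total_activity + bg_act) / spec.injected_activity,
        "tiac_h": float("nan"),
    }

    if noise:
        ant = rng.poisson(mean_ant).astype(np.int64)
        post = rng.poisson(mean_post).astype(np.int64)
    else:
        # exact expected counts (float), so noiseless quantification is exact
        ant = mean_ant.copy()
        post = mean_post.copy()
    truth["_mean_anterior"] = mean_ant
    truth["_mean_posterior"] = mean_post
    return ant, post, truth


def sample_blood(
    spec: PhantomSpec,
    times: Sequence[float],
    noise: bool = True,
    noise_sigma: float = 0.05,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Blood activity concentration samples [fraction of IA per kg].

    The true curve is the phantom's biexponential blood model; measurement
    error is multiplicative lognormal with log-sd ``noise_sigma``.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    a = np.asarray(spec.blood_amplitudes, dtype=float)
    lam = np.asarray(spec.blood_rates, dtype=float)
    conc = a @ np.exp(-np.outer(lam, t))
    if noise:
        if rng is None:
            rng = substream(spec.seed, "blood")
        conc = conc * rng.lognormal(0.0, noise_sigma, size=conc.shape)
    return conc


def simulate_lesion_course(
    lesion: PhantomLesionSpec,
    weeks: Sequence[int],
    noise_sd: float = 0.01,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> list[TumorMeasurement]:
    """Simulate the CT size course of one lesion on the 12-week visit grid.

    Both diameters scale by sqrt(shape(t)) with
    shape(t) = 1 - s * (1 - exp(-t / tau)), so the plateau AREA change is
    exactly -s x 100%.  Each measured axis carries independent lognormal
    noise with log-sd ``noise_sd`` (0 disables it); the longest measured
    axis is reported as L, per CT convention.
    """
    wk = list(weeks)
    if not wk or any(w not in ALLOWED_WEEKS for w in wk):
        raise ValueError(f"weeks must be a non-empty subset of {sorted(ALLOWED_WEEKS)}")
    if rng is None:
        rng = substream(seed, f"lesions/{lesion.lesion_id}")
    out: list[TumorMeasurement] = []
    for w in sorted(wk):
        if lesion.shrink_tau_wk <= 0:
            shape = 1.0 - lesion.shrinkage if w > 0 else 1.0
        else:
            shape = 1.0 - lesion.shrinkage * (1.0 - math.exp(-w / lesion.shrink_tau_wk))
        axis = math.sqrt(shape)
        L = lesion.baseline_L_mm * axis
        W = lesion.baseline_W_mm * axis
        if noise_sd > 0:
            L *= rng.lognormal(0.0, noise_sd)
            W *= rng.lognormal(0.0, noise_sd)
        L, W = max(L, W), min(L, W)
        out.append(
            TumorMeasurement(
                lesion_id=lesion.lesion_id,
                week=w,
                L=L,
                W=W,
                is_lymph_node=lesion.is_lymph_node,
            )
        )
    return out
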