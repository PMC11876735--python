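"""Render a synthetic planar pair and recover the organ activity.

Builds a one-organ slab phantom, renders anterior/posterior count images
at 24 h with Poisson noise, and quantifies the organ with the
conjugate-view (geometric-mean) method.  The recovered activity should sit
within counting noise of the generating truth, and exactly on it when
noise is disabled.
"""

import math

from prrtdose import (
    PhantomOrganSpec,
    PhantomSpec,
    PlanarScan,
    conjugate_view_activity,
    render_planar_pair,
    roi_counts,
    true_activity,
)
from prrtdose.pipeline import phantom_roiset

kidney = PhantomOrganSpec(
    name="kidneys",
    amplitudes=(0.020, 0.015),  # fractions of injected activity
    effective_rates=(math.log(2) / 80.0, math.log(2) / 8.0),  # 1/h
    mass=299.0,
    footprint=(60, 76, 40, 62),
    depth=8.0,  # cm below the anterior surface
)
spec = PhantomSpec(organs=(kidney,), seed=42)
roiset = phantom_roiset(spec)

for noise in (True, False):
    ant, post, truth = render_planar_pair(spec, t=24.0, duration=300.0, noise=noise)
    scan = PlanarScan(ant, post, 24.0, 300.0, spec.camera_sensitivity)
    cA, cP, _ = roi_counts(scan, roiset, "kidneys")
    activity = conjugate_view_activity(cA, cP, roiset.transmission["kidneys"], scan)
    expected = true_activity(kidney, 24.0, spec.injected_activity)
    label = "Poisson noise" if noise else "noise-free"
    print(f"{label:13s}: recovered {activity:8.2f} MBq  (truth {expected:.2f} MBq, "
          f"error {100 * (activity / expected - 1):+.3f}%)")

print("\nThe geometric mean of the two views cancels the organ depth, so the")
print("noise-free recovery is exact; with noise the error is at the counting-")
print("statistics level (~0.1% here).")
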