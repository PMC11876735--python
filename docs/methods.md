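# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `prrtdose`.

## Physical model

The radionuclide is ¹⁷⁷Lu: physical half-life 159.53 h (6.647 d), with
3.6×10⁹ nuclear transformations per MBq·h. Emission data used by the
sphere model are a mean non-penetrating (β + conversion/Auger electron)
energy of 2.37×10⁻¹⁴ J per decay (~148 keV) and 5.3×10⁻¹⁵ J per decay of
photon energy (the 113 and 208 keV gammas weighted by yield). Photon
absorbed fractions for unit-density spheres are a smooth synthetic table
(0.008 at 1 g rising to 0.085 at 1000 g, interpolated linearly in log
mass): the right magnitude and monotonicity, not a published tabulation.
Electrons are treated as fully absorbed, which is accurate for spheres
well above the ~2 mm β range of ¹⁷⁷Lu.

## Phantom and forward model

The phantom is a 2-D slab body: rectangular organ footprints at known
depth, a single effective attenuation coefficient μ = 0.137 cm⁻¹ (water at
~208 keV) through a 20 cm body, a camera sensitivity of 10 counts/(MBq·s),
and a uniform "circulating" background equal to a configurable fraction
(default 5%) of the physically decaying injected activity spread over the
body region at mid-depth. Expected counts follow narrow-beam attenuation
per view; measured counts are Poisson. This is deliberately the *same*
physics the conjugate-view method assumes: the phantom exists to exercise
the quantification and kinetics machinery against exact ground truth, not
to emulate scatter, septal penetration, or anatomy (XCAT-style realism is
out of scope). Organ footprints may not overlap; overlap resolution is not
modeled.

With noise disabled the renderer returns exact expected counts (floats),
which is what makes the noiseless-recovery tests meaningful at 1e-9
relative tolerance.

All randomness flows from one integer seed through named substreams
(`images/...`, `blood`, `lesions/<id>`, `cohort/...`, `renal/...`), so
adding an artifact never perturbs another artifact's draws and every
output is reproducible byte-for-byte.

## Kinetic fitting

Candidate models: monoexponential, biexponential (non-negative
amplitudes), and uptake–washout (two terms, exactly one negative
amplitude, f(0) ≥ 0, activity peaking typically near 24 h). Fitting is
unweighted least squares (optional 1/y weighting) via variable
projection: amplitudes are profiled linearly (non-negative least squares
for the washout models) while the log-rates are optimized by Nelder–Mead
from 20 multi-starts on a log-spaced grid spanning [λ_phys/10, 10 h⁻¹].
Coincident-rate proposals are rejected as degenerate. Selection is by
AICc with k = 2·(number of terms); the SSE entering AICc is floored at a
numerical-resolution scale (10⁻⁸ of the data maximum, per point) so that
on noiseless data nested models compare by parameter count rather than by
round-off residuals. Fits whose terminal effective half-life exceeds the
physical half-life are flagged, not rejected — noise can legitimately push
an estimate there, and clinical reports show terminal half-lives up to
161 h against a 159.5 h physical half-life.

Two TIAC estimators exist: the analytic Σ aᵢ/λᵢ of the selected model
(default), and a hybrid that trapezoids the observed samples and appends
an analytic tail from the last sample (physical-decay tail f_last/λ_phys,
or the fitted terminal rate). The hybrid integrates only the observed
span — no back-extrapolation to t = 0 — which matches its use as a
conservative whole-body integrator: the pipeline uses the hybrid with a
physical-decay tail for the whole-body TIAC, because the whole-body curve
is a many-term mixture (all organs plus background) that a low-order
model can underfit, and an underestimated whole-body TIAC would falsely
trigger the remainder-conservation error.

### Parameter-recovery experiment

The recovery experiment (200 replicates) renders the reference kidney
phantom — biexponential, amplitudes (0.020, 0.015) of injected activity,
effective half-lives (80 h, 8 h), hence TIAC 2.48 h — at the 6-point
clinical schedule (1, 4, 24, 48, 96, 168 h) with acquisitions short
enough to give ~10⁴ ROI counts, and fits the *washout family*
(biexponential / uptake–washout), i.e. the generating family, as a
practitioner fits curves known from the cohort to be biexponential. This
is a deliberate design choice: at n = 6 the AICc small-sample correction
separates 2- and 4-parameter models by ~40 points, so offering the
monoexponential as a candidate makes it win whenever noise masks the
second phase, and its systematic TIAC bias (about −30% for this truth)
then dominates the error budget. Model *selection* is validated
separately (parsimony on nested truth; uptake-shape identification).
Observed accuracy: ≈2.3% RMSE on the terminal half-life and ≈1.0% on the
TIAC, with all recovered terminal half-lives inside the 21–161 h study
window.

## Organ dosimetry

Doses follow the MIRD schema, D/A₀ = Σ_s τ_s·S(target←source), with τ in
hours and S in Gy/(GBq·h) (numerically mGy/(MBq·h)); readers validate
units from column headers. Activity not assigned to an explicit source is
the remainder of body: τ_RoB = τ_TB − Σ τ_s, which must be non-negative —
a violation raises a conservation error rather than clipping, because it
signals inconsistent upstream quantification. The remainder S-value is the
standard mass-weighted correction
S(t←RoB) = [S(t←TB)·M_TB − Σ S(t←s)·M_s]/M_RoB, floored at zero with a
warning if a table is inconsistent.

The packaged S-table is a *synthetic* fixture: self-dose terms from
electron physics (N·Δ_np/m plus a small photon self-absorption), photon
cross terms of plausible magnitude, and total-body rows constructed
mass-consistently so every remainder correction is non-negative. Organ
masses: kidneys 299 g, liver 1910 g, spleen 183 g, red marrow 1120 g,
total body 73.7 kg. Patient-specific self-dose mass scaling is available
in principle through user-supplied tables but is off by default, since
per-patient organ masses are not part of the standard planar chain here.

The red marrow uses the blood-based model with marrow mass 1.17 kg and a
marrow-to-blood concentration ratio of 1.0 (the standard assumption for
peptides that do not bind marrow); both are parameters. Course doses are
dose-per-GBq × 29.6 GBq ("planned" mode) or × the administered cycle sum
("actual" mode).

## Tumor dosimetry

Sphere dose factors are tabulated on a 1–1000 g log grid (10 points per
decade) and interpolated log-log, which is exact in the electron-only
limit (df ∝ 1/m is a straight line in log-log space) and accurate to
<0.1% with photons included. Lesions outside the grid raise by default —
a lesion below the smallest tabulated sphere is below camera resolution
and should be excluded, not extrapolated silently; power-law extrapolation
is available behind an explicit flag with a warning. Lesion dose per
administration is A·τ·df(m); cumulative course dose scales the measured
cycle by (total administered)/(reference-cycle activity), which encodes
the constant-uptake-per-cycle assumption (uptake proportional to mass).

## Response and toxicity reporting

Size change uses the area proxy L×W; the best change of a lesion is the
minimum percent change over follow-up (most negative, or smallest
increase). Lymph nodes are measured on the short axis, other lesions on
the long axis, in the single-diameter variant. Shrinkage fractions are
rounded to the nearest integer percent, threshold frequencies and
incidences to one decimal — the printed precision of such reports. The
dose–response association is a Spearman rank correlation with mid-ranked
ties; it is an added convenience statistic (the underlying clinical
question is usually answered by the scatter plot), and a constant vector
yields a flagged "undefined" result rather than an exception. The renal
rule fits an unweighted least-squares slope to percent change from
baseline versus years and flags at or below −20 %/year; the estimator is
an interpretation, since threshold reports rarely state one.

## Synthetic study cohort

`make_study_cohort` emulates the structure of a 20-patient Lu-177 PRRT
dosimetry substudy, whose counts it reproduces by construction:

* 20 imaging patients, 4–6 planar time points within 7 d, 15/3/1/1
  patients receiving 4/3/2/1 cycles of 7.4 GBq. Organ kinetics are
  log-normally varied around bases calibrated to give kidney TIAC ≈2.5 h,
  liver ≈14 h, spleen ≈1.9 h, with terminal half-lives clipped into
  25–150 h (inside the reported 21–161 h window); 6 of 20 kidneys get an
  uptake–washout shape peaking near 24 h. Blood is biexponential with
  ∫c dt ≈ 0.26 h/kg, giving a marrow TIAC near 0.3 h.
* 65 target lesions in dose strata of 17 below 50 Gy, 14 between 50 and
  100 Gy, and 34 at or above 100 Gy — a fixed frequency structure — with
  stratum ranges pinned at 7 and 2218 Gy. Masses are drawn
  log-uniformly within bounds that keep the implied TIAC in 0.05–6 h, and
  the ground-truth TIAC is back-computed from the stratum dose through
  the sphere table — so the dosimetry chain *recomputes* the dose, it is
  never copied.
* 52 lesions carry CT courses: 35 of the 38 at ≥50 Gy shrink (plateau
  area shrinkage uniform in 4%–56.5%) and 12 of the 14 below do, so 47 of
  52 shrink overall. Non-shrinking lesions grow by 8–25% at plateau.
  Shrinkage is defined on *area* (each axis scales by √(1−s)), so the
  plateau area change is exactly −s·100%. Axis measurements carry
  log-normal noise with log-sd 0.005; lesions with plateau magnitude
  below 15% get at least two follow-ups, so the sign of the best change
  is determined by the kinetics, not the noise (the smallest plateau,
  −4%, sits >3 noise SDs from zero), and the shrinkage counts are stable
  across seeds. The measured longest axis is reported as L, per CT
  convention.

What passing tests on this cohort do *not* show: robustness to scatter,
organ overlap, patient thickness variation along the body, partial-volume
effects, or CT measurement biases — none of which the phantom emulates.
The cohort's organ-dose summaries are plausibility-scaled, not a
reproduction of any patient data set.

## Problem sizes and determinism

Default experiment sizes — 200 recovery replicates, 500 quadrature
checks, a 20-patient imaging cohort on 128×128 images — were chosen so
the full chain and its validation complete in a couple of minutes on one
CPU while keeping Monte Carlo error well below the tolerances tested.
Report bundles are serialized with fixed float formats and sorted JSON
keys, so identical seed and configuration give byte-identical files.
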