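"""Fit exponential kinetics to a noisy time-activity series.

Simulates a kidney-like series with an uptake phase peaking near 24 h,
fits the three candidate models, and reports the AICc winner with its
terminal effective half-life and time-integrated activity coefficient
(TIAC) — the two numbers organ dosimetry needs.
"""

import math
import warnings

import numpy as np

from prrtdose import fit_time_activity, tiac_analytic, tiac_hybrid

rng = np.random.default_rng(7)
times = np.array([1.0, 4.0, 24.0, 48.0, 96.0, 168.0])
amps, rates = (0.030, -0.012), (math.log(2) / 90.0, math.log(2) / 9.0)
truth = np.asarray(amps) @ np.exp(-np.outer(rates, times))
observed = truth * rng.lognormal(0.0, 0.01, size=times.size)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fit = fit_time_activity(times, observed)

true_tiac = sum(a / r for a, r in zip(amps, rates))
print(f"selected model          : {fit.model}")
print(f"terminal half-life      : {fit.terminal_effective_half_life:6.1f} h "
      f"(truth {math.log(2) / rates[0]:.1f} h)")
print(f"analytic TIAC           : {tiac_analytic(fit):6.2f} h (truth {true_tiac:.2f} h)")
print(f"hybrid TIAC (phys tail) : {tiac_hybrid(times, observed):6.2f} h")
print(f"superphysical flag      : {fit.superphysical_flag}")

print("\nThe TIAC is the area under the fraction-of-injected-activity curve;")
print("multiplied by an S-value it gives absorbed dose per unit administered")
print("activity. The hybrid estimator trapezoids the data and appends a")
print("physical-decay tail, a conservative alternative to the model integral.")
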