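"""Full synthetic-cohort pipeline: images to report bundle.

Generates the study-structured synthetic cohort (20 imaging patients, 65
target lesions, 52 CT size courses), runs quantification, kinetic fitting,
organ and tumor dosimetry, and response statistics, and prints the
headline numbers.  Writes the deterministic report bundle to
./cohort_report/.
"""

import json
import warnings

from prrtdose import run_report

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = run_report(seed=1, outdir="cohort_report", n_patients=20)

print("lesions >= 100 Gy :", report["lesion_threshold_pct"]["100"], "%")
print("lesions >= 50 Gy  :", report["lesion_threshold_pct"]["50"], "%")
sh = report["shrinkage"]
print(f"shrinking (>=50 Gy): {sh['dose_ge_50Gy']['n_shrinking']}/{sh['dose_ge_50Gy']['n']}"
      f" = {sh['dose_ge_50Gy']['pct']}%")
print(f"shrinking (all)    : {sh['all']['n_shrinking']}/{sh['all']['n']}"
      f" = {sh['all']['pct']}%")
dr = report["dose_response"]
print(f"dose-response Spearman rho = {dr['spearman_rho']} (p = {dr['p_value']}, n = {dr['n']})")
n_kidney_flags = sum(f["kidney_over_threshold"] for f in report["flags"].values())
print(f"patients over 23 Gy kidney threshold: {n_kidney_flags}/{report['n_patients']}")

print("\nThe near-zero rank correlation shows that lesion shrinkage is spread")
print("across all dose levels in this cohort; the report bundle under")
print("cohort_report/ holds the per-patient and per-lesion tables.")
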