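"""Generate a synthetic exercise-test cohort and screen it.

Builds 1000 graded cardiopulmonary exercise tests (CPX) with the frozen
default configuration — bicycle and treadmill protocols, per-stage blood
lactate and Borg RPE — then applies the six exclusion criteria (re-tests,
missing values, short tests, foreign ergometry, implausible data) and
prints the cohort composition the way a baseline table would report it.
"""

import numpy as np

from borg_anchor import apply_exclusions, bmi_class, default_config, generate_cohort

cohort, truth = generate_cohort(default_config(n=1000, seed=7))
kept, report = apply_exclusions(cohort)

print(f"generated {report.n_input} records, kept {report.n_kept}")
for criterion, count in report.counts.items():
    print(f"  excluded {criterion}: {count}")

ages = np.array([r.age for r in kept])
male = np.mean([r.sex == "male" for r in kept])
bike = np.mean([r.ergometry == "bicycle" for r in kept])
vo2_bike = np.array([r.vo2max for r in kept if r.ergometry == "bicycle"])
vo2_tread = np.array([r.vo2max for r in kept if r.ergometry == "treadmill"])
bands = {}
for r in kept:
    bands[bmi_class(r.weight_kg, r.height_cm)] = bands.get(bmi_class(r.weight_kg, r.height_cm), 0) + 1

print(f"\nage {ages.mean():.1f} ({ages.std():.1f}) y | male {100*male:.1f}% | bicycle {100*bike:.1f}%")
print(f"VO2max bicycle {vo2_bike.mean():.1f} ({vo2_bike.std():.1f}), "
      f"treadmill {vo2_tread.mean():.1f} ({vo2_tread.std():.1f}) ml/kg/min")
print("BMI classes:", dict(sorted(bands.items(), key=lambda kv: -kv[1])))
print("\n(The kept fraction and covariate moments mirror the emulated outpatient")
print(" clinic population; the truth object carries each record's latent curve.)")
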