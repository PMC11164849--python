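"""Lactate thresholds and ordinal RPE anchors for one hand-built test.

One bicycle test with seven 3-min stages: baseline lactate is the
minimum of the resting sample and stage 1; LT1 is the first sustained
rise above baseline + 0.2 mmol/l; LT2 is the lactate at LT1 plus
1.5 mmol/l.  A Fritsch-Carlson monotone spline through the (lactate,
RPE) pairs then yields the rounded ordinal RPE at 2, 3, 4 mmol/l and at
the individual LT2 anchor.
"""

import datetime as dt

from borg_anchor import CPXRecord, StageMeasurement, anchors_for_record, compute_thresholds

blas = (1.0, 1.1, 1.5, 2.0, 3.0, 4.0, 6.0)
rpes = (7, 8, 10, 12, 14, 16, 18)
record = CPXRecord(
    participant_id="demo", test_date=dt.date(2021, 5, 3), age=34.0, sex="female",
    ergometry="bicycle", height_cm=168.0, weight_kg=63.0, vo2max=38.0,
    resting_bla=1.0,
    stages=[
        StageMeasurement(stage_index=i + 1, load=50.0 + 25.0 * i, bla=b, rpe=r)
        for i, (b, r) in enumerate(zip(blas, rpes))
    ],
)

th = compute_thresholds(record)
print(f"baseline bLa : {th.baseline_bla} mmol/l")
print(f"LT1          : stage {th.lt1_stage}, {th.lt1_bla} mmol/l (first rise > baseline + {th.delta})")
print(f"LT2 anchor   : {th.lt2_bla} mmol/l (LT1 + 1.5)")

anchors = anchors_for_record(record, th)
print(f"\nordinal RPE  : {anchors.rpe_2} @2  {anchors.rpe_3} @3  {anchors.rpe_4} @4  "
      f"{anchors.rpe_lt2} @LT2 (Borg 6-20)")
print("\n(Each value is the rounded spline prediction at that lactate")
print(" concentration; anchors outside the measured range stay missing.)")
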