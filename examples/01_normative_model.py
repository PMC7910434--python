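"""Expected normal thresholds and the device calibration offset.

The normative model predicts the sensitivity a healthy eye of a given age
should show at any grid point: 32.3 - 0.06 * age dB, with a pointwise SD
of 1.78 dB.  A healthy-control cohort whose measured grid means fall
short of that prediction defines a global device offset that is added to
all measured values before deviation scoring.
"""

import numpy as np

import micropoint as mp

model = mp.NormativeModel()

print("Expected normal threshold by age:")
for age in (42.9, 62.2, 67.7):
    print(f"  age {age:5.1f} y -> {mp.expected_threshold(model, age):.3f} dB")

# A control cohort measured at a grid mean of 25.9 dB at mean age 62.2
# reads ~2.67 dB below prediction; that shortfall is the calibration
# offset added to every measured threshold before scoring.
grid = mp.build_study_grid()
controls = mp.Exam(
    subject_id="controls",
    eye="right",
    exam_index=1,
    age=62.2,
    grid=grid,
    thresholds=np.full(33, 25.9),
    false_positive_rate=0.0,
    cohort="healthy",
)
offset = mp.estimate_offset(model, [controls])
print(f"\nCalibration offset from the control cohort: {offset.offset:+.2f} dB")
print("(positive: the device reads lower than the normative model predicts)")
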