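"""Cohort summaries and the abnormal-point eligibility filter.

A trial endpoint built on abnormal points needs eyes that actually have
them: the eligibility rule requires at least 5 abnormal points, in one
exam or in every exam.  This script summarises a simulated diseased
cohort per criterion and exam and reports how many eyes would qualify.
"""

import micropoint as mp

config = mp.SimulationConfig(n_healthy=22, n_iamd=25, seed=1)
dataset = mp.simulate_cohort(config)
model = config.model

offset = mp.estimate_offset(model, dataset.healthy)
criteria = mp.default_criteria()
outcomes = [
    mp.summarize_eye(mp.score_exam(e, model, offset, criteria), c, exam=e)
    for e in dataset.iamd
    for c in criteria
]

summary = mp.summarize_cohort(outcomes, min_abnormal=5)
cols = [
    "criterion", "exam_index", "n_abnormal_mean", "n_abnormal_sd",
    "pct_abnormal_pooled", "mean_deviation_abnormal_mean",
    "mean_deviation_all_mean", "n_excluded_no_abnormal",
]
print("Per-exam cohort summary (diseased eyes):")
print(summary.per_exam[cols].round(2).to_string(index=False))

print("\nEligibility at >= 5 abnormal points:")
print(summary.eligibility.round(1).to_string(index=False))
print("\n'all_exams' is the strict enrolment rule (qualify in both same-"
      "visit tests); pct_excluded is the screen-failure rate it implies.")
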