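"""Independent naive re-computations used as oracles in tests.

Everything here is deliberately written as plain loops over points/eyes,
independent of the vectorised implementations it checks.
"""

import math

import numpy as np

import micropoint as mp

STUDY_GRID = mp.build_study_grid()


def build_exam(
    thresholds,
    *,
    subject_id="S001",
    eye="right",
    exam_index=1,
    age=62.2,
    fp=0.05,
    cohort="healthy",
    grid=STUDY_GRID,
):
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim == 0:
        thresholds = np.full(len(grid), float(thresholds))
    return mp.Exam(
        subject_id=subject_id,
        eye=eye,
        exam_index=exam_index,
        age=age,
        grid=grid,
        thresholds=thresholds,
        false_positive_rate=fp,
        cohort=cohort,
    )


def random_exam(rng, *, subject_id="S001", exam_index=1, cohort="iAMD", age=None):
    """A random but valid 33-point exam for property tests."""
    if age is None:
        age = float(rng.uniform(50, 85))
    return build_exam(
        rng.uniform(5, 36, size=len(STUDY_GRID)),
        subject_id=subject_id,
        exam_index=exam_index,
        age=age,
        cohort=cohort,
    )


def naive_eye_summary(scores, criterion):
    """Loop-based per-eye summary of a list of PointScore."""
    n = len(scores)
    flagged = [s for s in scores if s.deviation < -criterion.cutoff_db]
    thr_all = sum(s.adjusted_threshold for s in scores) / n
    dev_all = sum(s.deviation for s in scores) / n
    mean = thr_all
    var = sum((s.adjusted_threshold - mean) ** 2 for s in scores) / (n - 1)
    out = {
        "n_points": n,
        "n_abnormal": len(flagged),
        "frac_abnormal": len(flagged) / n,
        "mean_threshold_all": thr_all,
        "mean_deviation_all": dev_all,
        "within_grid_sd": math.sqrt(var),
        "has_abnormal": bool(flagged),
    }
    if flagged:
        out["mean_threshold_abnormal"] = sum(
            s.adjusted_threshold for s in flagged
        ) / len(flagged)
        out["mean_deviation_abnormal"] = sum(s.deviation for s in flagged) / len(
            flagged
        )
    else:
        out["mean_threshold_abnormal"] = math.nan
        out["mean_deviation_abnormal"] = math.nan
    return out


def naive_bland_altman(value_1, value_2):
    """Two-pass loop computation of Bland-Altman statistics."""
    diffs = [a - b for a, b in zip(value_1, value_2)]
    n = len(diffs)
    mean_diff = sum(diffs) / n
    sd = math.sqrt(sum((d - mean_diff) ** 2 for d in diffs) / (n - 1))
    return {
        "n": n,
        "mean_diff": mean_diff,
        "sd_diff": sd,
        "loa_lower": mean_diff - 1.96 * sd,
        "loa_upper": mean_diff + 1.96 * sd,
        "span": 2 * 1.96 * sd,
    }


def naive_cohort_stats(outcomes):
    """Loop-based aggregates for one (criterion, exam) group of outcomes."""
    n = len(outcomes)
    counts = [o.n_abnormal for o in outcomes]
    mean_count = sum(counts) / n
    with_abn = [o for o in outcomes if o.n_abnormal >= 1]
    stats = {
        "n_eyes": n,
        "n_abnormal_mean": mean_count,
        "n_abnormal_min": min(counts),
        "n_abnormal_max": max(counts),
        "pct_abnormal_pooled": 100.0
        * sum(counts)
        / sum(o.n_points for o in outcomes),
        "pct_abnormal_mean_of_eyes": 100.0
        * sum(o.frac_abnormal for o in outcomes)
        / n,
        "n_excluded_no_abnormal": n - len(with_abn),
        "mean_deviation_all_mean": sum(o.mean_deviation_all for o in outcomes) / n,
    }
    if with_abn:
        stats["mean_deviation_abnormal_mean"] = sum(
            o.mean_deviation_abnormal for o in with_abn
        ) / len(with_abn)
    else:
        stats["mean_deviation_abnormal_mean"] = math.nan
    return stats
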