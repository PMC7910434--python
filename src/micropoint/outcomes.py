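"""Pointwise deviation scoring, abnormality classification and summaries.

A grid point is *abnormal* when its calibrated threshold falls more than
``z`` normative standard deviations below the age-expected value, i.e.
when

    deviation = (measured + offset) - expected(age)  <  -z * pointwise_sd

Two fixed clinical criteria are used: z = 1.65 (the lower 5% tail of the
healthy distribution) and z = 2.0 (2.5% tail).  The criteria are nested —
every point abnormal at 2 SD is abnormal at 1.65 SD.

By default the cutoffs are kept at full precision (1.65 x 1.78 = 2.937 dB,
2 x 1.78 = 3.56 dB) so that the nominal tail probabilities are preserved;
``rounded=True`` reproduces the one-decimal clinical convention of 2.9 and
3.6 dB.

Per-eye summaries restrict means to the abnormal subset (the candidate
trial endpoint) alongside whole-grid means; eyes without abnormal points
carry NaN in the restricted fields and are excluded from restricted
cohort aggregates, but stay in whole-grid aggregates and eligibility
denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import Exam
from .normative import CalibrationOffset, NormativeModel, expected_threshold

__all__ = [
    "AbnormalityCriterion",
    "CRITERION_5PCT",
    "CRITERION_2_5PCT",
    "default_criteria",
    "PointScore",
    "EyeOutcome",
    "CohortSummary",
    "score_exam",
    "summarize_eye",
    "check_eligibility",
    "summarize_cohort",
    "outcomes_to_frame",
    "scores_to_frame",
]


@dataclass(frozen=True)
class AbnormalityCriterion:
    """A fixed clinical cutoff ``z`` normative SDs below expectation.

    ``cutoff_db`` is derived as ``z * pointwise_sd``; with ``rounded=True``
    it is rounded to one decimal before use (clinical convention).
    """

    z: float
    pointwise_sd: float = 1.78
    rounded: bool = False

    def __post_init__(self) -> None:
        if not self.z > 0:
            raise ValueError(f"z must be positive, got {self.z}")
        if not self.pointwise_sd > 0:
            raise ValueError(
                f"pointwise_sd must be positive, got {self.pointwise_sd}"
            )

    @property
    def cutoff_db(self) -> float:
        cutoff = self.z * self.pointwise_sd
        return round(cutoff, 1) if self.rounded else cutoff

    @property
    def label(self) -> str:
        return f"z{self.z:g}"

    def is_abnormal(self, deviation: float) -> bool:
        """Strict comparison: a deviation exactly at the cutoff is normal."""
        return deviation < -self.cutoff_db


CRITERION_5PCT = AbnormalityCriterion(z=1.65)
CRITERION_2_5PCT = AbnormalityCriterion(z=2.0)


def default_criteria(
    pointwise_sd: float = 1.78, rounded: bool = False
) -> list[AbnormalityCriterion]:
    """The two standard criteria (5% and 2.5% tails) for a given SD."""
    return [
        AbnormalityCriterion(1.65, pointwise_sd, rounded),
        AbnormalityCriterion(2.0, pointwise_sd, rounded),
    ]


@dataclass(frozen=True)
class PointScore:
    """Deviation score of a single grid point under one or more criteria.

    ``abnormal`` maps each criterion label (e.g. ``"z1.65"``) to whether
    the point is abnormal under it.
    """

    point_index: int
    adjusted_threshold: float
    expected: float
    deviation: float
    abnormal: Mapping[str, bool]

    def abnormal_under(self, criterion: AbnormalityCriterion) -> bool:
        return self.abnormal[criterion.label]


def score_exam(
    exam: Exam,
    model: NormativeModel,
    offset: CalibrationOffset,
    criteria: Sequence[AbnormalityCriterion],
) -> list[PointScore]:
    """Score every grid point of one exam against the normative model.

    Returns one :class:`PointScore` per grid point, in grid order.  The
    adjusted threshold is ``measured + offset.offset``; the deviation is
    adjusted minus expected; abnormality is the strict comparison of
    :meth:`AbnormalityCriterion.is_abnormal` for each criterion.
    """
    criteria = list(criteria)
    if not criteria:
        raise ValueError("score_exam requires at least one criterion")
    expected = expected_threshold(model, exam.age)
    scores = []
    for point, measured in zip(exam.grid.points, exam.thresholds):
        adjusted = float(measured) + offset.offset
        deviation = adjusted - expected
        scores.append(
            PointScore(
                point_index=point.index,
                adjusted_threshold=adjusted,
                expected=expected,
                deviation=deviation,
                abnormal={c.label: c.is_abnormal(deviation) for c in criteria},
            )
        )
    return scores


@dataclass(frozen=True)
class EyeOutcome:
    """Per-eye, per-exam endpoint values under one abnormality criterion.

    Abnormal-restricted fields (``mean_threshold_abnormal``,
    ``mean_deviation_abnormal``) are NaN when the eye has no abnormal
    point; ``has_abnormal`` flags that case explicitly.
    """

    subject_id: str
    eye: str
    exam_index: int
    criterion: str
    n_points: int
    n_abnormal: int
    frac_abnormal: float
    mean_threshold_all: float
    mean_threshold_abnormal: float
    mean_deviation_all: float
    mean_deviation_abnormal: float
    within_grid_sd: float
    has_abnormal: bool

    @property
    def eye_id(self) -> tuple[str, str]:
        return (self.subject_id, self.eye)


def summarize_eye(
    scores: Sequence[PointScore],
    criterion: AbnormalityCriterion,
    *,
    exam: Exam | None = None,
) -> EyeOutcome:
    """Reduce one exam's point scores to an :class:`EyeOutcome`.

    ``within_grid_sd`` is the sample SD (ddof=1) of the adjusted
    thresholds over the grid.  ``exam`` supplies the identifiers; when
    omitted they default to empty/zero (useful for ad-hoc score lists).
    """
    if not scores:
        raise ValueError("summarize_eye requires a non-empty score list")
    adj = np.array([s.adjusted_threshold for s in scores])
    dev = np.array([s.deviation for s in scores])
    flags = np.array([s.abnormal_under(criterion) for s in scores])
    n_abn = int(flags.sum())
    return EyeOutcome(
        subject_id=exam.subject_id if exam else "",
        eye=exam.eye.value if exam else "",
        exam_index=exam.exam_index if exam else 0,
        criterion=criterion.label,
        n_points=len(scores),
        n_abnormal=n_abn,
        frac_abnormal=n_abn / len(scores),
        mean_threshold_all=float(adj.mean()),
        mean_threshold_abnormal=float(adj[flags].mean()) if n_abn else math.nan,
        mean_deviation_all=float(dev.mean()),
        mean_deviation_abnormal=float(dev[flags].mean()) if n_abn else math.nan,
        within_grid_sd=float(adj.std(ddof=1)) if len(scores) > 1 else 0.0,
        has_abnormal=bool(n_abn),
    )


def check_eligibility(
    outcomes_per_exam: Sequence[EyeOutcome],
    min_abnormal: int = 5,
    require_all_exams: bool = True,
) -> bool:
    """Trial-eligibility rule: enough abnormal points in the eye's exams.

    With ``require_all_exams`` every supplied exam must have at least
    ``min_abnormal`` abnormal points; otherwise one qualifying exam
    suffices.
    """
    if min_abnormal < 1:
        raise ValueError(f"min_abnormal must be >= 1, got {min_abnormal}")
    outcomes = list(outcomes_per_exam)
    if not outcomes:
        raise ValueError("check_eligibility requires at least one outcome")
    hits = [o.n_abnormal >= min_abnormal for o in outcomes]
    return all(hits) if require_all_exams else any(hits)


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level aggregates, one row per (criterion, exam).

    ``per_exam`` columns: eye counts, mean +/- sample SD and range of the
    abnormal-point count, percent abnormal under both conventions (pooled
    point count and mean of per-eye fractions), abnormal-restricted
    threshold/deviation means (over eyes with >= 1 abnormal point, with
    the exclusion count), and whole-grid deviation means.

    ``eligibility`` columns: per criterion and rule (each exam separately
    plus the all-exams rule), the number and percentage of eligible eyes
    and the percentage excluded.
    """

    per_exam: pd.DataFrame
    eligibility: pd.DataFrame
    n_eyes: int
    min_abnormal: int


def outcomes_to_frame(outcomes: Sequence[EyeOutcome]) -> pd.DataFrame:
    """Tabulate :class:`EyeOutcome` records as a DataFrame."""
    return pd.DataFrame([vars(o) for o in outcomes])


def scores_to_frame(
    scores_by_exam: Mapping[tuple[str, str, int], Sequence[PointScore]]
) -> pd.DataFrame:
    """Tabulate per-point scores keyed by (subject, eye, exam_index)."""
    rows = []
    for (subject, eye, exam_index), scores in scores_by_exam.items():
        for s in scores:
            row = {
                "subject_id": subject,
                "eye": eye,
                "exam_index": exam_index,
                "point_index": s.point_index,
                "adjusted_threshold": s.adjusted_threshold,
                "expected": s.expected,
                "deviation": s.deviation,
            }
            for label, flag in s.abnormal.items():
                row[f"abnormal_{label}"] = flag
            rows.append(row)
    return pd.DataFrame(rows)


def _sd(values: pd.Series) -> float:
    return float(values.std(ddof=1)) if len(values) > 1 else 0.0


def summarize_cohort(
    eye_outcomes: Sequence[EyeOutcome],
    min_abnormal: int = 5,
) -> CohortSummary:
    """Aggregate per-eye outcomes over a cohort.

    ``eye_outcomes`` may mix criteria and exam indices; aggregation is per
    (criterion, exam_index).  Eyes with no abnormal point are excluded
    from abnormal-restricted aggregates (their count is reported) but kept
    everywhere else.  Eligibility uses ``min_abnormal`` per exam and, for
    the ``all_exams`` rule, requires every exam of the eye to qualify.
    """
    outcomes = list(eye_outcomes)
    if not outcomes:
        raise ValueError("summarize_cohort requires at least one outcome")
    frame = outcomes_to_frame(outcomes)
    n_eyes = frame.groupby(["subject_id", "eye"]).ngroups

    per_exam_rows = []
    for (criterion, exam_index), grp in frame.groupby(
        ["criterion", "exam_index"], sort=True
    ):
        with_abn = grp[grp["has_abnormal"]]
        per_exam_rows.append(
            {
                "criterion": criterion,
                "exam_index": exam_index,
                "n_eyes": len(grp),
                "n_abnormal_mean": float(grp["n_abnormal"].mean()),
                "n_abnormal_sd": _sd(grp["n_abnormal"]),
                "n_abnormal_min": int(grp["n_abnormal"].min()),
                "n_abnormal_max": int(grp["n_abnormal"].max()),
                "pct_abnormal_pooled": 100.0
                * grp["n_abnormal"].sum()
                / grp["n_points"].sum(),
                "pct_abnormal_mean_of_eyes": 100.0
                * float(grp["frac_abnormal"].mean()),
                "n_excluded_no_abnormal": int((~grp["has_abnormal"]).sum()),
                "mean_threshold_abnormal_mean": float(
                    with_abn["mean_threshold_abnormal"].mean()
                )
                if len(with_abn)
                else math.nan,
                "mean_threshold_abnormal_sd": _sd(
                    with_abn["mean_threshold_abnormal"]
                )
                if len(with_abn)
                else math.nan,
                "mean_deviation_abnormal_mean": float(
                    with_abn["mean_deviation_abnormal"].mean()
                )
                if len(with_abn)
                else math.nan,
                "mean_deviation_abnormal_sd": _sd(
                    with_abn["mean_deviation_abnormal"]
                )
                if len(with_abn)
                else math.nan,
                "mean_deviation_all_mean": float(
                    grp["mean_deviation_all"].mean()
                ),
                "mean_deviation_all_sd": _sd(grp["mean_deviation_all"]),
                "mean_threshold_all_mean": float(
                    grp["mean_threshold_all"].mean()
                ),
                "mean_threshold_all_sd": _sd(grp["mean_threshold_all"]),
                "within_grid_sd_mean": float(grp["within_grid_sd"].mean()),
            }
        )

    eligibility_rows = []
    for criterion, grp in frame.groupby("criterion", sort=True):
        rules: list[tuple[str, pd.Series]] = []
        eligible_per_eye = (
            grp.assign(ok=grp["n_abnormal"] >= min_abnormal)
            .groupby(["subject_id", "eye"])["ok"]
        )
        for exam_index, exam_grp in grp.groupby("exam_index", sort=True):
            rules.append(
                (f"exam_{exam_index}", exam_grp["n_abnormal"] >= min_abnormal)
            )
        rules.append(("all_exams", eligible_per_eye.all()))
        for rule, mask in rules:
            n_total = len(mask)
            n_eligible = int(mask.sum())
            eligibility_rows.append(
                {
                    "criterion": criterion,
                    "rule": rule,
                    "min_abnormal": min_abnormal,
                    "n_total": n_total,
                    "n_eligible": n_eligible,
                    "pct_eligible": 100.0 * n_eligible / n_total,
                    "pct_excluded": 100.0 * (1 - n_eligible / n_total),
                }
            )

    return CohortSummary(
        per_exam=pd.DataFrame(per_exam_rows),
        eligibility=pd.DataFrame(eligibility_rows),
        n_eyes=n_eyes,
        min_abnormal=min_abnormal,
    )
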