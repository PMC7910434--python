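"""Test-retest agreement (Bland-Altman) and healthy/diseased separation.

Bland-Altman analysis summarises paired measurements (same eye, two
same-visit exams) by the mean difference and the 95% limits of agreement
(LoA), ``mean_diff +/- 1.96 * SD(differences)``.  The *span* (upper minus
lower limit, ``2 * 1.96 * sd_diff``) is the single-number repeatability
figure used throughout; the half-width (``1.96 * sd_diff``) is also
exposed to cover the alternative reading of a single printed LoA value.

Pairs can be built at three levels from scored exams: whole-grid eye
means, abnormal-point-only eye means (restricted to eyes with enough
abnormal points in *both* exams), and individual points.

Cohen's d quantifies the separation of a candidate endpoint between the
diseased and healthy groups, with the equal-weight pooled SD
``sqrt((sd_a^2 + sd_b^2) / 2)`` by default and an n-weighted pooled SD as
an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .outcomes import EyeOutcome, PointScore

__all__ = [
    "PairedSeries",
    "AgreementResult",
    "bland_altman",
    "cohens_d",
    "paired_eye_means",
    "paired_points",
]

#: Normal quantile used for the 95% limits of agreement (convention).
LOA_Z = 1.96


@dataclass(frozen=True)
class PairedSeries:
    """Paired measurements from exam 1 and exam 2 of the same units.

    ``level`` records what each pair is: ``eye_mean_all`` (whole-grid eye
    means), ``eye_mean_abnormal`` (abnormal-point eye means) or
    ``pointwise`` (individual grid points).
    """

    ids: tuple
    value_1: np.ndarray
    value_2: np.ndarray
    level: str

    def __post_init__(self) -> None:
        v1 = np.asarray(self.value_1, dtype=float)
        v2 = np.asarray(self.value_2, dtype=float)
        object.__setattr__(self, "value_1", v1)
        object.__setattr__(self, "value_2", v2)
        object.__setattr__(self, "ids", tuple(self.ids))
        if not (len(self.ids) == len(v1) == len(v2)):
            raise ValueError(
                f"paired series lengths differ: {len(self.ids)} ids, "
                f"{len(v1)} vs {len(v2)} values"
            )
        if np.isnan(v1).any() or np.isnan(v2).any():
            raise ValueError(
                "paired series contains undefined values; filter eyes "
                "without the required abnormal points before pairing"
            )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def differences(self) -> np.ndarray:
        """Exam 1 minus exam 2, the Bland-Altman y-axis."""
        return self.value_1 - self.value_2

    @property
    def means(self) -> np.ndarray:
        """Pair means, the Bland-Altman x-axis."""
        return (self.value_1 + self.value_2) / 2.0


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman summary of a paired series.

    ``span = loa_upper - loa_lower = 2 * 1.96 * sd_diff`` is the width of
    the 95% agreement interval; ``half_width`` is ``1.96 * sd_diff``.
    """

    n: int
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    level: str = ""

    @property
    def span(self) -> float:
        return self.loa_upper - self.loa_lower

    @property
    def half_width(self) -> float:
        return LOA_Z * self.sd_diff


def bland_altman(pairs: PairedSeries) -> AgreementResult:
    """Mean difference and 95% limits of agreement of a paired series.

    The difference is exam 1 minus exam 2; the SD of differences uses
    ddof=1.  Requires at least two pairs.
    """
    if len(pairs) < 2:
        raise ValueError(
            f"bland_altman requires >= 2 pairs, got {len(pairs)} "
            "(SD of differences undefined)"
        )
    diffs = pairs.differences
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    return AgreementResult(
        n=len(pairs),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_lower=mean_diff - LOA_Z * sd_diff,
        loa_upper=mean_diff + LOA_Z * sd_diff,
        level=pairs.level,
    )


def cohens_d(
    group_a: Sequence[float],
    group_b: Sequence[float],
    *,
    weighted: bool = False,
) -> float:
    """Standardised mean difference ``(mean_a - mean_b) / pooled SD``.

    The default pooled SD is the equal-weight form
    ``sqrt((sd_a^2 + sd_b^2) / 2)``; ``weighted=True`` uses the
    n-weighted pooled variance.  Sample SDs (ddof=1); the sign is
    preserved.  Raises when either group has fewer than two values or the
    pooled SD is zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"cohens_d requires n >= 2 per group, got {len(a)} and {len(b)}"
        )
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    if weighted:
        pooled = math.sqrt(
            ((len(a) - 1) * var_a + (len(b) - 1) * var_b)
            / (len(a) + len(b) - 2)
        )
    else:
        pooled = math.sqrt((var_a + var_b) / 2.0)
    if pooled == 0:
        raise ValueError("cohens_d undefined: pooled SD is zero")
    return float((a.mean() - b.mean()) / pooled)


def paired_eye_means(
    outcomes: Sequence[EyeOutcome],
    *,
    level: str = "all",
    min_abnormal: int = 5,
    exam_pair: tuple[int, int] = (1, 2),
    field: str = "threshold",
) -> PairedSeries:
    """Pair per-eye means between two exams.

    ``level='all'`` pairs whole-grid means of every eye with both exams;
    ``level='abnormal'`` pairs abnormal-point-only means, keeping only
    eyes with at least ``min_abnormal`` abnormal points in *both* exams.
    ``field`` selects threshold (dB, calibrated) or deviation means.
    """
    if level not in ("all", "abnormal"):
        raise ValueError(f"level must be 'all' or 'abnormal', got {level!r}")
    if field not in ("threshold", "deviation"):
        raise ValueError(
            f"field must be 'threshold' or 'deviation', got {field!r}"
        )
    attr = f"mean_{field}_{'all' if level == 'all' else 'abnormal'}"
    by_eye: dict[tuple[str, str], dict[int, EyeOutcome]] = {}
    for o in outcomes:
        by_eye.setdefault(o.eye_id, {})[o.exam_index] = o
    ids, v1, v2 = [], [], []
    first, second = exam_pair
    for eye_id, per_exam in sorted(by_eye.items()):
        if first not in per_exam or second not in per_exam:
            continue
        o1, o2 = per_exam[first], per_exam[second]
        if level == "abnormal" and (
            o1.n_abnormal < min_abnormal or o2.n_abnormal < min_abnormal
        ):
            continue
        ids.append(eye_id)
        v1.append(getattr(o1, attr))
        v2.append(getattr(o2, attr))
    return PairedSeries(
        ids=tuple(ids),
        value_1=np.array(v1),
        value_2=np.array(v2),
        level=f"eye_mean_{'all' if level == 'all' else 'abnormal'}",
    )


def paired_points(
    scores_by_exam: Mapping[tuple[str, str, int], Sequence[PointScore]],
    *,
    exam_pair: tuple[int, int] = (1, 2),
    field: str = "adjusted_threshold",
) -> PairedSeries:
    """Pair individual grid points between two exams of each eye.

    ``scores_by_exam`` maps (subject, eye, exam_index) to point scores;
    ``field`` is the :class:`PointScore` attribute to compare (calibrated
    threshold by default).
    """
    by_eye: dict[tuple[str, str], dict[int, Sequence[PointScore]]] = {}
    for (subject, eye, exam_index), scores in scores_by_exam.items():
        by_eye.setdefault((subject, eye), {})[exam_index] = scores
    ids, v1, v2 = [], [], []
    first, second = exam_pair
    for eye_id, per_exam in sorted(by_eye.items()):
        if first not in per_exam or second not in per_exam:
            continue
        s1 = {s.point_index: s for s in per_exam[first]}
        s2 = {s.point_index: s for s in per_exam[second]}
        for idx in sorted(s1.keys() & s2.keys()):
            ids.append((*eye_id, idx))
            v1.append(getattr(s1[idx], field))
            v2.append(getattr(s2[idx], field))
    return PairedSeries(
        ids=tuple(ids),
        value_1=np.array(v1),
        value_2=np.array(v2),
        level="pointwise",
    )
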