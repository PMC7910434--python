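"""Age-linear normative threshold model and device calibration offset.

The expected normal sensitivity at any grid point is modelled as a linear
function of age, identical at every location:

    expected dB = intercept + slope * age        (default 32.3 - 0.06*age)

with a single pointwise standard deviation (default 1.78 dB) describing the
spread of healthy measurements around that expectation.  Deviation scoring
(:mod:`micropoint.outcomes`) compares each measured threshold against this
expectation.

A device or cohort may read systematically lower than the normative model
predicts.  :func:`estimate_offset` quantifies that discrepancy from a set
of healthy-control exams as a single global calibration constant which is
*added* to every measured threshold before deviations are computed (a
positive offset means the device under-reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_model import Cohort, Exam

__all__ = [
    "NormativeModel",
    "CalibrationOffset",
    "expected_threshold",
    "estimate_offset",
    "NO_OFFSET",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormativeModel:
    """Location-independent linear age model for expected sensitivity.

    Attributes
    ----------
    intercept : float
        Expected threshold at age 0, dB.
    slope : float
        Change per year of age, dB/year (negative: sensitivity declines).
    pointwise_sd : float
        SD of healthy thresholds around the expectation, dB, assumed the
        same at every grid point and age.
    """

    intercept: float = 32.3
    slope: float = -0.06
    pointwise_sd: float = 1.78

    def __post_init__(self) -> None:
        if not self.pointwise_sd > 0:
            raise ValueError(
                f"pointwise_sd must be > 0, got {self.pointwise_sd}"
            )

    def predict(self, age: float | np.ndarray) -> float | np.ndarray:
        """Expected threshold at ``age`` (no validation; vectorised)."""
        return self.intercept + self.slope * np.asarray(age, dtype=float)[()]


def expected_threshold(model: NormativeModel, age: float) -> float:
    """Expected normal threshold (dB) at a subject's age.

    Raises :class:`ValueError` for non-positive age; use
    :meth:`NormativeModel.predict` for unvalidated analytic evaluation.
    """
    if not age > 0:
        raise ValueError(f"age must be positive, got {age}")
    return float(model.predict(age))


@dataclass(frozen=True)
class CalibrationOffset:
    """A global additive correction applied to measured thresholds.

    ``offset`` dB is added to every measured value before deviation
    scoring; offset 0 leaves thresholds unchanged.  ``n_eyes`` and
    ``source`` record provenance.
    """

    offset: float
    n_eyes: int = 0
    source: str = ""


#: Convenience constant: no calibration applied.
NO_OFFSET = CalibrationOffset(0.0, 0, "none")


def estimate_offset(
    model: NormativeModel, healthy_exams: Sequence[Exam]
) -> CalibrationOffset:
    """Estimate the device calibration offset from healthy-control exams.

    Each eye contributes the mean of its per-exam grid means; the eye's
    offset is ``expected_threshold(age) - that mean``, and the cohort
    offset is the unweighted mean over eyes.  For balanced designs (equal
    exam counts per eye) this equals the pooled-point computation, by
    linearity of the age model.

    Raises on empty input; logs a warning if any exam is not labelled
    healthy (it is still used — the caller chose the cohort).
    """
    healthy_exams = list(healthy_exams)
    if not healthy_exams:
        raise ValueError("estimate_offset requires at least one healthy exam")
    non_healthy = [e.exam_id for e in healthy_exams if e.cohort is not Cohort.HEALTHY]
    if non_healthy:
        log.warning(
            "estimate_offset: %d exam(s) not labelled healthy: %s",
            len(non_healthy),
            non_healthy[:5],
        )

    by_eye: dict[tuple[str, str], list[Exam]] = {}
    for exam in healthy_exams:
        by_eye.setdefault(exam.eye_id, []).append(exam)

    deltas = []
    for exams in by_eye.values():
        grid_mean = float(np.mean([e.mean_threshold for e in exams]))
        age = exams[0].age
        deltas.append(expected_threshold(model, age) - grid_mean)
    offset = float(np.mean(deltas))
    return CalibrationOffset(
        offset=offset,
        n_eyes=len(by_eye),
        source=f"estimated from {len(healthy_exams)} healthy exam(s), "
        f"{len(by_eye)} eye(s)",
    )
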