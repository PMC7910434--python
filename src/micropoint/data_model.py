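"""Grid geometry and exam containers.

A microperimetry exam measures differential light sensitivity (dB) at a
fixed set of retinal locations ("grid points") while the device tracks the
fundus.  Everything downstream — normative deviation scoring, abnormality
classification, agreement statistics — consumes the two containers defined
here: :class:`Grid` (the geometric layout of test points) and :class:`Exam`
(one test of one eye: a threshold per grid point plus QC metadata).

Two built-in layouts are provided:

``study33``
    1 central point plus rings at 1°, 3°, 5° and 7° eccentricity with
    8 points each (45° angular spacing), 33 points spanning the central
    14° of the macula.
``norm61``
    1 central point plus rings at 1°–5° with 12 points each (30° spacing),
    61 points covering the central 10° — the layout used to build the
    device's normative database.

Only the eccentricities of these layouts are device-documented; the angular
spacing is a convention of this package (evenly spaced rings starting at
0°), and custom layouts can be loaded from a YAML file via
:func:`load_grid`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Eye",
    "Cohort",
    "GridPoint",
    "Grid",
    "Exam",
    "build_study_grid",
    "build_normative_grid",
    "grid_from_dict",
    "load_grid",
    "qc_filter",
    "THRESHOLD_MIN",
    "THRESHOLD_MAX",
    "DEFAULT_MAX_FP",
]

log = logging.getLogger(__name__)

#: Device dynamic range for threshold sensitivity, dB.  Values are
#: validated against this range on construction, never clipped.
THRESHOLD_MIN = 0.0
THRESHOLD_MAX = 36.0

#: Default QC ceiling on the false-positive catch-trial response rate.
#: Exams at or above this fraction are considered unreliable.
DEFAULT_MAX_FP = 0.33


class Eye(str, Enum):
    """Laterality label.  No nasal/temporal semantics are attached to the
    grid coordinates; the label only disambiguates eyes of one subject."""

    LEFT = "left"
    RIGHT = "right"


class Cohort(str, Enum):
    HEALTHY = "healthy"
    IAMD = "iAMD"


@dataclass(frozen=True)
class GridPoint:
    """One test location, in polar degrees relative to fixation.

    ``angle`` is measured counter-clockwise from the horizontal meridian,
    in [0, 360).  Cartesian coordinates are derived, never stored, so the
    polar/Cartesian invariant holds exactly.
    """

    index: int
    eccentricity: float
    angle: float

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"point index must be >= 0, got {self.index}")
        if self.eccentricity < 0:
            raise ValueError(
                f"eccentricity must be non-negative, got {self.eccentricity}"
            )
        if not 0 <= self.angle < 360:
            raise ValueError(f"angle must be in [0, 360), got {self.angle}")

    @property
    def x(self) -> float:
        """Horizontal position, degrees."""
        if self.eccentricity == 0:
            return 0.0
        return self.eccentricity * math.cos(math.radians(self.angle))

    @property
    def y(self) -> float:
        """Vertical position, degrees."""
        if self.eccentricity == 0:
            return 0.0
        return self.eccentricity * math.sin(math.radians(self.angle))


@dataclass(frozen=True)
class Grid:
    """An ordered, contiguously indexed set of :class:`GridPoint`."""

    name: str
    points: tuple[GridPoint, ...]

    def __post_init__(self) -> None:
        indices = [p.index for p in self.points]
        if indices != list(range(len(self.points))):
            raise ValueError(
                f"grid '{self.name}': point indices must be unique and "
                f"contiguous from 0, got {indices}"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def eccentricities(self) -> np.ndarray:
        return np.array([p.eccentricity for p in self.points])

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 2) array of Cartesian (x, y) in degrees."""
        return np.array([[p.x, p.y] for p in self.points])


def _ring_grid(name: str, rings: Sequence[tuple[float, int]]) -> Grid:
    """Central point plus evenly spaced rings; ``rings`` is a sequence of
    (eccentricity, n_points) with angular spacing 360/n starting at 0°."""
    points = [GridPoint(0, 0.0, 0.0)]
    idx = 1
    for ecc, n in rings:
        step = 360.0 / n
        for k in range(n):
            points.append(GridPoint(idx, ecc, k * step))
            idx += 1
    return Grid(name, tuple(points))


def build_study_grid() -> Grid:
    """The 33-point custom study grid: fixation plus 8-point rings at
    1°, 3°, 5° and 7° eccentricity (central 14° of the macula)."""
    return _ring_grid("study33", [(1.0, 8), (3.0, 8), (5.0, 8), (7.0, 8)])


def build_normative_grid() -> Grid:
    """The 61-point grid underlying the device's normative database:
    fixation plus 12-point rings at 1°–5° (central 10°)."""
    return _ring_grid("norm61", [(e, 12) for e in (1.0, 2.0, 3.0, 4.0, 5.0)])


def grid_from_dict(spec: dict) -> Grid:
    """Build a grid from ``{"name": ..., "points": [[ecc, angle], ...]}``.

    Point order in the list fixes the point indices.
    """
    name = spec["name"]
    points = tuple(
        GridPoint(i, float(ecc), float(angle))
        for i, (ecc, angle) in enumerate(spec["points"])
    )
    return Grid(name, points)


def load_grid(path: str | Path) -> Grid:
    """Load a grid definition from a YAML file (name + ecc/angle pairs)."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return grid_from_dict(spec)


_BUILTIN_GRIDS = {
    "study33": build_study_grid,
    "norm61": build_normative_grid,
}


def get_grid(name: str) -> Grid:
    """Resolve a built-in grid by name (``study33`` or ``norm61``)."""
    try:
        return _BUILTIN_GRIDS[name]()
    except KeyError:
        raise KeyError(
            f"unknown grid '{name}'; built-ins: {sorted(_BUILTIN_GRIDS)}"
        ) from None


@dataclass(frozen=True)
class Exam:
    """One microperimetry test of one eye.

    Parameters
    ----------
    subject_id, eye
        Identify the eye; together with ``exam_index`` they identify the
        test (``exam_index`` 1 = first of the repeated same-visit tests).
    age
        Subject age in years at testing.
    grid
        The stimulus layout used.
    thresholds
        One sensitivity value in dB per grid point, in grid-point order.
        Must lie within the device dynamic range [0, 36] dB; out-of-range
        values are rejected, not clipped.
    false_positive_rate
        Fraction of catch trials answered, in [0, 1]; the exam-level
        reliability index used by :func:`qc_filter`.
    cohort
        ``healthy`` or ``iAMD``.
    """

    subject_id: str
    eye: Eye
    exam_index: int
    age: float
    grid: Grid
    thresholds: np.ndarray
    false_positive_rate: float
    cohort: Cohort

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "thresholds", np.asarray(self.thresholds, dtype=float)
        )
        object.__setattr__(self, "eye", Eye(self.eye))
        object.__setattr__(self, "cohort", Cohort(self.cohort))
        if self.exam_index < 1:
            raise ValueError(f"exam_index must be >= 1, got {self.exam_index}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not 0 <= self.false_positive_rate <= 1:
            raise ValueError(
                f"false_positive_rate must be in [0, 1], "
                f"got {self.false_positive_rate}"
            )
        if self.thresholds.shape != (len(self.grid),):
            raise ValueError(
                f"exam {self.exam_id}: expected {len(self.grid)} thresholds "
                f"for grid '{self.grid.name}', got {self.thresholds.shape}"
            )
        bad = np.flatnonzero(
            (self.thresholds < THRESHOLD_MIN) | (self.thresholds > THRESHOLD_MAX)
        )
        if bad.size:
            raise ValueError(
                f"exam {self.exam_id}: thresholds outside "
                f"[{THRESHOLD_MIN:g}, {THRESHOLD_MAX:g}] dB at point(s) "
                f"{bad.tolist()}: {self.thresholds[bad].tolist()}"
            )

    @property
    def eye_id(self) -> tuple[str, str]:
        """(subject_id, eye) — identifies the eye across repeated exams."""
        return (self.subject_id, self.eye.value)

    @property
    def exam_id(self) -> tuple[str, str, int]:
        return (self.subject_id, self.eye.value, self.exam_index)

    @property
    def mean_threshold(self) -> float:
        """Whole-grid mean sensitivity, dB (unadjusted)."""
        return float(np.mean(self.thresholds))

    def shifted(self, delta_db: float) -> "Exam":
        """Copy with every threshold shifted by ``delta_db`` (validated
        against the dynamic range like any other exam)."""
        return replace(self, thresholds=self.thresholds + delta_db)


def qc_filter(
    exams: Iterable[Exam], max_fp: float = DEFAULT_MAX_FP
) -> list[Exam]:
    """Drop unreliable exams by false-positive catch-trial rate.

    An exam is retained iff ``false_positive_rate < max_fp`` (strict: an
    exam exactly at the ceiling is excluded).  Order is preserved and each
    exclusion is logged.
    """
    if not 0 < max_fp <= 1:
        raise ValueError(f"max_fp must be in (0, 1], got {max_fp}")
    kept: list[Exam] = []
    for exam in exams:
        if exam.false_positive_rate < max_fp:
            kept.append(exam)
        else:
            log.info(
                "qc_filter: excluding exam %s (false-positive rate "
                "%.3f >= %.3f)",
                exam.exam_id,
                exam.false_positive_rate,
                max_fp,
            )
    return kept
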