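"""Synthetic microperimetry cohorts with known ground truth.

The study's raw exams are not deposited, so every pipeline stage is
exercised on simulated cohorts that reproduce the statistical structure
the analysis assumes:

* healthy eyes whose true sensitivity at every point equals the age-linear
  normative expectation minus a global device offset (default 2.67 dB, so
  the calibration stage has something to recover), with within-grid
  variation coming from measurement noise alone (SD ~1.7 dB, matching the
  ~1.8 dB within-grid SD seen in healthy controls);
* intermediate-AMD eyes with a *diffuse* whole-grid depression plus
  *focal* lesions on a subset of points (contiguous angular sector by
  default, random scatter as an option), calibrated so that the cohort
  shows a whole-grid mean deviation around -2.3 dB, a within-grid SD
  around 2.4 dB, and roughly a third of points abnormal, with wide
  eye-to-eye spread in the abnormal count;
* two same-visit exams per eye differing only by independent measurement
  noise, whose class-dependent SDs are calibrated against the reported
  agreement statistics (pointwise limits-of-agreement span near 9.6 dB,
  and abnormal-point eye means repeating better than whole-grid means).

Each eye draws its true sensitivity surface once and then produces
``n_exams`` noisy measurements of it, truncated to the device range and
quantised to 0.1 dB.  A single RNG stream per eye, seeded from the master
seed and the subject index, makes datasets bit-reproducible independent
of generation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    THRESHOLD_MAX,
    THRESHOLD_MIN,
    Cohort,
    Exam,
    Eye,
    Grid,
    build_study_grid,
)
from .normative import NormativeModel

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_eye", "simulate_cohort"]

log = logging.getLogger(__name__)

#: Warn when truncation to the device range affects more than this
#: fraction of points (floor effects bias deviation scores).
TRUNCATION_WARN_FRACTION = 0.01

_COHORT_STREAM = {Cohort.HEALTHY: 1, Cohort.IAMD: 2}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Ages are drawn per subject from cohort-specific normal distributions
    (defaults match the study cohorts: healthy 62.2 +/- 4.4 years, iAMD
    67.7 +/- 7.1), or uniformly from ``age_uniform`` when given.  All
    depression parameters are in dB and non-positive by construction
    (draws are clipped towards no-loss, never towards deeper loss).
    """

    n_healthy: int = 22
    n_iamd: int = 25
    n_exams: int = 2
    grid: Grid = field(default_factory=build_study_grid)
    model: NormativeModel = field(default_factory=NormativeModel)

    healthy_age_mean: float = 62.2
    healthy_age_sd: float = 4.4
    iamd_age_mean: float = 67.7
    iamd_age_sd: float = 7.1
    #: Optional (low, high): draw ages uniformly for both cohorts instead.
    age_uniform: tuple[float, float] | None = None

    #: Global dB subtracted from all simulated true thresholds; the
    #: calibration stage should recover it (as a positive offset).
    device_offset: float = 2.67

    #: Measurement noise SD per point per exam, healthy eyes.
    noise_sd_healthy: float = 1.73
    #: Measurement noise SD at unaffected points of iAMD eyes.
    noise_sd_unaffected: float = 2.05
    #: Measurement noise SD at focally affected points of iAMD eyes.
    noise_sd_lesion: float = 0.9
    #: SD of a whole-exam session shift shared by all points (0 = off).
    session_sd: float = 0.0

    #: Diffuse (whole-grid) depression per iAMD eye, dB.
    diffuse_mean: float = -0.6
    diffuse_sd: float = 0.5
    #: Number of focally affected points per iAMD eye: rounded normal
    #: draw clipped to [0, grid size].
    lesion_count_mean: float = 11.0
    lesion_count_sd: float = 8.0
    #: Per-eye mean focal lesion depth, dB (clipped to <= -1 when any
    #: points are affected, so "affected" means measurably affected).
    lesion_depth_mean: float = -4.5
    lesion_depth_sd: float = 1.2
    #: Per-point scatter of focal depth around the eye mean, dB.
    lesion_point_sd: float = 1.0
    #: "sector" = contiguous angular cluster (drusen-like focal damage);
    #: "random" = scattered points.
    spatial_mode: str = "sector"

    #: False-positive catch-trial rates are drawn uniformly in [0, fp_max].
    fp_max: float = 0.2

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "healthy_age_sd",
            "iamd_age_sd",
            "noise_sd_healthy",
            "noise_sd_unaffected",
            "noise_sd_lesion",
            "session_sd",
            "diffuse_sd",
            "lesion_count_sd",
            "lesion_depth_sd",
            "lesion_point_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_healthy < 0 or self.n_iamd < 0 or self.n_exams < 1:
            raise ValueError("cohort sizes must be >= 0 and n_exams >= 1")
        if self.spatial_mode not in ("sector", "random"):
            raise ValueError(
                f"spatial_mode must be 'sector' or 'random', got {self.spatial_mode!r}"
            )
        if not 0 <= self.lesion_count_mean <= len(self.grid):
            raise ValueError(
                f"lesion_count_mean must be within the grid size "
                f"[0, {len(self.grid)}], got {self.lesion_count_mean}"
            )
        if not 0 <= self.fp_max <= 1:
            raise ValueError(f"fp_max must be in [0, 1], got {self.fp_max}")


@dataclass(frozen=True)
class SimulatedDataset:
    """Simulated exams plus the per-eye ground truth that produced them."""

    exams: list[Exam]
    truth: pd.DataFrame
    config: SimulationConfig

    @property
    def healthy(self) -> list[Exam]:
        return [e for e in self.exams if e.cohort is Cohort.HEALTHY]

    @property
    def iamd(self) -> list[Exam]:
        return [e for e in self.exams if e.cohort is Cohort.IAMD]


def _draw_age(config: SimulationConfig, cohort: Cohort, rng: np.random.Generator) -> float:
    if config.age_uniform is not None:
        lo, hi = config.age_uniform
        age = rng.uniform(lo, hi)
    elif cohort is Cohort.HEALTHY:
        age = rng.normal(config.healthy_age_mean, config.healthy_age_sd)
    else:
        age = rng.normal(config.iamd_age_mean, config.iamd_age_sd)
    return round(max(age, 18.0), 1)


def _sector_order(grid: Grid) -> list[int]:
    """Circular ordering of points by angle (ties by eccentricity); the
    central point, which has no meaningful angle, is placed last."""
    peripheral = sorted(
        (p for p in grid.points if p.eccentricity > 0),
        key=lambda p: (p.angle, p.eccentricity),
    )
    central = [p for p in grid.points if p.eccentricity == 0]
    return [p.index for p in peripheral] + [p.index for p in central]


def _affected_points(
    config: SimulationConfig, k: int, rng: np.random.Generator
) -> np.ndarray:
    n = len(config.grid)
    if k == 0:
        return np.array([], dtype=int)
    if config.spatial_mode == "random":
        return np.sort(rng.choice(n, size=k, replace=False))
    order = _sector_order(config.grid)
    start = int(rng.integers(0, n))
    picked = [order[(start + i) % n] for i in range(k)]
    return np.sort(np.array(picked, dtype=int))


def simulate_eye(
    config: SimulationConfig,
    cohort_label: Cohort | str,
    subject_index: int,
) -> tuple[list[Exam], dict]:
    """Simulate all exams of one eye; returns (exams, ground-truth row).

    The RNG stream is seeded from ``(config.seed, cohort, subject_index)``
    so each eye is reproducible regardless of generation order.
    """
    cohort = Cohort(cohort_label)
    rng = np.random.default_rng(
        [config.seed, _COHORT_STREAM[cohort], subject_index]
    )
    subject_id = f"{'H' if cohort is Cohort.HEALTHY else 'A'}{subject_index:04d}"
    age = _draw_age(config, cohort, rng)
    n = len(config.grid)

    base = float(config.model.predict(age)) - config.device_offset
    true_surface = np.full(n, base)
    noise_sd = np.full(n, config.noise_sd_healthy)

    diffuse = 0.0
    affected = np.array([], dtype=int)
    focal_depths = np.array([])
    if cohort is Cohort.IAMD:
        diffuse = min(rng.normal(config.diffuse_mean, config.diffuse_sd), 0.0)
        k = int(
            np.clip(
                round(rng.normal(config.lesion_count_mean, config.lesion_count_sd)),
                0,
                n,
            )
        )
        affected = _affected_points(config, k, rng)
        eye_depth = rng.normal(config.lesion_depth_mean, config.lesion_depth_sd)
        if k:
            eye_depth = min(eye_depth, -1.0)
            focal_depths = np.minimum(
                rng.normal(eye_depth, config.lesion_point_sd, size=k), 0.0
            )
        true_surface = true_surface + diffuse
        true_surface[affected] += focal_depths
        noise_sd = np.full(n, config.noise_sd_unaffected)
        noise_sd[affected] = config.noise_sd_lesion

    exams = []
    n_clipped = 0
    for exam_index in range(1, config.n_exams + 1):
        session = rng.normal(0.0, config.session_sd) if config.session_sd else 0.0
        measured = true_surface + session + rng.normal(0.0, noise_sd, size=n)
        clipped = np.clip(measured, THRESHOLD_MIN, THRESHOLD_MAX)
        n_clipped += int(np.sum(clipped != measured))
        exams.append(
            Exam(
                subject_id=subject_id,
                eye=Eye.RIGHT,
                exam_index=exam_index,
                age=age,
                grid=config.grid,
                thresholds=np.round(clipped, 1),
                false_positive_rate=round(float(rng.uniform(0, config.fp_max)), 4),
                cohort=cohort,
            )
        )

    truth = {
        "subject_id": subject_id,
        "eye": Eye.RIGHT.value,
        "cohort": cohort.value,
        "age": age,
        "device_offset": config.device_offset,
        "diffuse_depression": diffuse,
        "n_affected": len(affected),
        "affected_indices": ";".join(str(i) for i in affected.tolist()),
        "mean_focal_depth": float(focal_depths.mean()) if len(focal_depths) else np.nan,
        "clipped_fraction": n_clipped / (n * config.n_exams),
    }
    return exams, truth


def simulate_cohort(config: SimulationConfig) -> SimulatedDataset:
    """Simulate both cohorts and assemble the ground-truth table.

    Warns when truncation at the device floor/ceiling affects more than
    1% of points in either cohort (floor effects bias deviations).
    """
    exams: list[Exam] = []
    truth_rows: list[dict] = []
    for cohort, n_eyes in (
        (Cohort.HEALTHY, config.n_healthy),
        (Cohort.IAMD, config.n_iamd),
    ):
        clipped = 0.0
        for subject_index in range(n_eyes):
            eye_exams, truth = simulate_eye(config, cohort, subject_index)
            exams.extend(eye_exams)
            truth_rows.append(truth)
            clipped += truth["clipped_fraction"]
        if n_eyes and clipped / n_eyes > TRUNCATION_WARN_FRACTION:
            log.warning(
                "simulate_cohort: %.2f%% of %s points truncated to the "
                "device range; deviation scores may be biased",
                100.0 * clipped / n_eyes,
                cohort.value,
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "subject_id",
            "eye",
            "cohort",
            "age",
            "device_offset",
            "diffuse_depression",
            "n_affected",
            "affected_indices",
            "mean_focal_depth",
            "clipped_fraction",
        ],
    )
    return SimulatedDataset(exams=exams, truth=truth, config=config)
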