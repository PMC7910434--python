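"""CSV exam tables and the end-to-end pipeline.

The on-disk exam format is one CSV row per tested grid point::

    subject_id,eye,exam_index,age,cohort,point_index,x_deg,y_deg,threshold_db,false_positive_rate

UTF-8, '.' decimal separator, thresholds stored at one decimal (device
output precision; internal computation is full precision).  Every
(subject_id, eye, exam_index) group must cover each grid point exactly
once, with constant exam-level fields; :func:`read_exams` reports
violations with row numbers.

:func:`run_pipeline` composes the full analysis: QC filter -> calibration
offset (estimated from healthy controls or fixed) -> pointwise deviation
scoring -> per-eye and cohort summaries -> eligibility -> Bland-Altman
agreement and Cohen's d, writing per-point, per-eye and cohort CSVs plus
a plain-text run log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import agreement as agr
from .data_model import (
    Cohort,
    Exam,
    Grid,
    get_grid,
    load_grid,
    qc_filter,
    DEFAULT_MAX_FP,
)
from .normative import CalibrationOffset, NormativeModel, estimate_offset
from .outcomes import (
    AbnormalityCriterion,
    CohortSummary,
    EyeOutcome,
    PointScore,
    default_criteria,
    outcomes_to_frame,
    score_exam,
    scores_to_frame,
    summarize_cohort,
    summarize_eye,
)
from .synthetic import SimulatedDataset, SimulationConfig, simulate_cohort

__all__ = ["EXAM_COLUMNS", "read_exams", "write_exams", "run_pipeline", "PipelineError", "PipelineResult"]

log = logging.getLogger(__name__)

EXAM_COLUMNS = [
    "subject_id",
    "eye",
    "exam_index",
    "age",
    "cohort",
    "point_index",
    "x_deg",
    "y_deg",
    "threshold_db",
    "false_positive_rate",
]

_COORD_TOL = 1e-6


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def write_exams(exams: Sequence[Exam], path: str | Path) -> None:
    """Write exams as the per-point CSV table.

    Thresholds are written at one decimal; all other numeric fields use
    the shortest exact float representation, so a write/read round trip
    reproduces one-decimal data bit-identically.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(EXAM_COLUMNS) + "\n")
        for exam in exams:
            for point, threshold in zip(exam.grid.points, exam.thresholds):
                fh.write(
                    f"{exam.subject_id},{exam.eye.value},{exam.exam_index},"
                    f"{float(exam.age)!r},{exam.cohort.value},{point.index},"
                    f"{point.x!r},{point.y!r},{threshold:.1f},"
                    f"{float(exam.false_positive_rate)!r}\n"
                )


def read_exams(path: str | Path, grid: Grid) -> list[Exam]:
    """Read and validate exams from the per-point CSV table.

    Raises :class:`ValueError` listing every violation (missing columns,
    duplicate or missing grid points, inconsistent exam-level fields,
    coordinates disagreeing with ``grid``) with 1-based file row numbers.
    """
    frame = pd.read_csv(Path(path))
    missing = [c for c in EXAM_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    # file row number of each record (1-based, counting the header)
    frame = frame.assign(_row=frame.index + 2)

    errors: list[str] = []
    exams: list[Exam] = []
    expected_indices = set(range(len(grid)))
    coords = {p.index: (p.x, p.y) for p in grid.points}

    for exam_id, grp in frame.groupby(
        ["subject_id", "eye", "exam_index"], sort=False
    ):
        label = f"exam {exam_id}"
        indices = grp["point_index"].tolist()
        dupes = sorted({i for i in indices if indices.count(i) > 1})
        if dupes:
            rows = grp.loc[grp["point_index"].isin(dupes), "_row"].tolist()
            errors.append(f"{label}: duplicate point(s) {dupes} (rows {rows})")
            continue
        absent = sorted(expected_indices - set(indices))
        extra = sorted(set(indices) - expected_indices)
        if absent or extra:
            errors.append(
                f"{label}: grid '{grid.name}' mismatch — missing point(s) "
                f"{absent}, unknown point(s) {extra} "
                f"(rows {grp['_row'].min()}–{grp['_row'].max()})"
            )
            continue
        for col in ("age", "cohort", "false_positive_rate"):
            if grp[col].nunique() > 1:
                errors.append(
                    f"{label}: exam-level field '{col}' is not constant "
                    f"(rows {grp['_row'].min()}–{grp['_row'].max()})"
                )
        grp = grp.sort_values("point_index")
        for _, rec in grp.iterrows():
            x, y = coords[int(rec["point_index"])]
            if abs(rec["x_deg"] - x) > _COORD_TOL or abs(rec["y_deg"] - y) > _COORD_TOL:
                errors.append(
                    f"{label}: point {int(rec['point_index'])} coordinates "
                    f"({rec['x_deg']}, {rec['y_deg']}) disagree with grid "
                    f"'{grid.name}' ({x:.6f}, {y:.6f}) (row {rec['_row']})"
                )
        try:
            exams.append(
                Exam(
                    subject_id=str(exam_id[0]),
                    eye=str(exam_id[1]),
                    exam_index=int(exam_id[2]),
                    age=float(grp["age"].iloc[0]),
                    grid=grid,
                    thresholds=grp["threshold_db"].to_numpy(dtype=float),
                    false_positive_rate=float(grp["false_positive_rate"].iloc[0]),
                    cohort=str(grp["cohort"].iloc[0]),
                )
            )
        except ValueError as exc:
            errors.append(
                f"{label}: {exc} (rows {grp['_row'].min()}–{grp['_row'].max()})"
            )
    if errors:
        raise ValueError(f"{path}: invalid exam table:\n" + "\n".join(errors))
    return exams


@dataclass
class PipelineResult:
    """Objects and file paths produced by :func:`run_pipeline`."""

    exams: list[Exam]
    offset: CalibrationOffset
    criteria: list[AbnormalityCriterion]
    scores: dict[tuple[str, str, int], list[PointScore]]
    eye_outcomes: list[EyeOutcome]
    cohort_summaries: dict[str, CohortSummary]
    agreement: pd.DataFrame
    effect_sizes: pd.DataFrame
    paths: dict[str, Path]


def _package_version() -> str:
    try:
        return version("micropoint")
    except PackageNotFoundError:  # pragma: no cover - editable corner case
        return "unknown"


def _resolve_grid(spec) -> Grid:
    if isinstance(spec, Grid):
        return spec
    if isinstance(spec, str) and spec in ("study33", "norm61"):
        return get_grid(spec)
    return load_grid(spec)


def run_pipeline(config: Mapping, outdir: str | Path) -> PipelineResult:
    """Run the whole analysis from a declarative configuration.

    ``config`` keys (all optional unless noted):

    ``input``
        Path to an exam CSV.  Exactly one of ``input`` / ``simulate``.
    ``simulate``
        Mapping of :class:`~micropoint.synthetic.SimulationConfig`
        overrides (e.g. ``{"n_iamd": 40, "seed": 7}``).
    ``grid``
        Built-in grid name or grid YAML path (default ``study33``).
    ``model``
        Normative model overrides (``intercept``, ``slope``,
        ``pointwise_sd``).
    ``offset``
        ``"estimate"`` (default; from healthy exams) or a fixed dB value.
    ``rounded_cutoffs``
        Use the one-decimal clinical cutoffs (default false).
    ``min_abnormal``
        Eligibility threshold, abnormal points per exam (default 5).
    ``qc_max_fp``
        False-positive QC ceiling (default 0.33).

    Outputs under ``outdir``: ``exams.csv`` (when simulated),
    ``truth.csv``, ``points.csv``, ``eyes.csv``, ``cohort_<label>.csv``,
    ``eligibility_<label>.csv``, ``agreement.csv``, ``effect_sizes.csv``
    and ``run_log.txt``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    log_lines: list[str] = [f"micropoint {_package_version()}"]

    def stage(name):
        class _Stage:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage '{name}': {exc}") from exc

        return _Stage()

    with stage("configuration"):
        grid = _resolve_grid(config.get("grid", "study33"))
        model = NormativeModel(**config.get("model", {}))
        if ("input" in config) == ("simulate" in config):
            raise ValueError("config needs exactly one of 'input' or 'simulate'")
        log_lines.append(f"grid: {grid.name} ({len(grid)} points)")
        log_lines.append(
            f"model: intercept={model.intercept} slope={model.slope} "
            f"pointwise_sd={model.pointwise_sd}"
        )

    dataset: SimulatedDataset | None = None
    with stage("input"):
        if "input" in config:
            exams = read_exams(config["input"], grid)
            log_lines.append(f"input: {config['input']} ({len(exams)} exams)")
        else:
            sim_kwargs = dict(config.get("simulate") or {})
            sim_config = SimulationConfig(grid=grid, model=model, **sim_kwargs)
            dataset = simulate_cohort(sim_config)
            exams = dataset.exams
            paths["exams"] = outdir / "exams.csv"
            write_exams(exams, paths["exams"])
            paths["truth"] = outdir / "truth.csv"
            dataset.truth.to_csv(paths["truth"], index=False)
            log_lines.append(
                f"simulated: {sim_config.n_healthy} healthy + "
                f"{sim_config.n_iamd} iAMD eyes x {sim_config.n_exams} exams "
                f"(seed {sim_config.seed})"
            )

    with stage("qc_filter"):
        max_fp = float(config.get("qc_max_fp", DEFAULT_MAX_FP))
        n_before = len(exams)
        exams = qc_filter(exams, max_fp)
        log_lines.append(
            f"qc_filter: kept {len(exams)}/{n_before} exams "
            f"(false-positive rate < {max_fp})"
        )
        if not exams:
            raise ValueError("no exams left after QC filtering")

    with stage("calibration"):
        offset_spec = config.get("offset", "estimate")
        if offset_spec == "estimate":
            healthy = [e for e in exams if e.cohort is Cohort.HEALTHY]
            offset = estimate_offset(model, healthy)
        else:
            offset = CalibrationOffset(float(offset_spec), 0, "fixed by config")
        log_lines.append(f"offset: {offset.offset:+.4f} dB ({offset.source})")

    with stage("scoring"):
        criteria = default_criteria(
            pointwise_sd=model.pointwise_sd,
            rounded=bool(config.get("rounded_cutoffs", False)),
        )
        for c in criteria:
            log_lines.append(
                f"criterion {c.label}: cutoff {c.cutoff_db:.4g} dB "
                f"({'rounded' if c.rounded else 'unrounded'})"
            )
        scores = {e.exam_id: score_exam(e, model, offset, criteria) for e in exams}
        paths["points"] = outdir / "points.csv"
        scores_to_frame(scores).to_csv(paths["points"], index=False)

    with stage("eye_summaries"):
        eye_outcomes = [
            summarize_eye(scores[e.exam_id], criterion, exam=e)
            for e in exams
            for criterion in criteria
        ]
        paths["eyes"] = outdir / "eyes.csv"
        outcomes_to_frame(eye_outcomes).to_csv(paths["eyes"], index=False)

    min_abnormal = int(config.get("min_abnormal", 5))
    cohort_summaries: dict[str, CohortSummary] = {}
    with stage("cohort_summaries"):
        by_cohort: dict[str, list[EyeOutcome]] = {}
        cohort_of_exam = {e.exam_id: e.cohort.value for e in exams}
        for outcome in eye_outcomes:
            key = (outcome.subject_id, outcome.eye, outcome.exam_index)
            by_cohort.setdefault(cohort_of_exam[key], []).append(outcome)
        for label, outs in sorted(by_cohort.items()):
            summary = summarize_cohort(outs, min_abnormal=min_abnormal)
            cohort_summaries[label] = summary
            paths[f"cohort_{label}"] = outdir / f"cohort_{label}.csv"
            summary.per_exam.to_csv(paths[f"cohort_{label}"], index=False)
            paths[f"eligibility_{label}"] = outdir / f"eligibility_{label}.csv"
            summary.eligibility.to_csv(paths[f"eligibility_{label}"], index=False)
            log_lines.append(
                f"cohort {label}: {summary.n_eyes} eyes, "
                f"min_abnormal {min_abnormal}"
            )

    with stage("agreement"):
        iamd_ids = {e.exam_id for e in exams if e.cohort is Cohort.IAMD}
        iamd_outcomes = [
            o
            for o in eye_outcomes
            if (o.subject_id, o.eye, o.exam_index) in iamd_ids
        ]
        iamd_scores = {k: v for k, v in scores.items() if k in iamd_ids}
        rows = []
        pairs = agr.paired_eye_means(
            [o for o in iamd_outcomes if o.criterion == criteria[0].label],
            level="all",
        )
        if len(pairs) >= 2:
            rows.append(("all_points", "", agr.bland_altman(pairs)))
        for criterion in criteria:
            pairs = agr.paired_eye_means(
                [o for o in iamd_outcomes if o.criterion == criterion.label],
                level="abnormal",
                min_abnormal=min_abnormal,
            )
            if len(pairs) >= 2:
                rows.append(("abnormal_points", criterion.label, agr.bland_altman(pairs)))
        point_pairs = agr.paired_points(iamd_scores)
        if len(point_pairs) >= 2:
            rows.append(("pointwise", "", agr.bland_altman(point_pairs)))
        agreement_frame = pd.DataFrame(
            [
                {
                    "level": level,
                    "criterion": criterion,
                    "n": result.n,
                    "mean_diff": result.mean_diff,
                    "sd_diff": result.sd_diff,
                    "loa_lower": result.loa_lower,
                    "loa_upper": result.loa_upper,
                    "span": result.span,
                    "half_width": result.half_width,
                }
                for level, criterion, result in rows
            ]
        )
        paths["agreement"] = outdir / "agreement.csv"
        agreement_frame.to_csv(paths["agreement"], index=False)

    with stage("effect_sizes"):
        healthy_ids = {e.exam_id for e in exams if e.cohort is Cohort.HEALTHY}
        healthy_devs = [
            o.mean_deviation_all
            for o in eye_outcomes
            if (o.subject_id, o.eye, o.exam_index) in healthy_ids
            and o.criterion == criteria[0].label
        ]
        effect_rows = []
        if len(healthy_devs) >= 2:
            for criterion in criteria:
                for exam_index in sorted({o.exam_index for o in iamd_outcomes}):
                    devs = [
                        o.mean_deviation_abnormal
                        for o in iamd_outcomes
                        if o.criterion == criterion.label
                        and o.exam_index == exam_index
                        and o.has_abnormal
                    ]
                    if len(devs) >= 2:
                        effect_rows.append(
                            {
                                "criterion": criterion.label,
                                "exam_index": exam_index,
                                "n_iamd": len(devs),
                                "n_healthy": len(healthy_devs),
                                "cohens_d": agr.cohens_d(devs, healthy_devs),
                            }
                        )
        effect_frame = pd.DataFrame(effect_rows)
        paths["effect_sizes"] = outdir / "effect_sizes.csv"
        effect_frame.to_csv(paths["effect_sizes"], index=False)

    with stage("run_log"):
        paths["run_log"] = outdir / "run_log.txt"
        log_lines.append(f"min_abnormal: {min_abnormal}")
        paths["run_log"].write_text("\n".join(log_lines) + "\n", encoding="utf-8")

    return PipelineResult(
        exams=exams,
        offset=offset,
        criteria=criteria,
        scores=scores,
        eye_outcomes=eye_outcomes,
        cohort_summaries=cohort_summaries,
        agreement=agreement_frame,
        effect_sizes=effect_frame,
        paths=paths,
    )
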