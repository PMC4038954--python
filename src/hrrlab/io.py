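"""CSV dialects, config files and end-to-end pipeline orchestration.

Beat files are long-format CSV with columns ``subject_id, beat_time_s, phase``
(strictly increasing times per subject; phases contiguous in the order
rest -> exercise -> recovery).  Metadata files carry one row per subject with
the scalar cohort fields; missing values are empty cells.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    HrrlabError,
    InsufficientDataError,
    ParseError,
    UndefinedReserveError,
    ValidationError,
)
from .hrr import compute_hrr_profile
from .preprocessing import PHASES, BeatSeries
from .records import METADATA_COLUMNS, SubjectRecord, cohort_to_frame
from .spectral import METHODS, recovery_spectrum
from .stats import run_model1, run_model2, table1_summary
from .synthetic import GeneratorConfig, GroupParams, default_config

log = logging.getLogger("hrrlab")

BEAT_HEADER = ["subject_id", "beat_time_s", "phase"]

#: machine-readable exclusion reason codes
EXCLUDE_SUBMAXIMAL = "submaximal_rer_below_1.05"
EXCLUDE_NO_BEATS = "no_beat_series"
EXCLUDE_FAILED = "analysis_failed"

_PHASE_ORDER = {p: i for i, p in enumerate(PHASES)}


def write_beats(path, subjects: list[SubjectRecord]) -> None:
    """Write every subject's beat series to one long-format CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(BEAT_HEADER)
        for s in subjects:
            if s.beats is None:
                continue
            for t, phase in zip(s.beats.beat_times, s.beats.phases):
                writer.writerow([s.subject_id, f"{t:.6f}", phase])


def read_beats(path) -> dict[str, BeatSeries]:
    """Parse and validate a beat CSV into one BeatSeries per subject.

    Raises :class:`ParseError` with the first offending line number on
    non-monotone times, unknown phases, phase order violations or missing
    columns.
    """
    rows: dict[str, list[tuple[float, str, int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != BEAT_HEADER:
            raise ParseError(
                f"expected header {BEAT_HEADER}, got {header}", line=1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 3:
                raise ParseError(f"expected 3 columns, got {len(row)}", line=lineno)
            sid, t_str, phase = (c.strip() for c in row)
            try:
                t = float(t_str)
            except ValueError:
                raise ParseError(f"invalid beat_time_s {t_str!r}", line=lineno)
            if phase not in PHASES:
                raise ParseError(f"unknown phase {phase!r}", line=lineno)
            rows.setdefault(sid, []).append((t, phase, lineno))

    series: dict[str, BeatSeries] = {}
    for sid, entries in rows.items():
        prev_t = -np.inf
        prev_phase_idx = 0
        recovery_onset = None
        for t, phase, lineno in entries:
            if t <= prev_t:
                raise ParseError(
                    f"subject {sid}: beat times not strictly increasing", line=lineno
                )
            idx = _PHASE_ORDER[phase]
            if idx < prev_phase_idx:
                raise ParseError(
                    f"subject {sid}: phase {phase!r} after "
                    f"{PHASES[prev_phase_idx]!r} (order must be rest->exercise->recovery)",
                    line=lineno,
                )
            if phase == "recovery" and recovery_onset is None:
                recovery_onset = t
            prev_t = t
            prev_phase_idx = idx
        times = np.array([e[0] for e in entries])
        phases = np.array([e[1] for e in entries], dtype=object)
        series[sid] = BeatSeries(
            beat_times=times,
            phases=phases,
            recovery_onset=recovery_onset if recovery_onset is not None else times[-1],
        )
    return series


def write_metadata(path, subjects: list[SubjectRecord]) -> None:
    pd.DataFrame([s.metadata_row() for s in subjects]).to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ("subject_id", "group") if c not in frame.columns]
    if missing:
        raise ParseError(f"metadata file missing columns {missing}")
    return frame


def load_config(path) -> GeneratorConfig:
    """Read a generator config from YAML/JSON; omitted fields take defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return default_config()
    groups = raw.pop("groups", None)
    if groups is not None:
        raw["groups"] = {
            label: GroupParams(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in params.items()
                }
            )
            for label, params in groups.items()
        }
        raw.setdefault(
            "n_per_group", {label: 0 for label in raw["groups"]}
        )
        if "phase_durations" in raw:
            raw["phase_durations"] = tuple(raw["phase_durations"])
        return GeneratorConfig(**raw)
    n_per_group = raw.pop("n_per_group", None)
    seed = raw.pop("seed", 0)
    if "phase_durations" in raw:
        raw["phase_durations"] = tuple(raw["phase_durations"])
    return default_config(n_per_group=n_per_group, seed=seed, **raw)


def dump_config(path, config: GeneratorConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    metrics: pd.DataFrame  # one analysis row per included subject
    summary: pd.DataFrame
    model1: dict
    model2: dict
    exclusions: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def _record_from_metadata(row: pd.Series, beats: BeatSeries | None) -> SubjectRecord:
    kwargs = {}
    for col in METADATA_COLUMNS:
        if col in row.index and not pd.isna(row[col]):
            kwargs[col] = row[col]
    for flag in ("nsvt", "syncope", "mwt_ge_30", "family_history_scd"):
        if flag in kwargs:
            kwargs[flag] = bool(kwargs[flag])
    if "nyha" in kwargs:
        kwargs["nyha"] = int(kwargs["nyha"])
    return SubjectRecord(beats=beats, **kwargs)


def analyze_subjects(
    subjects: list[SubjectRecord],
    methods=METHODS,
    min_rer: float = 1.05,
) -> tuple[list[SubjectRecord], pd.DataFrame, list[str]]:
    """Compute HRR metrics and band powers per subject, applying the
    submaximal-test exclusion; returns (included, exclusion log, warnings)."""
    included = []
    exclusions = []
    warnings = []
    for s in subjects:
        if np.isfinite(s.rer) and s.rer < min_rer:
            exclusions.append(
                {"subject_id": s.subject_id, "reason": EXCLUDE_SUBMAXIMAL, "detail": f"rer={s.rer:.3f}"}
            )
            continue
        if s.beats is None:
            exclusions.append(
                {"subject_id": s.subject_id, "reason": EXCLUDE_NO_BEATS, "detail": ""}
            )
            continue
        try:
            s.hrr = compute_hrr_profile(s.beats)
            for method in methods:
                s.bands[method] = recovery_spectrum(s.beats, method=method)
        except (InsufficientDataError, UndefinedReserveError, ValidationError) as exc:
            exclusions.append(
                {"subject_id": s.subject_id, "reason": EXCLUDE_FAILED, "detail": str(exc)}
            )
            continue
        if s.hrr.warnings:
            warnings.extend(f"{s.subject_id}: {w}" for w in s.hrr.warnings)
        included.append(s)
    log_df = pd.DataFrame(exclusions, columns=["subject_id", "reason", "detail"])
    return included, log_df, warnings


def run_pipeline(
    beats_path,
    metadata_path,
    methods=METHODS,
    elimination_threshold: float = 0.05,
) -> PipelineResult:
    """Full analysis: per-subject metrics, cohort summary, comparisons and the
    two regression models.  Deterministic given the inputs."""
    beat_map = read_beats(beats_path)
    metadata = read_metadata(metadata_path)
    if metadata.empty:
        raise ValidationError("empty cohort: metadata file has no rows")
    subjects = []
    for _, row in metadata.iterrows():
        beats = beat_map.get(str(row["subject_id"]))
        subjects.append(_record_from_metadata(row, beats))
    included, exclusion_log, warnings = analyze_subjects(subjects, methods=methods)
    for entry in exclusion_log.itertuples():
        log.info("excluded %s: %s %s", entry.subject_id, entry.reason, entry.detail)
    if not included:
        raise ValidationError("no subjects remain after exclusions")
    frame = cohort_to_frame(included)
    summary = table1_summary(frame)
    model1 = model2 = {}
    try:
        model1 = run_model1(frame, threshold=elimination_threshold)
    except HrrlabError as exc:
        warnings.append(f"model 1 skipped: {exc}")
    patients = frame[frame["is_patient"]]
    if len(patients) > 8:
        try:
            model2 = run_model2(patients, model1 or None, threshold=elimination_threshold)
        except HrrlabError as exc:
            warnings.append(f"model 2 skipped: {exc}")
    return PipelineResult(
        metrics=frame,
        summary=summary,
        model1=model1,
        model2=model2,
        exclusions=exclusion_log,
        warnings=warnings,
    )


def _regression_to_dict(model) -> dict:
    return {
        "response": model.response,
        "n": model.n,
        "r_squared": model.r_squared,
        "coefficients": model.coefficients,
        "retained": model.retained,
        "eliminated": model.eliminated,
    }


def write_results(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(out / "subject_metrics.csv", index=False)
    result.summary.to_csv(out / "cohort_summary.csv", index=False)
    result.exclusions.to_csv(out / "exclusions.csv", index=False)
    report = {
        "model1": {k: _regression_to_dict(v) for k, v in result.model1.items()},
        "model2": {
            k: {
                "stage1": {s: _regression_to_dict(m) for s, m in v.stage1.items()},
                "screen_passed": v.screen_passed,
                "stage2": _regression_to_dict(v.stage2) if v.stage2 else None,
            }
            for k, v in result.model2.items()
        },
        "warnings": result.warnings,
    }
    with open(out / "regression_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
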