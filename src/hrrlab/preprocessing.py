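"""Beat-time series to clean RR tachograms and windowed heart-rate estimates.

The primitive input everywhere is a :class:`BeatSeries` — one timestamp per
heartbeat with a phase label (``rest``/``exercise``/``recovery``).  This module
derives RR tachograms, rejects artifactual intervals, computes 10-beat windowed
heart rates (including resting and peak HR), and resamples tachograms onto a
uniform grid for the evenly-spaced spectral estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import InsufficientDataError, ValidationError

PHASES = ("rest", "exercise", "recovery")

#: artifact rejection rule: absolute RR bounds (ms) and max relative jump
RR_FLOOR_MS = 300.0
RR_CEIL_MS = 2000.0
RR_MAX_REL_DELTA = 0.20

DEFAULT_RESAMPLE_HZ = 4.0


@dataclass(frozen=True)
class BeatSeries:
    """Timestamped heartbeats with per-beat phase labels.

    Parameters
    ----------
    beat_times:
        Beat times in seconds from recording start, strictly increasing.
    phases:
        Phase label per beat, each one of ``rest``, ``exercise``, ``recovery``.
    recovery_onset:
        Time (s) at which workload returned to zero; all recovery-relative
        times reference this origin.
    """

    beat_times: np.ndarray
    phases: np.ndarray
    recovery_onset: float

    def __post_init__(self):
        times = np.asarray(self.beat_times, dtype=float)
        phases = np.asarray(self.phases, dtype=object)
        if times.ndim != 1 or times.size != phases.size:
            raise ValidationError("beat_times and phases must be 1-d and equal length")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValidationError("beat times must be strictly increasing")
        unknown = set(phases.tolist()) - set(PHASES)
        if unknown:
            raise ValidationError(f"unknown phase labels: {sorted(unknown)}")
        object.__setattr__(self, "beat_times", times)
        object.__setattr__(self, "phases", phases)

    def __len__(self):
        return self.beat_times.size

    def phase_times(self, phase: str) -> np.ndarray:
        if phase not in PHASES:
            raise ValidationError(f"unknown phase {phase!r}")
        return self.beat_times[self.phases == phase]


@dataclass(frozen=True)
class Tachogram:
    """RR-interval series; uniform after :func:`resample_uniform`."""

    sample_times: np.ndarray  # s, time of the *ending* beat of each interval
    rr_ms: np.ndarray
    uniform: bool = False
    sampling_rate: float | None = None
    accepted: np.ndarray | None = None  # bool mask set by filter_artifacts
    mean_removed: bool = False

    def __post_init__(self):
        t = np.asarray(self.sample_times, dtype=float)
        rr = np.asarray(self.rr_ms, dtype=float)
        if t.shape != rr.shape or t.ndim != 1:
            raise ValidationError("sample_times and rr_ms must be 1-d and equal length")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "rr_ms", rr)
        if self.accepted is not None:
            acc = np.asarray(self.accepted, dtype=bool)
            if acc.shape != t.shape:
                raise ValidationError("accepted mask shape mismatch")
            object.__setattr__(self, "accepted", acc)

    def __len__(self):
        return self.rr_ms.size

    @property
    def span(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.sample_times[-1] - self.sample_times[0])


@dataclass
class ArtifactReport:
    """Indices and reasons for rejected RR samples."""

    indices: list[int] = field(default_factory=list)
    reasons: list[str] = field(default_factory=list)
    n_total: int = 0
    warning: bool = False  # set when > 20% of samples were rejected

    @property
    def n_rejected(self) -> int:
        return len(self.indices)


def rr_from_beats(beats: BeatSeries, phase: str | None = None) -> Tachogram:
    """Successive-difference RR tachogram (ms), timestamped at the ending beat.

    ``phase=None`` uses the whole recording; otherwise only beats in that phase.
    """
    times = beats.beat_times if phase is None else beats.phase_times(phase)
    if times.size < 2:
        raise InsufficientDataError(
            f"need >= 2 beats to form RR intervals (got {times.size} in phase {phase!r})"
        )
    rr = np.diff(times) * 1000.0
    return Tachogram(sample_times=times[1:], rr_ms=rr)


def filter_artifacts(tachogram: Tachogram) -> tuple[Tachogram, ArtifactReport]:
    """Reject RR samples outside [300, 2000] ms or jumping > 20% from the
    previous accepted sample; rejected values are replaced by linear
    interpolation between accepted neighbours (for spectral use) and flagged
    in the ``accepted`` mask (windowed HR means must skip them).

    If more than 20% of the samples are rejected the report carries a
    ``warning`` flag; analysis proceeds.
    """
    if tachogram.uniform:
        raise ValidationError("filter_artifacts expects a non-uniform tachogram")
    rr = tachogram.rr_ms
    n = rr.size
    report = ArtifactReport(n_total=n)
    accepted = np.ones(n, dtype=bool)
    prev_ok: float | None = None
    for i, value in enumerate(rr):
        reason = None
        if not np.isfinite(value) or value < RR_FLOOR_MS:
            reason = "below-floor" if np.isfinite(value) else "non-finite"
        elif value > RR_CEIL_MS:
            reason = "above-ceiling"
        elif prev_ok is not None and abs(value - prev_ok) > RR_MAX_REL_DELTA * prev_ok:
            reason = "delta-exceeds-20pct"
        if reason is None:
            prev_ok = value
        else:
            accepted[i] = False
            report.indices.append(i)
            report.reasons.append(reason)

    cleaned = rr.copy()
    if not accepted.all():
        if not accepted.any():
            raise ValidationError("all RR samples rejected; nothing to interpolate from")
        idx = np.arange(n)
        cleaned[~accepted] = np.interp(idx[~accepted], idx[accepted], rr[accepted])
    if n and report.n_rejected / n > 0.20:
        report.warning = True
    out = Tachogram(
        sample_times=tachogram.sample_times,
        rr_ms=cleaned,
        uniform=False,
        accepted=accepted,
    )
    return out, report


def _accepted_intervals(beats: BeatSeries) -> tuple[np.ndarray, np.ndarray]:
    """Accepted RR intervals over the whole recording: (end_times, rr_ms)."""
    tach = rr_from_beats(beats)
    filtered, _ = filter_artifacts(tach)
    mask = filtered.accepted
    return tach.sample_times[mask], tach.rr_ms[mask]


def ten_beat_hr(
    beats: BeatSeries, t: float, n_intervals: int = 10, max_dist_s: float = 30.0
) -> tuple[float, tuple[float, float]]:
    """Mean HR over the 10 consecutive accepted RR intervals centred on ``t``.

    The window takes 5 intervals ending before ``t`` and 5 ending at/after,
    shifting inward at recording edges.  Returns ``(hr_bpm, (t_start, t_end))``
    where the tuple is the actual span of the window used.
    """
    end_times, rr = _accepted_intervals(beats)
    n = rr.size
    if n < n_intervals:
        raise InsufficientDataError(
            f"need {n_intervals} accepted RR intervals, have {n}"
        )
    k = int(np.searchsorted(end_times, t))
    start = int(np.clip(k - n_intervals // 2, 0, n - n_intervals))
    window_rr = rr[start : start + n_intervals]
    window_end = end_times[start : start + n_intervals]
    t_start = float(window_end[0] - window_rr[0] / 1000.0)
    t_end = float(window_end[-1])
    if t_end < t - max_dist_s or t_start > t + max_dist_s:
        raise InsufficientDataError(
            f"no {n_intervals}-interval window within {max_dist_s} s of t={t}"
        )
    hr = float(np.mean(60000.0 / window_rr))
    return hr, (t_start, t_end)


def resting_hr(beats: BeatSeries) -> float:
    """10-beat mean HR at the midpoint of the rest phase (beats/min)."""
    rest_times = beats.phase_times("rest")
    if rest_times.size < 2:
        raise InsufficientDataError("rest phase missing or too short")
    midpoint = float(0.5 * (rest_times[0] + rest_times[-1]))
    hr, _ = ten_beat_hr(beats, midpoint)
    return hr


def peak_hr(beats: BeatSeries) -> float:
    """Maximum 10-interval rolling mean HR over the exercise phase (beats/min)."""
    ex_times = beats.phase_times("exercise")
    if ex_times.size < 2:
        raise InsufficientDataError("exercise phase missing or too short")
    end_times, rr = _accepted_intervals(beats)
    in_ex = (end_times >= ex_times[0]) & (end_times <= ex_times[-1])
    rr_ex = rr[in_ex]
    if rr_ex.size < 10:
        raise InsufficientDataError(
            f"need 10 accepted exercise RR intervals, have {rr_ex.size}"
        )
    hr = 60000.0 / rr_ex
    kernel = np.ones(10) / 10.0
    rolling = np.convolve(hr, kernel, mode="valid")
    return float(rolling.max())


def resample_uniform(
    tachogram: Tachogram, rate: float = DEFAULT_RESAMPLE_HZ
) -> Tachogram:
    """Cubic-spline resample of a cleaned non-uniform tachogram onto a
    ``rate``-Hz grid spanning the input; endpoints clamped to the nearest
    sample value.  Output length is ``floor(span * rate) + 1``.
    """
    if tachogram.uniform:
        raise ValidationError("input tachogram is already uniform")
    if rate <= 0:
        raise ValidationError("sampling rate must be positive")
    t = tachogram.sample_times
    rr = tachogram.rr_ms
    if t.size < 4:
        raise InsufficientDataError("need >= 4 samples for cubic-spline resampling")
    span = tachogram.span
    if span < 60.0:
        raise InsufficientDataError(f"tachogram spans {span:.1f} s; need >= 60 s")
    n_out = int(np.floor(span * rate)) + 1
    grid = t[0] + np.arange(n_out) / rate
    spline = CubicSpline(t, rr)
    values = spline(np.clip(grid, t[0], t[-1]))
    return Tachogram(
        sample_times=grid, rr_ms=values, uniform=True, sampling_rate=float(rate)
    )
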