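"""Per-subject heart-rate-recovery statistics and exercise-response classification.

Nine recovery statistics per subject: the absolute HR drop from peak at 1, 2
and 3 minutes after exercise cessation, each also normalized to peak HR and to
heart-rate reserve (peak minus resting HR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InsufficientDataError, UndefinedReserveError, ValidationError
from .preprocessing import BeatSeries, peak_hr, resting_hr, ten_beat_hr

RECOVERY_TIMES_S = (60, 120, 180)


@dataclass
class HRRMetrics:
    """Resting/peak HR plus the 3 time points x 3 normalizations recovery grid.

    Missing time points hold ``nan`` and are listed in ``missing``.
    """

    hr_rest: float
    hr_peak: float
    delta_hr: float
    hr_at: dict[int, float]
    hrr_abs: dict[int, float]
    hrr_pct_peak: dict[int, float]
    hrr_pct_reserve: dict[int, float]
    missing: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def absolute_hrr(hr_peak: float, hr_t: float) -> float:
    """Absolute HR reduction ``hr_peak - hr_t`` (beats/min); may be negative."""
    if not (math.isfinite(hr_peak) and math.isfinite(hr_t)):
        raise ValidationError("heart rates must be finite")
    if hr_peak <= 0 or hr_t <= 0:
        raise ValidationError("heart rates must be positive")
    return hr_peak - hr_t


def pct_of_peak(hrr_abs: float, hr_peak: float) -> float:
    """HR reduction as a percentage of peak HR."""
    if hr_peak <= 0:
        raise ValidationError("peak HR must be positive")
    return 100.0 * hrr_abs / hr_peak


def pct_of_reserve(hrr_abs: float, hr_peak: float, hr_rest: float) -> float:
    """HR reduction as a percentage of heart-rate reserve (peak minus rest)."""
    if hr_peak <= hr_rest:
        raise UndefinedReserveError(
            f"reserve undefined: peak HR {hr_peak} <= resting HR {hr_rest}"
        )
    return 100.0 * hrr_abs / (hr_peak - hr_rest)


def classify_abpr(sbp_rest: float, sbp_peak: float) -> str:
    """Exercise blood-pressure response: ``abnormal`` iff the systolic rise is
    strictly below 20 mm Hg (a rise of exactly 20 is ``normal``)."""
    if sbp_rest <= 0 or sbp_peak <= 0:
        raise ValidationError("blood pressures must be positive")
    return "abnormal" if (sbp_peak - sbp_rest) < 20.0 else "normal"


def compute_hrr_profile(beats: BeatSeries) -> HRRMetrics:
    """Full recovery profile from a beat series with all three phases.

    HR at each recovery time point is the 10-beat mean centred on
    ``recovery_onset + t``.  A time point with insufficient data is recorded
    as missing; the others are still populated.
    """
    hr_rest = resting_hr(beats)
    hr_peak_v = peak_hr(beats)
    delta = hr_peak_v - hr_rest
    if delta <= 1e-9:
        raise UndefinedReserveError(
            f"no exercise HR rise (peak {hr_peak_v:.1f} <= rest {hr_rest:.1f})"
        )
    metrics = HRRMetrics(
        hr_rest=hr_rest,
        hr_peak=hr_peak_v,
        delta_hr=delta,
        hr_at={},
        hrr_abs={},
        hrr_pct_peak={},
        hrr_pct_reserve={},
    )
    nan = float("nan")
    for t in RECOVERY_TIMES_S:
        try:
            hr_t, _ = ten_beat_hr(beats, beats.recovery_onset + t)
        except InsufficientDataError:
            metrics.missing.append(t)
            metrics.hr_at[t] = nan
            metrics.hrr_abs[t] = nan
            metrics.hrr_pct_peak[t] = nan
            metrics.hrr_pct_reserve[t] = nan
            continue
        drop = absolute_hrr(hr_peak_v, hr_t)
        if drop < 0:
            metrics.warnings.append(f"HR at {t} s exceeds peak HR (drop {drop:.1f})")
        metrics.hr_at[t] = hr_t
        metrics.hrr_abs[t] = drop
        metrics.hrr_pct_peak[t] = pct_of_peak(drop, hr_peak_v)
        metrics.hrr_pct_reserve[t] = pct_of_reserve(drop, hr_peak_v, hr_rest)
    return metrics
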