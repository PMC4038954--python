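"""Seeded synthetic exercise-test cohorts with realistic HR dynamics.

Each subject's instantaneous heart rate follows a piecewise profile — constant
at rest, a linear ramp to peak during exercise, and a mono-exponential decay
``plateau + (peak - plateau) * exp(-t/tau)`` in recovery.  Sinusoidal LF/HF
modulation and white noise are applied in the RR (ms) domain, inverted to an
instantaneous rate, and beats are emitted by integral pulse frequency
modulation (IPFM): one beat each time the running integral of the rate crosses
an integer.

Subject metadata (demographics, echo measures, blood pressures, exercise
summaries) is drawn from per-group distributions; the shipped defaults encode
published group-level summary statistics for a hypertrophic-cardiomyopathy
exercise cohort and its healthy controls, with the recovery plateau and time
constant calibrated so the group-mean profile passes through the reported
1/2/3-minute recovery heart rates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit

from .errors import GenerationError, ValidationError
from .preprocessing import BeatSeries
from .records import GROUPS, SubjectRecord

_IPFM_DT = 0.01  # s; integration grid for the rate integral


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GroupParams:
    """Per-group sampling distributions; ``(mean, sd)`` pairs throughout."""

    hr_rest: tuple[float, float]
    hr_peak: tuple[float, float]
    hr_plateau: tuple[float, float]
    tau: tuple[float, float]  # s
    male_fraction: float = 0.5
    age: tuple[float, float] = (45.0, 12.0)
    bmi: tuple[float, float] = (26.0, 4.0)
    map_rest: tuple[float, float] = (92.0, 10.0)
    sbp_rest: tuple[float, float] = (122.0, 15.0)
    sbp_peak: tuple[float, float] = (167.0, 28.0)
    peak_vo2: tuple[float, float] = (28.0, 7.0)
    peak_workload: tuple[float, float] = (170.0, 60.0)
    rer: tuple[float, float] = (1.15, 0.05)
    mwt: tuple[float, float] | None = None  # mm; echo fields absent for controls
    la_size: tuple[float, float] | None = None
    ef: tuple[float, float] | None = None
    e_eprime_lateral: tuple[float, float] | None = None
    lvot_log: tuple[float, float] | None = None  # log-normal (log-median, log-sd)
    nyha_probs: tuple[float, ...] = (1.0,)
    p_nsvt: float = 0.0
    p_syncope: float = 0.0
    p_family_history: float = 0.0

    def validate(self) -> None:
        for name in ("hr_rest", "hr_peak", "hr_plateau", "tau"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValidationError(f"{name} SD must be >= 0, got {sd}")
        if self.hr_rest[0] >= self.hr_peak[0]:
            raise ValidationError("hr_rest mean must be below hr_peak mean")
        if self.hr_plateau[0] > self.hr_peak[0]:
            raise ValidationError("hr_plateau mean must be <= hr_peak mean")
        if self.tau[0] <= 0:
            raise ValidationError("tau mean must be > 0")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValidationError("male_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generator settings: group distributions, modulation, seed."""

    groups: dict[str, GroupParams]
    n_per_group: dict[str, int]
    lf_freq: float = 0.10
    hf_freq: float = 0.25
    lf_amp_ms: float = 20.0
    hf_amp_ms: float = 20.0
    noise_sd_ms: float = 5.0
    ectopy_rate: float = 0.0  # ectopic beats per minute
    phase_durations: tuple[float, float, float] = (180.0, 480.0, 240.0)
    seed: int = 0

    def __post_init__(self):
        for label in self.groups:
            if label not in GROUPS:
                raise ValidationError(f"unknown group label {label!r}")
            self.groups[label].validate()
        for label, n in self.n_per_group.items():
            if label not in self.groups:
                raise ValidationError(f"n_per_group references unknown group {label!r}")
            if n < 0:
                raise ValidationError("n_per_group must be >= 0")
        if not 0.04 <= self.lf_freq < 0.15 <= self.hf_freq <= 0.4:
            raise ValidationError(
                "modulation frequencies must satisfy 0.04 <= lf < 0.15 <= hf <= 0.4"
            )
        if self.lf_amp_ms < 0 or self.hf_amp_ms < 0 or self.noise_sd_ms < 0:
            raise ValidationError("modulation amplitudes and noise SD must be >= 0")
        if self.ectopy_rate < 0:
            raise ValidationError("ectopy_rate must be >= 0")
        if any(d <= 0 for d in self.phase_durations):
            raise ValidationError("phase durations must be > 0")
        if self.phase_durations[2] < 180.0:
            raise ValidationError("recovery duration must be >= 180 s")

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.floating):
                return float(obj)
            if isinstance(obj, np.integer):
                return int(obj)
            return obj

        d = dataclasses.asdict(self)
        d["groups"] = {k: dataclasses.asdict(v) for k, v in self.groups.items()}
        return plain(d)


def calibrate_recovery(
    hr_peak: float, hr_targets: dict[float, float]
) -> tuple[float, float]:
    """Least-squares (plateau, tau) so that ``plateau + (peak-plateau)e^{-t/tau}``
    passes through the target recovery heart rates ``{t_seconds: hr}``."""
    t = np.array(sorted(hr_targets), dtype=float)
    hr = np.array([hr_targets[k] for k in sorted(hr_targets)], dtype=float)

    def model(tt, plateau, tau):
        return plateau + (hr_peak - plateau) * np.exp(-tt / tau)

    (plateau, tau), _ = curve_fit(
        model, t, hr, p0=(hr[-1] - 5.0, 70.0), bounds=([20.0, 1.0], [hr_peak, 600.0])
    )
    return float(plateau), float(tau)


def default_config(
    n_per_group: dict[str, int] | int | None = None, seed: int = 0, **overrides
) -> GeneratorConfig:
    """Generator config parameterized from the published group summaries.

    Recovery kinetics per group are calibrated against the reported mean heart
    rates at 1, 2 and 3 minutes of recovery.
    """
    specs = {
        "control": dict(
            hr_rest=(80.5, 14.7),
            hr_peak=(176.8, 18.1),
            targets={60: 141.4, 120: 123.2, 180: 114.7},
            male_fraction=9 / 18,
            age=(39.7, 10.0),
            bmi=(24.1, 3.0),
            map_rest=(90.8, 7.5),
            sbp_rest=(120.3, 10.1),
            sbp_peak=(165.6, 21.4),
            peak_vo2=(35.1, 8.4),
            peak_workload=(206.1, 73.6),
            nyha_probs=(1.0,),
        ),
        "nonobstructive": dict(
            hr_rest=(74.6, 15.8),
            hr_peak=(148.3, 24.4),
            targets={60: 121.9, 120: 110.5, 180: 104.9},
            male_fraction=26 / 28,
            age=(47.5, 13.7),
            bmi=(29.9, 5.4),
            map_rest=(94.3, 12.3),
            sbp_rest=(127.7, 16.1),
            sbp_peak=(171.4, 28.8),
            peak_vo2=(24.2, 6.1),
            peak_workload=(152.3, 50.9),
            mwt=(16.5, 3.0),
            la_size=(44.5, 6.3),
            ef=(66.4, 8.6),
            e_eprime_lateral=(8.0, 3.0),
            lvot_log=(np.log(6.0), 0.45),
            nyha_probs=(17 / 28, 10 / 28, 1 / 28),
            p_nsvt=0.25,
            p_syncope=0.10,
            p_family_history=0.20,
        ),
        "obstructive": dict(
            hr_rest=(81.1, 10.6),
            hr_peak=(153.0, 14.7),
            targets={60: 128.9, 120: 118.5, 180: 116.6},
            male_fraction=11 / 13,
            age=(44.9, 11.8),
            bmi=(28.9, 5.3),
            map_rest=(89.6, 13.4),
            sbp_rest=(118.8, 22.3),
            sbp_peak=(165.4, 33.8),
            peak_vo2=(22.5, 4.4),
            peak_workload=(123.5, 32.5),
            mwt=(18.7, 2.5),
            la_size=(41.8, 5.0),
            ef=(68.2, 5.5),
            e_eprime_lateral=(10.0, 3.5),
            lvot_log=(np.log(78.0), 0.30),
            nyha_probs=(5 / 13, 8 / 13),
            p_nsvt=0.25,
            p_syncope=0.10,
            p_family_history=0.20,
        ),
    }
    default_n = {"control": 18, "nonobstructive": 28, "obstructive": 13}
    if n_per_group is None:
        n_per_group = default_n
    elif isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in specs}
    groups = {}
    for label, spec in specs.items():
        targets = spec.pop("targets")
        plateau, tau = calibrate_recovery(spec["hr_peak"][0], targets)
        groups[label] = GroupParams(
            hr_plateau=(plateau, 8.0), tau=(tau, 15.0), **spec
        )
    return GeneratorConfig(
        groups=groups, n_per_group=dict(n_per_group), seed=seed, **overrides
    )


# ---------------------------------------------------------------------------
# HR profile and IPFM core


@dataclass(frozen=True)
class HRProfile:
    """Piecewise instantaneous HR (beats/min): rest, linear ramp, exponential
    recovery; continuous at the phase boundaries."""

    hr_rest: float
    hr_peak: float
    hr_plateau: float
    tau: float
    rest_s: float
    exercise_s: float
    recovery_s: float

    def __post_init__(self):
        if self.hr_rest >= self.hr_peak:
            raise ValidationError("hr_rest must be below hr_peak")
        if self.hr_plateau > self.hr_peak:
            raise ValidationError("hr_plateau must be <= hr_peak")
        if self.tau <= 0:
            raise ValidationError("tau must be > 0")

    @property
    def recovery_onset(self) -> float:
        return self.rest_s + self.exercise_s

    @property
    def total_s(self) -> float:
        return self.rest_s + self.exercise_s + self.recovery_s

    def hr(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.empty_like(t)
        rest_end = self.rest_s
        ex_end = self.recovery_onset
        in_rest = t < rest_end
        in_ex = (t >= rest_end) & (t < ex_end)
        in_rec = t >= ex_end
        out[in_rest] = self.hr_rest
        frac = (t[in_ex] - rest_end) / self.exercise_s
        out[in_ex] = self.hr_rest + frac * (self.hr_peak - self.hr_rest)
        trec = t[in_rec] - ex_end
        out[in_rec] = self.hr_plateau + (self.hr_peak - self.hr_plateau) * np.exp(
            -trec / self.tau
        )
        return out


def ipfm_beat_times(
    times: np.ndarray, rate_beats_per_s: np.ndarray
) -> np.ndarray:
    """Emit a beat each time the running integral of the rate crosses an
    integer; crossings located by linear interpolation of the integral."""
    rate = np.asarray(rate_beats_per_s, dtype=float)
    if not np.all(np.isfinite(rate)) or np.any(rate <= 0):
        raise GenerationError("instantaneous rate must be finite and positive")
    integral = cumulative_trapezoid(rate, times, initial=0.0)
    n_beats = int(np.floor(integral[-1]))
    if n_beats < 1:
        raise GenerationError("rate integral never reaches 1; no beats emitted")
    targets = np.arange(1, n_beats + 1, dtype=float)
    return np.interp(targets, integral, times)


def _modulated_rate(
    profile: HRProfile, config: GeneratorConfig, phases_lf_hf: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Time grid and instantaneous rate (beats/s) with RR-domain modulation."""
    t = np.arange(0.0, profile.total_s + _IPFM_DT, _IPFM_DT)
    hr = profile.hr(t)
    if np.any(hr <= 20.0) or np.any(hr >= 250.0):
        raise GenerationError(
            f"HR profile leaves (20, 250) beats/min (range {hr.min():.1f}-{hr.max():.1f}); "
            "check hr_rest/hr_peak/hr_plateau"
        )
    rr_ms = 60000.0 / hr
    phi_lf, phi_hf = phases_lf_hf
    rr_ms = (
        rr_ms
        + config.lf_amp_ms * np.sin(2 * np.pi * config.lf_freq * t + phi_lf)
        + config.hf_amp_ms * np.sin(2 * np.pi * config.hf_freq * t + phi_hf)
    )
    hr_inst = 60000.0 / rr_ms
    if np.any(~np.isfinite(hr_inst)) or np.any(hr_inst <= 20.0) or np.any(hr_inst >= 250.0):
        raise GenerationError(
            "modulated HR leaves (20, 250) beats/min; reduce lf_amp_ms/hf_amp_ms"
        )
    return t, 1000.0 / rr_ms  # beats per second


def _label_phases(beat_times: np.ndarray, profile: HRProfile) -> np.ndarray:
    labels = np.empty(beat_times.size, dtype=object)
    labels[:] = "recovery"
    labels[beat_times < profile.recovery_onset] = "exercise"
    labels[beat_times < profile.rest_s] = "rest"
    return labels


def _truncated_normal(rng, mean, sd, lo=-np.inf, hi=np.inf, max_tries=200):
    if sd == 0:
        value = mean
        if not lo <= value <= hi:
            raise GenerationError(f"degenerate draw {value} outside [{lo}, {hi}]")
        return float(value)
    for _ in range(max_tries):
        value = rng.normal(mean, sd)
        if lo <= value <= hi:
            return float(value)
    raise GenerationError(
        f"could not draw N({mean}, {sd}) within [{lo}, {hi}] in {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# public generators


def generate_subject(
    config: GeneratorConfig, group: str, subject_seed: int, subject_id: str | None = None
) -> SubjectRecord:
    """One synthetic subject: IPFM beat series plus metadata draws.

    Deterministic for a fixed ``(config, group, subject_seed)``.
    """
    if group not in config.groups:
        raise ValidationError(f"group {group!r} not in config")
    params = config.groups[group]
    rng = np.random.default_rng(subject_seed)

    # HR kinetics; redraw until ordering constraints hold
    for _ in range(200):
        hr_rest = rng.normal(*params.hr_rest)
        hr_peak = rng.normal(*params.hr_peak)
        hr_plateau = rng.normal(*params.hr_plateau)
        tau = rng.normal(*params.tau)
        # peak capped at 210 so default RR-domain modulation cannot push the
        # instantaneous HR past the 250 beats/min generator bound
        if (
            40.0 < hr_rest < hr_peak - 20.0
            and hr_peak < 210.0
            and hr_rest - 20.0 < hr_plateau < hr_peak - 10.0
            and hr_plateau > 40.0
            and tau > 10.0
        ):
            break
    else:
        raise GenerationError(
            f"could not draw consistent HR kinetics for group {group!r}"
        )

    rest_s, exercise_s, recovery_s = config.phase_durations
    profile = HRProfile(
        hr_rest=hr_rest,
        hr_peak=hr_peak,
        hr_plateau=hr_plateau,
        tau=tau,
        rest_s=rest_s,
        exercise_s=exercise_s,
        recovery_s=recovery_s,
    )
    phases_lf_hf = (rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi))
    t_grid, rate = _modulated_rate(profile, config, phases_lf_hf)
    beat_times = ipfm_beat_times(t_grid, rate)

    if config.noise_sd_ms > 0 and beat_times.size >= 2:
        rr = np.diff(beat_times)
        rr = rr + rng.normal(0.0, config.noise_sd_ms / 1000.0, size=rr.size)
        if np.any(rr <= 0):
            raise GenerationError("noise_sd_ms too large: non-positive RR produced")
        beat_times = np.concatenate(([beat_times[0]], beat_times[0] + np.cumsum(rr)))

    beats = BeatSeries(
        beat_times=beat_times,
        phases=_label_phases(beat_times, profile),
        recovery_onset=profile.recovery_onset,
    )
    if config.ectopy_rate > 0:
        beats = inject_ectopy(
            beats, config.ectopy_rate, int(rng.integers(0, 2**31))
        ).beats

    sex = "male" if rng.random() < params.male_fraction else "female"
    nyha_probs = np.asarray(params.nyha_probs, dtype=float)
    nyha = int(rng.choice(np.arange(1, nyha_probs.size + 1), p=nyha_probs / nyha_probs.sum()))
    mwt = _truncated_normal(rng, *params.mwt, lo=15.0) if params.mwt else np.nan
    record = SubjectRecord(
        subject_id=subject_id or f"{group[:3]}-{subject_seed & 0xFFFFFFFF:08x}",
        group=group,
        sex=sex,
        age=_truncated_normal(rng, *params.age, lo=18.0, hi=90.0),
        bmi=_truncated_normal(rng, *params.bmi, lo=15.0, hi=55.0),
        map_rest=_truncated_normal(rng, *params.map_rest, lo=50.0),
        sbp_rest=_truncated_normal(rng, *params.sbp_rest, lo=80.0),
        sbp_peak=_truncated_normal(rng, *params.sbp_peak, lo=90.0),
        nyha=nyha,
        nsvt=bool(rng.random() < params.p_nsvt),
        syncope=bool(rng.random() < params.p_syncope),
        family_history_scd=bool(rng.random() < params.p_family_history),
        mwt=mwt,
        mwt_ge_30=bool(np.isfinite(mwt) and mwt >= 30.0),
        la_size=_truncated_normal(rng, *params.la_size, lo=20.0) if params.la_size else np.nan,
        ef=_truncated_normal(rng, *params.ef, lo=20.0, hi=85.0) if params.ef else np.nan,
        e_eprime_lateral=(
            _truncated_normal(rng, *params.e_eprime_lateral, lo=2.0)
            if params.e_eprime_lateral
            else np.nan
        ),
        lvot_gradient_peak=(
            float(rng.lognormal(*params.lvot_log)) if params.lvot_log else np.nan
        ),
        peak_vo2=_truncated_normal(rng, *params.peak_vo2, lo=8.0),
        peak_workload=_truncated_normal(rng, *params.peak_workload, lo=30.0),
        rer=_truncated_normal(rng, *params.rer, lo=1.05),
        beats=beats,
        kinetics={
            "hr_rest": hr_rest,
            "hr_peak": hr_peak,
            "hr_plateau": hr_plateau,
            "tau": tau,
        },
    )
    return record


def generate_cohort(config: GeneratorConfig) -> list[SubjectRecord]:
    """Deterministic cohort: per-subject seeds spawned from the master seed."""
    ss = np.random.SeedSequence(config.seed)
    labels = [g for g in GROUPS if config.n_per_group.get(g, 0) > 0]
    total = sum(config.n_per_group.get(g, 0) for g in labels)
    children = ss.spawn(total)
    subjects = []
    i = 0
    for group in labels:
        for j in range(config.n_per_group[group]):
            seed = int(children[i].generate_state(1)[0])
            i += 1
            try:
                subjects.append(
                    generate_subject(
                        config, group, seed, subject_id=f"{group[:3]}-{j:03d}"
                    )
                )
            except GenerationError as exc:
                raise GenerationError(
                    f"subject {j} of group {group!r}: {exc}"
                ) from exc
    return subjects


@dataclass(frozen=True)
class EctopyResult:
    beats: BeatSeries
    n_injected: int
    indices: tuple[int, ...]


def inject_ectopy(beats: BeatSeries, rate: float, seed: int) -> EctopyResult:
    """Displace randomly chosen beats early (coupling interval 40-60% of the
    local RR), leaving the following beat in place as a compensatory pause.

    ``rate`` is ectopic events per minute; the number of events is Poisson.
    """
    if rate < 0:
        raise ValidationError("ectopy rate must be >= 0")
    if rate == 0 or len(beats) < 4:
        return EctopyResult(beats=beats, n_injected=0, indices=())
    rng = np.random.default_rng(seed)
    duration_min = (beats.beat_times[-1] - beats.beat_times[0]) / 60.0
    n_events = int(rng.poisson(rate * duration_min))
    candidates = np.arange(2, len(beats) - 1)
    n_events = min(n_events, candidates.size)
    if n_events == 0:
        return EctopyResult(beats=beats, n_injected=0, indices=())
    chosen = np.sort(rng.choice(candidates, size=n_events, replace=False))
    times = beats.beat_times.copy()
    applied = []
    for i in chosen:
        local_rr = times[i] - times[i - 1]
        new_t = times[i - 1] + rng.uniform(0.40, 0.60) * local_rr
        if times[i - 1] < new_t < times[i + 1]:
            times[i] = new_t
            applied.append(int(i))
    out = BeatSeries(
        beat_times=times, phases=beats.phases.copy(), recovery_onset=beats.recovery_onset
    )
    return EctopyResult(beats=out, n_injected=len(applied), indices=tuple(applied))
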