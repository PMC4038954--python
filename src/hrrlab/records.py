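"""Cohort row type shared by the generator, the metrics layer and statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .hrr import HRRMetrics
from .preprocessing import BeatSeries
from .spectral import BandPowers

GROUPS = ("control", "nonobstructive", "obstructive")
PATIENT_GROUPS = ("nonobstructive", "obstructive")

#: scalar columns written to / read from the metadata CSV
METADATA_COLUMNS = [
    "subject_id",
    "group",
    "sex",
    "age",
    "bmi",
    "map_rest",
    "sbp_rest",
    "sbp_peak",
    "nyha",
    "nsvt",
    "syncope",
    "mwt_ge_30",
    "family_history_scd",
    "mwt",
    "la_size",
    "ef",
    "lvot_gradient_peak",
    "e_eprime_lateral",
    "peak_vo2",
    "peak_workload",
    "rer",
]


@dataclass
class SubjectRecord:
    """One cohort row: demographics, clinical profile, exercise summaries and
    (optionally) the beat series plus derived metrics."""

    subject_id: str
    group: str
    sex: str = "male"
    age: float = np.nan
    bmi: float = np.nan
    map_rest: float = np.nan
    sbp_rest: float = np.nan
    sbp_peak: float = np.nan
    nyha: int = 1
    nsvt: bool = False
    syncope: bool = False
    mwt_ge_30: bool = False
    family_history_scd: bool = False
    mwt: float = np.nan
    la_size: float = np.nan
    ef: float = np.nan
    lvot_gradient_peak: float = np.nan
    e_eprime_lateral: float = np.nan
    peak_vo2: float = np.nan
    peak_workload: float = np.nan
    rer: float = np.nan
    beats: BeatSeries | None = None
    hrr: HRRMetrics | None = None
    bands: dict[str, BandPowers] = field(default_factory=dict)
    #: generator ground truth (drawn HR kinetics); None for real recordings
    kinetics: dict | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}; expected {GROUPS}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")

    @property
    def is_patient(self) -> bool:
        return self.group in PATIENT_GROUPS

    @property
    def risk_factor_count(self) -> int:
        abpr = False
        if np.isfinite(self.sbp_rest) and np.isfinite(self.sbp_peak):
            abpr = (self.sbp_peak - self.sbp_rest) < 20.0
        return int(self.nsvt) + int(self.syncope) + int(self.mwt_ge_30) + int(
            self.family_history_scd
        ) + int(abpr)

    def metadata_row(self) -> dict:
        return {col: getattr(self, col) for col in METADATA_COLUMNS}


def cohort_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten a cohort into one analysis row per subject.

    HRR metrics appear as ``hr_at_60`` / ``hrr_abs_60`` / ``hrr_pct_peak_60``
    / ``hrr_pct_reserve_60`` etc.; band powers as ``lf_nu_welch`` etc.
    """
    rows = []
    for s in subjects:
        row = s.metadata_row()
        row["is_patient"] = s.is_patient
        row["risk_factor_count"] = s.risk_factor_count
        if s.hrr is not None:
            row["hr_rest"] = s.hrr.hr_rest
            row["hr_peak"] = s.hrr.hr_peak
            row["delta_hr"] = s.hrr.delta_hr
            for t in (60, 120, 180):
                row[f"hr_at_{t}"] = s.hrr.hr_at.get(t, np.nan)
                row[f"hrr_abs_{t}"] = s.hrr.hrr_abs.get(t, np.nan)
                row[f"hrr_pct_peak_{t}"] = s.hrr.hrr_pct_peak.get(t, np.nan)
                row[f"hrr_pct_reserve_{t}"] = s.hrr.hrr_pct_reserve.get(t, np.nan)
        for method, bp in s.bands.items():
            row[f"lf_nu_{method}"] = bp.lf_nu
            row[f"hf_nu_{method}"] = bp.hf_nu
            row[f"lf_hf_ratio_{method}"] = (
                bp.lf_hf_ratio if bp.lf_hf_ratio is not None else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
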