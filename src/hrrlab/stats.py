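"""Cohort-level statistics: group comparisons, frequency tests and the two
backward-elimination regression models.

Comparisons follow a normality gate: normally distributed variables are
summarized as mean +/- SD and compared with pooled-variance t tests or one-way
ANOVA with Bonferroni-adjusted pairwise post hocs; non-normal variables use
median [IQR] and rank tests (Mann-Whitney U / Kruskal-Wallis).

Model 1 pools patients and controls and backward-eliminates from {disease
indicator, sex, age, peak HR, BMI, peak VO2} against recovery HR at each time
point.  Model 2, in patients only, screens five disease-severity surrogates
univariably and refits the screen-passing ones together with the Model-1
retained covariates (forced, never eliminated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import InsufficientDataError, RankDeficiencyError, ValidationError

DEFAULT_ALPHA = 0.05
MODEL1_RESPONSES = ("hr_at_60", "hr_at_120", "hr_at_180")
MODEL1_COVARIATES = ("is_patient", "male", "age", "hr_peak", "bmi", "peak_vo2")
MODEL2_SURROGATES = ("e_eprime_lateral", "la_size", "ef", "mwt", "lvot_gradient_peak")


@dataclass
class ComparisonResult:
    """Outcome of one between-group comparison."""

    name: str
    test: str
    statistic: float
    p_value: float
    df: float | None = None
    estimates: dict = field(default_factory=dict)
    pairwise: dict = field(default_factory=dict)  # pair -> Bonferroni-adjusted p
    degenerate: bool = False


@dataclass
class RegressionModel:
    """Fitted linear model: per-covariate B, 95% CI and p, plus the
    backward-elimination trace when applicable."""

    response: str
    coefficients: dict[str, dict]  # name -> {b, ci_low, ci_high, p}
    n: int
    retained: list[str] = field(default_factory=list)
    eliminated: list[str] = field(default_factory=list)  # in removal order
    r_squared: float = float("nan")


@dataclass
class Model2Report:
    response: str
    stage1: dict[str, RegressionModel]  # univariable screen per surrogate
    screen_passed: list[str]
    stage2: RegressionModel | None


# ---------------------------------------------------------------------------
# elementary tests


def normality_gate(values, alpha: float = DEFAULT_ALPHA) -> str:
    """Shapiro-Wilk gate deciding summary style and test family."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise InsufficientDataError(f"normality gate needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        return "non-normal"  # degenerate constant vector
    _, p = sps.shapiro(x)
    return "normal" if p >= alpha else "non-normal"


def t_test_independent(a, b, equal_var: bool = True) -> ComparisonResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("t test needs n >= 2 per group")
    degenerate = np.ptp(a) == 0 and np.ptp(b) == 0
    if degenerate and a[0] == b[0]:
        return ComparisonResult(
            name="t_test",
            test="t",
            statistic=0.0,
            p_value=1.0,
            df=a.size + b.size - 2,
            degenerate=True,
        )
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else float(res.df)
    return ComparisonResult(
        name="t_test",
        test="t" if equal_var else "welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=df,
        estimates={
            "mean_a": float(a.mean()),
            "sd_a": float(a.std(ddof=1)),
            "mean_b": float(b.mean()),
            "sd_b": float(b.std(ddof=1)),
        },
        degenerate=bool(not np.isfinite(res.pvalue)),
    )


def anova_bonferroni(groups: dict[str, np.ndarray]) -> ComparisonResult:
    """One-way ANOVA with all pairwise pooled t tests, Bonferroni-adjusted
    (multiplier = number of pairs, capped at 1)."""
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise InsufficientDataError("ANOVA needs n >= 2 per group")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        result = ComparisonResult(
            name="anova", test="anova", statistic=0.0, p_value=1.0, degenerate=True
        )
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                result.pairwise[(labels[i], labels[j])] = 1.0
        return result
    f, p = sps.f_oneway(*arrays)
    result = ComparisonResult(
        name="anova",
        test="anova",
        statistic=float(f),
        p_value=float(p),
        estimates={
            g: {"mean": float(a.mean()), "sd": float(a.std(ddof=1))}
            for g, a in zip(labels, arrays)
        },
    )
    pairs = [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    k = len(pairs)
    for ga, gb in pairs:
        sub = t_test_independent(groups[ga], groups[gb])
        result.pairwise[(ga, gb)] = min(1.0, k * sub.p_value)
    return result


def fisher_exact(table) -> ComparisonResult:
    """Two-sided Fisher's exact test on a 2x2 count table (hypergeometric
    probabilities at most that of the observed table are summed)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("Fisher's exact test requires a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValidationError("counts must be nonnegative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("empty row or column margin")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return ComparisonResult(
        name="fisher_exact",
        test="fisher",
        statistic=float(odds),
        p_value=float(p),
        estimates={"table": t.tolist()},
    )


def rank_tests(*groups) -> ComparisonResult:
    """Mann-Whitney U for two groups (exact when both n <= 20 and tie-free,
    normal approximation with tie correction otherwise) or Kruskal-Wallis for
    three."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) not in (2, 3):
        raise ValidationError("rank_tests takes 2 or 3 groups")
    if any(a.size < 2 for a in arrays):
        raise InsufficientDataError("rank tests need n >= 2 per group")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return ComparisonResult(
            name="rank", test="rank", statistic=0.0, p_value=1.0, degenerate=True
        )
    estimates = {
        i: {
            "median": float(np.median(a)),
            "iqr": (float(np.percentile(a, 25)), float(np.percentile(a, 75))),
        }
        for i, a in enumerate(arrays)
    }
    if len(arrays) == 2:
        a, b = arrays
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return ComparisonResult(
            name="mann_whitney",
            test=f"mann_whitney_{method}",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            estimates=estimates,
        )
    stat, p = sps.kruskal(*arrays)
    return ComparisonResult(
        name="kruskal_wallis",
        test="kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
        estimates=estimates,
    )


# ---------------------------------------------------------------------------
# regression


def _design_matrix(X: pd.DataFrame) -> pd.DataFrame:
    Xd = X.astype(float)
    return sm.add_constant(Xd, has_constant="add")


def _collinear_columns(Xd: pd.DataFrame) -> list[str]:
    """Columns implicated in a rank deficiency (smallest singular directions)."""
    arr = Xd.to_numpy()
    _, s, vt = np.linalg.svd(arr, full_matrices=False)
    tol = s.max() * max(arr.shape) * np.finfo(float).eps
    bad = []
    for row in vt[s < tol]:
        for j in np.nonzero(np.abs(row) > 1e-8)[0]:
            name = Xd.columns[j]
            if name != "const" and name not in bad:
                bad.append(name)
    return bad


def linear_regression(y, X: pd.DataFrame, response: str = "y") -> RegressionModel:
    """OLS with intercept; 95% CIs and two-sided p from the t distribution."""
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValidationError("y and X have different lengths")
    if y.size <= X.shape[1] + 1:
        raise InsufficientDataError(
            f"need n > p + 1 (n={y.size}, p={X.shape[1]})"
        )
    Xd = _design_matrix(X)
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise RankDeficiencyError(_collinear_columns(Xd))
    fit = sm.OLS(y, Xd).fit()
    ci = fit.conf_int(alpha=0.05)
    coefficients = {}
    for name in Xd.columns:
        coefficients[name] = {
            "b": float(fit.params[name]),
            "ci_low": float(ci.loc[name, 0]),
            "ci_high": float(ci.loc[name, 1]),
            "p": float(fit.pvalues[name]),
        }
    return RegressionModel(
        response=response,
        coefficients=coefficients,
        n=int(y.size),
        retained=[c for c in X.columns],
        r_squared=float(fit.rsquared),
    )


def backward_eliminate(
    y,
    X: pd.DataFrame,
    forced: tuple[str, ...] = (),
    threshold: float = DEFAULT_ALPHA,
    response: str = "y",
) -> RegressionModel:
    """Iteratively drop the non-forced covariate with the largest p-value
    >= ``threshold`` until every retained non-forced covariate is below it.

    An intercept-only final model is allowed.
    """
    missing = [c for c in forced if c not in X.columns]
    if missing:
        raise ValidationError(f"forced covariates not in design: {missing}")
    current = list(X.columns)
    trace: list[str] = []
    model = None
    while True:
        if current:
            model = linear_regression(y, X[current], response=response)
            candidates = {
                c: model.coefficients[c]["p"] for c in current if c not in forced
            }
            if not candidates:
                break
            worst, worst_p = max(candidates.items(), key=lambda kv: kv[1])
            if worst_p < threshold:
                break
            current.remove(worst)
            trace.append(worst)
        else:
            # intercept-only
            Xd = sm.add_constant(pd.DataFrame(index=range(len(y))), has_constant="add")
            fit = sm.OLS(np.asarray(y, dtype=float), Xd).fit()
            ci = fit.conf_int(alpha=0.05)
            model = RegressionModel(
                response=response,
                coefficients={
                    "const": {
                        "b": float(fit.params["const"]),
                        "ci_low": float(ci.loc["const", 0]),
                        "ci_high": float(ci.loc["const", 1]),
                        "p": float(fit.pvalues["const"]),
                    }
                },
                n=int(len(y)),
            )
            break
    model.retained = current
    model.eliminated = trace
    return model


def _prepare(frame: pd.DataFrame, response: str, covariates) -> tuple[np.ndarray, pd.DataFrame]:
    """Listwise-complete response and design columns; adds ``male`` indicator."""
    work = frame.copy()
    if "male" not in work.columns and "sex" in work.columns:
        work["male"] = (work["sex"] == "male").astype(float)
    if "is_patient" in covariates and "is_patient" in work.columns:
        work["is_patient"] = work["is_patient"].astype(float)
    cols = [response, *covariates]
    missing = [c for c in cols if c not in work.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    sub = work[cols].apply(pd.to_numeric, errors="coerce").dropna()
    return sub[response].to_numpy(), sub[list(covariates)]


def run_model1(
    frame: pd.DataFrame,
    threshold: float = DEFAULT_ALPHA,
    responses=MODEL1_RESPONSES,
) -> dict[str, RegressionModel]:
    """Pooled-cohort backward elimination per recovery time point."""
    results = {}
    for response in responses:
        y, X = _prepare(frame, response, list(MODEL1_COVARIATES))
        if X["is_patient"].nunique() < 2:
            raise RankDeficiencyError(
                ["is_patient"],
                "single-group cohort: disease indicator is constant",
            )
        results[response] = backward_eliminate(
            y, X, threshold=threshold, response=response
        )
    return results


def run_model2(
    patients: pd.DataFrame,
    model1: dict[str, RegressionModel] | None = None,
    threshold: float = DEFAULT_ALPHA,
    responses=MODEL1_RESPONSES,
) -> dict[str, Model2Report]:
    """Patient-only two-stage analysis.

    Stage 1 screens each disease-severity surrogate univariably; stage 2 fits
    the screen-passing surrogates together with the Model-1 retained
    covariates for that response (forced into the model, disease indicator
    excluded since it is constant in patients).
    """
    if (patients.get("is_patient") is not None) and (~patients["is_patient"].astype(bool)).any():
        raise ValidationError("run_model2 expects a patient-only cohort")
    reports = {}
    for response in responses:
        stage1 = {}
        passed = []
        for surrogate in MODEL2_SURROGATES:
            if surrogate not in patients.columns:
                continue
            y, X = _prepare(patients, response, [surrogate])
            if X[surrogate].nunique() < 2 or len(y) <= 2:
                continue
            model = linear_regression(y, X, response=response)
            stage1[surrogate] = model
            if model.coefficients[surrogate]["p"] < threshold:
                passed.append(surrogate)
        forced = []
        if model1 and response in model1:
            forced = [
                c
                for c in model1[response].retained
                if c not in ("is_patient",) and c not in passed
            ]
        stage2 = None
        covs = passed + forced
        if covs:
            y, X = _prepare(patients, response, covs)
            stage2 = backward_eliminate(
                y, X, forced=tuple(forced), threshold=threshold, response=response
            )
        reports[response] = Model2Report(
            response=response, stage1=stage1, screen_passed=passed, stage2=stage2
        )
    return reports


# ---------------------------------------------------------------------------
# summary table


#: variable -> column, in display order
SUMMARY_VARIABLES = [
    ("Age (yrs)", "age"),
    ("Body mass index (kg/m^2)", "bmi"),
    ("Mean arterial blood pressure at rest (mm Hg)", "map_rest"),
    ("Systolic blood pressure at rest (mm Hg)", "sbp_rest"),
    ("Systolic blood pressure at peak (mm Hg)", "sbp_peak"),
    ("Resting heart rate (beats/min)", "hr_rest"),
    ("Peak heart rate (beats/min)", "hr_peak"),
    ("Change in heart rate (beats/min)", "delta_hr"),
    ("Maximal oxygen consumption (ml/kg/min)", "peak_vo2"),
    ("Peak workload achieved (W)", "peak_workload"),
    ("Maximal wall thickness (mm)", "mwt"),
    ("Ejection fraction (%)", "ef"),
    ("Left atrial size (mm)", "la_size"),
    ("Mean heart rate at 1 minute (beats/min)", "hr_at_60"),
    ("Mean heart rate reduction at 1 minute (beats/min)", "hrr_abs_60"),
    ("Reduction of peak heart rate at 1 minute (%)", "hrr_pct_peak_60"),
    ("Reduction of heart rate reserve at 1 minute (%)", "hrr_pct_reserve_60"),
    ("Mean heart rate at 2 minutes (beats/min)", "hr_at_120"),
    ("Mean heart rate reduction at 2 minutes (beats/min)", "hrr_abs_120"),
    ("Reduction of peak heart rate at 2 minutes (%)", "hrr_pct_peak_120"),
    ("Reduction of heart rate reserve at 2 minutes (%)", "hrr_pct_reserve_120"),
    ("Mean heart rate at 3 minutes (beats/min)", "hr_at_180"),
    ("Mean heart rate reduction at 3 minutes (beats/min)", "hrr_abs_180"),
    ("Reduction of peak heart rate at 3 minutes (%)", "hrr_pct_peak_180"),
    ("Reduction of heart rate reserve at 3 minutes (%)", "hrr_pct_reserve_180"),
    ("Normalized low frequency spectral power (n.u)", "lf_nu_welch"),
    ("Normalized high frequency spectral power (n.u)", "hf_nu_welch"),
    ("Low:high frequency ratio", "lf_hf_ratio_welch"),
]


def _summary_cell(values: np.ndarray, style: str) -> str:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return ""
    if style == "normal":
        return f"{values.mean():.1f} ± {values.std(ddof=1):.1f}"
    lo, hi = np.percentile(values, [25, 75])
    return f"{np.median(values):.2f} [{lo:.2f}–{hi:.2f}]"


def table1_summary(frame: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Group-summary table (control / all patients / nonobstructive /
    obstructive) with a between-group test per row.

    Rows are mean +/- SD with t/ANOVA when every group passes the normality
    gate, otherwise median [IQR] with rank tests.
    """
    groups = {
        "control": frame[frame["group"] == "control"],
        "all_patients": frame[frame["group"] != "control"],
        "nonobstructive": frame[frame["group"] == "nonobstructive"],
        "obstructive": frame[frame["group"] == "obstructive"],
    }
    rows = []
    # sex frequency row via Fisher's exact (control vs all patients)
    if "sex" in frame.columns:
        counts = {
            g: (
                int((sub["sex"] == "male").sum()),
                int((sub["sex"] == "female").sum()),
            )
            for g, sub in groups.items()
        }
        row = {"variable": "Men", "test": "fisher", "p_value": np.nan}
        for g, (m, f) in counts.items():
            row[g] = f"{m}/{m + f}"
        table = [list(counts["control"]), list(counts["all_patients"])]
        try:
            row["p_value"] = fisher_exact(table).p_value
        except ValidationError:
            pass
        rows.append(row)

    for label, column in SUMMARY_VARIABLES:
        if column not in frame.columns:
            continue
        samples = {
            g: pd.to_numeric(sub[column], errors="coerce").dropna().to_numpy()
            for g, sub in groups.items()
        }
        present = {g: v for g, v in samples.items() if v.size >= 3}
        if not present:
            continue
        try:
            styles = {g: normality_gate(v, alpha) for g, v in present.items()}
            style = "normal" if all(s == "normal" for s in styles.values()) else "non-normal"
        except InsufficientDataError:
            style = "non-normal"
        row = {"variable": label, "test": "", "p_value": np.nan}
        for g, v in samples.items():
            row[g] = _summary_cell(v, style)
        comparable = [
            samples[g]
            for g in ("control", "nonobstructive", "obstructive")
            if samples.get(g) is not None and samples[g].size >= 2
        ]
        try:
            if len(comparable) == 3:
                if style == "normal":
                    res = anova_bonferroni(
                        {
                            "control": samples["control"],
                            "nonobstructive": samples["nonobstructive"],
                            "obstructive": samples["obstructive"],
                        }
                    )
                else:
                    res = rank_tests(*comparable)
            elif len(comparable) == 2:
                res = (
                    t_test_independent(*comparable)
                    if style == "normal"
                    else rank_tests(*comparable)
                )
            else:
                res = None
            if res is not None:
                row["test"] = res.test
                row["p_value"] = res.p_value
        except (InsufficientDataError, ValidationError):
            pass
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "variable",
            "control",
            "all_patients",
            "nonobstructive",
            "obstructive",
            "test",
            "p_value",
        ],
    )
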