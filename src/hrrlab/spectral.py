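"""RR-interval power spectra by three estimators, reduced to band powers.

Estimators: Welch-averaged periodogram and an autoregressive spectrum (via the
Levinson-Durbin recursion) on evenly resampled tachograms, and the classical
Lomb-Scargle periodogram on the raw unevenly sampled RR series.  All three are
rescaled so the one-sided PSD integrates to the detrended series variance,
which makes band powers directly comparable across methods.

Band edges follow the standard HRV convention: VLF [0.0033, 0.04) Hz,
LF [0.04, 0.15) Hz, HF [0.15, 0.4] Hz.  Normalized units divide LF and HF by
total power minus VLF, so ``lf_nu + hf_nu == 1`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import InsufficientDataError, ValidationError
from .preprocessing import (
    BeatSeries,
    Tachogram,
    filter_artifacts,
    resample_uniform,
    rr_from_beats,
)

VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

DEFAULT_AR_ORDER = 16
WELCH_SEGMENT_S = 60.0
METHODS = ("welch", "ar", "lomb_scargle")


@dataclass(frozen=True)
class SpectralResult:
    """One-sided PSD (ms^2/Hz) on a nonnegative increasing frequency grid."""

    frequencies: np.ndarray
    psd: np.ndarray
    method: str
    params: dict

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.psd, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise ValidationError("frequencies and psd must be 1-d and equal length")
        if f.size and (np.any(np.diff(f) <= 0) or f[0] < 0):
            raise ValidationError("frequency grid must be nonnegative and increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "psd", p)


@dataclass(frozen=True)
class BandPowers:
    """Integrated band powers (ms^2), normalized units and LF:HF ratio.

    ``lf_hf_ratio`` is ``None`` when HF power is zero (never infinity).
    """

    vlf: float
    lf: float
    hf: float
    total: float
    lf_nu: float
    hf_nu: float
    lf_hf_ratio: float | None


def _detrend(values: np.ndarray) -> np.ndarray:
    """Remove mean and linear trend (least squares)."""
    return signal.detrend(np.asarray(values, dtype=float), type="linear")


def _rescale_to_variance(freqs, psd, variance):
    """Scale a one-sided PSD so its trapezoidal integral equals ``variance``."""
    integral = np.trapezoid(psd, freqs)
    if integral <= 0:
        return psd
    return psd * (variance / integral)


def welch_psd(series: Tachogram, segment_s: float = WELCH_SEGMENT_S) -> SpectralResult:
    """Welch PSD: detrended, Hann-windowed segments with 50% overlap,
    scaled so the PSD integral equals the detrended-series variance."""
    if not series.uniform or series.sampling_rate is None:
        raise ValidationError("welch_psd requires a uniform tachogram")
    fs = series.sampling_rate
    if series.span < 120.0:
        raise InsufficientDataError(f"series spans {series.span:.0f} s; need >= 120 s")
    x = _detrend(series.rr_ms)
    nperseg = int(round(segment_s * fs))
    if x.size < nperseg:
        raise InsufficientDataError("series shorter than one Welch segment")
    freqs, psd = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
        scaling="density",
    )
    psd = _rescale_to_variance(freqs, psd, float(np.var(x)))
    return SpectralResult(
        frequencies=freqs,
        psd=psd,
        method="welch",
        params={"fs": fs, "segment_s": segment_s, "window": "hann", "overlap": 0.5},
    )


def levinson_durbin(acf: np.ndarray, order: int):
    """Solve the Yule-Walker equations by the Levinson-Durbin recursion.

    Parameters
    ----------
    acf:
        Autocorrelation sequence, lags 0..m with ``acf[0] > 0``.
    order:
        AR model order p, with ``p < len(acf)``.

    Returns
    -------
    (a, k, sigma2):
        AR coefficients ``a[0..p-1]`` (prediction form
        ``x_t = sum a_j x_{t-j} + e_t``), reflection coefficients, and the
        innovation variance, which is non-increasing in order.
    """
    r = np.asarray(acf, dtype=float)
    if r.ndim != 1 or r.size < 1 or r[0] <= 0:
        raise ValidationError("acf must be 1-d with acf[0] > 0")
    if order < 0 or order >= r.size:
        raise ValidationError(f"order must satisfy 0 <= order < len(acf)={r.size}")
    a = np.zeros(order)
    k = np.zeros(order)
    sigma2 = float(r[0])
    for m in range(order):
        num = r[m + 1] - np.dot(a[:m], r[m:0:-1])
        if sigma2 <= 0:
            raise ValidationError(
                f"non-positive-definite acf: innovation variance {sigma2:.3g} at order {m}"
            )
        km = num / sigma2
        k[m] = km
        a_new = a.copy()
        a_new[m] = km
        a_new[:m] = a[:m] - km * a[m - 1 :: -1][:m]
        a = a_new
        sigma2 *= 1.0 - km * km
    if sigma2 < 0:
        raise ValidationError("non-positive-definite acf: negative residual variance")
    return a, k, sigma2


def _biased_acf(x: np.ndarray, maxlag: int) -> np.ndarray:
    n = x.size
    acf = np.array([np.dot(x[: n - lag], x[lag:]) for lag in range(maxlag + 1)])
    return acf / n


def ar_psd(
    series: Tachogram, order: int = DEFAULT_AR_ORDER, n_freqs: int = 1024
) -> SpectralResult:
    """Autoregressive PSD from Yule-Walker coefficients, Parseval-rescaled."""
    if not series.uniform or series.sampling_rate is None:
        raise ValidationError("ar_psd requires a uniform tachogram")
    if series.span < 120.0:
        raise InsufficientDataError(f"series spans {series.span:.0f} s; need >= 120 s")
    fs = series.sampling_rate
    x = _detrend(series.rr_ms)
    variance = float(np.var(x))
    freqs = np.linspace(0.0, fs / 2.0, n_freqs)
    if order == 0 or variance == 0:
        psd = np.full(n_freqs, variance / (fs / 2.0))
    else:
        acf = _biased_acf(x, order)
        a, _, sigma2 = levinson_durbin(acf, order)
        z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, order + 1)) / fs)
        denom = np.abs(1.0 - z @ a) ** 2
        psd = 2.0 * sigma2 / fs / denom  # one-sided
        psd = _rescale_to_variance(freqs, psd, variance)
    return SpectralResult(
        frequencies=freqs,
        psd=psd,
        method="ar",
        params={"fs": fs, "order": order},
    )


def lomb_scargle_psd(
    tachogram: Tachogram, f_max: float = 0.5, oversample: int = 4
) -> SpectralResult:
    """Classical Lomb-Scargle periodogram on the raw unevenly sampled RR
    series (no resampling), rescaled to ms^2/Hz so a pure sinusoid of
    amplitude A recovers band power A^2/2."""
    if tachogram.uniform:
        # allowed, but treated identically: the estimator never resamples
        pass
    t = tachogram.sample_times
    x = np.asarray(tachogram.rr_ms, dtype=float)
    if x.size < 60:
        raise InsufficientDataError(f"need >= 60 samples, have {x.size}")
    if np.ptp(t) == 0:
        raise ValidationError("degenerate time axis: all sample times equal")
    span = tachogram.span
    if span < 120.0:
        raise InsufficientDataError(f"series spans {span:.0f} s; need >= 120 s")
    # mean centring + linear detrend (the recovery record is nonstationary)
    coeffs = np.polyfit(t, x, 1)
    resid = x - np.polyval(coeffs, t)
    df = 1.0 / (oversample * span)
    freqs = np.arange(1, int(np.floor(f_max / df)) + 1) * df
    pgram = signal.lombscargle(t, resid, 2.0 * np.pi * freqs)
    # density conversion: peak lobe width ~ 1/span and peak height ~ N A^2/4,
    # so scaling by 2*span/N makes a pure tone's band integral ~ A^2/2
    pgram = pgram * 2.0 * span / x.size
    # prepend f=0 with zero power (mean removed) so the grid covers [0, f_max]
    freqs = np.concatenate(([0.0], freqs))
    psd = np.concatenate(([0.0], pgram))
    return SpectralResult(
        frequencies=freqs,
        psd=psd,
        method="lomb_scargle",
        params={"f_max": f_max, "oversample": oversample},
    )


def _band_integral(freqs, psd, lo, hi, n_fine=4096):
    """Trapezoidal band integral with exact edge handling via interpolation."""
    lo = max(lo, freqs[0])
    hi = min(hi, freqs[-1])
    if hi <= lo:
        return 0.0
    fine = np.linspace(lo, hi, n_fine)
    return float(np.trapezoid(np.interp(fine, freqs, psd), fine))


def band_powers(spec: SpectralResult) -> BandPowers:
    """Integrate VLF/LF/HF bands; normalized units and LF:HF ratio.

    Total power is defined as vlf + lf + hf, so ``lf_nu + hf_nu == 1``
    whenever LF + HF power is positive.
    """
    f, p = spec.frequencies, spec.psd
    if np.any(p < 0):
        raise ValidationError("PSD contains negative values")
    if f[0] > VLF_BAND[0] or f[-1] < HF_BAND[1]:
        raise ValidationError(
            f"frequency grid [{f[0]:.4f}, {f[-1]:.4f}] does not cover "
            f"[{VLF_BAND[0]}, {HF_BAND[1]}] Hz"
        )
    vlf = _band_integral(f, p, *VLF_BAND)
    lf = _band_integral(f, p, *LF_BAND)
    hf = _band_integral(f, p, *HF_BAND)
    total = vlf + lf + hf
    denom = total - vlf
    if denom > 0:
        lf_nu = lf / denom
        hf_nu = hf / denom
    else:
        lf_nu = hf_nu = float("nan")
    ratio = lf / hf if hf > 0 else None
    return BandPowers(
        vlf=vlf, lf=lf, hf=hf, total=total, lf_nu=lf_nu, hf_nu=hf_nu, lf_hf_ratio=ratio
    )


def recovery_spectrum(
    beats: BeatSeries,
    method: str = "welch",
    window_s: float = 180.0,
    ar_order: int = DEFAULT_AR_ORDER,
    resample_hz: float = 4.0,
) -> BandPowers:
    """Band powers over the first ``window_s`` seconds of recovery.

    Cleans the recovery tachogram, then routes to the chosen estimator
    (resampling first for ``welch``/``ar``; raw uneven samples for
    ``lomb_scargle``).
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {METHODS}")
    rec_times = beats.phase_times("recovery")
    if rec_times.size < 2 or rec_times[-1] - beats.recovery_onset < window_s:
        raise InsufficientDataError(
            f"recovery phase shorter than {window_s:.0f} s"
        )
    tach = rr_from_beats(beats, "recovery")
    mask = tach.sample_times <= beats.recovery_onset + window_s
    tach = Tachogram(sample_times=tach.sample_times[mask], rr_ms=tach.rr_ms[mask])
    cleaned, _ = filter_artifacts(tach)
    spec = spectrum(cleaned, method, ar_order=ar_order, resample_hz=resample_hz)
    return band_powers(spec)


def spectrum(
    cleaned: Tachogram,
    method: str,
    ar_order: int = DEFAULT_AR_ORDER,
    resample_hz: float = 4.0,
) -> SpectralResult:
    """Dispatch a cleaned non-uniform tachogram to the chosen estimator."""
    if method == "lomb_scargle":
        return lomb_scargle_psd(cleaned)
    uniform = resample_uniform(cleaned, rate=resample_hz)
    if method == "welch":
        return welch_psd(uniform)
    if method == "ar":
        return ar_psd(uniform, order=ar_order)
    raise ValidationError(f"unknown method {method!r}")
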