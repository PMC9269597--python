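"""HRV feature catalog: 15 time-domain, 36 frequency-domain, 12 non-linear.

Frequency-domain features are computed three ways — Welch's averaged
periodogram and a Burg autoregressive model on the evenly resampled
tachogram, and a Lomb-Scargle periodogram directly on the uneven
(beat time, interval) pairs — each yielding peak, absolute, relative and
log band power for the VLF (<0.04 Hz), LF (0.04-0.15 Hz) and HF
(0.15-0.4 Hz) bands.  Non-linear features cover the Poincare scatter
(SD1/SD2 family), sample entropy and detrended fluctuation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal as sps

from .pulse import NNISeries

__all__ = [
    "FreqBands",
    "PSDEstimate",
    "HRVFeatureSet",
    "time_domain_features",
    "resample_nni",
    "psd_estimate",
    "band_features",
    "poincare_features",
    "sample_entropy",
    "dfa",
    "extract_all_features",
    "TIME_DOMAIN_NAMES",
    "NONLINEAR_NAMES",
    "PSD_METHODS",
]

TIME_DOMAIN_NAMES = (
    "nni_count", "nni_mean", "nni_min", "nni_max", "nni_diff_mean",
    "hr_mean", "hr_min", "hr_max",
    "sdnn", "rmssd", "sdsd", "nn20", "pnn20", "nn50", "pnn50",
)

NONLINEAR_NAMES = (
    "sd1", "sd2", "sd_ratio", "ellipse_area", "sampen",
    "dfa_alpha1", "dfa_alpha2", "dfa_alpha_overall",
    "csi", "cvi", "sd2_sd1_ratio", "poincare_corr",
)

PSD_METHODS = ("welch", "ar", "lomb")

_BAND_FEATURES = ("peak_hz", "abs_ms2", "rel", "log")

_UNITS = {
    "nni_count": "beats", "nni_mean": "ms", "nni_min": "ms", "nni_max": "ms",
    "nni_diff_mean": "ms", "hr_mean": "bpm", "hr_min": "bpm", "hr_max": "bpm",
    "sdnn": "ms", "rmssd": "ms", "sdsd": "ms", "nn20": "count", "pnn20": "%",
    "nn50": "count", "pnn50": "%",
    "sd1": "ms", "sd2": "ms", "sd_ratio": "", "ellipse_area": "ms^2",
    "sampen": "", "dfa_alpha1": "", "dfa_alpha2": "", "dfa_alpha_overall": "",
    "csi": "", "cvi": "", "sd2_sd1_ratio": "", "poincare_corr": "",
    "peak_hz": "Hz", "abs_ms2": "ms^2", "rel": "", "log": "ln(ms^2)",
}


@dataclass(frozen=True)
class FreqBands:
    """VLF / LF / HF band edges in Hz (half-open except the HF top edge)."""

    vlf: tuple[float, float] = (0.0, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)

    def __post_init__(self) -> None:
        edges = [*self.vlf, *self.lf, *self.hf]
        if edges != sorted(edges) or self.vlf[1] != self.lf[0] or self.lf[1] != self.hf[0]:
            raise ValueError("bands must be contiguous, non-overlapping and increasing")

    def items(self):
        return (("vlf", self.vlf), ("lf", self.lf), ("hf", self.hf))


@dataclass
class PSDEstimate:
    """One-sided power spectral density of the tachogram, ms^2/Hz."""

    freqs: np.ndarray
    power: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0) or np.any(self.freqs < 0):
            raise ValueError("frequency grid must be non-negative increasing")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be non-negative")


class HRVFeatureSet:
    """Ordered name -> value map with units and a method tag per feature.

    Values are floats or ``None`` when a feature could not be computed
    (degenerate input); missing values are explicit, never silent NaN.
    """

    def __init__(self) -> None:
        self.features: dict[str, float | None] = {}
        self.units: dict[str, str] = {}
        self.method_tags: dict[str, str] = {}

    def add(self, name: str, value, units: str, tag: str) -> None:
        if name in self.features:
            raise KeyError(f"duplicate feature {name!r}")
        if value is not None:
            value = float(value)
            if not np.isfinite(value):
                value = None
        self.features[name] = value
        self.units[name] = units
        self.method_tags[name] = tag

    def update(self, other: "HRVFeatureSet") -> None:
        for name in other.features:
            self.add(name, other.features[name], other.units[name], other.method_tags[name])

    def __getitem__(self, name: str) -> float | None:
        return self.features[name]

    def __len__(self) -> int:
        return len(self.features)

    def names(self, tag: str | None = None) -> list[str]:
        if tag is None:
            return list(self.features)
        return [n for n, t in self.method_tags.items() if t == tag]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature": list(self.features),
                "value": [self.features[n] for n in self.features],
                "units": [self.units[n] for n in self.features],
                "method_tag": [self.method_tags[n] for n in self.features],
            }
        )


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def time_domain_features(nni: NNISeries) -> HRVFeatureSet:
    """The 15 time-domain statistics of the NN-interval series.

    sdnn is the sample SD of the intervals; rmssd the root mean square of
    successive differences; sdsd their sample SD; nnXX counts successive
    differences strictly greater than XX ms in magnitude and pnnXX is the
    corresponding percentage.  Heart-rate statistics are over 60000/nni.
    """
    x = nni.nni
    if x.size < 2:
        raise ValueError("time-domain features need at least 2 intervals (sdnn)")
    if x.size < 3:
        raise ValueError("difference-based features (rmssd, sdsd, nnXX) need >= 3 intervals")
    hr = 60000.0 / x
    diffs = np.diff(x)
    fs = HRVFeatureSet()
    vals = {
        "nni_count": x.size,
        "nni_mean": np.mean(x),
        "nni_min": np.min(x),
        "nni_max": np.max(x),
        "nni_diff_mean": np.mean(np.abs(diffs)),
        "hr_mean": np.mean(hr),
        "hr_min": np.min(hr),
        "hr_max": np.max(hr),
        "sdnn": _sd(x),
        "rmssd": np.sqrt(np.mean(diffs**2)),
        "sdsd": _sd(diffs),
        "nn20": np.sum(np.abs(diffs) > 20.0),
        "pnn20": 100.0 * np.sum(np.abs(diffs) > 20.0) / diffs.size,
        "nn50": np.sum(np.abs(diffs) > 50.0),
        "pnn50": 100.0 * np.sum(np.abs(diffs) > 50.0) / diffs.size,
    }
    for name in TIME_DOMAIN_NAMES:
        fs.add(name, vals[name], _UNITS[name], "time")
    return fs


def resample_nni(nni: NNISeries, fs_interp: float = 4.0):
    """Evenly resampled tachogram for the FFT-based spectral estimators.

    Cubic interpolation of interval value against interval end time, sampled
    on a uniform ``fs_interp`` grid spanning the recording.  Falls back to
    linear interpolation (with a warning) when fewer than 4 points exist.
    """
    from .pulse import Signal

    if nni.nni.size < 2:
        raise ValueError("resampling needs at least 2 intervals")
    t, y = nni.nni_times, nni.nni
    kind = "cubic"
    if t.size < 4:
        warnings.warn("fewer than 4 intervals; falling back to linear interpolation",
                      stacklevel=2)
        kind = "linear"
    f = interpolate.interp1d(t, y, kind=kind, fill_value=(y[0], y[-1]), bounds_error=False)
    grid = np.arange(t[0], t[-1], 1.0 / fs_interp)
    return Signal(values=f(grid), fs=fs_interp, t0=float(t[0]))


def psd_estimate(
    nni: NNISeries,
    method: str = "welch",
    fs_interp: float = 4.0,
    welch_nperseg: int = 256,
    welch_nfft: int = 4096,
    ar_order: int = 16,
    ar_nfreq: int = 2049,
    lomb_oversample: int = 4,
    f_max: float = 0.5,
) -> PSDEstimate:
    """Power spectral density of the NN-interval series, ms^2/Hz.

    welch
        Averaged modified periodogram of the resampled tachogram (Hann
        window, ``welch_nperseg`` samples = 64 s at 4 Hz, 50% overlap,
        zero-padded to ``welch_nfft`` bins).
    ar
        Burg all-pole model of order ``ar_order`` on the mean-removed
        resampled tachogram, evaluated on a uniform grid.
    lomb
        Least-squares periodogram on the uneven (beat time, interval) pairs,
        rescaled so its integral equals the interval variance.
    """
    if method not in PSD_METHODS:
        raise ValueError(f"unknown PSD method {method!r}; expected one of {PSD_METHODS}")

    if method == "lomb":
        t, y = nni.nni_times, nni.nni
        if t.size < 8:
            raise ValueError("Lomb-Scargle needs at least 8 intervals")
        span = t[-1] - t[0]
        df = 1.0 / (span * lomb_oversample)
        freqs = np.arange(df, f_max + df / 2, df)
        yc = y - y.mean()
        raw = sps.lombscargle(t, yc, 2 * np.pi * freqs)
        area = np.trapezoid(raw, freqs)
        var = np.var(yc)
        power = raw * (var / area) if area > 0 else raw
        return PSDEstimate(freqs=freqs, power=power, method="lomb")

    tach = resample_nni(nni, fs_interp=fs_interp)
    y = tach.values
    if method == "welch":
        if y.size < welch_nperseg:
            raise ValueError(
                f"resampled series ({y.size} samples) shorter than one Welch "
                f"segment ({welch_nperseg})"
            )
        freqs, power = sps.welch(
            y, fs=tach.fs, window="hann", nperseg=welch_nperseg,
            noverlap=welch_nperseg // 2, nfft=welch_nfft, detrend="constant",
        )
        keep = freqs <= f_max
        return PSDEstimate(freqs=freqs[keep], power=power[keep], method="welch")

    # Burg autoregressive spectrum
    from statsmodels.regression.linear_model import burg

    if y.size <= ar_order:
        raise ValueError(f"series too short for AR order {ar_order}")
    yc = y - y.mean()
    phi, sigma2 = burg(yc, order=ar_order)
    freqs = np.linspace(0.0, min(f_max, tach.fs / 2.0), ar_nfreq)
    # one-sided PSD of an AR(p) process: 2*sigma2 / (fs |1 - sum phi_k e^{-i w k}|^2)
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, ar_order + 1)) / tach.fs)
    denom = np.abs(1.0 - z @ phi) ** 2
    power = 2.0 * sigma2 / (tach.fs * denom)
    return PSDEstimate(freqs=freqs, power=power, method="ar")


def band_features(psd: PSDEstimate, bands: FreqBands | None = None) -> HRVFeatureSet:
    """Peak frequency and absolute/relative/log power per VLF/LF/HF band.

    Absolute power is the trapezoidal integral of the PSD over the band;
    relative powers are normalized by the three-band total and sum to one.
    A band not covered by the frequency grid yields explicit missing values.
    """
    if bands is None:
        bands = FreqBands()
    fs = HRVFeatureSet()
    tag = f"freq_{psd.method}"
    abs_powers: dict[str, float | None] = {}
    peaks: dict[str, float | None] = {}
    for name, (lo, hi) in bands.items():
        # include the top edge only for the final band
        top_closed = hi >= bands.hf[1]
        mask = (psd.freqs >= lo) & ((psd.freqs <= hi) if top_closed else (psd.freqs < hi))
        if mask.sum() < 2:
            abs_powers[name] = None
            peaks[name] = None
            continue
        f_b, p_b = psd.freqs[mask], psd.power[mask]
        abs_powers[name] = float(np.trapezoid(p_b, f_b))
        peaks[name] = float(f_b[np.argmax(p_b)])
    total = sum(v for v in abs_powers.values() if v is not None)
    for name, _ in bands.items():
        a = abs_powers[name]
        fs.add(f"{psd.method}_{name}_peak_hz", peaks[name], _UNITS["peak_hz"], tag)
        fs.add(f"{psd.method}_{name}_abs_ms2", a, _UNITS["abs_ms2"], tag)
        rel = None if a is None or total <= 0 else a / total
        fs.add(f"{psd.method}_{name}_rel", rel, _UNITS["rel"], tag)
        logp = None if a is None or a <= 0 else np.log(a)
        fs.add(f"{psd.method}_{name}_log", logp, _UNITS["log"], tag)
    return fs


def poincare_features(nni: NNISeries) -> HRVFeatureSet:
    """Poincare scatter dispersion: SD1 (perpendicular to the identity line),
    SD2 (along it), their ratios, the fitted ellipse area and companions.

    SD1^2 = var(diff)/2 and SD2^2 = 2 var(nni) - var(diff)/2 (sample
    variances); csi = SD2/SD1 and cvi = log10(16 SD1 SD2) are the
    cardio-sympathetic and cardio-vagal indices.  Ratios are missing when the
    denominator dispersion vanishes.
    """
    x = nni.nni
    if x.size < 3:
        raise ValueError("Poincare features need at least 3 intervals")
    diffs = np.diff(x)
    var_d = np.var(diffs, ddof=1)
    var_x = np.var(x, ddof=1)
    sd1 = float(np.sqrt(var_d / 2.0))
    sd2 = float(np.sqrt(max(2.0 * var_x - var_d / 2.0, 0.0)))
    fs = HRVFeatureSet()
    fs.add("sd1", sd1, _UNITS["sd1"], "nonlinear")
    fs.add("sd2", sd2, _UNITS["sd2"], "nonlinear")
    fs.add("sd_ratio", None if sd2 == 0 else sd1 / sd2, _UNITS["sd_ratio"], "nonlinear")
    fs.add("ellipse_area", np.pi * sd1 * sd2, _UNITS["ellipse_area"], "nonlinear")
    fs.add("csi", None if sd1 == 0 else sd2 / sd1, _UNITS["csi"], "nonlinear")
    prod = 16.0 * sd1 * sd2
    fs.add("cvi", None if prod <= 0 else np.log10(prod), _UNITS["cvi"], "nonlinear")
    fs.add("sd2_sd1_ratio", None if sd1 == 0 else sd2 / sd1,
           _UNITS["sd2_sd1_ratio"], "nonlinear")
    if var_x > 0:
        xc = x - x.mean()
        corr = float(np.dot(xc[:-1], xc[1:]) / np.dot(xc, xc))
    else:
        corr = None
    fs.add("poincare_corr", corr, _UNITS["poincare_corr"], "nonlinear")
    return fs


def sample_entropy(nni, m: int = 2, r: float = 0.2) -> float | None:
    """Sample entropy SampEn(m, r) of the interval series.

    ``r`` is a fraction of the series SD; matches use the Chebyshev distance
    strictly below ``r * SD`` with self-matches excluded.  Returns ``None``
    (with a warning) when either template count is zero.
    """
    x = np.asarray(nni.nni if isinstance(nni, NNISeries) else nni, dtype=float)
    n = x.size
    if n < 10 * m:
        raise ValueError(f"sample entropy needs at least {10 * m} intervals")
    tol = r * np.std(x)
    if tol == 0:
        warnings.warn("zero tolerance (constant series); SampEn undefined", stacklevel=2)
        return None

    def _count(mm: int) -> int:
        # restrict to the n-m templates that have an (m+1)-length extension,
        # so A and B share the same index range
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=-1)
        iu = np.triu_indices(templ.shape[0], k=1)
        return int(np.sum(d[iu] < tol))

    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        warnings.warn("no template matches; SampEn undefined for this series",
                      stacklevel=2)
        return None
    return float(-np.log(a / b))


def dfa(
    nni,
    short_scales: tuple[int, int] = (4, 16),
    long_scales: tuple[int, int] = (16, 64),
) -> tuple[float | None, float | None, float | None]:
    """Detrended fluctuation analysis scaling exponents (alpha1, alpha2, overall).

    The mean-centered series is integrated; for each window size n the
    integrated profile is split into non-overlapping windows, each linearly
    detrended, and F(n) is the RMS residual.  alpha is the slope of
    log F(n) vs log n over the short (4-16 beats) and long (16-64 beats)
    scale ranges.  alpha2 is missing when the series is too short.
    """
    x = np.asarray(nni.nni if isinstance(nni, NNISeries) else nni, dtype=float)
    if x.size < 4 * short_scales[1]:
        raise ValueError("series too short for DFA short scales")
    profile = np.cumsum(x - x.mean())

    def _fluct(n: int) -> float:
        return dfa_fluctuation(profile, n)

    def _alpha(lo: int, hi: int) -> float | None:
        ns = np.unique(np.logspace(np.log10(lo), np.log10(hi), 10).astype(int))
        ns = ns[(ns >= 4) & (ns <= x.size // 4)]
        if ns.size < 3:
            return None
        f = np.array([_fluct(int(n)) for n in ns])
        good = f > 0
        if good.sum() < 3:
            return None
        return float(np.polyfit(np.log10(ns[good]), np.log10(f[good]), 1)[0])

    alpha1 = _alpha(*short_scales)
    alpha2 = _alpha(*long_scales)
    overall = _alpha(short_scales[0], long_scales[1])
    return alpha1, alpha2, overall


def dfa_fluctuation(profile: np.ndarray, n: int) -> float:
    """RMS residual of the integrated profile around per-window linear trends."""
    k = profile.size // n
    segs = profile[: k * n].reshape(k, n)
    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    slope = segs @ tc / np.dot(tc, tc)
    resid = segs - segs.mean(axis=1, keepdims=True) - np.outer(slope, tc)
    return float(np.sqrt(np.mean(resid**2)))


def nonlinear_features(nni: NNISeries) -> HRVFeatureSet:
    """The 12 non-linear features: Poincare family, SampEn and DFA exponents."""
    fs = poincare_features(nni)
    try:
        se = sample_entropy(nni)
    except ValueError:
        se = None
    out = HRVFeatureSet()
    # preserve catalog order
    partial = dict(fs.features)
    try:
        a1, a2, ao = dfa(nni)
    except ValueError:
        a1 = a2 = ao = None
    vals = {
        **partial,
        "sampen": se,
        "dfa_alpha1": a1,
        "dfa_alpha2": a2,
        "dfa_alpha_overall": ao,
    }
    for name in NONLINEAR_NAMES:
        out.add(name, vals[name], _UNITS[name], "nonlinear")
    return out


def extract_all_features(
    nni: NNISeries,
    bands: FreqBands | None = None,
    fs_interp: float = 4.0,
    strict: bool = False,
) -> HRVFeatureSet:
    """Full catalog: 15 time-domain + 36 frequency-domain + 12 non-linear.

    Missing values are explicit (``None``); with ``strict=True`` any family
    failure raises instead.
    """
    out = HRVFeatureSet()
    out.update(time_domain_features(nni))
    for method in PSD_METHODS:
        try:
            psd = psd_estimate(nni, method=method, fs_interp=fs_interp)
            out.update(band_features(psd, bands))
        except ValueError:
            if strict:
                raise
            tag = f"freq_{method}"
            for bname in ("vlf", "lf", "hf"):
                for feat in _BAND_FEATURES:
                    out.add(f"{method}_{bname}_{feat}", None, _UNITS[feat], tag)
    out.update(nonlinear_features(nni))
    return out
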