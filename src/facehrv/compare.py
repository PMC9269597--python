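"""Dual-source agreement analysis: alignment, error metrics, correlations, FDR.

The video branch and the PPG branch each yield heart rates and an HRV
feature set per recording.  This module trims the pair to a common window,
computes the heart-rate error metrics (globally and per minute), correlates
every feature between sources with the Pearson, Spearman and Kendall tests,
and adjusts the p-values with the Benjamini-Hochberg step-up procedure.  A
feature counts as significantly correlated only when its q-value clears the
threshold under all three tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pulse import PeakTrain, Signal

__all__ = [
    "ErrorMetrics",
    "ComparisonReport",
    "align_pair",
    "error_metrics",
    "correlate_feature_tables",
    "benjamini_hochberg",
    "significant_features",
    "run_study",
    "StudyConfig",
]

_TESTS = ("pearson", "spearman", "kendall")


@dataclass
class ErrorMetrics:
    """Signed mean error, mean absolute error, SD of differences and RMSE (bpm)."""

    me: float
    mae: float
    sd: float
    rmse: float
    n: int


def _trim_signal(sig: Signal, cut_s: float, target_n: int) -> Signal:
    start = int(np.floor(cut_s * sig.fs))
    values = sig.values[start:start + target_n]
    return Signal(values=values, fs=sig.fs, t0=0.0)


def _trim_train(train: PeakTrain, cut_s: float, new_duration: float) -> PeakTrain:
    rel = train.times - train.t0
    keep = (rel >= cut_s) & (rel < cut_s + new_duration)
    idx = train.indices[keep] - int(round(cut_s * train.fs))
    return PeakTrain(indices=idx, fs=train.fs, t0=0.0, duration_s=new_duration)


def align_pair(a, b, min_overlap_s: float = 60.0):
    """Trim the longer of two recordings symmetrically to match the shorter.

    Works on :class:`Signal` or :class:`PeakTrain` members (durations must be
    known).  Half of the surplus duration is removed from each end; an odd
    surplus sample goes from the end.  Raises when the common duration falls
    below ``min_overlap_s``.
    """
    def dur(x) -> float:
        d = x.duration_s
        if d is None:
            raise ValueError("member has unknown duration; cannot align")
        return d

    da, db = dur(a), dur(b)
    target = min(da, db)
    if target < min_overlap_s:
        raise ValueError(f"common duration {target:.1f} s below {min_overlap_s} s")

    def trim(x, d):
        surplus = d - target
        if surplus <= 0:
            return x
        if isinstance(x, Signal):
            n_target = int(round(target * x.fs))
            n_cut = x.values.size - n_target
            n_start = n_cut // 2  # odd surplus: extra sample from the end
            return _trim_signal(x, n_start / x.fs, n_target)
        return _trim_train(x, surplus / 2.0, target)

    return trim(a, da), trim(b, db)


def error_metrics(hr_a, hr_b) -> ErrorMetrics:
    """Elementwise error metrics between two heart-rate vectors (a - b).

    me is the signed mean difference (sign retained); mae the mean absolute
    difference; sd the sample SD of the differences (0 when n = 1); rmse the
    root mean square difference, so rmse >= |me| always.
    """
    a = np.asarray(hr_a, dtype=float)
    b = np.asarray(hr_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("heart-rate vectors must be equal-length and non-empty")
    d = a - b
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return ErrorMetrics(
        me=float(np.mean(d)),
        mae=float(np.mean(np.abs(d))),
        sd=sd,
        rmse=float(np.sqrt(np.mean(d**2))),
        n=d.size,
    )


def correlate_feature_tables(tab_a: pd.DataFrame, tab_b: pd.DataFrame) -> pd.DataFrame:
    """Per-feature Pearson r, Spearman rho and Kendall tau-b between sources.

    Both tables are samples x features with identical shape and columns.
    Pairs with a missing value in either table are dropped per feature; at
    least 4 complete pairs are required, and zero variance in either column
    yields missing coefficients.  Returns a DataFrame with one row per
    feature and r/p columns per test (q-values are added separately).
    """
    if list(tab_a.columns) != list(tab_b.columns) or len(tab_a) != len(tab_b):
        raise ValueError("feature tables must share samples and feature columns")
    rows = []
    for feat in tab_a.columns:
        x = pd.to_numeric(tab_a[feat], errors="coerce").to_numpy(dtype=float)
        y = pd.to_numeric(tab_b[feat], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        row: dict = {"feature": feat, "n": int(ok.sum())}
        x, y = x[ok], y[ok]
        degenerate = x.size < 4 or np.ptp(x) == 0 or np.ptp(y) == 0
        if degenerate:
            for t in _TESTS:
                row[f"r_{t}"] = np.nan
                row[f"p_{t}"] = np.nan
        else:
            pr = stats.pearsonr(x, y)
            sr = stats.spearmanr(x, y)
            kt = stats.kendalltau(x, y)  # tau-b, tie-corrected
            row.update(
                r_pearson=pr.statistic, p_pearson=pr.pvalue,
                r_spearman=sr.statistic, p_spearman=sr.pvalue,
                r_kendall=kt.statistic, p_kendall=kt.pvalue,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def benjamini_hochberg(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q(i) = min over j with p(j) >= p(i) of m * p(j) / rank(j)``, capped at
    one and returned in the input order.  ``m`` is the family size (defaults
    to the number of tests); NaNs pass through untouched and do not consume
    ranks.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    pf = p[finite]
    if np.any((pf < 0) | (pf > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pf.size == 0:
        return out
    if m is None:
        m = pf.size
    order = np.argsort(pf, kind="stable")
    ranked = pf[order] * m / np.arange(1, pf.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(pf)
    q[order] = np.minimum(q_sorted, 1.0)
    out[finite] = q
    return out


def add_q_values(corr: pd.DataFrame, m: int | None = None) -> pd.DataFrame:
    """Append per-test q-value columns; each test is its own BH family."""
    corr = corr.copy()
    for t in _TESTS:
        family_m = m if m is not None else int(corr[f"p_{t}"].notna().sum())
        corr[f"q_{t}"] = benjamini_hochberg(corr[f"p_{t}"].to_numpy(), m=family_m)
    return corr


def significant_features(corr: pd.DataFrame, threshold_q: float = 0.5) -> pd.DataFrame:
    """Features with q below threshold under ALL three correlation tests."""
    mask = np.ones(len(corr), dtype=bool)
    for t in _TESTS:
        mask &= corr[f"q_{t}"].to_numpy() < threshold_q
    corr = corr.copy()
    corr["significant_all"] = mask
    return corr


@dataclass
class StudyConfig:
    """Pipeline settings for :func:`run_study`."""

    use_evm: bool = True
    evm_alpha: float = 50.0
    evm_level: int = 4
    band_hz: tuple[float, float] = (0.67, 3.0)
    min_distance_s: float = 0.33
    height_k: float = 0.5
    threshold_q: float = 0.5
    strict: bool = False


@dataclass
class ComparisonReport:
    """Everything the agreement analysis produces for a set of recordings."""

    hr_table: pd.DataFrame
    metrics_global: ErrorMetrics
    per_minute: pd.DataFrame
    correlations: pd.DataFrame | None
    n_significant: dict | None
    hr_sd_a: float = 0.0
    hr_sd_b: float = 0.0
    notes: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        d = {
            "hr_table": self.hr_table.to_dict(orient="records"),
            "metrics_global": vars(self.metrics_global),
            "per_minute": self.per_minute.to_dict(orient="records"),
            "hr_sd_a": self.hr_sd_a,
            "hr_sd_b": self.hr_sd_b,
            "n_significant": self.n_significant,
            "notes": self.notes,
        }
        if self.correlations is not None:
            d["correlations"] = self.correlations.to_dict(orient="records")
        return d


def _video_branch(study, config: StudyConfig):
    """Fixed-ROI crop -> color magnification -> red mean -> peaks."""
    from .evm import EVMParams, magnify_color
    from .pulse import channel_mean_signal, detect_peaks, preprocess_signal
    from .video import crop_to_roi, fixed_track

    track = fixed_track(study.roi_truth, study.video.n_frames)
    roi_stack = crop_to_roi(study.video, track)
    if config.use_evm:
        level = config.evm_level
        while 2 ** level > min(roi_stack.shape):
            level -= 1
        params = EVMParams(alpha=config.evm_alpha, level=level,
                           f_lo=config.band_hz[0], f_hi=config.band_hz[1])
        roi_stack = magnify_color(roi_stack, params)
    sig = channel_mean_signal(roi_stack, "R")
    sig = preprocess_signal(sig, band=config.band_hz)
    return detect_peaks(sig, config.min_distance_s, config.height_k)


def _ppg_branch(ppg: Signal, config: StudyConfig):
    from .pulse import detect_peaks, preprocess_signal

    sig = preprocess_signal(ppg, band=config.band_hz)
    return detect_peaks(sig, config.min_distance_s, config.height_k)


def run_study(studies, config: StudyConfig | None = None) -> ComparisonReport:
    """Run both branches on paired recordings and build the full report.

    ``studies`` is an iterable of :class:`~facehrv.synthetic.SynthStudy`
    (or any object with ``video``, ``ppg`` and ``roi_truth``).  For each
    sample both branches are executed, the pair is time-aligned, count-based
    heart rates and per-minute rates are compared, and the HRV feature tables
    are correlated across sources (when at least 4 samples succeed).
    """
    from .hrv import extract_all_features
    from .pulse import mean_heart_rate, peaks_to_nni, per_minute_heart_rate

    if config is None:
        config = StudyConfig()
    rows, notes = [], []
    feats_a, feats_b = [], []
    minute_diffs = []
    for i, study in enumerate(studies):
        try:
            train_v = _video_branch(study, config)
            train_p = _ppg_branch(study.ppg, config)
            train_v, train_p = align_pair(train_v, train_p)
            hr_v = mean_heart_rate(train_v)
            hr_p = mean_heart_rate(train_p)
            rows.append({"sample": i, "hr_video": hr_v, "hr_ppg": hr_p,
                         "n_peaks_video": len(train_v), "n_peaks_ppg": len(train_p)})
            if train_v.duration_s >= 60:
                minute_diffs.append(
                    per_minute_heart_rate(train_v) - per_minute_heart_rate(train_p)
                )
            feats_a.append(extract_all_features(peaks_to_nni(train_v)).features)
            feats_b.append(extract_all_features(peaks_to_nni(train_p)).features)
        except (ValueError, RuntimeError) as exc:
            if config.strict:
                raise
            notes.append(f"sample {i} excluded: {exc}")
    if not rows:
        raise ValueError("no sample completed both branches")

    hr_table = pd.DataFrame(rows)
    metrics = error_metrics(hr_table["hr_video"], hr_table["hr_ppg"])
    if minute_diffs:
        md = np.stack(minute_diffs)
        per_minute = pd.DataFrame({
            "minute": np.arange(md.shape[1]),
            "me_bpm": md.mean(axis=0),
            "mae_bpm": np.abs(md).mean(axis=0),
            "sd_bpm": md.std(axis=0, ddof=1) if md.shape[0] > 1 else np.zeros(md.shape[1]),
            "rmse_bpm": np.sqrt((md**2).mean(axis=0)),
        })
    else:
        per_minute = pd.DataFrame(columns=["minute", "me_bpm", "mae_bpm", "sd_bpm", "rmse_bpm"])

    correlations = None
    n_sig = None
    if len(feats_a) >= 4:
        tab_a = pd.DataFrame(feats_a)
        tab_b = pd.DataFrame(feats_b)
        corr = correlate_feature_tables(tab_a, tab_b)
        corr = add_q_values(corr, m=len(corr))
        corr = significant_features(corr, config.threshold_q)
        correlations = corr
        n_sig = {"total": int(corr["significant_all"].sum())}
    else:
        notes.append("fewer than 4 samples: correlation section empty")

    return ComparisonReport(
        hr_table=hr_table,
        metrics_global=metrics,
        per_minute=per_minute,
        correlations=correlations,
        n_significant=n_sig,
        hr_sd_a=float(np.std(hr_table["hr_video"], ddof=1)) if len(hr_table) > 1 else 0.0,
        hr_sd_b=float(np.std(hr_table["hr_ppg"], ddof=1)) if len(hr_table) > 1 else 0.0,
        notes=notes,
    )
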