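"""Pulse-signal processing: from a waveform to beats, NN intervals and heart rates.

Both measurement branches end up here: the PPG trace from the pulse oximeter
and the spatial-mean red channel of the (magnified) face video are each a
uniformly sampled :class:`Signal`.  Peak detection turns a signal into a
:class:`PeakTrain`; successive peak spacings become the :class:`NNISeries`
that the HRV feature catalog consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "Signal",
    "PeakTrain",
    "NNISeries",
    "channel_mean_signal",
    "preprocess_signal",
    "detect_peaks",
    "peaks_to_nni",
    "mean_heart_rate",
    "per_minute_heart_rate",
    "HEART_BAND_HZ",
    "NNI_PLAUSIBLE_MS",
]

#: Default passband for pulse signals, Hz (40-180 bpm).
HEART_BAND_HZ = (0.67, 3.0)

#: Physiological plausibility window for NN intervals, ms.
NNI_PLAUSIBLE_MS = (300.0, 2000.0)


@dataclass
class Signal:
    """Uniformly sampled scalar waveform.

    Parameters
    ----------
    values : ndarray
        Amplitude samples.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("Signal requires a non-empty 1-D value array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


@dataclass
class PeakTrain:
    """Detected systolic peaks of a pulse signal."""

    indices: np.ndarray
    fs: float
    t0: float = 0.0
    #: Duration of the signal the peaks were detected in (for rate computation).
    duration_s: float | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.indices / self.fs

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class NNISeries:
    """Normal-to-normal inter-beat intervals in milliseconds.

    ``nni[i]`` spans ``(nni_times[i] - nni[i]/1000, nni_times[i])``; when no
    interval was rejected this equals ``diff(beat_times) * 1000`` and
    ``nni_times == beat_times[1:]``.  Implausible intervals (see
    :data:`NNI_PLAUSIBLE_MS`) are dropped at construction time, so the two
    arrays may be shorter than the raw beat count implies.
    """

    nni: np.ndarray
    nni_times: np.ndarray
    beat_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.nni = np.asarray(self.nni, dtype=float)
        self.nni_times = np.asarray(self.nni_times, dtype=float)
        if self.nni.shape != self.nni_times.shape:
            raise ValueError("nni and nni_times must have equal length")
        if np.any(self.nni <= 0):
            raise ValueError("all NN intervals must be positive")
        if self.beat_times is None:
            # reconstruct a plausible beat grid from interval endpoints
            self.beat_times = np.concatenate(
                ([self.nni_times[0] - self.nni[0] / 1000.0], self.nni_times)
            ) if self.nni.size else np.empty(0)
        self.beat_times = np.asarray(self.beat_times, dtype=float)

    def __len__(self) -> int:
        return self.nni.size

    @property
    def duration_s(self) -> float:
        return float(self.nni_times[-1] - (self.nni_times[0] - self.nni[0] / 1000.0))


def load_ppg_csv(path, fs: float | None = None) -> Signal:
    """Read a two-column (time_s, amplitude) PPG CSV.

    The sampling rate is taken from ``fs`` when given, else inferred from the
    median spacing of the time column (which must be uniform).
    """
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("PPG CSV needs columns time_s, amplitude")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if fs is None:
        dt = np.diff(t)
        if dt.size == 0 or np.ptp(dt) > 1e-6 * np.median(dt) + 1e-9:
            raise ValueError("cannot infer fs from a non-uniform time column")
        fs = 1.0 / float(np.median(dt))
    return Signal(values=v, fs=fs, t0=float(t[0]) if t.size else 0.0)


def channel_mean_signal(frames, channel: str = "R") -> Signal:
    """Spatial mean of one color channel per frame.

    ``frames`` is a :class:`~facehrv.video.FrameStack`; ``channel`` is one of
    the letters of its declared ``channel_order`` (the pipeline uses the red
    channel, which best reflects pulsatile skin-tone changes).
    """
    order = frames.channel_order
    if channel not in order:
        raise ValueError(f"channel {channel!r} not in declared order {order!r}")
    if frames.frames.shape[0] == 0:
        raise ValueError("empty frame stack")
    idx = order.index(channel)
    values = frames.frames[..., idx].mean(axis=(1, 2))
    return Signal(values=np.asarray(values, dtype=float), fs=frames.fps, t0=frames.t0)


def preprocess_signal(sig: Signal, band: tuple[float, float] = HEART_BAND_HZ) -> Signal:
    """Detrend and band-pass a pulse signal ahead of peak picking.

    A linear trend is removed, then a zero-phase 3rd-order Butterworth
    band-pass confined to ``band`` (Hz) is applied with ``sosfiltfilt``.
    Length, sampling rate and t0 are preserved; the output is zero-mean.
    """
    f_lo, f_hi = band
    nyq = sig.fs / 2.0
    if not (0 < f_lo < f_hi < nyq):
        raise ValueError(f"band {band} invalid for fs={sig.fs} Hz")
    sos = sps.butter(3, [f_lo / nyq, f_hi / nyq], btype="bandpass", output="sos")
    # sosfiltfilt needs more samples than its edge padding
    padlen = 3 * (2 * sos.shape[0] + 1)
    if sig.values.size <= padlen:
        raise ValueError(
            f"signal too short for filtering ({sig.values.size} <= warm-up {padlen})"
        )
    detrended = sps.detrend(sig.values, type="linear")
    filtered = sps.sosfiltfilt(sos, detrended)
    return Signal(values=filtered, fs=sig.fs, t0=sig.t0)


def detect_peaks(
    sig: Signal,
    min_distance_s: float = 0.33,
    height_k: float = 0.5,
) -> PeakTrain:
    """Locate systolic peaks with minimum-spacing and height rules.

    Keeps local maxima that are at least ``min_distance_s`` apart (the higher
    peak wins a conflict) and at least ``mean + height_k * std`` of the signal
    high.  ``min_distance_s`` defaults to 0.33 s (a 180 bpm ceiling) and
    ``height_k`` to 0.5; the signal is expected to be preprocessed
    (zero-mean), making the threshold effectively ``0.5 sigma``.
    """
    if min_distance_s <= 0:
        raise ValueError("min_distance_s must be positive")
    x = sig.values
    mu = float(np.mean(x))
    sd = float(np.std(x))
    distance = max(int(round(min_distance_s * sig.fs)), 1)
    # reflect the signal at both ends so a systolic bump truncated by the
    # recording boundary still presents a detectable local maximum
    pad = min(distance, x.size - 1)
    xp = np.pad(x, pad, mode="reflect")
    idx, _ = sps.find_peaks(xp, distance=distance, height=mu + height_k * sd)
    idx = idx - pad
    idx = idx[(idx >= 0) & (idx < x.size)]
    return PeakTrain(indices=idx, fs=sig.fs, t0=sig.t0, duration_s=sig.duration_s)


def peaks_to_nni(
    train: PeakTrain,
    plausible_ms: tuple[float, float] = NNI_PLAUSIBLE_MS,
) -> NNISeries:
    """Successive peak spacings in ms, with implausible intervals rejected.

    Intervals outside ``plausible_ms`` (default 300-2000 ms, i.e. 30-200 bpm)
    are treated as ectopic beats or detection artifacts and removed together
    with their boundary, rather than merged into a neighbour.
    """
    if len(train) < 2:
        raise ValueError("need at least 2 peaks to form intervals")
    times = train.times
    nni = np.diff(times) * 1000.0
    lo, hi = plausible_ms
    keep = (nni >= lo) & (nni <= hi)
    return NNISeries(nni=nni[keep], nni_times=times[1:][keep], beat_times=times)


def mean_heart_rate(train: PeakTrain, duration_s: float | None = None) -> float:
    """Count-based heart rate: 60 * (number of peaks) / duration, in bpm.

    This is the rate used for the between-branch error metrics; it is distinct
    from the HRV feature ``hr_mean`` (mean of 60000/nni).
    """
    if duration_s is None:
        duration_s = train.duration_s
    if duration_s is None or duration_s <= 0:
        raise ValueError("positive duration required")
    return 60.0 * len(train) / duration_s


def per_minute_heart_rate(
    train: PeakTrain, total_duration_s: float | None = None
) -> np.ndarray:
    """Peak counts per full one-minute window ``[60k, 60(k+1))``.

    For a 60 s window the count equals bpm.  The trailing partial window is
    discarded; durations below 60 s are an error.
    """
    if total_duration_s is None:
        total_duration_s = train.duration_s
    if total_duration_s is None or total_duration_s < 60.0:
        raise ValueError("per-minute stratification needs at least 60 s")
    n_windows = int(total_duration_s // 60)
    rel = train.times - train.t0
    counts = np.histogram(rel, bins=np.arange(0.0, 60.0 * (n_windows + 1), 60.0))[0]
    return counts.astype(float)
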