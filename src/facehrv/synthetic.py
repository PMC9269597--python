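"""Synthetic paired recordings: ground-truth beats, PPG trace and face video.

No public recordings back this pipeline, so every downstream stage is
exercised on generated data whose statistical structure matches what the
method assumes: an RR series with low- and high-frequency autonomic
modulation (integral pulse frequency modulation, IPFM), a pulse-oximeter-like
trace with one Gaussian systolic bump per beat, and a small video whose
skin-patch red channel is modulated by the same beat train.

IPFM integrates an instantaneous beat rate

    r(t) = r0 * (1 + lf_amp * sin(2 pi f_lf t) + hf_amp * sin(2 pi f_hf t))

and fires a beat each time the integral crosses an integer, so the interval
spectrum inherits power at the chosen modulation frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pulse import Signal
from .video import FrameStack, ROIBox, write_frames, write_roi

__all__ = [
    "RRGroundTruth",
    "SynthStudy",
    "generate_rr_series",
    "synthesize_ppg",
    "synthesize_face_video",
    "write_study",
]

_NNI_CLAMP_MS = (300.0, 2000.0)


@dataclass
class RRGroundTruth:
    """Ground-truth beat times (s) and NN intervals (ms) with generator settings."""

    beat_times: np.ndarray
    nni: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.nni = np.asarray(self.nni, dtype=float)
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if self.nni.size != self.beat_times.size - 1:
            raise ValueError("nni must have one fewer element than beat_times")

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    @property
    def duration_s(self) -> float:
        return float(self.params.get("duration_s", self.beat_times[-1]))


@dataclass
class SynthStudy:
    """A paired synthetic recording: truth + PPG + video + the skin-patch ROI."""

    truth: RRGroundTruth
    ppg: Signal
    video: FrameStack
    roi_truth: ROIBox
    fps: float
    ppg_fs: float


def generate_rr_series(
    duration_s: float,
    mean_hr_bpm: float = 70.0,
    lf_amp: float = 0.03,
    lf_freq_hz: float = 0.1,
    hf_amp: float = 0.025,
    hf_freq_hz: float = 0.25,
    jitter_sd_ms: float = 0.0,
    seed: int | None = None,
) -> RRGroundTruth:
    """Generate a beat train by integral pulse frequency modulation.

    ``lf_amp``/``hf_amp`` are fractional modulations of the instantaneous
    rate (0.03 means +/-3%); ``lf_freq_hz`` and ``hf_freq_hz`` should sit in
    the LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) autonomic bands.  Independent
    Gaussian jitter of ``jitter_sd_ms`` is added to each interval afterwards;
    intervals are clamped to the physiological 300-2000 ms window and beat
    times rebuilt cumulatively, so ``nni == diff(beat_times) * 1000`` holds
    exactly.  Fully reproducible from ``seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not (30.0 <= mean_hr_bpm <= 180.0):
        raise ValueError(f"mean heart rate {mean_hr_bpm} bpm outside the physiological 30-180 range")
    if lf_amp < 0 or hf_amp < 0 or jitter_sd_ms < 0:
        raise ValueError("modulation amplitudes and jitter must be non-negative")

    r0 = mean_hr_bpm / 60.0  # beats per second
    if lf_amp == 0 and hf_amp == 0:
        # integral is linear: crossings fall exactly on a uniform grid,
        # with the integrator's reset beat at t = 0
        n = int(np.floor(duration_s * r0))
        beats = np.arange(0, n + 1) / r0
    else:
        dt = 1e-3
        t = np.arange(0.0, duration_s + dt, dt)
        rate = r0 * (
            1.0
            + lf_amp * np.sin(2 * np.pi * lf_freq_hz * t)
            + hf_amp * np.sin(2 * np.pi * hf_freq_hz * t)
        )
        integral = np.concatenate(([0.0], np.cumsum((rate[1:] + rate[:-1]) / 2.0 * dt)))
        n = int(np.floor(integral[-1]))
        # invert the (monotone) integral at integer crossings; t = 0 is a beat
        beats = np.interp(np.arange(1, n + 1, dtype=float), integral, t)
        beats = np.concatenate(([0.0], beats[beats <= duration_s]))

    if beats.size < 2:
        raise ValueError("duration too short to contain two beats")

    nni = np.diff(beats) * 1000.0
    if jitter_sd_ms > 0:
        rng = np.random.default_rng(seed)
        nni = nni + rng.normal(0.0, jitter_sd_ms, size=nni.size)
    nni = np.clip(nni, *_NNI_CLAMP_MS)
    beat_times = beats[0] + np.concatenate(([0.0], np.cumsum(nni / 1000.0)))
    params = dict(
        duration_s=duration_s, mean_hr_bpm=mean_hr_bpm, lf_amp=lf_amp,
        lf_freq_hz=lf_freq_hz, hf_amp=hf_amp, hf_freq_hz=hf_freq_hz,
        jitter_sd_ms=jitter_sd_ms, seed=seed,
    )
    return RRGroundTruth(beat_times=beat_times, nni=nni, params=params)


def _pulse_waveform(t: np.ndarray, beat_times: np.ndarray, width_s: float) -> np.ndarray:
    """Sum of unit-amplitude Gaussian bumps (sd = width_s) at the beat times."""
    out = np.zeros_like(t)
    dt = t[1] - t[0] if t.size > 1 else 1.0
    half = 5.0 * width_s
    for tb in beat_times:
        i0 = max(int((tb - half - t[0]) / dt), 0)
        i1 = min(int((tb + half - t[0]) / dt) + 2, t.size)
        if i0 >= i1:
            continue
        seg = t[i0:i1]
        out[i0:i1] += np.exp(-0.5 * ((seg - tb) / width_s) ** 2)
    return out


def synthesize_ppg(
    truth: RRGroundTruth,
    fs_hz: float = 100.0,
    pulse_width_s: float = 0.05,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Signal:
    """Pulse-oximeter-like trace: one Gaussian systolic bump per beat.

    The Gaussian template (sd ``pulse_width_s``, unit amplitude) matches the
    low-complexity, Gaussian-shaped waveform the peak detector assumes.
    Additive white Gaussian noise has sd ``noise_sd`` x pulse amplitude.
    """
    if truth.n_beats == 0:
        raise ValueError("ground truth contains no beats")
    if fs_hz < 25:
        raise ValueError("PPG sampling rate must be at least 25 Hz")
    if truth.nni.size and pulse_width_s * 1000.0 >= truth.nni.min():
        raise ValueError("pulse width must be below the shortest NN interval")
    n = int(round(truth.duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    values = _pulse_waveform(t, truth.beat_times, pulse_width_s)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=n)
    return Signal(values=values, fs=fs_hz)


def synthesize_face_video(
    truth: RRGroundTruth,
    fps: float = 30.0,
    width: int = 64,
    height: int = 64,
    roi: ROIBox | None = None,
    modulation_depth: float = 0.01,
    noise_sd: float = 0.0,
    pulse_width_s: float = 0.12,
    seed: int | None = None,
    quantize_8bit: bool = False,
    ppg_fs: float = 100.0,
    ppg_noise_sd: float = 0.0,
) -> SynthStudy:
    """Paired study: a video whose skin patch pulses with the RR ground truth.

    The background is static mid-gray; inside ``roi`` a skin-tone patch has
    its red channel modulated multiplicatively,

        red(t) = base_red * (1 + modulation_depth * pulse(t)) + noise,

    with ``pulse`` the same Gaussian-bump train the PPG uses (smoothed wider,
    since video samples at the frame rate).  Frames are float32 in [0, 1] by
    default so percent-level modulations stay representable; ``quantize_8bit``
    rounds to uint8 to emulate a real camera.  A matching PPG trace is
    generated from the same truth and returned alongside.
    """
    if not (0 < modulation_depth <= 0.1):
        raise ValueError("modulation depth must lie in (0, 0.1]")
    if roi is None:
        roi = ROIBox(x=width // 4, y=height // 4, w=width // 2, h=height // 2)
    if not roi.inside(height, width):
        raise ValueError(f"ROI {roi} does not fit a {width}x{height} frame")

    n_frames = int(round(fps * truth.duration_s))
    t = np.arange(n_frames) / fps
    pulse = _pulse_waveform(t, truth.beat_times, pulse_width_s).astype(np.float32)

    background = np.float32(0.5)
    skin = np.array([0.80, 0.60, 0.50], dtype=np.float32)  # RGB skin tone

    frames = np.full((n_frames, height, width, 3), background, dtype=np.float32)
    frames[:, roi.y:roi.y + roi.h, roi.x:roi.x + roi.w, :] = skin
    red = skin[0] * (1.0 + modulation_depth * pulse)
    frames[:, roi.y:roi.y + roi.h, roi.x:roi.x + roi.w, 0] = red[:, None, None]
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        frames += rng.standard_normal(frames.shape, dtype=np.float32) * np.float32(noise_sd)
    if quantize_8bit:
        frames = np.clip(np.round(frames * 255.0), 0, 255).astype(np.uint8)

    video = FrameStack(frames=frames, fps=fps, channel_order="RGB")
    ppg_seed = None if seed is None else seed + 1
    ppg = synthesize_ppg(truth, fs_hz=ppg_fs, noise_sd=ppg_noise_sd, seed=ppg_seed)
    return SynthStudy(truth=truth, ppg=ppg, video=video, roi_truth=roi,
                      fps=fps, ppg_fs=ppg_fs)


def write_study(study: SynthStudy, out_dir: str | Path) -> Path:
    """Serialize a study: frames (PNG dir or .npy), ppg.csv, truth.json, roi.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_frames(study.video, out / ("frames" if study.video.frames.dtype == np.uint8 else "frames.npy"))
    times = study.ppg.times
    with open(out / "ppg.csv", "w") as fh:
        fh.write("time_s,amplitude\n")
        for ti, vi in zip(times, study.ppg.values):
            fh.write(f"{ti:.6f},{vi:.8g}\n")
    truth = {
        "beat_times": study.truth.beat_times.tolist(),
        "nni_ms": study.truth.nni.tolist(),
        "params": study.truth.params,
        "fps": study.fps,
        "ppg_fs": study.ppg_fs,
    }
    (out / "truth.json").write_text(json.dumps(truth))
    write_roi(study.roi_truth, out / "roi.json")
    return out
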