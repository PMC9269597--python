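"""Eulerian color magnification.

Amplifies subtle pulse-synchronous color changes: the clip is spatially
low-passed by a Gaussian pyramid, each spatial location of the coarse level
is temporally band-passed around the heart band, the band is scaled by
``alpha`` (and per-channel gains), upsampled back to full resolution and
added to the original frames.  Processing stays in RGB because the pipeline
only consumes the red channel afterwards; the temporal filter is an ideal
(brick-wall) FFT filter applied over the whole clip, which suits this
offline, batch-processed pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .video import FrameStack

__all__ = ["EVMParams", "temporal_ideal_bandpass", "magnify_color"]


@dataclass
class EVMParams:
    """Color-magnification settings.

    alpha
        Dimensionless amplification of the temporal band (default 50).
    level
        Gaussian-pyramid depth; each level halves H and W (default 4).
    f_lo, f_hi
        Temporal passband in Hz; the default 0.67-3.0 Hz covers 40-180 bpm.
    channel_gains
        Per-channel multipliers applied to the amplified band.
    """

    alpha: float = 50.0
    level: int = 4
    f_lo: float = 0.67
    f_hi: float = 3.0
    channel_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def validate(self, fps: float, height: int, width: int) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not (0 <= self.f_lo < self.f_hi <= fps / 2.0):
            raise ValueError(
                f"band [{self.f_lo}, {self.f_hi}] Hz invalid for fps={fps}"
            )
        if self.level < 0 or 2 ** self.level > min(height, width):
            raise ValueError(
                f"pyramid level {self.level} too deep for {height}x{width} frames"
            )


def temporal_ideal_bandpass(
    series: np.ndarray, fps: float, f_lo: float, f_hi: float, axis: int = 0
) -> np.ndarray:
    """Ideal (brick-wall) temporal band-pass along ``axis``.

    Fourier coefficients with ``f_lo <= |f| <= f_hi`` are kept, all others
    (including DC) zeroed; the output is real with the input's shape.
    """
    series = np.asarray(series)
    n = series.shape[axis]
    if n < 4:
        raise ValueError("need at least 4 time samples")
    if not (0 <= f_lo < f_hi <= fps / 2.0):
        raise ValueError(f"band [{f_lo}, {f_hi}] Hz outside [0, Nyquist={fps / 2}]")
    freqs = np.fft.rfftfreq(n, d=1.0 / fps)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    spec = np.fft.rfft(series, axis=axis)
    shape = [1] * series.ndim
    shape[axis] = mask.size
    spec = spec * mask.reshape(shape)
    out = np.fft.irfft(spec, n=n, axis=axis)
    return out.astype(series.dtype) if np.issubdtype(series.dtype, np.floating) else out


def _pyramid_down(stack: np.ndarray, level: int) -> np.ndarray:
    """`level` steps of Gaussian blur + 2x decimation on the spatial axes."""
    out = stack
    for _ in range(level):
        out = ndi.gaussian_filter(out, sigma=(0, 1.0, 1.0, 0), mode="reflect")
        out = out[:, ::2, ::2, :]
    return out


def _upsample_to(stack: np.ndarray, height: int, width: int) -> np.ndarray:
    """Bilinear resize of the spatial axes to exactly (height, width)."""
    zoom = (1.0, height / stack.shape[1], width / stack.shape[2], 1.0)
    return ndi.zoom(stack, zoom, order=1, mode="nearest", grid_mode=True)


def magnify_color(frames: FrameStack, params: EVMParams | None = None) -> FrameStack:
    """Add the amplified temporal band back onto the clip.

    output = input + alpha * gains * upsample(bandpass(pyr_down(input, level)))

    Shape, fps and channel order are preserved.  Integer input is promoted to
    float32 (the amplified band is fractional); float input keeps its dtype.
    """
    if params is None:
        params = EVMParams()
    H, W = frames.shape
    params.validate(frames.fps, H, W)
    if frames.duration_s < 2.0 / max(params.f_lo, 1e-9):
        import warnings

        warnings.warn(
            "clip shorter than two periods of f_lo; band estimate will be poor",
            stacklevel=2,
        )
    x = frames.frames
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float32)
    coarse = _pyramid_down(x, params.level)
    band = temporal_ideal_bandpass(coarse, frames.fps, params.f_lo, params.f_hi, axis=0)
    del coarse
    gains = np.asarray(params.channel_gains, dtype=x.dtype).reshape(1, 1, 1, 3)
    band = band * (params.alpha * gains)
    band = _upsample_to(band, H, W)
    out = x + band.astype(x.dtype)
    return FrameStack(frames=out, fps=frames.fps, t0=frames.t0,
                      channel_order=frames.channel_order)
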