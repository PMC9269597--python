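"""Frame I/O, face detection and ROI stabilization.

The face is located per frame with a Viola-Jones-style boosted cascade
(scikit-image's ``Cascade`` with its bundled frontal-face model).  Raw
detections jitter by a few pixels even on a static face, so the track is
stabilized: the committed box only moves when the raw box center translates
by at least a threshold.  All coordinates are 0-based, half-open, origin at
the top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "FrameStack",
    "ROIBox",
    "ROITrack",
    "load_frames",
    "write_frames",
    "detect_face_track",
    "stabilize_track",
    "crop_to_roi",
    "default_cascade_file",
]


@dataclass
class FrameStack:
    """Ordered video frames with explicit frame rate and channel order."""

    frames: np.ndarray  # (T, H, W, 3)
    fps: float
    t0: float = 0.0
    channel_order: str = "RGB"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (T, H, W, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("need at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if len(self.channel_order) != 3:
            raise ValueError("channel_order must name three channels")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of one frame."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass(frozen=True)
class ROIBox:
    """Half-open pixel box [x, x+w) x [y, y+h), origin top-left."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("ROI width and height must be positive")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def inside(self, height: int, width: int) -> bool:
        return 0 <= self.x and 0 <= self.y and self.x + self.w <= width and self.y + self.h <= height

    def intersects(self, height: int, width: int) -> bool:
        return self.x < width and self.y < height and self.x + self.w > 0 and self.y + self.h > 0

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "w": self.w, "h": self.h}

    @classmethod
    def from_dict(cls, d: dict) -> "ROIBox":
        return cls(x=int(d["x"]), y=int(d["y"]), w=int(d["w"]), h=int(d["h"]))


@dataclass
class ROITrack:
    """One ROI box per frame, plus whether the detector actually fired."""

    boxes: list[ROIBox]
    source: str = "auto"  # "auto" (cascade) or "fixed"
    detector_hits: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.boxes:
            raise ValueError("track must contain at least one box")
        if self.detector_hits is None:
            self.detector_hits = np.ones(len(self.boxes), dtype=bool)
        self.detector_hits = np.asarray(self.detector_hits, dtype=bool)
        if self.detector_hits.size != len(self.boxes):
            raise ValueError("detector_hits length must match boxes")

    def __len__(self) -> int:
        return len(self.boxes)


def default_cascade_file() -> str:
    """Path of the bundled frontal-face cascade model."""
    from skimage import data as skdata

    return skdata.lbp_frontal_face_cascade_filename()


def load_frames(path: str | Path, fps: float, channel_order: str = "RGB") -> FrameStack:
    """Load a frame stack from a PNG directory, an ``.npy`` stack or a video file.

    A directory is read as a lexicographically ordered image sequence; an
    ``.npy`` file as a lossless (T, H, W, 3) array; anything else is handed to
    imageio (requires a backend able to decode the container).
    """
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"})
        if not files:
            raise ValueError(f"no image frames found in {path}")
        imgs = [np.asarray(iio.imread(f)) for f in files]
        shapes = {im.shape for im in imgs}
        if len(shapes) != 1:
            raise ValueError(f"mixed frame sizes in {path}: {sorted(shapes)}")
        frames = np.stack(imgs, axis=0)
        if frames.ndim == 3:  # grayscale sequence
            frames = np.repeat(frames[..., None], 3, axis=-1)
    elif path.suffix == ".npy":
        frames = np.load(path)
    else:
        try:
            frames = np.asarray(iio.imread(path, plugin=None))
        except Exception as exc:  # pragma: no cover - backend-dependent
            raise ValueError(f"cannot decode video file {path}: {exc}") from exc
    return FrameStack(frames=frames, fps=fps, channel_order=channel_order)


def write_frames(stack: FrameStack, path: str | Path) -> Path:
    """Write a stack losslessly: PNG sequence for uint8, ``.npy`` otherwise.

    Returns the path written.  ``load_frames`` of the result round-trips
    pixel-exactly.
    """
    import imageio.v3 as iio

    path = Path(path)
    if stack.frames.dtype == np.uint8 and path.suffix == "":
        path.mkdir(parents=True, exist_ok=True)
        width = len(str(stack.n_frames - 1))
        for i in range(stack.n_frames):
            iio.imwrite(path / f"frame_{i:0{width}d}.png", stack.frames[i])
        return path
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path, stack.frames)
    return path


def _select_box(detections: list[dict]) -> ROIBox | None:
    """Largest-area detection wins; None when the detector found nothing."""
    if not detections:
        return None
    best = max(detections, key=lambda d: d["width"] * d["height"])
    return ROIBox(x=int(best["c"]), y=int(best["r"]), w=int(best["width"]), h=int(best["height"]))


def detect_face_track(
    frames: FrameStack,
    cascade_file: str | None = None,
    min_size: tuple[int, int] = (24, 24),
    max_size: tuple[int, int] | None = None,
    scale_factor: float = 1.2,
    step_ratio: float = 1.0,
) -> ROITrack:
    """Run the cascade face detector on every frame.

    Frames with no detection carry the last successful box forward; leading
    frames before the first hit borrow the first successful box.  When a frame
    yields several detections the largest-area box is kept.  Raises if no face
    is found in any frame.
    """
    from skimage.feature import Cascade

    if cascade_file is None:
        cascade_file = default_cascade_file()
    cascade = Cascade(cascade_file)
    h, w = frames.shape
    if max_size is None:
        max_size = (h, w)

    img = frames.frames
    if img.dtype != np.uint8:
        img = np.clip(img, 0.0, 1.0) if img.max() <= 1.0 else img / img.max()
        img = (np.asarray(img, dtype=float) * 255).astype(np.uint8)

    raw: list[ROIBox | None] = []
    hits = np.zeros(frames.n_frames, dtype=bool)
    for t in range(frames.n_frames):
        dets = cascade.detect_multi_scale(
            img=img[t],
            scale_factor=scale_factor,
            step_ratio=step_ratio,
            min_size=min_size,
            max_size=max_size,
        )
        box = _select_box(list(dets))
        raw.append(box)
        hits[t] = box is not None

    if not hits.any():
        raise ValueError("no face detected in any frame; cannot build an ROI track")

    first = next(b for b in raw if b is not None)
    boxes: list[ROIBox] = []
    last = first
    for box in raw:
        if box is not None:
            last = box
        boxes.append(last)
    return ROITrack(boxes=boxes, source="auto", detector_hits=hits)


def fixed_track(box: ROIBox, n_frames: int) -> ROITrack:
    """Constant ROI track (configured box, no detector)."""
    return ROITrack(boxes=[box] * n_frames, source="fixed",
                    detector_hits=np.zeros(n_frames, dtype=bool))


def stabilize_track(track: ROITrack, translation_threshold_px: float = 10.0) -> ROITrack:
    """Suppress sub-threshold ROI motion.

    The committed box changes only when the raw box center has moved at least
    ``translation_threshold_px`` (Euclidean) from the committed center, in
    which case the raw box position is adopted.  Box size is frozen to the
    first committed box, so downstream crops are shape-stable.
    """
    if translation_threshold_px < 0:
        raise ValueError("threshold must be non-negative")
    first = track.boxes[0]
    w0, h0 = first.w, first.h
    committed = first
    out: list[ROIBox] = []
    for raw in track.boxes:
        cx, cy = raw.center
        ox, oy = committed.center
        if np.hypot(cx - ox, cy - oy) >= translation_threshold_px and raw is not committed:
            # adopt the raw position but keep the frozen size, centered alike
            committed = ROIBox(
                x=int(round(cx - w0 / 2.0)), y=int(round(cy - h0 / 2.0)), w=w0, h=h0
            )
        out.append(committed)
    return ROITrack(boxes=out, source=track.source, detector_hits=track.detector_hits)


def crop_to_roi(frames: FrameStack, track: ROITrack) -> FrameStack:
    """Crop every frame to its (frozen-size) ROI box.

    Boxes are clamped to the frame bounds; any clamped-away margin is refilled
    by edge replication so every output frame has the frozen box shape.
    """
    if len(track) != frames.n_frames:
        raise ValueError("track length must match frame count")
    H, W = frames.shape
    w0, h0 = track.boxes[0].w, track.boxes[0].h
    out = np.empty((frames.n_frames, h0, w0, 3), dtype=frames.frames.dtype)
    for t, box in enumerate(track.boxes):
        if not box.intersects(H, W):
            raise ValueError(f"ROI box at frame {t} lies fully outside the frame")
        x0, x1 = max(box.x, 0), min(box.x + box.w, W)
        y0, y1 = max(box.y, 0), min(box.y + box.h, H)
        patch = frames.frames[t, y0:y1, x0:x1]
        pad_top = y0 - box.y
        pad_bot = box.h - patch.shape[0] - pad_top
        pad_left = x0 - box.x
        pad_right = box.w - patch.shape[1] - pad_left
        if pad_top or pad_bot or pad_left or pad_right:
            patch = np.pad(
                patch,
                ((max(pad_top, 0), max(pad_bot, 0)),
                 (max(pad_left, 0), max(pad_right, 0)),
                 (0, 0)),
                mode="edge",
            )
        out[t] = patch[:h0, :w0]
    return FrameStack(frames=out, fps=frames.fps, t0=frames.t0,
                      channel_order=frames.channel_order)


def write_roi(box: ROIBox, path: str | Path) -> None:
    Path(path).write_text(json.dumps(box.to_dict()))


def read_roi(path: str | Path) -> ROIBox:
    return ROIBox.from_dict(json.loads(Path(path).read_text()))
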