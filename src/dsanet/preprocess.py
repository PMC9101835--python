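"""Video ingestion and key-frame preprocessing.

The pipeline mirrors clinical practice for contrast angiography video:
strip the black acquisition border, min-max normalize, resample to the
model resolution, pick the peak-opacification frame as the key frame, and
assemble the temporal window used for temporal-difference supervision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
from scipy import ndimage

from .avi import read_avi

MODEL_SIZE = 256
TDL_FRAMES = 10
#: border threshold as a fraction of the frame's dynamic range (tolerates
#: compression noise in nominally black borders)
BORDER_THRESHOLD_FRAC = 2.0 / 255.0


class VideoFormatError(ValueError):
    """Raised when an input video violates the format contract."""


@dataclass
class DsaVideo:
    """Ordered grayscale frame stack for one acquisition."""

    patient_id: str
    frames: np.ndarray  # (T, H, W) float32
    fov_scale: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise VideoFormatError("frames must be a (T, H, W) stack")
        if self.frame_count < 3:
            raise VideoFormatError(
                f"video {self.patient_id!r} has {self.frame_count} frames; need >= 3"
            )
        if not np.all(np.isfinite(self.frames)):
            raise VideoFormatError("frame intensities must be finite")

    @property
    def frame_count(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


@dataclass
class KeyFrameBundle:
    """Key frame plus the auxiliary inputs derived from its video."""

    key_index: int
    key_frame: np.ndarray               # (S, S) in [0, 1]
    aug_frames: tuple[np.ndarray, np.ndarray]  # key_index - 1, key_index + 1
    tdl_window: np.ndarray              # (TDL_FRAMES, S, S) in [0, 1]
    fd_map: np.ndarray                  # (S, S) >= 0, frame-difference target


@dataclass
class MaskImage:
    """Binary mask with an optional connected-component labelling."""

    role: str  # tumor_gt | liver_gt | tumor_pred | liver_pred
    pixels: np.ndarray
    lesion_components: list[np.ndarray] | None = field(default=None)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if not np.isin(px, (0, 1)).all():
            raise ValueError("mask pixels must be binary")
        self.pixels = px.astype(np.uint8)


def load_video(path, fmt: str | None = None, patient_id: str | None = None,
               fov_scale: float = 1.0) -> DsaVideo:
    """Load an AVI file or an ordered PNG frame stack directory.

    PNG stacks are ordered by sorted file name.  ``fmt`` is inferred from
    the path when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"video input not found: {path}")
    if fmt is None:
        fmt = "png_stack" if path.is_dir() else "avi"
    pid = patient_id or path.stem

    if fmt == "avi":
        try:
            stack = read_avi(path).astype(np.float32)
        except ValueError as e:
            raise VideoFormatError(str(e)) from e
    elif fmt == "png_stack":
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {path}")
        frames = []
        for f in files:
            img = np.asarray(imageio.imread(f))
            if img.ndim == 3:
                img = img[..., 0]
            frames.append(img.astype(np.float32))
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise VideoFormatError(
                f"inconsistent frame sizes in {path}: {sorted(shapes)}"
            )
        stack = np.stack(frames)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return DsaVideo(patient_id=pid, frames=stack, fov_scale=fov_scale)


def remove_black_border(frame: np.ndarray) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Crop rows/columns that are entirely black border.

    A 3×3 median filter suppresses isolated noise first; a row/column is
    border when every filtered pixel falls below a small fraction of the
    frame's dynamic range.  Returns the cropped frame and the half-open
    crop box ``(r0, r1, c0, c1)`` so the identical crop can be applied to
    paired masks.
    """
    frame = np.asarray(frame, dtype=np.float32)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame must be finite")
    filt = ndimage.median_filter(frame, size=3)
    lo, hi = float(filt.min()), float(filt.max())
    if hi <= lo:  # constant frame: all black is degenerate, else no border
        if lo == 0.0:
            raise ValueError("border removal would leave an empty image")
        return frame.copy(), (0, frame.shape[0], 0, frame.shape[1])
    thr = lo + BORDER_THRESHOLD_FRAC * (hi - lo)
    dark_rows = np.all(filt <= thr, axis=1)
    dark_cols = np.all(filt <= thr, axis=0)

    def leading(run: np.ndarray) -> int:
        idx = np.flatnonzero(~run)
        return int(idx[0]) if idx.size else len(run)

    r0, r1 = leading(dark_rows), len(dark_rows) - leading(dark_rows[::-1])
    c0, c1 = leading(dark_cols), len(dark_cols) - leading(dark_cols[::-1])
    if r0 >= r1 or c0 >= c1:
        raise ValueError("border removal would leave an empty image")
    return frame[r0:r1, c0:c1], (r0, r1, c0, c1)


def apply_crop(image: np.ndarray, box: tuple[int, int, int, int]) -> np.ndarray:
    r0, r1, c0, c1 = box
    return image[r0:r1, c0:c1]


def normalize_minmax(frame: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; a constant frame maps to all zeros."""
    frame = np.asarray(frame, dtype=np.float32)
    lo, hi = float(frame.min()), float(frame.max())
    if hi == lo:
        return np.zeros_like(frame)
    return (frame - lo) / (hi - lo)


def resize_to_model(frame: np.ndarray, size: int = MODEL_SIZE,
                    is_mask: bool = False) -> np.ndarray:
    """Resample to ``size``×``size``: bilinear for intensity, nearest for masks."""
    frame = np.asarray(frame)
    h, w = frame.shape
    if (h, w) == (size, size):
        out = frame.astype(np.uint8 if is_mask else np.float32).copy()
        return out
    if is_mask:
        ri = np.minimum((np.arange(size) + 0.5) * h / size, h - 1).astype(np.intp)
        ci = np.minimum((np.arange(size) + 0.5) * w / size, w - 1).astype(np.intp)
        out = frame[np.ix_(ri, ci)]
        return (np.asarray(out, dtype=np.float32) >= 0.5).astype(np.uint8)
    rows = (np.arange(size) + 0.5) * h / size - 0.5
    cols = (np.arange(size) + 0.5) * w / size - 0.5
    grid = np.meshgrid(rows, cols, indexing="ij")
    out = ndimage.map_coordinates(
        frame.astype(np.float32), np.stack(grid), order=1, mode="nearest"
    )
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def preprocess_video(video: DsaVideo, size: int = MODEL_SIZE
                     ) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Full frame pipeline: crop border, normalize, resize every frame.

    The crop box is detected on the temporal-maximum image so that every
    frame (including the near-empty pre-contrast baseline) receives the
    same crop.  Min-max normalization uses the video-global minimum and
    maximum: one linear map for the whole stack, which preserves the
    relative opacification of frames (per-frame scaling would stretch the
    dark baseline to full range and break key-frame selection).
    Returns the (T, size, size) stack and the crop box.
    """
    stamp = video.frames.max(axis=0)
    _, box = remove_black_border(stamp)
    cropped = np.stack([apply_crop(f, box) for f in video.frames])
    lo, hi = float(cropped.min()), float(cropped.max())
    if hi > lo:
        cropped = (cropped - lo) / (hi - lo)
    else:
        cropped = np.zeros_like(cropped)
    frames = np.stack([resize_to_model(f, size=size) for f in cropped])
    return frames, box


def select_key_frame(frames: np.ndarray) -> int:
    """Index of peak opacification: argmax of mean |frame_t - frame_0|.

    Ties break to the lowest index.  Expects preprocessed frames.
    """
    frames = np.asarray(frames, dtype=np.float32)
    if frames.shape[0] < 3:
        raise VideoFormatError("need at least 3 frames")
    dev = np.abs(frames - frames[0]).mean(axis=(1, 2))
    return int(np.argmax(dev))


def build_key_frame_bundle(frames: np.ndarray, key_index: int) -> KeyFrameBundle:
    """Assemble the key frame, ±1 augmentation frames, the temporal window
    ending at the key frame (clamp-padded with frame 0), and the mean
    consecutive-frame-difference target."""
    frames = np.asarray(frames, dtype=np.float32)
    T = frames.shape[0]
    if not 0 <= key_index < T:
        raise IndexError(f"key_index {key_index} out of range for T={T}")
    prev_i = max(key_index - 1, 0)
    next_i = min(key_index + 1, T - 1)
    window_idx = [max(i, 0) for i in range(key_index - TDL_FRAMES + 1, key_index + 1)]
    window = frames[window_idx]
    fd_map = np.abs(np.diff(window, axis=0)).mean(axis=0)
    return KeyFrameBundle(
        key_index=int(key_index),
        key_frame=frames[key_index],
        aug_frames=(frames[prev_i], frames[next_i]),
        tdl_window=window,
        fd_map=fd_map.astype(np.float32),
    )


def preprocess_and_bundle(video: DsaVideo, size: int = MODEL_SIZE
                          ) -> tuple[KeyFrameBundle, tuple[int, int, int, int]]:
    """Convenience: preprocess, select key frame, and bundle in one call."""
    frames, box = preprocess_video(video, size=size)
    key = select_key_frame(frames)
    return build_key_frame_bundle(frames, key), box


def preprocess_mask(mask: np.ndarray, box: tuple[int, int, int, int],
                    size: int = MODEL_SIZE) -> np.ndarray:
    """Apply a frame's crop box to its paired mask and resize (nearest)."""
    return resize_to_model(apply_crop(np.asarray(mask), box), size=size, is_mask=True)
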