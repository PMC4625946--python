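"""Video input/output: frame sequences, luminance conversion, track artifacts.

The whole pipeline works on a :class:`VideoCube`, a grayscale intensity volume
``I(x, y, t)`` with values in [0, 255].  Frames are stored frame-major
(``intensities[t]`` is the ``t``-th frame as a (rows, cols) array); all public
coordinates follow the image convention x = column, y = row, 0-based.

RGB input is reduced to YIQ luminance ``Y = 0.299 R + 0.587 G + 0.114 B``
(classic NTSC coefficients), rounded half-up — the glottis is located purely
from luminance, chroma carries no extra information for the dark gap.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "VideoCube",
    "GlottisTrack",
    "InputError",
    "FormatError",
    "rgb_to_luminance",
    "load_sequence",
    "write_track",
    "read_track",
]

_IMAGE_EXTENSIONS = {".png", ".tif", ".tiff"}
_VIDEO_EXTENSIONS = {".avi", ".mpg", ".mpeg", ".mp4"}


class InputError(ValueError):
    """Missing or undecodable input."""


class FormatError(ValueError):
    """Structurally invalid input (e.g. inconsistent frame shapes)."""


@dataclass
class VideoCube:
    """Grayscale intensity volume I(x, y, t).

    Parameters
    ----------
    intensities
        Array of shape ``(T, n_rows, m_cols)`` with values in [0, 255].
    frame_rate
        Acquisition rate in frames per second (> 0).
    """

    intensities: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or self.intensities.shape[0] < 1:
            raise FormatError("intensities must be a (T, rows, cols) stack with T >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        lo, hi = float(self.intensities.min()), float(self.intensities.max())
        if lo < 0 or hi > 255:
            raise ValueError(f"intensities out of [0, 255]: [{lo}, {hi}]")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(n rows, m columns)."""
        return self.intensities.shape[1:]

    def frame(self, t: int) -> np.ndarray:
        return self.intensities[t]


@dataclass
class GlottisTrack:
    """Per-frame binary glottal masks plus the glottal area waveform (GAW).

    ``areas[t]`` always equals ``masks[t].sum()``; ``roi_trace[t]`` is the ROI
    window that was active when frame ``t`` was segmented (may be ``None`` for
    tracks built outside the pipeline).
    """

    masks: np.ndarray  # (T, rows, cols) bool
    roi_trace: Sequence = field(default_factory=list)

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks).astype(bool)
        if self.masks.ndim != 3:
            raise FormatError("masks must be a (T, rows, cols) stack")

    @property
    def areas(self) -> np.ndarray:
        """Glottal area waveform: pixel count per frame."""
        return self.masks.reshape(self.masks.shape[0], -1).sum(axis=1)

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def rgb_to_luminance(frame: np.ndarray) -> np.ndarray:
    """YIQ luminance of an RGB frame, rounded half-up to uint8.

    Grayscale input (2-D) passes through unchanged.
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame.astype(np.uint8)
    if frame.ndim == 3 and frame.shape[2] >= 3:
        y = (0.299 * frame[..., 0].astype(float)
             + 0.587 * frame[..., 1].astype(float)
             + 0.114 * frame[..., 2].astype(float))
        return np.clip(_round_half_up(y), 0, 255).astype(np.uint8)
    raise FormatError(f"cannot interpret frame of shape {frame.shape}")


_NATURAL_RE = re.compile(r"(\d+)")


def _natural_key(name: str):
    return [int(p) if p.isdigit() else p for p in _NATURAL_RE.split(name)]


def _list_frame_files(directory: Path) -> list[Path]:
    files = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in _IMAGE_EXTENSIONS)
    if not files:
        raise InputError(f"no PNG/TIFF frames found in {directory}")
    digit_runs = [re.findall(r"\d+", p.stem) for p in files]
    widths = {len(r[-1]) for r in digit_runs if r}
    if len(widths) > 1:
        # zero padding inconsistent: lexicographic order would interleave
        warnings.warn(
            "frame names are not zero-padded; falling back to natural sort",
            stacklevel=3,
        )
        files = sorted(files, key=lambda p: _natural_key(p.name))
    return files


def load_sequence(path: str | Path, frame_rate: float) -> VideoCube:
    """Read an image-sequence directory or a video container into a VideoCube.

    Directories must hold >= 1 decodable PNG/TIFF frame; frames are ordered
    lexicographically (zero-padded names expected, natural-sort fallback with
    a warning otherwise).  RGB frames are converted to YIQ luminance.
    """
    path = Path(path)
    if path.is_dir():
        files = _list_frame_files(path)
        frames = []
        for f in files:
            try:
                frames.append(rgb_to_luminance(iio.imread(f)))
            except (OSError, ValueError) as exc:
                raise InputError(f"cannot decode frame {f}: {exc}") from exc
    elif path.is_file() and path.suffix.lower() in _VIDEO_EXTENSIONS:
        try:
            raw = iio.imread(path)
        except (OSError, ValueError) as exc:
            raise InputError(f"cannot decode video {path}: {exc}") from exc
        if raw.ndim == 2:
            raw = raw[None]
        frames = [rgb_to_luminance(fr) for fr in raw]
    else:
        raise InputError(f"no decodable input at {path}")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise FormatError(f"inconsistent frame shapes: {sorted(shapes)}")
    return VideoCube(np.stack(frames), frame_rate=frame_rate)


def write_track(track: GlottisTrack, out_dir: str | Path,
                manifest: dict | None = None) -> None:
    """Write one PNG mask per frame, the GAW CSV, and a JSON run manifest.

    CSV header is ``frame,area_px,roi_x0,roi_x1,roi_y0,roi_y1``; ROI columns
    are -1 when no window is attached to a frame.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(track.n_frames - 1)))
        rows = []
        for t in range(track.n_frames):
            mask = (track.masks[t].astype(np.uint8)) * 255
            iio.imwrite(out_dir / f"mask_{t:0{width}d}.png", mask)
            roi = track.roi_trace[t] if t < len(track.roi_trace) else None
            if roi is None:
                x0 = x1 = y0 = y1 = -1
            else:
                x0, x1, y0, y1 = roi.x_cl, roi.x_cr, roi.y_cu, roi.y_cd
            rows.append((t, int(track.masks[t].sum()), x0, x1, y0, y1))
        pd.DataFrame(
            rows, columns=["frame", "area_px", "roi_x0", "roi_x1", "roi_y0", "roi_y1"]
        ).to_csv(out_dir / "gaw.csv", index=False)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest or {}, fh, indent=2, default=str)
    except OSError as exc:
        raise IOError(f"cannot write track to {out_dir}: {exc}") from exc


def read_track(out_dir: str | Path) -> GlottisTrack:
    """Read back a mask sequence written by :func:`write_track`."""
    out_dir = Path(out_dir)
    files = sorted(out_dir.glob("mask_*.png"))
    if not files:
        raise InputError(f"no mask PNGs in {out_dir}")
    masks = np.stack([iio.imread(f) > 127 for f in files])
    return GlottisTrack(masks)
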