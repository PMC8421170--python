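"""Frame-sequence input/output and track tables.

Conventions shared by every module in the package: coordinates are 0-based
pixel centres with ``x`` the column index and ``y`` the row index, origin at
the top-left; frames are single-channel 8-bit rasters.

The physical pixel scale defaults to 0.2 um/px (a plausible value for a
x400 bright-field setup with a small-sensor camera). It multiplies every
velocity the package reports, so it should be calibrated per instrument and
passed explicitly whenever known.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PIXEL_SCALE_UM",
    "FrameSequence",
    "read_frames",
    "write_frames",
    "write_mask",
    "write_tracks",
    "read_tracks",
]

#: Default micrometres per pixel. Overridable everywhere it is used.
DEFAULT_PIXEL_SCALE_UM = 0.2

#: Luma weights (ITU-R BT.601) for collapsing colour input to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])

_FRAME_EXTENSIONS = (".png", ".tif", ".tiff")

#: Column schema of the flat track table written by :func:`write_tracks`.
TRACK_COLUMNS = ["track_id", "frame", "x", "y", "area", "velocity_um_s"]


@dataclass
class FrameSequence:
    """An ordered stack of grayscale frames with acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``, dtype ``uint8``.
    fps
        Acquisition frame rate in frames per second.
    pixel_scale_um
        Physical size of one pixel in micrometres.
    """

    frames: np.ndarray
    fps: float
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) stack")
        if self.frames.size == 0:
            raise ValueError("frame sequence is empty")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.pixel_scale_um <= 0:
            raise ValueError("pixel_scale_um must be positive")
        if self.frames.dtype != np.uint8:
            self.frames = np.clip(np.round(self.frames), 0, 255).astype(np.uint8)

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, index) -> np.ndarray:
        return self.frames[index]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each frame."""
        return self.frames.shape[1:]


def _to_gray_u8(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:  # H x W x channels
        if img.shape[2] == 4:
            img = img[..., :3]
        img = img @ _LUMA
    if img.dtype != np.uint8:
        img = np.clip(np.round(img.astype(float)), 0, 255).astype(np.uint8)
    return img


def read_frames(
    path: str | os.PathLike,
    fps_override: float | None = None,
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
) -> FrameSequence:
    """Read a frame sequence from a video container or a frame directory.

    A directory is read as lexicographically ordered PNG/TIFF frames (the
    package's lossless interchange format); anything else is handed to
    imageio, which covers AVI/MP4 when an ffmpeg plugin is available.
    Colour input is collapsed to grayscale with the standard luma weights.

    ``fps_override`` takes precedence over container metadata; directories
    carry no rate, so it is required for them (default 1 fps otherwise).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS
        )
        if not files:
            raise ValueError(f"no PNG/TIFF frames found in {path}")
        frames = [_to_gray_u8(iio.imread(p)) for p in files]
        fps = fps_override if fps_override is not None else 1.0
    else:
        raw = iio.imread(path)  # (n, H, W[, C]) for multi-frame input
        if raw.ndim == 2:
            raw = raw[None]
        frames = [_to_gray_u8(f) for f in raw]
        fps = fps_override
        if fps is None:
            try:
                meta = iio.immeta(path)
                fps = float(meta.get("fps", 0)) or None
            except Exception:
                fps = None
        if fps is None:
            raise ValueError(f"no frame rate in {path} metadata; pass fps_override")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame sizes: {sorted(shapes)}")
    return FrameSequence(np.stack(frames), fps=fps, pixel_scale_um=pixel_scale_um)


def write_frames(seq: FrameSequence, directory: str | os.PathLike) -> list[Path]:
    """Write each frame as a zero-padded PNG; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(len(seq) - 1)))
    paths = []
    for i, frame in enumerate(seq.frames):
        p = directory / f"frame_{i:0{width}d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a binary mask as a 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def write_tracks(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a track table as CSV.

    Columns: ``track_id,frame,x,y,area,velocity_um_s``. Floats are printed
    with enough digits to round-trip; the first observation of a track has
    no step velocity and is written as an empty field.
    """
    table = table.loc[:, TRACK_COLUMNS]
    table.to_csv(path, index=False, float_format="%.9g")


def read_tracks(path: str | os.PathLike) -> pd.DataFrame:
    """Read a CSV written by :func:`write_tracks`."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    return df[TRACK_COLUMNS]
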