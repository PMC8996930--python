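"""Frame ingestion: video containers or image directories to 1-fps grayscale.

Pens are filmed by ceiling surveillance cameras at native rates around 30 fps;
the indices only need ~1 frame per second, so ingestion decimates by frame
skipping (select every ``floor(native/sample)``-th frame, no temporal
averaging). Coordinates are (row, col), 0-based; crop rectangles are half-open
``(row0, col0, row1, col1)``. Timestamps are derived from the sampled index and
rate — surveillance-container timestamps are not trusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v2 as imageio
import numpy as np

from .errors import (
    DimensionMismatchError,
    EmptySequenceError,
    FrameSourceError,
    ParameterError,
)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}

#: ITU-R BT.601 luminance weights used for all RGB→gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class FrameRecord:
    """One sampled grayscale frame.

    Attributes
    ----------
    index
        0-based position in the *sampled* sequence (after decimation).
    timestamp_s
        Seconds from session start, ``index / sample_rate_fps``.
    pixels
        2-D uint8 array of intensities in [0, 255].
    """

    index: int
    timestamp_s: float
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ParameterError(
                f"frame pixels must be 2-D, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ParameterError("frame must have positive dimensions")

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class FrameSequence:
    """An ordered, uniformly sampled sequence of grayscale frames."""

    frames: list[FrameRecord]
    sample_rate_fps: float
    crop_region: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.sample_rate_fps <= 0:
            raise ParameterError("sample_rate_fps must be positive")
        shapes = {f.pixels.shape for f in self.frames}
        if len(shapes) > 1:
            raise DimensionMismatchError(f"mixed frame shapes: {sorted(shapes)}")
        self.frames = sorted(self.frames, key=lambda f: f.index)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[FrameRecord]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> FrameRecord:
        return self.frames[i]

    @property
    def frame_shape(self) -> tuple[int, int]:
        if not self.frames:
            raise EmptySequenceError("sequence has no frames")
        return self.frames[0].pixels.shape  # type: ignore[return-value]

    def pixel_stack(self) -> np.ndarray:
        """All frames as one (n, h, w) uint8 array."""
        return np.stack([f.pixels for f in self.frames])

    def dump_png(self, directory: str | Path, prefix: str = "frame") -> list[Path]:
        """Write each frame as ``<prefix>_<index:06d>.png`` for audit."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for f in self.frames:
            p = directory / f"{prefix}_{f.index:06d}.png"
            imageio.imwrite(p, f.pixels)
            paths.append(p)
        return paths


def to_grayscale(color_frame: np.ndarray) -> np.ndarray:
    """Convert a 3-channel RGB frame to single-channel luminance.

    Uses the fixed BT.601 weighting ``0.299 R + 0.587 G + 0.114 B`` rounded to
    the nearest integer; a 2-D input is returned unchanged (already gray).
    """
    arr = np.asarray(color_frame)
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=False)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ParameterError(
            f"expected an (h, w, 3) color frame, got shape {arr.shape}"
        )
    luma = arr.astype(np.float64) @ np.asarray(LUMA_WEIGHTS)
    return np.clip(np.rint(luma), 0, 255).astype(np.uint8)


def _validate_crop(
    crop: tuple[int, int, int, int], shape: tuple[int, int]
) -> tuple[int, int, int, int]:
    r0, c0, r1, c1 = (int(v) for v in crop)
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ParameterError(
            f"crop region {crop} invalid for frame shape {shape}"
        )
    return r0, c0, r1, c1


def _apply_crop(
    pixels: np.ndarray, crop: tuple[int, int, int, int] | None
) -> np.ndarray:
    if crop is None:
        return pixels
    r0, c0, r1, c1 = _validate_crop(crop, pixels.shape[:2])
    return pixels[r0:r1, c0:c1]


def _list_frame_files(directory: Path) -> list[Path]:
    files = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    )
    return files


def _read_directory(
    directory: Path,
    step: int,
    crop_region: tuple[int, int, int, int] | None,
) -> list[np.ndarray]:
    files = _list_frame_files(directory)
    if not files:
        raise EmptySequenceError(f"no decodable frames in {directory}")
    frames: list[np.ndarray] = []
    shape: tuple[int, int] | None = None
    for path in files[::step]:
        try:
            raw = imageio.imread(path)
        except Exception as exc:  # noqa: BLE001 - surface the path
            raise FrameSourceError(f"cannot read frame image {path}") from exc
        gray = _apply_crop(to_grayscale(raw), crop_region)
        if shape is None:
            shape = gray.shape
        elif gray.shape != shape:
            raise DimensionMismatchError(
                f"frame {path} has shape {gray.shape}, expected {shape}"
            )
        frames.append(gray)
    return frames


def _read_video(
    path: Path,
    step: int,
    sample_rate_fps: float,
    native_fps: float | None,
    crop_region: tuple[int, int, int, int] | None,
) -> tuple[list[np.ndarray], int]:
    try:
        reader = imageio.get_reader(path)
    except Exception as exc:  # noqa: BLE001
        raise FrameSourceError(
            f"cannot open video {path}: no imageio backend could decode it"
        ) from exc
    with reader:
        if native_fps is None:
            meta = reader.get_meta_data()
            native_fps = float(meta.get("fps", 0) or 0)
            if native_fps <= 0:
                raise FrameSourceError(
                    f"video {path} reports no frame rate; pass native_fps"
                )
        step = max(1, math.floor(native_fps / sample_rate_fps))
        frames = [
            _apply_crop(to_grayscale(np.asarray(raw)), crop_region)
            for i, raw in enumerate(reader)
            if i % step == 0
        ]
    if not frames:
        raise EmptySequenceError(f"zero decodable frames in {path}")
    return frames, step


def read_frame_sequence(
    source: str | Path,
    sample_rate_fps: float = 1.0,
    crop_region: tuple[int, int, int, int] | None = None,
    native_fps: float | None = None,
) -> FrameSequence:
    """Read a video file or frame-image directory as a sampled gray sequence.

    Parameters
    ----------
    source
        Path to a video container or to a directory of image frames whose
        filenames sort into temporal order.
    sample_rate_fps
        Target rate after decimation. Must not exceed the native rate.
    crop_region
        Optional half-open (row0, col0, row1, col1) rectangle applied to
        every frame before analysis.
    native_fps
        Native capture rate. Required to decimate a directory (directories
        carry no rate metadata); for videos the container metadata is used
        when omitted.

    Returns
    -------
    FrameSequence
        Frames renumbered 0..N−1 with timestamps ``index / sample_rate_fps``.
    """
    source = Path(source)
    if not source.exists():
        raise FrameSourceError(f"frame source does not exist: {source}")
    if sample_rate_fps <= 0:
        raise ParameterError("sample_rate_fps must be positive")
    if native_fps is not None:
        if native_fps <= 0:
            raise ParameterError("native_fps must be positive")
        if sample_rate_fps > native_fps:
            raise ParameterError(
                f"sample rate {sample_rate_fps} fps exceeds native {native_fps} fps"
            )
    step = max(1, math.floor((native_fps or sample_rate_fps) / sample_rate_fps))

    if source.is_dir():
        grays = _read_directory(source, step, crop_region)
    else:
        grays, step = _read_video(
            source, step, sample_rate_fps, native_fps, crop_region
        )

    records = [
        FrameRecord(index=i, timestamp_s=i / sample_rate_fps, pixels=g)
        for i, g in enumerate(grays)
    ]
    return FrameSequence(
        frames=records, sample_rate_fps=sample_rate_fps, crop_region=crop_region
    )
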