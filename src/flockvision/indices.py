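"""Cluster and unrest indices and the camera proportionality factor.

Two per-frame statistics summarise flock behaviour from a top-view camera:

* **Cluster index** (crowding, dimensionless), per frame::

      CI(i) = 2 · Ā · √(h² + w²) / (P̄ · D̄ · (n_A − 1))

  where Ā, P̄ are the mean blob area and perimeter (pixels), D̄ the mean
  pairwise distance between blob centroids, n_A the number of blobs, and
  h, w the frame dimensions. Fewer, larger, closer blobs (birds huddling,
  hence merging) give a higher index. The source formula's typesetting
  admits two denominators — ``P̄·D̄·(n_A − 1)`` (default) and ``P̄·D̄·n_A``
  (``variant="nA_inverse"``) — and two radicals — the image diagonal
  √(h²+w²) (default, dimensionally consistent) or (h²+w²)
  (``diagonal=False``). Frames with n_A < 2 have no D̄ and are flagged
  invalid rather than assigned a value.

* **Unrest index** (movement, cm), per consecutive frame pair::

      UI(i, i−1) = k · max{ d_H(F(i), F(i−1)), d_H(F(i−1), F(i)) }

  the symmetric Hausdorff distance between the bird point sets of two
  frames one second apart, scaled by the camera factor k (cm/pixel),

      k = 2 · H · tan(α/2) / w_sensor

  with H the camera mount height (cm), α the lens opening angle and
  w_sensor the sensor length in pixels along the frame's largest dimension.

All computation here is pure: identical inputs and parameters give
bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import (
    DegenerateHistogramError,
    DimensionMismatchError,
    EmptyForegroundError,
    EmptySequenceError,
    InvalidFrameError,
    ParameterError,
)
from .io_frames import FrameSequence
from .segmentation import (
    FrameShapeSet,
    SegmentationParams,
    clean_mask,
    estimate_background,
    extract_shapes,
    lowpass_filter,
    segment_foreground,
)

ClusterVariant = Literal["nA_minus_1", "nA_inverse"]
PointMode = Literal["foreground_pixels", "centroids"]


@dataclass(frozen=True)
class CameraGeometry:
    """Ceiling-camera geometry and the derived cm-per-pixel factor.

    Parameters
    ----------
    mount_height_cm
        Camera height H above the floor, cm.
    lens_angle_deg
        Lens opening angle α, degrees, strictly between 0 and 180.
    sensor_length_px
        Sensor length in pixels along the largest frame dimension.
    """

    mount_height_cm: float
    lens_angle_deg: float
    sensor_length_px: int

    def __post_init__(self) -> None:
        if self.mount_height_cm <= 0:
            raise ParameterError("mount_height_cm must be positive")
        if not (0 < self.lens_angle_deg < 180):
            raise ParameterError("lens_angle_deg must be in (0, 180)")
        if self.sensor_length_px <= 0:
            raise ParameterError("sensor_length_px must be positive")

    @property
    def k_cm_per_px(self) -> float:
        return calibration_factor(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CameraGeometry":
        return cls(
            mount_height_cm=float(d["mount_height_cm"]),
            lens_angle_deg=float(d["lens_angle_deg"]),
            sensor_length_px=int(d["sensor_length_px"]),
        )


def calibration_factor(geometry: CameraGeometry) -> float:
    """Proportionality factor k = 2·H·tan(α/2) / sensor_length, in cm/pixel."""
    alpha = math.radians(geometry.lens_angle_deg)
    return 2.0 * geometry.mount_height_cm * math.tan(alpha / 2.0) / geometry.sensor_length_px


def directed_hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """max over a∈A of min over b∈B of the Euclidean distance.

    Computed on squared distances with a single final square root (sqrt is
    monotone, so this is bit-identical to the naive double loop with
    per-pair square roots). Sets too large for the full distance matrix
    fall back to exact KD-tree nearest-neighbour queries.
    """
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.size == 0 or B.size == 0:
        raise EmptyForegroundError(
            "Hausdorff distance is undefined for an empty point set"
        )
    if A.shape[0] * B.shape[0] <= 4_000_000:
        d2 = (
            (A[:, 0, None] - B[None, :, 0]) ** 2
            + (A[:, 1, None] - B[None, :, 1]) ** 2
        )
        return float(np.sqrt(d2.min(axis=1).max()))
    dists, _ = cKDTree(B).query(A, k=1)
    return float(np.max(dists))


def symmetric_hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """max of the two directed Hausdorff distances; symmetric in A, B."""
    return max(directed_hausdorff(A, B), directed_hausdorff(B, A))


def _mask_hausdorff(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Symmetric Hausdorff between the foreground pixel sets of two masks.

    Fast path via the exact Euclidean distance transform: the directed
    distance from A to B is the maximum of B's distance transform over A's
    pixels. Agrees exactly with the brute-force double loop on pixel grids.
    """
    if not mask_a.any() or not mask_b.any():
        raise EmptyForegroundError("mask Hausdorff requires non-empty foreground")
    dt_b = ndimage.distance_transform_edt(~mask_b)
    dt_a = ndimage.distance_transform_edt(~mask_a)
    return float(max(dt_b[mask_a].max(), dt_a[mask_b].max()))


def _mask_points(mask: np.ndarray, point_mode: PointMode, connectivity: int = 8) -> np.ndarray:
    if point_mode == "foreground_pixels":
        return np.argwhere(mask)
    shape_set = extract_shapes(mask, connectivity=connectivity)
    return np.array([s.centroid for s in shape_set.shapes], dtype=np.float64)


def unrest_index(
    mask_curr: np.ndarray,
    mask_prev: np.ndarray,
    k: float,
    point_mode: PointMode = "foreground_pixels",
) -> float:
    """Movement between two consecutive frames, in cm.

    ``k`` times the symmetric Hausdorff distance between the bird point sets
    of the two masks. ``point_mode='foreground_pixels'`` (default) uses every
    foreground pixel — the most literal reading of "the birds" — while
    ``'centroids'`` uses blob centroids (faster, coarser). An empty
    foreground raises :class:`EmptyForegroundError`; callers record the pair
    as missing, never as zero movement.
    """
    mask_curr = np.asarray(mask_curr, dtype=bool)
    mask_prev = np.asarray(mask_prev, dtype=bool)
    if mask_curr.shape != mask_prev.shape:
        raise DimensionMismatchError(
            f"mask shapes differ: {mask_curr.shape} vs {mask_prev.shape}"
        )
    if point_mode == "foreground_pixels":
        return k * _mask_hausdorff(mask_curr, mask_prev)
    pts_curr = _mask_points(mask_curr, point_mode)
    pts_prev = _mask_points(mask_prev, point_mode)
    return k * symmetric_hausdorff(pts_curr, pts_prev)


def cluster_index(
    shape_set: FrameShapeSet,
    variant: ClusterVariant = "nA_minus_1",
    diagonal: bool = True,
) -> float:
    """Crowding statistic of one frame (see module docstring for the formula).

    Raises :class:`InvalidFrameError` when fewer than two blobs are present
    (D̄ undefined); such frames are excluded from block averages.
    """
    n = shape_set.n_clusters
    if n < 2:
        raise InvalidFrameError(
            f"cluster index undefined for frame {shape_set.frame_index}: "
            f"{n} blob(s), need >= 2"
        )
    a_bar = shape_set.mean_area
    p_bar = shape_set.mean_perimeter
    d_bar = shape_set.mean_pair_distance
    if p_bar is None or p_bar <= 0 or d_bar is None or d_bar <= 0:
        raise InvalidFrameError(
            f"frame {shape_set.frame_index}: non-positive mean perimeter or "
            "centroid distance"
        )
    h, w = shape_set.frame_height_px, shape_set.frame_width_px
    size_term = math.hypot(h, w) if diagonal else float(h * h + w * w)
    denom_n = (n - 1) if variant == "nA_minus_1" else n
    return 2.0 * a_bar * size_term / (p_bar * d_bar * denom_n)


@dataclass
class IndexSeries:
    """Per-frame cluster values and per-pair unrest values for one session.

    ``cluster_values`` holds one ``(frame_index, cluster_index, valid)``
    entry per frame (value NaN when invalid); ``unrest_values`` one
    ``(frame_index, unrest_cm)`` entry per consecutive frame pair, keyed by
    the later frame, NaN when either frame had empty foreground.
    ``params_fingerprint`` hashes the full parameter set so exported series
    are traceable to their configuration.
    """

    cluster_values: list[tuple[int, float, bool]]
    unrest_values: list[tuple[int, float]]
    sample_rate_fps: float
    params_fingerprint: str

    def to_dataframe(self) -> pd.DataFrame:
        unrest = {i: u for i, u in self.unrest_values}
        rows = [
            {
                "frame_index": i,
                "timestamp_s": i / self.sample_rate_fps,
                "cluster_index": v,
                "valid": flag,
                "unrest_cm": unrest.get(i, float("nan")),
            }
            for i, v, flag in self.cluster_values
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(Path(path), index=False)

    @property
    def n_valid(self) -> int:
        return sum(1 for _, _, flag in self.cluster_values if flag)


def params_fingerprint(**param_groups) -> str:
    """Order-independent SHA-256 fingerprint of a nested parameter mapping."""
    canon = json.dumps(param_groups, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def compute_index_series(
    frames: FrameSequence,
    seg_params: SegmentationParams,
    geometry: CameraGeometry,
    variant: ClusterVariant = "nA_minus_1",
    point_mode: PointMode = "foreground_pixels",
    diagonal: bool = True,
    background: np.ndarray | None = None,
    background_max_frames: int | None = 100,
) -> IndexSeries:
    """Run the full per-frame pipeline over a sequence.

    Segmentation → cluster index per frame → unrest index per consecutive
    pair. Frames where the index is undefined (n_A < 2, or empty foreground)
    are flagged, never silently dropped. Deterministic for fixed inputs.
    """
    if len(frames) < 2:
        raise EmptySequenceError("need at least 2 frames for an index series")
    if background is None and seg_params.background_method == "median_of_sequence":
        background = estimate_background(
            frames, "median_of_sequence", max_frames=background_max_frames
        )
    k = calibration_factor(geometry)

    cluster_values: list[tuple[int, float, bool]] = []
    unrest_values: list[tuple[int, float]] = []
    prev_mask: np.ndarray | None = None
    prev_dt: np.ndarray | None = None  # distance transform of prev frame
    any_valid = False
    for rec in frames:
        smoothed = lowpass_filter(rec, seg_params.lowpass_sigma)
        try:
            raw_mask = segment_foreground(smoothed, background, seg_params)
        except DegenerateHistogramError:
            # frame identical to background: nothing segmentable
            raw_mask = np.zeros(rec.pixels.shape, dtype=bool)
        mask = clean_mask(raw_mask, seg_params)
        shape_set = extract_shapes(mask, seg_params.connectivity, rec.index)
        try:
            ci = cluster_index(shape_set, variant=variant, diagonal=diagonal)
            cluster_values.append((rec.index, ci, True))
            any_valid = True
        except InvalidFrameError:
            cluster_values.append((rec.index, float("nan"), False))
        # one distance transform per frame serves both adjacent pairs
        curr_dt = (
            ndimage.distance_transform_edt(~mask)
            if point_mode == "foreground_pixels" and mask.any()
            else None
        )
        if prev_mask is not None:
            try:
                if point_mode == "foreground_pixels":
                    if curr_dt is None or prev_dt is None:
                        raise EmptyForegroundError("empty foreground in pair")
                    ui = k * float(
                        max(prev_dt[mask].max(), curr_dt[prev_mask].max())
                    )
                else:
                    ui = unrest_index(mask, prev_mask, k, point_mode=point_mode)
                any_valid = True
            except EmptyForegroundError:
                ui = float("nan")
            unrest_values.append((rec.index, ui))
        prev_mask, prev_dt = mask, curr_dt

    if not any_valid:
        raise EmptySequenceError("all frames invalid: no index could be computed")

    fingerprint = params_fingerprint(
        segmentation=asdict(seg_params),
        geometry=asdict(geometry),
        variant=variant,
        point_mode=point_mode,
        diagonal=diagonal,
        sample_rate_fps=frames.sample_rate_fps,
    )
    return IndexSeries(
        cluster_values=cluster_values,
        unrest_values=unrest_values,
        sample_rate_fps=frames.sample_rate_fps,
        params_fingerprint=fingerprint,
    )


def load_config(path: str | Path) -> dict:
    """Read a YAML/JSON config with ``geometry`` and ``segmentation`` blocks."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    out = dict(cfg)
    if "geometry" in cfg:
        out["geometry"] = CameraGeometry.from_dict(cfg["geometry"])
    if "segmentation" in cfg:
        out["segmentation"] = SegmentationParams(**cfg["segmentation"])
    return out
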