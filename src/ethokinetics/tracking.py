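"""Centroid tracking from grayscale frame stacks and pixel-to-cm calibration.

Mirrors a classical threshold / analyze-particles chain: binarize each
frame (animal darker than background by default), label 4-connected
components, drop small ones, and take the centroid of the largest
surviving component. Frames where nothing survives yield MISSING points,
which are preserved by tracking and handled by an explicit interpolation
step before calibration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .kinematics import Trajectory

__all__ = [
    "FrameStack",
    "RawTrack",
    "Calibration",
    "TrackingError",
    "IncompleteTrackError",
    "extract_centroid",
    "track_stack",
    "fill_missing",
    "calibrate_track",
    "read_frame_stack",
]

#: 4-connectivity structuring element for component labelling.
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

DEFAULT_FRAME_INTERVAL_S = 1.0 / 30.0
DEFAULT_MAX_GAP = 5


class TrackingError(ValueError):
    """Raised for invalid tracking inputs."""


class IncompleteTrackError(TrackingError):
    """Raised when a track still contains MISSING frames at calibration."""

    def __init__(self, missing_indices):
        self.missing_indices = list(missing_indices)
        super().__init__(f"track has MISSING frames at indices {self.missing_indices}")


@dataclass(frozen=True)
class FrameStack:
    """Ordered grayscale frames plus their sampling interval."""

    frames: np.ndarray  # (n, H, W) integer intensities 0..255
    frame_interval_s: float
    source_id: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3 or f.shape[0] < 1:
            raise TrackingError("frames must be a non-empty (n, H, W) array")
        if self.frame_interval_s <= 0:
            raise TrackingError("frame_interval_s must be > 0")
        object.__setattr__(self, "frames", f)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class RawTrack:
    """Per-frame pixel centroids; MISSING frames are NaN rows."""

    points: np.ndarray  # (n, 2) float, NaN rows for MISSING
    frame_interval_s: float
    source_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2:
            raise TrackingError("points must be an (n, 2) array")
        if self.frame_interval_s <= 0:
            raise TrackingError("frame_interval_s must be > 0")
        object.__setattr__(self, "points", p)

    @property
    def n_frames(self) -> int:
        return len(self.points)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.points).any(axis=1)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "t_s": np.arange(self.n_frames) * self.frame_interval_s,
                "x_px": self.points[:, 0],
                "y_px": self.points[:, 1],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_interval_s: float | None = None) -> "RawTrack":
        df = pd.read_csv(path)
        if frame_interval_s is None:
            t = df["t_s"].to_numpy(float)
            frame_interval_s = float(t[1] - t[0]) if len(t) > 1 else DEFAULT_FRAME_INTERVAL_S
        pts = df[["x_px", "y_px"]].to_numpy(float)
        return cls(points=pts, frame_interval_s=frame_interval_s, source_id=str(path))


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-cm scale factors and the pixel origin of arena (0, 0)."""

    px_per_cm_x: float
    px_per_cm_y: float
    origin_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.px_per_cm_x <= 0 or self.px_per_cm_y <= 0:
            raise TrackingError("scale factors must be > 0")

    def to_cm(self, points_px: np.ndarray) -> np.ndarray:
        p = np.asarray(points_px, dtype=float)
        out = np.empty_like(p)
        out[..., 0] = (p[..., 0] - self.origin_px[0]) / self.px_per_cm_x
        out[..., 1] = (p[..., 1] - self.origin_px[1]) / self.px_per_cm_y
        return out

    def to_px(self, points_cm: np.ndarray) -> np.ndarray:
        p = np.asarray(points_cm, dtype=float)
        out = np.empty_like(p)
        out[..., 0] = p[..., 0] * self.px_per_cm_x + self.origin_px[0]
        out[..., 1] = p[..., 1] * self.px_per_cm_y + self.origin_px[1]
        return out

    @classmethod
    def from_yaml(cls, path) -> "Calibration":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            px_per_cm_x=float(d["px_per_cm_x"]),
            px_per_cm_y=float(d["px_per_cm_y"]),
            origin_px=tuple(float(v) for v in d.get("origin_px", (0.0, 0.0))),
        )


MISSING = (math.nan, math.nan)


def extract_centroid(
    frame: np.ndarray,
    intensity_threshold: float,
    min_area_px: int = 1,
    invert: bool = False,
    weighted: bool = False,
) -> tuple[float, float] | None:
    """Centroid (x_px, y_px) of the largest dark component, or None.

    Pixels strictly darker than ``intensity_threshold`` are foreground
    (``invert=True`` flips polarity for a light animal on a dark arena).
    Components are 4-connected; those below ``min_area_px`` are dropped and
    area ties resolve to the smaller component label. ``weighted=True``
    weights the centroid by darkness (255 - intensity) instead of the plain
    blob centroid.
    """
    f = np.asarray(frame)
    if f.ndim != 2 or f.size == 0:
        raise TrackingError("frame must be a non-empty 2-D array")
    if not (0 <= intensity_threshold <= 255):
        raise TrackingError("intensity_threshold must be in [0, 255]")
    if min_area_px < 1:
        raise TrackingError("min_area_px must be >= 1")
    mask = (f > intensity_threshold) if invert else (f < intensity_threshold)
    labels, n = ndimage.label(mask, structure=_STRUCT4)
    if n == 0:
        return None
    areas = np.bincount(labels.ravel())[1:]  # skip background
    areas = np.where(areas >= min_area_px, areas, 0)
    if areas.max() == 0:
        return None
    best = int(np.argmax(areas)) + 1  # argmax -> smallest label on ties
    ys, xs = np.nonzero(labels == best)
    if weighted:
        wgt = 255.0 - f[ys, xs].astype(float)
        total = wgt.sum()
        return (float((xs * wgt).sum() / total), float((ys * wgt).sum() / total))
    return (float(xs.mean()), float(ys.mean()))


def track_stack(
    stack: FrameStack,
    intensity_threshold: float,
    min_area_px: int = 1,
    invert: bool = False,
    weighted: bool = False,
) -> RawTrack:
    """One centroid (or MISSING) per frame, in frame order; no interpolation."""
    pts = np.full((stack.n_frames, 2), np.nan)
    for i in range(stack.n_frames):
        c = extract_centroid(
            stack.frames[i], intensity_threshold, min_area_px, invert=invert, weighted=weighted
        )
        if c is not None:
            pts[i] = c
    return RawTrack(points=pts, frame_interval_s=stack.frame_interval_s,
                    source_id=stack.source_id)


def fill_missing(track: RawTrack, max_gap: int = DEFAULT_MAX_GAP) -> tuple[RawTrack, list[int]]:
    """Linearly interpolate MISSING gaps of at most ``max_gap`` frames.

    Leading/trailing gaps and gaps longer than ``max_gap`` are left
    MISSING. Returns the repaired track and the list of filled indices.
    """
    pts = track.points.copy()
    missing = track.missing_mask()
    filled: list[int] = []
    i = 0
    n = len(pts)
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        gap = j - i
        if i > 0 and j < n and gap <= max_gap:
            p0, p1 = pts[i - 1], pts[j]
            for k in range(gap):
                frac = (k + 1) / (gap + 1)
                pts[i + k] = p0 + frac * (p1 - p0)
                filled.append(i + k)
        i = j
    return (
        RawTrack(points=pts, frame_interval_s=track.frame_interval_s,
                 source_id=track.source_id),
        filled,
    )


def calibrate_track(
    track: RawTrack,
    cal: Calibration,
    subject_id: str = "",
    group_label: str = "",
    test_stage: str = "",
) -> Trajectory:
    """Convert a complete pixel track to an arena-coordinate trajectory."""
    missing = track.missing_mask()
    if missing.any():
        raise IncompleteTrackError(np.flatnonzero(missing).tolist())
    if track.n_frames < 2:
        raise TrackingError("track needs at least 2 frames")
    cm = cal.to_cm(track.points)
    t = np.arange(track.n_frames) * track.frame_interval_s
    return Trajectory(
        t_s=t,
        x_cm=cm[:, 0],
        y_cm=cm[:, 1],
        subject_id=subject_id,
        group_label=group_label,
        test_stage=test_stage,
    )


def read_frame_stack(path, frame_interval_s: float | None = None) -> FrameStack:
    """Load frames from a multi-page TIFF or a directory of PNG/TIFF files.

    Directory frames are taken in lexicographic order. When the frame
    interval is not given, 1/30 s is assumed with a warning (consumer
    webcam default); velocity and acceleration units depend on it.
    """
    if frame_interval_s is None:
        warnings.warn(
            "frame_interval_s not provided; defaulting to 1/30 s — "
            "velocity/acceleration units depend on the true frame rate"
        )
        frame_interval_s = DEFAULT_FRAME_INTERVAL_S
    p = Path(path)
    if p.is_dir():
        import imageio.v3 as iio

        files = sorted(
            f for f in p.iterdir() if f.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise TrackingError(f"no PNG/TIFF frames found in {p}")
        frames = np.stack([np.asarray(iio.imread(f)) for f in files])
    elif p.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        frames = tifffile.imread(p)
        if frames.ndim == 2:
            frames = frames[None]
    else:
        raise TrackingError(f"unsupported frame source: {p}")
    if frames.ndim == 4:  # RGB(A) -> luminance
        frames = frames[..., :3].mean(axis=-1)
    return FrameStack(frames=frames.astype(np.uint8), frame_interval_s=frame_interval_s,
                      source_id=str(p))
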