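"""Image sequences, ROI specifications and feature tables: containers and I/O.

Coordinate convention: pixel coordinates are 0-based with ``x`` indexing
columns and ``y`` indexing rows; an ROI covers the half-open extent
``[x, x+w) x [y, y+h)``.  Frames are ordered by acquisition time; when read
from a directory the files are sorted lexicographically so frame order never
depends on filesystem listing order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import (
    BitDepthError,
    BoundsError,
    InvariantError,
    SchemaError,
    ShapeMismatchError,
)

__all__ = [
    "ImageSequence",
    "ROI",
    "ROISet",
    "read_sequence",
    "write_sequence",
    "read_rois",
    "write_rois",
    "FEATURE_COLUMNS",
    "FEATURE_TABLE_COLUMNS",
    "write_feature_table",
    "read_feature_table",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}

#: The six texture features, in fixed serialization order.
FEATURE_COLUMNS = [
    "echo_intensity",
    "heterogeneity",
    "internal_heterogeneity",
    "glnu",
    "rlnu",
    "entropy",
]

#: Full feature-table schema (identification columns first).
FEATURE_TABLE_COLUMNS = ["case_id", "group", "frame_index", "roi_id"] + FEATURE_COLUMNS


@dataclass
class ImageSequence:
    """Ordered 8-bit grayscale frames for one case.

    Parameters
    ----------
    case_id : str
        Identifier of the subject/clip.
    group : str
        Group label (e.g. ``normal`` / ``steatosis`` / ``fibrosis``).
    frames : numpy.ndarray
        ``(F, H, W)`` array of dtype ``uint8``; index 0 is acquisition time 0.
    frame_rate_hz : float, optional
        Acquisition frame rate, used only to convert frame shifts to seconds.
    """

    case_id: str
    group: str
    frames: np.ndarray
    frame_rate_hz: float | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ShapeMismatchError(
                f"frames must be a (F, H, W) stack, got shape {frames.shape}"
            )
        if frames.dtype != np.uint8:
            raise BitDepthError(
                f"frames must be uint8 (8-bit grayscale), got dtype {frames.dtype}"
            )
        if self.frame_rate_hz is not None and self.frame_rate_hz <= 0:
            raise InvariantError("frame_rate_hz must be positive")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest: half-open ``[x, x+w) x [y, y+h)``."""

    roi_id: int
    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise BoundsError(f"roi {self.roi_id}: x and y must be non-negative")
        if self.w <= 0 or self.h <= 0:
            raise BoundsError(f"roi {self.roi_id}: w and h must be positive")
        if self.w * self.h < 16:
            raise InvariantError(
                f"roi {self.roi_id}: w*h = {self.w * self.h} < 16 pixels "
                "(too few for a stable histogram)"
            )

    def extract(self, frame: np.ndarray) -> np.ndarray:
        """Return the ROI pixel block of ``frame`` (a view, not a copy)."""
        return frame[self.y : self.y + self.h, self.x : self.x + self.w]

    def check_bounds(self, height: int, width: int, frame_index: int | None = None) -> None:
        if self.x + self.w > width or self.y + self.h > height:
            where = "" if frame_index is None else f" on frame {frame_index}"
            raise BoundsError(
                f"roi {self.roi_id}{where} exceeds frame bounds "
                f"({height}x{width}): x+w={self.x + self.w}, y+h={self.y + self.h}"
            )


@dataclass
class ROISet:
    """Per-frame ROI collections with a constant count and consistent ids.

    ``per_frame[t]`` holds the ROIs of frame ``t``; ``roi_id k`` refers to the
    corresponding region on every frame.
    """

    per_frame: list[tuple[ROI, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.per_frame = [tuple(rois) for rois in self.per_frame]
        if not self.per_frame:
            return
        counts = {len(r) for r in self.per_frame}
        if len(counts) != 1:
            raise InvariantError(
                f"inconsistent ROI count across frames: {sorted(counts)}"
            )
        ids0 = [r.roi_id for r in self.per_frame[0]]
        for t, rois in enumerate(self.per_frame):
            ids = [r.roi_id for r in rois]
            if ids != ids0:
                raise InvariantError(
                    f"frame {t} roi_ids {ids} differ from frame 0 roi_ids {ids0}"
                )

    @classmethod
    def broadcast(cls, rois: Sequence[ROI], n_frames: int) -> "ROISet":
        """Apply one frame's ROI layout identically to all ``n_frames`` frames."""
        return cls([tuple(rois)] * n_frames)

    @property
    def n_frames(self) -> int:
        return len(self.per_frame)

    @property
    def n_rois(self) -> int:
        return len(self.per_frame[0]) if self.per_frame else 0

    @property
    def roi_ids(self) -> list[int]:
        return [r.roi_id for r in self.per_frame[0]] if self.per_frame else []

    def validate_against(self, sequence: ImageSequence) -> None:
        """Check frame count and that every ROI lies inside the frames."""
        if self.n_frames != sequence.n_frames:
            raise InvariantError(
                f"ROISet covers {self.n_frames} frames, sequence has "
                f"{sequence.n_frames}"
            )
        height, width = sequence.shape
        for t, rois in enumerate(self.per_frame):
            for roi in rois:
                roi.check_bounds(height, width, frame_index=t)


def _rescale_to_uint8(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.round((arr - lo) / (hi - lo) * 255.0).astype(np.uint8)


def _coerce_frame(arr: np.ndarray, source: str, allow_rescale: bool) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise BitDepthError(f"{source}: color images are not supported")
    if arr.dtype == np.uint8:
        return arr
    if allow_rescale:
        warnings.warn(
            f"{source}: rescaling {arr.dtype} data to 8-bit", stacklevel=3
        )
        return _rescale_to_uint8(arr)
    raise BitDepthError(
        f"{source}: expected 8-bit grayscale, got dtype {arr.dtype} "
        "(pass allow_rescale=True to rescale)"
    )


def read_sequence(
    path: str | Path,
    case_id: str,
    group: str,
    frame_rate_hz: float | None = None,
    allow_rescale: bool = False,
) -> ImageSequence:
    """Load an :class:`ImageSequence` from a directory of frames or a multi-page TIFF.

    Directories are read in lexicographic filename order.  All frames must be
    8-bit grayscale of identical shape; other bit depths are rejected unless
    ``allow_rescale`` is set, in which case they are min-max rescaled to
    [0, 255] with a warning.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames found in {path}")
        for f in files:
            arr = np.asarray(iio.imread(f))
            if arr.ndim == 3 and arr.shape[-1] not in (3, 4):
                # multi-page file inside a directory: take its pages in order
                frames.extend(_coerce_frame(a, str(f), allow_rescale) for a in arr)
            else:
                frames.append(_coerce_frame(arr, str(f), allow_rescale))
    else:
        arr = np.asarray(tifffile.imread(path))
        if arr.ndim == 2:
            arr = arr[None]
        frames = [_coerce_frame(a, str(path), allow_rescale) for a in arr]

    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ShapeMismatchError(
            f"{path}: frames have mixed shapes {sorted(shapes)}"
        )
    return ImageSequence(
        case_id=case_id,
        group=group,
        frames=np.stack(frames),
        frame_rate_hz=frame_rate_hz,
    )


def write_sequence(sequence: ImageSequence, path: str | Path) -> None:
    """Write a sequence as a multi-page 8-bit grayscale TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, sequence.frames, photometric="minisblack")


_ROI_COLUMNS = ["frame_index", "roi_id", "x", "y", "w", "h"]


def _rois_from_records(records: pd.DataFrame, sequence: ImageSequence) -> ROISet:
    records = records.copy()
    missing = [c for c in _ROI_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"ROI spec is missing columns: {missing}")
    for c in ["roi_id", "x", "y", "w", "h"]:
        records[c] = records[c].astype(int)

    blank = records["frame_index"].isna()
    if blank.all():
        rois = [
            ROI(int(r.roi_id), int(r.x), int(r.y), int(r.w), int(r.h))
            for r in records.itertuples()
        ]
        roi_set = ROISet.broadcast(rois, sequence.n_frames)
    elif blank.any():
        raise InvariantError(
            "ROI spec mixes broadcast rows (empty frame_index) with per-frame rows"
        )
    else:
        records["frame_index"] = records["frame_index"].astype(int)
        per_frame: list[tuple[ROI, ...]] = []
        grouped = dict(tuple(records.groupby("frame_index")))
        for t in range(sequence.n_frames):
            if t not in grouped:
                raise InvariantError(f"ROI spec has no rows for frame {t}")
            rows = grouped[t]
            per_frame.append(
                tuple(
                    ROI(int(r.roi_id), int(r.x), int(r.y), int(r.w), int(r.h))
                    for r in rows.itertuples()
                )
            )
        roi_set = ROISet(per_frame)
    roi_set.validate_against(sequence)
    return roi_set


def read_rois(path: str | Path, sequence: ImageSequence) -> ROISet:
    """Read an ROI spec (CSV or JSON) and validate it against ``sequence``.

    The spec carries columns/keys ``frame_index, roi_id, x, y, w, h``.  Rows
    with an empty ``frame_index`` describe a single-frame layout that is
    broadcast to every frame.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = pd.DataFrame(json.loads(path.read_text()))
        if "frame_index" not in records.columns:
            records["frame_index"] = np.nan
    else:
        records = pd.read_csv(path)
    return _rois_from_records(records, sequence)


def write_rois(roi_set: ROISet, path: str | Path) -> None:
    """Write an ROI spec as CSV, collapsing to broadcast rows when possible."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    constant = all(r == roi_set.per_frame[0] for r in roi_set.per_frame)
    frames = [None] if constant else range(roi_set.n_frames)
    for t in frames:
        for roi in roi_set.per_frame[0 if t is None else t]:
            rows.append(
                {
                    "frame_index": "" if t is None else t,
                    "roi_id": roi.roi_id,
                    "x": roi.x,
                    "y": roi.y,
                    "w": roi.w,
                    "h": roi.h,
                }
            )
    pd.DataFrame(rows, columns=_ROI_COLUMNS).to_csv(path, index=False)


def write_feature_table(rows: Iterable[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write per-ROI feature records as CSV in the fixed column order.

    Floats are serialized with 8 significant digits so a read-back reproduces
    them to well beyond measurement precision.
    """
    if isinstance(rows, pd.DataFrame):
        table = rows.copy()
    else:
        table = pd.DataFrame(list(rows))
    if len(table) == 0:
        table = pd.DataFrame(columns=FEATURE_TABLE_COLUMNS)
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table is missing fields: {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[FEATURE_TABLE_COLUMNS].to_csv(path, index=False, float_format="%.8g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table CSV, checking the schema."""
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: feature table is missing columns {missing}")
    return table
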