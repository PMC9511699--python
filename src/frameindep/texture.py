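"""Quantitative texture features for B-mode ultrasound ROIs.

Six features are computed per ROI / per case:

``echo_intensity``
    Mean gray level of the ROI (0-255).
``internal_heterogeneity``
    Standard deviation of gray level within the ROI ("local variance").
``heterogeneity``
    Standard deviation of the ROI mean intensities across *all* ROIs and
    frames of a case ("regional variance between ROIs") — a case-level
    feature repeated on every row of the feature table.
``glnu`` / ``rlnu``
    Gray-level and run-length nonuniformity of the gray-level run-length
    matrix, normalized by the squared run count so both lie in (0, 1]
    (1 = all runs share one gray level / one length).
``entropy``
    First-order Shannon entropy (bits) of the ROI's 256-level histogram.

All standard deviations use the population convention (divisor ``n``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FEATURE_TABLE_COLUMNS, ImageSequence, ROISet
from .errors import EmptyInputError, RangeError

__all__ = [
    "RunLengthMatrix",
    "run_length_matrix",
    "echo_intensity",
    "internal_heterogeneity",
    "heterogeneity",
    "glnu",
    "rlnu",
    "entropy",
    "CaseFeatureRecord",
    "extract_features",
]

Direction = Literal["horizontal", "vertical"]


@dataclass
class RunLengthMatrix:
    """Counts of maximal same-level pixel runs.

    ``counts[i, j]`` is the number of maximal runs of quantized gray level
    ``i`` with length ``j + 1`` (column ``j`` holds runs of length ``j+1``).
    """

    levels: int
    direction: Direction
    counts: np.ndarray

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())

    @property
    def n_pixels(self) -> int:
        lengths = np.arange(1, self.counts.shape[1] + 1)
        return int((self.counts * lengths).sum())


def _require_pixels(pixels: np.ndarray, minimum: int = 1) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.size < minimum:
        raise EmptyInputError(
            f"operation needs at least {minimum} pixel(s), got {arr.size}"
        )
    return arr


def quantize(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Map 8-bit values onto ``levels`` equal-width bins over [0, 255]."""
    if levels < 2:
        raise RangeError("levels must be >= 2")
    return np.minimum(np.asarray(pixels, dtype=np.int64) * levels // 256, levels - 1)


def run_length_matrix(
    pixels: np.ndarray, levels: int = 16, direction: Direction = "horizontal"
) -> RunLengthMatrix:
    """Build the gray-level run-length matrix of an ROI.

    Maximal runs of equal quantized level are counted along rows
    (``horizontal``) or columns (``vertical``).  The matrix conserves pixels:
    summing length times count over all entries returns the ROI pixel count.
    """
    arr = _require_pixels(pixels)
    if arr.ndim != 2:
        raise RangeError("run_length_matrix expects a 2-D pixel grid")
    if direction not in ("horizontal", "vertical"):
        raise RangeError(f"unknown direction {direction!r}")
    q = quantize(arr, levels)
    if direction == "vertical":
        q = q.T
    h, w = q.shape
    flat = q.ravel()
    # run starts: first pixel, every row start, every value change
    change = np.empty(flat.size, dtype=bool)
    change[0] = True
    change[1:] = flat[1:] != flat[:-1]
    change[::w] = True
    starts = np.flatnonzero(change)
    lengths = np.diff(np.append(starts, flat.size))
    run_levels = flat[starts]

    counts = np.zeros((levels, int(lengths.max())), dtype=np.int64)
    np.add.at(counts, (run_levels, lengths - 1), 1)
    return RunLengthMatrix(levels=levels, direction=direction, counts=counts)


def echo_intensity(pixels: np.ndarray) -> float:
    """Mean gray level of the ROI."""
    return float(_require_pixels(pixels).mean())


def internal_heterogeneity(pixels: np.ndarray) -> float:
    """Population standard deviation of gray level within the ROI."""
    return float(np.std(_require_pixels(pixels, minimum=2)))


def heterogeneity(roi_means: Sequence[float]) -> float:
    """Population standard deviation across a case's ROI mean intensities."""
    means = np.asarray(roi_means, dtype=float)
    if means.size < 2:
        raise EmptyInputError("heterogeneity needs >= 2 ROI means")
    return float(np.std(means))


def _check_runs(rlm: RunLengthMatrix) -> int:
    n = rlm.n_runs
    if n < 1:
        raise EmptyInputError("run-length matrix holds zero runs")
    return n


def glnu(rlm: RunLengthMatrix) -> float:
    """Gray-level nonuniformity, normalized to (0, 1].

    ``sum_i (sum_j counts[i, j])**2 / N_runs**2``: 1 iff a single gray level
    produces all runs, 1/G when G levels contribute equal run counts.
    """
    n = _check_runs(rlm)
    level_totals = rlm.counts.sum(axis=1)
    return float((level_totals.astype(float) ** 2).sum() / n**2)


def rlnu(rlm: RunLengthMatrix) -> float:
    """Run-length nonuniformity, normalized to (0, 1].

    ``sum_j (sum_i counts[i, j])**2 / N_runs**2``: 1 iff all runs share one
    length.
    """
    n = _check_runs(rlm)
    length_totals = rlm.counts.sum(axis=0)
    return float((length_totals.astype(float) ** 2).sum() / n**2)


def entropy(pixels: np.ndarray, base: float = 2.0) -> float:
    """Shannon entropy of the ROI's 256-level histogram (bits by default)."""
    arr = _require_pixels(pixels)
    counts = np.bincount(arr.ravel().astype(np.int64), minlength=256)
    return float(stats.entropy(counts, base=base))


@dataclass
class CaseFeatureRecord:
    """Per-ROI feature rows of one case plus its case-level heterogeneity."""

    case_id: str
    group: str
    heterogeneity: float
    rows: pd.DataFrame  # FEATURE_TABLE_COLUMNS schema


def extract_features(
    sequence: ImageSequence,
    rois: ROISet,
    rl_levels: int = 16,
    rl_directions: Iterable[Direction] = ("horizontal", "vertical"),
) -> CaseFeatureRecord:
    """Compute the six texture features for every (frame, ROI) of a case.

    GLNU/RLNU are averaged over ``rl_directions``.  The case-level
    heterogeneity (spread of ROI means over all frames and ROIs) is filled
    into every row so the table is self-contained for downstream modeling.
    """
    rois.validate_against(sequence)
    directions = tuple(rl_directions)
    if not directions:
        raise RangeError("at least one run-length direction is required")

    records: list[dict] = []
    roi_means: list[float] = []
    for t in range(sequence.n_frames):
        frame = sequence.frames[t]
        for roi in rois.per_frame[t]:
            block = roi.extract(frame)
            mean = echo_intensity(block)
            roi_means.append(mean)
            g = np.mean(
                [glnu(run_length_matrix(block, rl_levels, d)) for d in directions]
            )
            r = np.mean(
                [rlnu(run_length_matrix(block, rl_levels, d)) for d in directions]
            )
            records.append(
                {
                    "case_id": sequence.case_id,
                    "group": sequence.group,
                    "frame_index": t,
                    "roi_id": roi.roi_id,
                    "echo_intensity": mean,
                    "internal_heterogeneity": internal_heterogeneity(block),
                    "glnu": float(g),
                    "rlnu": float(r),
                    "entropy": entropy(block),
                }
            )

    case_het = heterogeneity(roi_means) if len(roi_means) >= 2 else 0.0
    rows = pd.DataFrame(records)
    rows["heterogeneity"] = case_het
    return CaseFeatureRecord(
        case_id=sequence.case_id,
        group=sequence.group,
        heterogeneity=case_het,
        rows=rows[FEATURE_TABLE_COLUMNS],
    )
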