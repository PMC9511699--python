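"""Jensen-Shannon divergence between ROI grayscale distributions.

The independence question is framed distributionally: each ROI on each
frame yields a smoothed 256-bin gray-level histogram, and divergence is
measured between histogram pairs drawn either from the *same* case at a
frame shift (intra-case) or from two *different* cases (inter-case).  The
intra population at all shifts is later tested for noninferiority against
the inter population, and the divergence-vs-shift curve exposes periodic
structure such as respiratory motion.

All divergences use log base 2, so JS lies in [0, 1].
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .core_io import ImageSequence, ROISet
from .errors import EmptyInputError, InsufficientCasesError, RangeError

__all__ = [
    "gray_histogram",
    "roi_histograms",
    "kl_divergence",
    "js_divergence",
    "intra_pairs",
    "all_intra_pairs",
    "inter_pairs",
    "shift_curve",
    "pool_shift_curves",
    "estimate_period",
    "SAMPLE_COLUMNS",
]

_LN2 = np.log(2.0)

#: Serialization schema of a divergence sample set.
SAMPLE_COLUMNS = [
    "kind",
    "case_a",
    "case_b",
    "frame_a",
    "frame_b",
    "roi_id",
    "shift",
    "js",
]


def gray_histogram(pixels: np.ndarray, pseudocount: float = 1e-6) -> np.ndarray:
    """Smoothed 256-bin probability distribution of 8-bit ROI pixels.

    ``pseudocount`` is added to every bin before normalization so all bins
    are strictly positive (KL-safe); probabilities sum to 1.
    """
    arr = np.asarray(pixels)
    if arr.size == 0:
        raise EmptyInputError("gray_histogram of an empty ROI")
    if pseudocount <= 0:
        raise RangeError("pseudocount must be > 0")
    counts = np.bincount(arr.ravel().astype(np.int64), minlength=256).astype(float)
    counts += pseudocount
    return counts / counts.sum()


def roi_histograms(
    sequence: ImageSequence, rois: ROISet, pseudocount: float = 1e-6
) -> np.ndarray:
    """Histograms for every (frame, ROI) of a case: shape ``(F, R, 256)``."""
    rois.validate_against(sequence)
    out = np.empty((sequence.n_frames, rois.n_rois, 256))
    for t in range(sequence.n_frames):
        frame = sequence.frames[t]
        for k, roi in enumerate(rois.per_frame[t]):
            out[t, k] = gray_histogram(roi.extract(frame), pseudocount)
    return out


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float | np.ndarray:
    """Kullback-Leibler divergence ``sum p log2(p/q)`` along the last axis.

    Requires smoothed histograms: a zero bin in ``q`` where ``p`` has mass
    makes the divergence undefined and raises.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    out = rel_entr(p, q).sum(axis=-1) / _LN2
    if not np.all(np.isfinite(out)):
        raise ValueError(
            "KL divergence undefined: q has a zero bin where p has mass "
            "(histograms must be smoothed)"
        )
    return float(out) if np.ndim(out) == 0 else out


def js_divergence(p: np.ndarray, q: np.ndarray) -> float | np.ndarray:
    """Jensen-Shannon divergence along the last axis, in [0, 1].

    ``JS(P, Q) = 0.5 KL(P||M) + 0.5 KL(Q||M)`` with ``M = (P+Q)/2`` and log
    base 2: symmetric, bounded, 0 iff ``P = Q``, 1 for disjoint supports.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)
    out = 0.5 * (rel_entr(p, m).sum(axis=-1) + rel_entr(q, m).sum(axis=-1)) / _LN2
    # mixture M has mass wherever P or Q does, so out is always finite
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.ndim(out) == 0 else out


def intra_pairs(
    sequence: ImageSequence,
    rois: ROISet,
    shift: int,
    pseudocount: float = 1e-6,
    hists: np.ndarray | None = None,
    cross_roi: bool = False,
) -> pd.DataFrame:
    """Intra-case JS samples at one time shift.

    Pairs ROI ``k`` on frame ``t`` with the *same* ``roi_id`` on frame
    ``t + shift`` (spatially corresponding region, so the sample measures
    temporal rather than spatial divergence), for every admissible ``t``;
    yields ``(F - shift) * R`` samples.  With ``cross_roi=True`` every ROI
    on frame ``t`` is instead paired with every ROI on ``t + shift``
    (``(F - shift) * R * R`` samples, temporal and spatial divergence
    conflated; the recorded ``roi_id`` is the earlier frame's).  ``hists``
    may carry precomputed :func:`roi_histograms` output to avoid
    recomputation.
    """
    F = sequence.n_frames
    if not 1 <= shift <= F - 1:
        raise RangeError(f"shift must be in [1, {F - 1}], got {shift}")
    if hists is None:
        hists = roi_histograms(sequence, rois, pseudocount)
    R = rois.n_rois
    if cross_roi:
        # (F-shift, R, 1, 256) against (F-shift, 1, R, 256)
        js = js_divergence(hists[: F - shift, :, None], hists[shift:, None, :])
        frames_a = np.repeat(np.arange(F - shift), R * R)
        roi_ids = np.tile(np.repeat(rois.roi_ids, R), F - shift)
    else:
        js = js_divergence(hists[: F - shift], hists[shift:])  # (F-shift, R)
        frames_a = np.repeat(np.arange(F - shift), R)
        roi_ids = np.tile(rois.roi_ids, F - shift)
    return pd.DataFrame(
        {
            "kind": "intra",
            "case_a": sequence.case_id,
            "case_b": sequence.case_id,
            "frame_a": frames_a,
            "frame_b": frames_a + shift,
            "roi_id": roi_ids,
            "shift": shift,
            "js": np.asarray(js).ravel(),
        }
    )[SAMPLE_COLUMNS]


def all_intra_pairs(
    sequence: ImageSequence,
    rois: ROISet,
    pseudocount: float = 1e-6,
    min_shift: int = 1,
    max_shift: int | None = None,
    cross_roi: bool = False,
) -> pd.DataFrame:
    """Intra-case JS samples pooled over shifts ``min_shift..max_shift``.

    By default every possible shift 1..F-1 enters the pooled intra
    population; a shift window restricts the test to pairs at least (or at
    most) a given time apart.
    """
    F = sequence.n_frames
    max_shift = F - 1 if max_shift is None else max_shift
    if not 1 <= min_shift <= max_shift <= F - 1:
        raise RangeError(
            f"shift window [{min_shift}, {max_shift}] not within [1, {F - 1}]"
        )
    hists = roi_histograms(sequence, rois, pseudocount)
    parts = [
        intra_pairs(sequence, rois, shift, hists=hists, cross_roi=cross_roi)
        for shift in range(min_shift, max_shift + 1)
    ]
    return pd.concat(parts, ignore_index=True)


def inter_pairs(
    sequences: Sequence[ImageSequence],
    rois_by_case: Mapping[str, ROISet],
    max_pairs: int = 2000,
    seed: int | np.random.Generator = 0,
    pseudocount: float = 1e-6,
) -> pd.DataFrame:
    """Inter-case JS samples: ROI regions drawn from two distinct cases.

    ``max_pairs`` pairs of (case, frame, roi) slots are drawn uniformly at
    random (with replacement) over all combinations with ``case_a != case_b``,
    reproducibly from ``seed``.
    """
    if len(sequences) < 2:
        raise InsufficientCasesError("inter-case sampling needs >= 2 cases")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    hists = [
        roi_histograms(seq, rois_by_case[seq.case_id], pseudocount)
        for seq in sequences
    ]
    n_cases = len(sequences)
    case_a = rng.integers(0, n_cases, size=max_pairs)
    # draw case_b uniformly over the remaining cases
    case_b = rng.integers(0, n_cases - 1, size=max_pairs)
    case_b[case_b >= case_a] += 1

    rows = []
    for ca, cb in zip(case_a, case_b):
        seq_a, seq_b = sequences[ca], sequences[cb]
        ha, hb = hists[ca], hists[cb]
        fa = int(rng.integers(0, ha.shape[0]))
        fb = int(rng.integers(0, hb.shape[0]))
        ka = int(rng.integers(0, ha.shape[1]))
        kb = int(rng.integers(0, hb.shape[1]))
        rows.append(
            {
                "kind": "inter",
                "case_a": seq_a.case_id,
                "case_b": seq_b.case_id,
                "frame_a": fa,
                "frame_b": fb,
                # roi ids may differ between the two regions; record region a's
                "roi_id": rois_by_case[seq_a.case_id].roi_ids[ka],
                "shift": np.nan,
                "js": float(js_divergence(ha[fa, ka], hb[fb, kb])),
            }
        )
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def shift_curve(
    sequence: ImageSequence,
    rois: ROISet,
    pseudocount: float = 1e-6,
    hists: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean/SD of intra-case JS at every shift 1..F-1.

    Columns: ``shift, mean_js, sd_js, n`` with ``n = (F - shift) * R``.
    """
    F = sequence.n_frames
    if F < 3:
        raise RangeError("shift curve needs at least 3 frames")
    if hists is None:
        hists = roi_histograms(sequence, rois, pseudocount)
    rows = []
    for shift in range(1, F):
        js = np.asarray(js_divergence(hists[: F - shift], hists[shift:])).ravel()
        rows.append(
            {
                "shift": shift,
                "mean_js": float(js.mean()),
                "sd_js": float(js.std()),
                "n": js.size,
            }
        )
    return pd.DataFrame(rows)


def pool_shift_curves(curves: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Average per-case shift curves into a cohort curve (weighted by n).

    Only shifts present in every curve are kept, so short clips do not bias
    the tail; ``sd_js`` is the pooled within-case SD (between-case mean
    differences are not folded in).
    """
    if not curves:
        raise EmptyInputError("no shift curves to pool")
    common = set(curves[0]["shift"])
    for c in curves[1:]:
        common &= set(c["shift"])
    rows = []
    for shift in sorted(common):
        parts = [c[c["shift"] == shift].iloc[0] for c in curves]
        n = sum(int(p["n"]) for p in parts)
        mean = sum(p["mean_js"] * p["n"] for p in parts) / n
        var = sum((p["sd_js"] ** 2) * p["n"] for p in parts) / n
        rows.append(
            {"shift": shift, "mean_js": mean, "sd_js": float(np.sqrt(var)), "n": n}
        )
    return pd.DataFrame(rows)


def estimate_period(
    curve: pd.DataFrame,
    min_lag: int = 2,
    threshold: float | None = None,
) -> float | None:
    """Dominant period (in frames) of a divergence-vs-shift curve.

    The mean-JS sequence is linearly detrended (slow divergence drift would
    otherwise mask the oscillation and bias the peak) and its unbiased
    autocorrelation is scanned for the first local maximum at lag >=
    ``min_lag`` exceeding the significance threshold (default
    ``2 / sqrt(L)``, a conventional white-noise band).  The peak location is
    refined by parabolic interpolation.  Returns ``None`` when no
    significant peak exists (flat or aperiodic curves).
    """
    x = np.asarray(curve["mean_js"], dtype=float)
    L = x.size
    if L < 8:
        raise RangeError(f"period estimation needs a curve of length >= 8, got {L}")
    lags = np.arange(L, dtype=float)
    x = x - np.polyval(np.polyfit(lags, x, 1), lags)
    if np.allclose(x, 0.0):
        return None
    acf = np.correlate(x, x, mode="full")[L - 1 :]
    # unbiased normalization removes the triangular taper that would drag
    # peaks toward smaller lags
    overlap = L - np.arange(L)
    acf = acf / overlap
    acf = acf / acf[0]
    thr = 2.0 / np.sqrt(L) if threshold is None else threshold
    # require a minimum overlap so the unbiased tail noise cannot fire
    max_lag = L - max(4, L // 8)
    for k in range(min_lag, max_lag):
        if acf[k] > acf[k - 1] and acf[k] >= acf[k + 1] and acf[k] > thr:
            # parabolic refinement around the discrete peak
            denom = acf[k - 1] - 2 * acf[k] + acf[k + 1]
            offset = 0.0 if denom == 0 else 0.5 * (acf[k - 1] - acf[k + 1]) / denom
            return float(k + np.clip(offset, -0.5, 0.5))
    return None
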