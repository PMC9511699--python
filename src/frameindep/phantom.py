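"""Synthetic B-mode-like speckle phantom with controllable dependence.

The phantom does not attempt acoustic realism; it reproduces the
*statistical* structure the divergence analysis assumes:

* group-dependent mean echo intensity and speckle spread (liver-disease
  scale presets: normal / steatosis / fibrosis),
* between-case variation of the mean intensity,
* within-case frame-to-frame texture correlation ``rho`` — the parameter
  the independence test is supposed to recover,
* periodic frame-wide intensity modulation emulating respiratory motion,
  with an amplitude that grows over successive cycles,
* a slow linear intensity drift.

Frame ``t`` of a case is

    clip_0_255( base + rho * persistent + sqrt(1 - rho^2) * fresh_t
                + A(t) * sin(2 pi t / T) + drift * t )

where ``base = mu_group + Normal(0, sigma_between)`` is the case mean,
``persistent`` is one fixed speckle field per case, ``fresh_t`` is
regenerated every frame, and ``A(t) = breath_amplitude * amp_growth**(t/T)``.

Each speckle field is the sum of two components:

* a fine component — mean-zero rescaled multiplicative gamma noise (shape
  ``gamma_shape``), the granular texture of coherent imaging, with SD
  ``sigma_within``;
* a smooth structural component — Gaussian-filtered noise with correlation
  length ``struct_scale_px`` and SD ``sigma_structure``, emulating regional
  tissue heterogeneity (different liver regions having different mean
  echogenicity).

The structural component is what makes ``rho`` observable in 256-bin value
histograms: when it persists (``rho`` near 1) two frames' corresponding
regions share their regional mean offsets, so intra-case histograms are far
closer than inter-case ones; when it is regenerated every frame
(``rho = 0``) regions of the same case differ in regional mean just as much
as regions of different cases.  Pixel-level speckle correlation alone is
invisible to value histograms once the uncorrelated jitter exceeds the
1-gray-level bin width, so without regional structure the test could not
distinguish correlated from uncorrelated sequences (see docs/methods.md).

At ``rho = 1`` (and no breathing/drift) every frame is identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .core_io import (
    ImageSequence,
    ROI,
    ROISet,
    read_rois,
    read_sequence,
    write_rois,
    write_sequence,
)
from .errors import ConfigError

__all__ = [
    "GroupParams",
    "PhantomConfig",
    "PhantomCohort",
    "roi_grid",
    "generate_case",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "load_preset",
]

#: Default frame rate: one 35-frame respiratory cycle per 4.5 s.
DEFAULT_FRAME_RATE_HZ = 35.0 / 4.5


@dataclass
class GroupParams:
    """Per-group intensity parameters (8-bit gray-level units).

    ``mu``: mean echo intensity; ``sigma_within``: fine speckle spread
    within an ROI; ``sigma_structure``: SD of the smooth regional-
    heterogeneity field; ``sigma_between``: spread of the per-case global
    mean around ``mu`` (kept small — a large frame-constant case offset
    would separate intra from inter divergence regardless of ``rho``).
    """

    mu: float
    sigma_within: float
    sigma_structure: float = 7.0
    sigma_between: float = 0.5


def _default_groups() -> dict[str, GroupParams]:
    # liver-pathology scale: echo-intensity means and within-ROI speckle
    # spreads; regional heterogeneity ordered fibrosis > steatosis > normal
    return {
        "normal": GroupParams(mu=25.4, sigma_within=13.2, sigma_structure=6.0),
        "steatosis": GroupParams(mu=34.7, sigma_within=12.0, sigma_structure=7.0),
        "fibrosis": GroupParams(mu=55.9, sigma_within=16.3, sigma_structure=10.0),
    }


@dataclass
class PhantomConfig:
    """Full description of a synthetic cohort; serializable to YAML/JSON."""

    groups: dict[str, GroupParams] = field(default_factory=_default_groups)
    cases_per_group: int | dict[str, int] = 4
    frames_per_case: int = 60
    frame_size: tuple[int, int] = (96, 96)  # (H, W)
    rois_per_frame: int = 5
    roi_size: tuple[int, int] = (24, 24)  # (h, w)
    rho: float = 0.9
    breath_period_frames: int = 35
    breath_amplitude: float = 4.0
    amp_growth: float = 1.15
    drift_per_frame: float = 0.02
    gamma_shape: float = 4.0
    struct_scale_px: float = 8.0
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        self.groups = {
            name: params if isinstance(params, GroupParams) else GroupParams(**params)
            for name, params in self.groups.items()
        }
        if not 0.0 <= self.rho <= 1.0:
            raise ConfigError(f"rho must be in [0, 1], got {self.rho}")
        if self.breath_period_frames < 2:
            raise ConfigError("breath_period_frames must be >= 2")
        if self.amp_growth < 1.0:
            raise ConfigError("amp_growth must be >= 1")
        if self.gamma_shape <= 0:
            raise ConfigError("gamma_shape must be > 0")
        self.frame_size = tuple(self.frame_size)  # type: ignore[assignment]
        self.roi_size = tuple(self.roi_size)  # type: ignore[assignment]

    def n_cases(self, group: str) -> int:
        if isinstance(self.cases_per_group, Mapping):
            return int(self.cases_per_group[group])
        return int(self.cases_per_group)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame_size"] = list(self.frame_size)
        d["roi_size"] = list(self.roi_size)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhantomConfig":
        d = dict(d)
        if "groups" in d:
            d["groups"] = {
                name: params
                if isinstance(params, GroupParams)
                else GroupParams(**params)
                for name, params in d["groups"].items()
            }
        return cls(**d)


@dataclass
class PhantomCohort:
    """Generated sequences + ROI sets with the ground-truth config."""

    sequences: list[ImageSequence]
    rois: dict[str, ROISet]
    truth: PhantomConfig


def roi_grid(config: PhantomConfig) -> list[ROI]:
    """Place R non-overlapping ROIs on a fixed grid (same layout for every
    case, so inter-case divergence reflects content, not geometry)."""
    H, W = config.frame_size
    rh, rw = config.roi_size
    margin, gap = 4, 4
    n_cols = max(0, (W - 2 * margin + gap) // (rw + gap))
    n_rows = max(0, (H - 2 * margin + gap) // (rh + gap))
    if n_cols * n_rows < config.rois_per_frame:
        raise ConfigError(
            f"cannot place {config.rois_per_frame} ROIs of {rh}x{rw} on a "
            f"{H}x{W} frame (grid fits {n_cols * n_rows})"
        )
    rois = []
    for k in range(config.rois_per_frame):
        row, col = divmod(k, n_cols)
        rois.append(
            ROI(
                roi_id=k,
                x=margin + col * (rw + gap),
                y=margin + row * (rh + gap),
                w=rw,
                h=rh,
            )
        )
    return rois


def _speckle_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    params: GroupParams,
    config: PhantomConfig,
) -> np.ndarray:
    """Mean-zero speckle field: fine gamma noise + smooth regional structure."""
    k = config.gamma_shape
    fine = (rng.gamma(k, 1.0 / k, size=shape) - 1.0) * (
        params.sigma_within * np.sqrt(k)
    )
    s = config.struct_scale_px
    if params.sigma_structure > 0 and s > 0:
        smooth = gaussian_filter(rng.standard_normal(shape), sigma=s, mode="wrap")
        # a unit-variance white field filtered by a gaussian kernel has
        # SD ~ 1/(2 sqrt(pi) s) per dimension; rescale to sigma_structure
        smooth *= params.sigma_structure * (2.0 * np.sqrt(np.pi) * s)
        fine += smooth
    return fine


def generate_case(
    case_id: str,
    group: str,
    params: GroupParams,
    config: PhantomConfig,
    seed: int | np.random.SeedSequence,
) -> tuple[ImageSequence, ROISet]:
    """Generate one case's frame stack and its ROI grid."""
    rng = np.random.default_rng(seed)
    H, W = config.frame_size
    F = config.frames_per_case
    T = config.breath_period_frames
    rho = config.rho

    base = params.mu + rng.normal(0.0, params.sigma_between)
    persistent = _speckle_field(rng, (H, W), params, config)
    frames = np.empty((F, H, W), dtype=np.uint8)
    fresh_scale = np.sqrt(max(0.0, 1.0 - rho**2))
    for t in range(F):
        fresh = _speckle_field(rng, (H, W), params, config)
        amp = config.breath_amplitude * config.amp_growth ** (t / T)
        img = (
            base
            + rho * persistent
            + fresh_scale * fresh
            + amp * np.sin(2.0 * np.pi * t / T)
            + config.drift_per_frame * t
        )
        frames[t] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    sequence = ImageSequence(
        case_id=case_id,
        group=group,
        frames=frames,
        frame_rate_hz=config.frame_rate_hz,
    )
    roi_set = ROISet.broadcast(roi_grid(config), F)
    roi_set.validate_against(sequence)
    return sequence, roi_set


def generate_cohort(config: PhantomConfig) -> PhantomCohort:
    """Generate the full multi-group cohort, bit-reproducible from the seed."""
    root = np.random.SeedSequence(config.seed)
    sequences: list[ImageSequence] = []
    rois: dict[str, ROISet] = {}
    groups = sorted(config.groups)
    case_seeds = root.spawn(sum(config.n_cases(g) for g in groups))
    i = 0
    for group in groups:
        params = config.groups[group]
        for c in range(config.n_cases(group)):
            case_id = f"{group}_{c:02d}"
            seq, roi_set = generate_case(case_id, group, params, config, case_seeds[i])
            sequences.append(seq)
            rois[case_id] = roi_set
            i += 1
    return PhantomCohort(sequences=sequences, rois=rois, truth=config)


def write_cohort(cohort: PhantomCohort, path: str | Path) -> None:
    """Write a cohort as ``<case_id>/frames.tif`` + ``rois.csv`` per case,
    plus cohort-level ``cases.csv`` and ``truth.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    index = []
    for seq in cohort.sequences:
        case_dir = path / seq.case_id
        write_sequence(seq, case_dir / "frames.tif")
        write_rois(cohort.rois[seq.case_id], case_dir / "rois.csv")
        index.append(
            {
                "case_id": seq.case_id,
                "group": seq.group,
                "n_frames": seq.n_frames,
                "frame_rate_hz": seq.frame_rate_hz,
            }
        )
    pd.DataFrame(
        index, columns=["case_id", "group", "n_frames", "frame_rate_hz"]
    ).to_csv(path / "cases.csv", index=False)
    (path / "truth.json").write_text(json.dumps(cohort.truth.to_dict(), indent=2))


def read_cohort(path: str | Path) -> PhantomCohort:
    """Read a cohort written by :func:`write_cohort`."""
    path = Path(path)
    index = pd.read_csv(path / "cases.csv")
    truth_file = path / "truth.json"
    truth = (
        PhantomConfig.from_dict(json.loads(truth_file.read_text()))
        if truth_file.exists()
        else PhantomConfig()
    )
    sequences = []
    rois = {}
    for row in index.itertuples():
        case_dir = path / str(row.case_id)
        seq = read_sequence(
            case_dir / "frames.tif",
            case_id=str(row.case_id),
            group=str(row.group),
            frame_rate_hz=None if pd.isna(row.frame_rate_hz) else float(row.frame_rate_hz),
        )
        sequences.append(seq)
        rois[seq.case_id] = read_rois(case_dir / "rois.csv", seq)
    return PhantomCohort(sequences=sequences, rois=rois, truth=truth)


def load_preset(name_or_path: str | Path) -> PhantomConfig:
    """Load a phantom config from a bundled preset name (e.g. ``table1``)
    or a YAML/JSON file path."""
    p = Path(name_or_path)
    if p.suffix in (".yaml", ".yml", ".json") and p.exists():
        text = p.read_text()
    else:
        ref = resources.files("frameindep").joinpath(f"presets/{name_or_path}.yaml")
        if not ref.is_file():
            raise ConfigError(f"no such preset or config file: {name_or_path}")
        text = ref.read_text()
    data = yaml.safe_load(text)
    return PhantomConfig.from_dict(data)
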