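"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(x, y)`` with x rightwards and y downwards;
* grid modules are 0-based ``(row, col)`` cells of the segmentation grid
  (default 72x96 cells of 5x5 px over a 360x480 frame);
* intervals of grid modules are half-open ``[start, end)``;
* per-point perfusion classes are encoded as integers via :data:`CLASSES`
  (``0=good, 1=expert, 2=poor``); the integer order is also the deterministic
  tie-break order used by the point classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Perfusion class names, indexed by integer label.
CLASSES: tuple[str, ...] = ("good", "expert", "poor")
GOOD, EXPERT, POOR = 0, 1, 2

#: Feature names in column order of every (n, 4) feature matrix.
FEATURE_NAMES: tuple[str, ...] = ("i_max", "upslope", "t_max", "t_half")


class ICGFAError(Exception):
    """Base class for all package errors."""


class FormatError(ICGFAError):
    """Malformed input frame/series (wrong shape, dtype, channel count)."""


class GeometryError(ICGFAError):
    """Line or band geometry inconsistent with the frame/annotation."""


class InputError(ICGFAError):
    """Invalid numeric input (too short series, non-monotone time...)."""


class ContractError(ICGFAError):
    """A documented API pre-condition was violated by the caller."""


@dataclass
class FramePairSequence:
    """Time-stamped paired white-light and fluorescence frames.

    ``white`` is (T, H, W, 3); ``nir`` is the native NIR grayscale stack
    (T, H, W) and is present in ``native`` mode. In ``overlay`` mode the
    imager exposes the fluorescence only as a green tint over the white-light
    image: ``display`` (T, H, W, 3) holds those frames and ``nir`` may be
    absent. ``validity`` marks pixels that carry real image content (it is
    filled in by stabilisation for warped-in border pixels).
    """

    white: np.ndarray
    times: np.ndarray
    mode: str = "native"
    nir: Optional[np.ndarray] = None
    display: Optional[np.ndarray] = None
    validity: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("native", "overlay"):
            raise FormatError(f"unknown mode {self.mode!r}")
        if self.white.ndim != 4 or self.white.shape[-1] != 3:
            raise FormatError("white must be (T, H, W, 3)")
        if self.mode == "native" and self.nir is None:
            raise FormatError("native mode requires an NIR stack")
        if self.mode == "overlay" and self.display is None:
            raise FormatError("overlay mode requires a display stack")
        if len(self.times) != len(self.white):
            raise FormatError("times and frames disagree in length")

    def __len__(self) -> int:
        return len(self.white)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.white.shape[1], self.white.shape[2]


@dataclass
class GroundTruthAnnotation:
    """Per-segment annotation: sampled line, per-module labels, stapler band.

    ``line`` is an ordered (n, 2) array of pixel coordinates from the
    perfused (proximal) end towards the non-perfused (distal) end.
    ``labels`` has one class per grid module along the line. ``stapler_band``
    is the half-open interval of grid columns covered by the stapler
    (None for poor-perfusion segments where no transection site exists).
    """

    line: np.ndarray
    labels: np.ndarray
    stapler_center: Optional[int]
    stapler_band: Optional[tuple[int, int]]
    boundary_col: Optional[int] = None
    line_cols: Optional[np.ndarray] = None
    expert_id: int = 0

    def band_in_line_index(self) -> Optional[tuple[int, int]]:
        """Stapler band converted from absolute grid columns to indices
        along the annotated line (None when there is no band)."""
        if self.stapler_band is None or self.line_cols is None:
            return None
        start = int(np.searchsorted(self.line_cols, self.stapler_band[0]))
        end = int(np.searchsorted(self.line_cols, self.stapler_band[1]))
        return start, end


@dataclass
class GridIntensitySeries:
    """Per-grid-cell fluorescence intensity time series.

    ``values`` is (rows, cols, T) mean cell intensity on the 0-255 scale,
    ``valid`` the matching boolean mask (False where warping left a cell
    without usable pixels), ``times`` the frame times in seconds.
    """

    values: np.ndarray
    times: np.ndarray
    valid: np.ndarray
    cell_shape: tuple[int, int]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[0], self.values.shape[1]


@dataclass
class CurveFeatures:
    """The four intensity-time milestones of one fluorescence inflow curve:
    peak intensity, inflow upslope (units/s), and the times (s, from window
    start) to the peak and to the first half-peak crossing."""

    i_max: float
    upslope: float
    t_max: float
    t_half: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.i_max, self.upslope, self.t_max, self.t_half])


@dataclass
class FeatureGrid:
    """Milestone features per grid cell, plus validity/degeneracy masks."""

    features: np.ndarray          # (rows, cols, 4) in FEATURE_NAMES order
    valid: np.ndarray             # (rows, cols) bool
    degenerate: np.ndarray        # (rows, cols) bool
    onset_time: float             # seconds from recording start
    window: float                 # seconds of inflow used
    normalized: bool = False

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.features.shape[0], self.features.shape[1]


@dataclass
class LineSample:
    """One condensed, labelled line across the perfusion boundary.

    ``coords`` is the (n, 2) array of grid modules (row, col) along the
    line, proximal to distal; ``features`` the (n, 4) condensed milestone
    matrix; ``labels`` the per-coordinate class (may be None at predict
    time).
    """

    coords: np.ndarray
    features: np.ndarray
    labels: Optional[np.ndarray]
    video_id: str = ""
    expert_id: int = 0
    line_id: int = 0

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class Dataset:
    """A collection of line samples with a train/validation/test split
    keyed by video id (no video ever spans two splits)."""

    samples: list[LineSample]
    split: dict[str, str] = field(default_factory=dict)

    def subset(self, part: str) -> list[LineSample]:
        return [s for s in self.samples if self.split.get(s.video_id) == part]

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in CLASSES}
        for s in self.samples:
            if s.labels is None:
                continue
            for c, n in zip(*np.unique(s.labels, return_counts=True)):
                counts[CLASSES[int(c)]] += int(n)
        return counts


@dataclass
class ZonePrediction:
    """Per-coordinate predicted labels plus the extracted expert interval.

    ``expert_zone`` is the longest contiguous run of expert labels (line
    index space, half-open) when one of qualifying length exists; otherwise
    ``no_prediction`` is set -- the display then shows only the non-expert
    zoning, as on mal-perfused bowel.
    """

    labels: np.ndarray
    expert_zone: Optional[tuple[int, int]]
    no_prediction: bool
    posteriors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.no_prediction != (self.expert_zone is None):
            raise ContractError("no_prediction must mirror a missing zone")


def labels_from_names(names: Sequence[str]) -> np.ndarray:
    """Convert class-name strings to the integer encoding."""
    lookup = {name: i for i, name in enumerate(CLASSES)}
    return np.array([lookup[n] for n in names], dtype=np.int64)
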