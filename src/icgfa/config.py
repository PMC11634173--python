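"""Configuration schemas (scene, features, models, evaluation) with YAML IO.

Every config is a frozen-ish dataclass with validation in ``__post_init__``;
``load_config``/``dump_config`` round-trip them through YAML and reject
unknown keys so a typo in a config file fails loudly instead of silently
falling back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .containers import ICGFAError


class ConfigError(ICGFAError):
    """Invalid or inconsistent configuration."""


Range = tuple[float, float]


def _check_range(name: str, r: Range) -> None:
    if len(r) != 2 or r[0] > r[1]:
        raise ConfigError(f"{name} must be (low, high) with low <= high, got {r}")


@dataclass
class ZoneKinetics:
    """Per-zone ranges for the gamma-variate inflow parameters.

    ``amplitude`` is the peak rise above baseline (0-255 intensity units),
    ``arrival`` the dye arrival delay t0 (s), ``time_to_peak`` the rise time
    tp from arrival to peak (s), ``shape`` the dimensionless gamma-variate
    exponent. Concrete values are drawn uniformly from each range per scene.
    """

    amplitude: Range
    arrival: Range
    time_to_peak: Range
    shape: Range

    def __post_init__(self) -> None:
        for name in ("amplitude", "arrival", "time_to_peak", "shape"):
            _check_range(name, tuple(getattr(self, name)))
        if self.time_to_peak[0] <= 0 or self.shape[0] <= 0:
            raise ConfigError("time_to_peak and shape must be positive")


def _default_zone_params() -> dict:
    # Well-perfused bowel fills early and brightly; the expert band sits on
    # the perfused side of the boundary with intermediate kinetics; poor
    # bowel shows only a weak, late rise (diffusion rather than inflow).
    return {
        "good": ZoneKinetics((150.0, 180.0), (10.0, 14.0), (13.0, 18.0), (1.8, 2.5)),
        "expert": ZoneKinetics((70.0, 110.0), (14.0, 18.0), (19.0, 25.0), (1.8, 2.5)),
        "poor": ZoneKinetics((4.0, 14.0), (26.0, 34.0), (30.0, 40.0), (1.8, 2.5)),
    }


@dataclass
class SceneConfig:
    """Parameters of one synthetic angiography scene.

    The frame geometry mirrors the segmentation convention used throughout
    (72x96 grid of 5x5 px modules over 360x480 frames) and recordings last
    at least 90 s after injection. ``boundary_pos`` places the
    fluorescent/non-fluorescent boundary as a fraction of frame width;
    ``expert_width`` is the stapler calibration (~12 grid modules).
    ``perfusion="poor"`` renders a mal-perfused segment with no expert band.
    """

    frame_height: int = 360
    frame_width: int = 480
    grid_rows: int = 72
    grid_cols: int = 96
    fps: float = 2.0
    duration: float = 90.0
    boundary_pos: float = 0.55
    expert_width: int = 12
    zone_params: dict = field(default_factory=_default_zone_params)
    baseline_range: Range = (5.0, 10.0)
    noise_sd: float = 3.0
    motion_amplitude: float = 2.0
    perfusion: str = "normal"
    band_row_range: tuple[int, int] = (20, 52)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_height % self.grid_rows or self.frame_width % self.grid_cols:
            raise ConfigError("frame dimensions must be divisible by the grid")
        if not 0.0 <= self.boundary_pos <= 1.0:
            raise ConfigError("boundary_pos must lie in [0, 1]")
        if self.expert_width < 1:
            raise ConfigError("expert_width must be >= 1 grid module")
        if self.duration < 30.0:
            raise ConfigError("duration must cover the 30 s inflow window")
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        if self.perfusion not in ("normal", "poor"):
            raise ConfigError("perfusion must be 'normal' or 'poor'")
        if self.noise_sd < 0 or self.motion_amplitude < 0:
            raise ConfigError("noise_sd and motion_amplitude must be >= 0")
        zp = {}
        for zone, params in self.zone_params.items():
            if isinstance(params, dict):
                params = ZoneKinetics(**{k: tuple(v) for k, v in params.items()})
            zp[zone] = params
        self.zone_params = zp
        for zone in ("good", "expert", "poor"):
            if zone not in self.zone_params:
                raise ConfigError(f"zone_params missing zone {zone!r}")
        a_good = self.zone_params["good"].amplitude
        a_exp = self.zone_params["expert"].amplitude
        a_poor = self.zone_params["poor"].amplitude
        if not (a_good[0] > a_exp[0] > a_poor[1]):
            raise ConfigError(
                "zone amplitudes must satisfy A_good > A_expert_min > A_poor"
            )

    @property
    def cell_shape(self) -> tuple[int, int]:
        return (self.frame_height // self.grid_rows,
                self.frame_width // self.grid_cols)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps)) + 1

    @property
    def times(self):
        import numpy as np

        return np.arange(self.n_frames) / self.fps


@dataclass
class FeatureConfig:
    """Milestone-extraction parameters."""

    window: float = 30.0          # seconds of inflow used for prediction
    smooth_window: int = 3        # centred moving-average width (frames)
    baseline_frames: int = 3      # frames averaged for the curve baseline
    onset_frac: float = 0.1       # rise fraction defining inflow onset
    half_frac: float = 0.5        # rise fraction defining t_half
    upslope_mode: str = "onset_to_peak"   # or "max_derivative"
    min_intensity_range: float = 32.0     # normalisation denominator floor
    min_upslope_range: float = 2.0
    min_valid_fraction: float = 0.5       # cell validity over the window

    def __post_init__(self) -> None:
        if self.window <= 0 or self.smooth_window < 1:
            raise ConfigError("window must be > 0 and smooth_window >= 1")
        if self.upslope_mode not in ("onset_to_peak", "max_derivative"):
            raise ConfigError("unknown upslope_mode")


@dataclass
class SamplingConfig:
    """Line sampling / augmentation parameters."""

    rect_height: int = 35         # px, perpendicular extent of the rectangle
    n_lines: int = 4              # augmentation lines per segment
    length_jitter: float = 0.2    # +/- fraction of base line length
    max_offset: int = 10          # grid modules of perpendicular offset
    median_raw_curves: bool = False  # median intensities before milestones

    def __post_init__(self) -> None:
        if self.rect_height < 1 or self.n_lines < 1:
            raise ConfigError("rect_height and n_lines must be >= 1")


@dataclass
class KNNConfig:
    k: int = 10
    n_folds: int = 10

    def __post_init__(self) -> None:
        if self.k < 1 or self.n_folds < 2:
            raise ConfigError("k >= 1 and n_folds >= 2 required")


@dataclass
class LSTMConfig:
    """Training hyper-parameters of the sequence model."""

    hidden_units: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 60
    patience: int = 5
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ConfigError("hidden_units, max_epochs, patience must be >= 1")


@dataclass
class EvalConfig:
    min_run: int = 6              # modules needed to qualify as an expert zone
    hit_rule: str = "center"      # or "overlap"
    overlay_alpha: float = 0.4

    def __post_init__(self) -> None:
        if self.hit_rule not in ("center", "overlap"):
            raise ConfigError("hit_rule must be 'center' or 'overlap'")


_SECTIONS = {
    "scene": SceneConfig,
    "features": FeatureConfig,
    "sampling": SamplingConfig,
    "knn": KNNConfig,
    "lstm": LSTMConfig,
    "evaluation": EvalConfig,
}


@dataclass
class RunConfig:
    """Top-level run configuration grouping all per-stage sections."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    knn: KNNConfig = field(default_factory=KNNConfig)
    lstm: LSTMConfig = field(default_factory=LSTMConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path_or_dict) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file path or a plain dict."""
    if isinstance(path_or_dict, dict):
        data = path_or_dict
    else:
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {name: _build(cls, data.get(name, {}) or {})
              for name, cls in _SECTIONS.items()}
    return RunConfig(seed=int(data.get("seed", 0)), **kwargs)


def dump_config(config: RunConfig, path) -> None:
    """Write the fully resolved configuration as YAML."""

    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(encode(config), fh, sort_keys=False)
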