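"""Intensity-time curve milestones and their normalisation.

Each spatial location's fluorescence inflow curve is summarised by four
milestones -- the standard angiographic description of bolus arrival:

* ``i_max``   peak intensity of the (lightly smoothed) curve;
* ``t_max``   time from window start to the first attainment of the peak;
* ``t_half``  time to the first upward crossing of half the rise above
  baseline (linearly interpolated between samples);
* ``upslope`` the inflow slope ``(i_max - baseline) / (t_max - t_onset)``
  with onset defined by the 10%-rise crossing.

The baseline is the mean of the first three smoothed samples (recordings
start at injection, so early frames are pre-inflow). Milestones are
computed over a fixed window (default 30 s) starting at the recording's
global inflow onset, which makes times comparable across recordings with
different injection-to-arrival delays.
"""

from __future__ import annotations

import warnings

import numpy as np

from .config import FeatureConfig
from .containers import (
    CurveFeatures,
    FeatureGrid,
    GridIntensitySeries,
    ICGFAError,
    InputError,
)

__all__ = ["compute_milestones", "featurize_grid", "normalize_features",
           "FeatureScaling", "detect_onset", "NoInflowError"]


class NoInflowError(ICGFAError):
    """No inflow onset was detected in the recording."""


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average along the last axis; the window shrinks at
    the series edges so no phantom samples are introduced."""
    if window <= 1:
        return values.astype(np.float64)
    half = window // 2
    n = values.shape[-1]
    cum = np.cumsum(np.concatenate(
        [np.zeros(values.shape[:-1] + (1,)), values], axis=-1), axis=-1)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (cum[..., hi] - cum[..., lo]) / (hi - lo)


def _first_crossing(smoothed: np.ndarray, times: np.ndarray,
                    level: np.ndarray, idx_max: np.ndarray,
                    start_interval: np.ndarray | None = None):
    """First upward crossing of ``level`` at or before the peak sample,
    linearly interpolated; vectorised over leading axes.

    Returns (crossing_time, crossing_interval). Curves already at or above
    the level at the first considered sample cross at that sample's time.
    """
    n = smoothed.shape[-1]
    lvl = level[..., None]
    steps = np.arange(1, n)
    rising = (smoothed[..., 1:] >= lvl) & (smoothed[..., :-1] < lvl)
    rising &= steps <= idx_max[..., None]
    if start_interval is not None:
        rising &= steps >= np.maximum(start_interval[..., None], 1)
    has = rising.any(axis=-1)
    j = np.where(has, rising.argmax(axis=-1) + 1, 1)
    s_lo = np.take_along_axis(smoothed, (j - 1)[..., None], -1)[..., 0]
    s_hi = np.take_along_axis(smoothed, j[..., None], -1)[..., 0]
    t_lo = times[j - 1]
    t_hi = times[j]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (level - s_lo) / (s_hi - s_lo)
    t_cross = t_lo + np.clip(frac, 0.0, 1.0) * (t_hi - t_lo)
    # already above the level at the start of the considered range
    first = (start_interval if start_interval is not None
             else np.zeros_like(idx_max))
    s_first = np.take_along_axis(smoothed, first[..., None], -1)[..., 0]
    above = s_first >= level
    t_cross = np.where(above, times[first], t_cross)
    j = np.where(above, first, j)
    t_cross = np.where(has | above, t_cross, np.nan)
    return t_cross, j


def _milestones(values: np.ndarray, times: np.ndarray,
                config: FeatureConfig):
    """Vectorised milestone computation over (..., T) curves.

    Returns (features (..., 4), degenerate mask). Times are measured from
    ``times[0]``.
    """
    values = np.asarray(values, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    n = values.shape[-1]
    if n < 3:
        raise InputError("need at least 3 samples per curve")
    if np.any(np.diff(times) <= 0):
        raise InputError("times must be strictly increasing")
    s = _smooth(values, config.smooth_window)
    baseline = s[..., :config.baseline_frames].mean(axis=-1)
    i_max = s.max(axis=-1)
    idx_max = s.argmax(axis=-1)       # first attainment of the max
    rel = times - times[0]
    t_max = rel[idx_max]
    rise = i_max - baseline
    degenerate = rise <= 1e-9

    onset_level = baseline + config.onset_frac * rise
    half_level = baseline + config.half_frac * rise
    t_onset, j_onset = _first_crossing(s, rel, onset_level, idx_max)
    t_half, _ = _first_crossing(s, rel, half_level, idx_max,
                                start_interval=np.maximum(j_onset - 1, 0))
    t_onset = np.where(np.isnan(t_onset), 0.0, t_onset)
    t_half = np.where(np.isnan(t_half), t_max, t_half)
    # enforce the milestone ordering t_onset <= t_half <= t_max even on
    # pathological non-monotone curves
    t_half = np.clip(t_half, t_onset, t_max)

    if config.upslope_mode == "max_derivative":
        slope = np.diff(s, axis=-1) / np.diff(rel)
        upslope = slope.max(axis=-1)
    else:
        dt = t_max - t_onset
        with np.errstate(invalid="ignore", divide="ignore"):
            upslope = np.where(dt > 0, rise / np.where(dt > 0, dt, 1.0), 0.0)
    upslope = np.maximum(upslope, 0.0)

    feats = np.stack([i_max, upslope, t_max, t_half], axis=-1)
    zeros = np.zeros_like(feats)
    feats = np.where(degenerate[..., None], zeros, feats)
    return feats, degenerate


def compute_milestones(series: np.ndarray, times: np.ndarray,
                       config: FeatureConfig | None = None) -> CurveFeatures:
    """Milestones of a single intensity-time series (see module docstring).

    A flat series yields all-zero features with the ``degenerate`` flag.
    """
    config = config or FeatureConfig()
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise InputError("series must be 1-D; use featurize_grid for grids")
    feats, degen = _milestones(series[None, :], times, config)
    return CurveFeatures(i_max=float(feats[0, 0]), upslope=float(feats[0, 1]),
                         t_max=float(feats[0, 2]), t_half=float(feats[0, 3]),
                         degenerate=bool(degen[0]))


def detect_onset(grid: GridIntensitySeries,
                 config: FeatureConfig | None = None) -> int:
    """Frame index of global inflow onset.

    The spatial mean over valid cells is tracked; onset is the first frame
    where it exceeds its early baseline by 3 baseline standard deviations
    (with a small absolute floor for noiseless recordings).
    """
    config = config or FeatureConfig()
    vals = np.where(grid.valid, grid.values, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_series = np.nanmean(vals, axis=(0, 1))
    k = max(config.baseline_frames, 3)
    base = mean_series[:k].mean()
    sd = mean_series[:k].std()
    threshold = base + max(3.0 * sd, 0.5)
    above = mean_series > threshold
    if not above.any():
        raise NoInflowError("global mean never exceeded the onset threshold")
    return int(above.argmax())


def featurize_grid(grid: GridIntensitySeries,
                   config: FeatureConfig | None = None) -> FeatureGrid:
    """Milestones per grid cell over the inflow window.

    The window spans ``[onset, onset + window]``; a window that outruns the
    recording is truncated with a warning. Cells invalid in more than half
    of the window frames are flagged invalid (their features are NaN).
    """
    config = config or FeatureConfig()
    onset_idx = detect_onset(grid, config)
    times = grid.times
    t_end = times[onset_idx] + config.window
    if t_end > times[-1]:
        warnings.warn("inflow window outruns the recording; truncating")
    stop = int(np.searchsorted(times, t_end, side="right"))
    sel = slice(onset_idx, max(stop, onset_idx + 3))
    vals = grid.values[:, :, sel]
    vmask = grid.valid[:, :, sel]
    window_times = times[sel]

    valid = vmask.mean(axis=-1) >= config.min_valid_fraction
    # fill the occasional warped-out frame by previous-valid values so the
    # milestone scan sees a complete curve
    filled = vals.copy()
    if not vmask.all():
        idx = np.where(vmask, np.arange(vmask.shape[-1]), 0)
        idx = np.maximum.accumulate(idx, axis=-1)
        filled = np.take_along_axis(vals, idx, axis=-1)
        filled = np.where(np.isnan(filled), 0.0, filled)

    feats, degen = _milestones(filled.reshape(-1, filled.shape[-1]),
                               window_times, config)
    rows, cols = grid.grid_shape
    feats = feats.reshape(rows, cols, 4)
    degen = degen.reshape(rows, cols)
    feats = np.where(valid[..., None], feats, np.nan)
    return FeatureGrid(features=feats.astype(np.float64), valid=valid,
                       degenerate=degen, onset_time=float(times[onset_idx]),
                       window=float(config.window))


class FeatureScaling:
    """Per-recording feature scaling with exact inversion.

    Intensity-like features (i_max, upslope) are min-max scaled to [0, 1];
    the denominator is floored at a minimal physiologic dynamic range so a
    recording with no real inflow (mal-perfused bowel) is not noise-
    stretched to full scale. Time features are divided by the window length.
    """

    def __init__(self, mins: np.ndarray, scales: np.ndarray):
        self.mins = np.asarray(mins, dtype=float)
        self.scales = np.asarray(scales, dtype=float)

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (features - self.mins) / self.scales

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        return scaled * self.scales + self.mins


def normalize_features(fg: FeatureGrid, config: FeatureConfig | None = None
                       ) -> tuple[FeatureGrid, FeatureScaling]:
    """Per-recording normalisation of a feature grid (see FeatureScaling).

    Raises :class:`InputError` when no non-degenerate valid cell exists.
    """
    config = config or FeatureConfig()
    usable = fg.valid & ~fg.degenerate
    if not usable.any():
        raise InputError("no valid, non-degenerate cells to normalise")
    feats = fg.features
    sub = feats[usable]
    mins = np.zeros(4)
    scales = np.ones(4)
    for col, floor in ((0, config.min_intensity_range),
                       (1, config.min_upslope_range)):
        lo = float(sub[:, col].min())
        hi = float(sub[:, col].max())
        mins[col] = lo
        scales[col] = max(hi - lo, floor)
    scales[2] = scales[3] = fg.window
    scaling = FeatureScaling(mins, scales)
    out = scaling.transform(feats)
    out = np.where(usable[..., None], out, np.nan)
    return FeatureGrid(features=out, valid=fg.valid, degenerate=fg.degenerate,
                       onset_time=fg.onset_time, window=fg.window,
                       normalized=True), scaling
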