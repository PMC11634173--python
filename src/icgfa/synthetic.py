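"""Synthetic fluorescence-angiography scene generation.

Real recordings pair a white-light view of the bowel with a near-infrared
(NIR) channel in which the ICG bolus lights up perfused tissue over ~90 s.
This module emulates that situation with known ground truth: a horizontal
bowel band whose inflow kinetics vary smoothly along its length from
well-perfused ("good") through the recommended stapling band ("expert") to
non-perfused ("poor") tissue, a gamma-variate bolus model per location,
sensor noise, per-frame affine camera jitter, and both native-NIR and
green-overlay display renderings.

Every random draw flows from ``SceneConfig.seed``, so a fixed seed yields a
byte-identical scene.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.transform import AffineTransform as _SkAffine

from .config import ConfigError, SceneConfig
from .containers import (
    EXPERT,
    GOOD,
    POOR,
    FormatError,
    FramePairSequence,
    GroundTruthAnnotation,
)

__all__ = [
    "simulate_curve",
    "render_scene",
    "render_overlay_mode",
    "expert_annotations",
]


def simulate_curve(params: dict, times: np.ndarray) -> np.ndarray:
    """Gamma-variate bolus-passage curve for one location.

    ``I(t) = baseline`` for ``t <= t0`` and
    ``I(t) = baseline + A * ((t-t0)/tp)**alpha * exp(alpha*(1-(t-t0)/tp))``
    afterwards, which peaks at exactly ``baseline + A`` at ``t = t0 + tp``.

    Parameters
    ----------
    params
        Mapping with keys ``amplitude`` (A), ``arrival`` (t0, s),
        ``time_to_peak`` (tp, s), ``shape`` (alpha) and ``baseline``.
    times
        Strictly increasing sample times in seconds.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ConfigError("times must be strictly increasing")
    tp = float(params["time_to_peak"])
    alpha = float(params["shape"])
    if tp <= 0 or alpha <= 0:
        raise ConfigError("time_to_peak and shape must be positive")
    a = float(params["amplitude"])
    t0 = float(params["arrival"])
    base = float(params.get("baseline", 0.0))
    tau = np.maximum(times - t0, 0.0) / tp
    with np.errstate(divide="ignore"):
        curve = base + a * tau ** alpha * np.exp(alpha * (1.0 - tau))
    curve[times <= t0] = base
    return curve


def _draw_zone_values(rng: np.random.Generator, config: SceneConfig) -> dict:
    """Draw one concrete parameter set per zone from the configured ranges."""
    values = {}
    for zone, kin in config.zone_params.items():
        values[zone] = {
            "amplitude": rng.uniform(*kin.amplitude),
            "arrival": rng.uniform(*kin.arrival),
            "time_to_peak": rng.uniform(*kin.time_to_peak),
            "shape": rng.uniform(*kin.shape),
        }
    base = rng.uniform(*config.baseline_range)
    for zone in values:
        values[zone]["baseline"] = base
    return values


def _column_params(config: SceneConfig, zone_values: dict) -> dict:
    """Piecewise-linear kinetic parameter profile per pixel column.

    Parameters are constant at the good-zone values up to the proximal edge
    of the expert band, interpolate good -> expert -> poor across the band,
    and stay at the poor values beyond the boundary. The interpolation
    breakpoints therefore coincide with the label run boundaries.
    """
    cell_w = config.cell_shape[1]
    b_col = int(round(config.boundary_pos * config.grid_cols))
    b_col = min(max(b_col, config.expert_width + 2), config.grid_cols - 2)
    band_start = b_col - config.expert_width
    x = np.arange(config.frame_width) + 0.5
    if config.perfusion == "poor":
        # Mal-perfused segment: weak late kinetics everywhere, mild gradient.
        xp = [0.0, config.frame_width]
        mix = np.interp(x, xp, [0.0, 1.0])
        out = {}
        for key in ("amplitude", "arrival", "time_to_peak", "shape", "baseline"):
            lo = zone_values["poor"][key]
            hi = zone_values["poor"][key] * (0.6 if key == "amplitude" else 1.0)
            out[key] = lo + (hi - lo) * mix
        return {"columns": out, "boundary_col": None,
                "band": None, "b_col": None}
    xp = np.array([
        band_start * cell_w,
        (band_start + config.expert_width / 2.0) * cell_w,
        b_col * cell_w,
    ])
    out = {}
    for key in ("amplitude", "arrival", "time_to_peak", "shape", "baseline"):
        fp = np.array([
            zone_values["good"][key],
            zone_values["expert"][key],
            zone_values["poor"][key],
        ])
        out[key] = np.interp(x, xp, fp)
    return {"columns": out, "boundary_col": b_col,
            "band": (band_start, b_col), "b_col": b_col}


def _procedural_texture(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Seeded multi-scale blob texture in [0, 1] with trackable structure."""
    tex = np.zeros(shape, dtype=np.float64)
    for sigma, weight in ((2.0, 1.0), (6.0, 1.0), (14.0, 0.8)):
        layer = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
        tex += weight * layer / (layer.std() + 1e-12)
    tex -= tex.min()
    tex /= tex.max() + 1e-12
    return tex


def _white_light_image(rng: np.random.Generator, config: SceneConfig) -> np.ndarray:
    """Static white-light luminance plane (H, W) float in [50, 230].

    The RGB tissue image derives from this plane via :func:`_compose_white`
    with G = max(R, B) per pixel, which makes the green-overlay display
    rendering exactly invertible by the green-excess extraction formula.
    """
    tex = _procedural_texture(rng, (config.frame_height, config.frame_width))
    return 50.0 + 180.0 * tex


def _compose_white(plane: np.ndarray) -> np.ndarray:
    """Tissue RGB from the luminance plane: R = G = plane, B = 0.72*plane."""
    out = np.empty(plane.shape + (3,), dtype=np.uint8)
    p = np.clip(np.rint(plane), 0, 255)
    out[..., 0] = p
    out[..., 1] = p
    out[..., 2] = np.clip(np.rint(0.72 * p), 0, 255)
    return out


def _vertical_profile(config: SceneConfig) -> np.ndarray:
    """Bowel-band fluorescence weight per pixel row (1 inside, cosine
    roll-off to 0 over 10 px outside the band)."""
    cell_h = config.cell_shape[0]
    top = config.band_row_range[0] * cell_h
    bottom = config.band_row_range[1] * cell_h
    roll = 10.0
    y = np.arange(config.frame_height) + 0.5
    prof = np.zeros(config.frame_height)
    inside = (y >= top) & (y < bottom)
    prof[inside] = 1.0
    up = (y >= top - roll) & (y < top)
    prof[up] = 0.5 * (1 - np.cos(np.pi * (y[up] - (top - roll)) / roll))
    down = (y >= bottom) & (y < bottom + roll)
    prof[down] = 0.5 * (1 + np.cos(np.pi * (y[down] - bottom) / roll))
    return prof


def _motion_transforms(rng: np.random.Generator, config: SceneConfig,
                       n_frames: int) -> list[np.ndarray]:
    """Per-frame affine jitter (frame 0 = identity): rigid motion plus a
    small shear, all scaled by ``motion_amplitude`` (pixels)."""
    amp = config.motion_amplitude
    h, w = config.frame_height, config.frame_width
    center = np.array([w / 2.0, h / 2.0])
    mats = [np.eye(3)]
    for _ in range(1, n_frames):
        if amp == 0:
            mats.append(np.eye(3))
            continue
        dx, dy = rng.uniform(-amp, amp, size=2)
        rot = np.deg2rad(rng.uniform(-0.15, 0.15) * amp)
        shear = rng.uniform(-0.002, 0.002) * amp
        tf = (_SkAffine(translation=center)
              + _SkAffine(rotation=rot, shear=shear)
              + _SkAffine(translation=-center))
        m = tf.params.copy()
        m[0, 2] += dx
        m[1, 2] += dy
        mats.append(m)
    return mats


def _warp(frame: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Apply a forward affine (x, y homogeneous, output<-input mapping is
    the inverse) with bilinear interpolation and zero fill."""
    inv = np.linalg.inv(matrix)
    # scipy's affine_transform works in (row, col) index space.
    swap = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    m = swap @ inv @ swap
    if frame.ndim == 2:
        return ndimage.affine_transform(frame, m[:2, :2], m[:2, 2], order=1,
                                        mode="constant", cval=0.0,
                                        output=np.float32)
    out = np.empty(frame.shape, dtype=np.float32)
    for c in range(frame.shape[-1]):
        out[..., c] = ndimage.affine_transform(frame[..., c], m[:2, :2],
                                               m[:2, 2], order=1,
                                               mode="constant", cval=0.0,
                                               output=np.float32)
    return out


def render_scene(config: SceneConfig):
    """Render one scene: paired white-light/NIR video plus ground truth.

    Returns
    -------
    (FramePairSequence, GroundTruthAnnotation)
        The NIR stack holds each pixel's zone curve (smoothly interpolated
        across the boundary) plus Gaussian sensor noise, jittered by the
        per-frame camera motion; the white-light channel is a static
        textured image under the same motion. The annotation describes the
        centre line, per-module labels and the stapler band.
    """
    rng = np.random.default_rng(config.seed)
    zone_values = _draw_zone_values(rng, config)
    profile = _column_params(config, zone_values)
    times = config.times
    n_frames = len(times)
    h, w = config.frame_height, config.frame_width

    # (W, T) curve per pixel column -- kinetics only vary along the bowel.
    cols = profile["columns"]
    tau = np.maximum(times[None, :] - cols["arrival"][:, None], 0.0)
    tau /= cols["time_to_peak"][:, None]
    alpha = cols["shape"][:, None]
    curves = cols["amplitude"][:, None] * tau ** alpha * np.exp(alpha * (1.0 - tau))
    curves[tau <= 0] = 0.0
    curves += cols["baseline"][:, None]

    vprof = _vertical_profile(config).astype(np.float32)
    wplane = _white_light_image(rng, config).astype(np.float32)
    motion = _motion_transforms(rng, config, n_frames)

    white = np.empty((n_frames, h, w, 3), dtype=np.uint8)
    nir = np.empty((n_frames, h, w), dtype=np.uint8)
    white_still = _compose_white(wplane)
    curves_f = curves.astype(np.float32)
    moving = config.motion_amplitude > 0
    for t in range(n_frames):
        frame = vprof[:, None] * curves_f[:, t][None, :]
        if moving and t > 0:
            frame = _warp(frame, motion[t])
            white[t] = _compose_white(_warp(wplane, motion[t]))
        else:
            white[t] = white_still
        if config.noise_sd > 0:
            frame = frame + config.noise_sd * rng.standard_normal(
                frame.shape, dtype=np.float32)
        nir[t] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)

    annotation = _make_annotation(config, profile)
    seq = FramePairSequence(
        white=white, nir=nir, times=times, mode="native",
        meta={
            "motion_transforms": motion,
            "zone_values": zone_values,
            "seed": config.seed,
            "perfusion": config.perfusion,
        },
    )
    return seq, annotation


def _make_annotation(config: SceneConfig, profile: dict) -> GroundTruthAnnotation:
    cell_h, cell_w = config.cell_shape
    row = (config.band_row_range[0] + config.band_row_range[1]) // 2
    margin = 2
    line_cols = np.arange(margin, config.grid_cols - margin)
    y = row * cell_h + cell_h / 2.0
    line = np.stack([line_cols * cell_w + cell_w / 2.0,
                     np.full(line_cols.shape, y)], axis=1)
    if profile["band"] is None:
        labels = np.full(len(line_cols), POOR, dtype=np.int64)
        return GroundTruthAnnotation(line=line, labels=labels,
                                     stapler_center=None, stapler_band=None,
                                     boundary_col=None, line_cols=line_cols)
    band_start, band_end = profile["band"]
    labels = np.where(line_cols < band_start, GOOD,
                      np.where(line_cols < band_end, EXPERT, POOR)).astype(np.int64)
    return GroundTruthAnnotation(
        line=line, labels=labels,
        stapler_center=(band_start + band_end) // 2,
        stapler_band=(band_start, band_end),
        boundary_col=profile["b_col"], line_cols=line_cols,
    )


def expert_annotations(annotation: GroundTruthAnnotation, n_experts: int,
                       rng: np.random.Generator,
                       max_shift: int = 2) -> list[GroundTruthAnnotation]:
    """Emulate several experts choosing slightly different stapling sites.

    Expert 0 is the original annotation; each additional expert shifts the
    stapler band by up to ``max_shift`` modules towards the perfused side
    (never past the boundary), re-deriving the per-module labels.
    """
    if annotation.stapler_band is None:
        return [annotation] * n_experts
    out = [annotation]
    width = annotation.stapler_band[1] - annotation.stapler_band[0]
    for e in range(1, n_experts):
        shift = int(rng.integers(-max_shift, max_shift + 1))
        start = annotation.stapler_band[0] + shift
        end = start + width
        end = min(end, annotation.boundary_col)
        start = end - width
        line_cols = annotation.line_cols
        labels = np.where(line_cols < start, GOOD,
                          np.where(line_cols < end, EXPERT, POOR)).astype(np.int64)
        out.append(GroundTruthAnnotation(
            line=annotation.line.copy(), labels=labels,
            stapler_center=(start + end) // 2, stapler_band=(start, end),
            boundary_col=annotation.boundary_col, line_cols=line_cols,
            expert_id=e,
        ))
    return out


def render_overlay_mode(seq: FramePairSequence) -> FramePairSequence:
    """Re-render a native scene as a green-overlay display recording.

    Each display pixel blends the white-light pixel towards pure green in
    proportion to the NIR intensity ``f``: all three tissue channels are
    attenuated by ``1 - f/255`` and the green channel additionally carries
    ``f``. With ``f = 255`` this gives (0, 255, 0) on any background; with
    ``f = 0`` the white-light frame passes through unchanged. On tissue
    whose green channel does not exceed max(red, blue) the green-excess
    extraction formula inverts the rendering up to rounding.
    """
    if seq.nir is None:
        raise FormatError("overlay rendering needs the native NIR stack")
    nir = seq.nir.astype(np.float32)
    if nir.max() > 255 or nir.min() < 0:
        warnings.warn("NIR intensities outside [0, 255]; clipping")
        nir = np.clip(nir, 0, 255)
    a = nir / 255.0
    white = seq.white.astype(np.float32)
    r = white[..., 0] * (1.0 - a)
    b = white[..., 2] * (1.0 - a)
    g = white[..., 1] * (1.0 - a) + nir
    display = np.stack([r, g, b], axis=-1)
    display = np.clip(np.rint(display), 0, 255).astype(np.uint8)
    return FramePairSequence(
        white=seq.white, times=seq.times, mode="overlay",
        nir=None, display=display, validity=seq.validity,
        meta=dict(seq.meta),
    )
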