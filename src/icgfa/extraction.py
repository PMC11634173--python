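"""Per-grid-cell fluorescence intensity extraction.

Stabilised frames are segmented into a 72x96 grid of 5x5-pixel modules over
the 360x480 field; each module's fluorescence value is the mean of its valid
pixels. Native NIR frames are used directly; overlay-display recordings are
first reduced to a grayscale fluorescence estimate as the green-channel
excess over the other channels, which nulls achromatic tissue and isolates
the green dye tint.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .config import ConfigError
from .containers import FormatError, FramePairSequence, GridIntensitySeries

__all__ = ["overlay_to_grayscale", "grid_aggregate", "build_grid_series"]

#: Reference frame geometry: (rows, cols) grid over (height, width) pixels.
DEFAULT_GRID = (72, 96)
DEFAULT_FRAME = (360, 480)


def overlay_to_grayscale(rgb_frame: np.ndarray) -> np.ndarray:
    """Fluorescence estimate from a green-overlay display frame.

    Returns ``clamp(G - max(R, B), 0, 255)`` as float32: the green excess
    over the brighter of the other channels, which is zero on any
    achromatic (gray/white) pixel and 255 on pure green. The alternative
    ``G - (R + B)/2`` leaves residue on warm-toned tissue and is not used.
    """
    rgb_frame = np.asarray(rgb_frame)
    if rgb_frame.ndim != 3 or rgb_frame.shape[-1] != 3:
        raise FormatError("overlay frame must be (H, W, 3)")
    f = rgb_frame.astype(np.float32)
    excess = f[..., 1] - np.maximum(f[..., 0], f[..., 2])
    return np.clip(excess, 0.0, 255.0)


def grid_aggregate(frame: np.ndarray, validity: np.ndarray | None = None,
                   grid_shape: tuple[int, int] = DEFAULT_GRID):
    """Mean intensity per grid cell.

    Parameters
    ----------
    frame
        Grayscale frame whose dimensions are divisible by ``grid_shape``.
    validity
        Optional boolean mask of usable pixels; cells with no valid pixel
        get value NaN and a False entry in the returned cell mask.

    Returns
    -------
    (values, valid) : ((rows, cols) float32, (rows, cols) bool)
    """
    frame = np.asarray(frame, dtype=np.float32)
    rows, cols = grid_shape
    if frame.ndim != 2:
        raise FormatError("frame must be 2-D grayscale")
    if frame.shape[0] % rows or frame.shape[1] % cols:
        raise ConfigError(
            f"frame {frame.shape} not divisible by grid {grid_shape}")
    ch = frame.shape[0] // rows
    cw = frame.shape[1] // cols
    blocks = frame.reshape(rows, ch, cols, cw)
    if validity is None:
        return blocks.mean(axis=(1, 3)), np.ones((rows, cols), dtype=bool)
    vblocks = np.asarray(validity, dtype=np.float32).reshape(rows, ch, cols, cw)
    counts = vblocks.sum(axis=(1, 3))
    sums = (blocks * vblocks).sum(axis=(1, 3))
    valid = counts > 0
    with np.errstate(invalid="ignore"):
        values = np.where(valid, sums / np.where(valid, counts, 1.0), np.nan)
    return values.astype(np.float32), valid


def _fluorescence_frame(seq: FramePairSequence, t: int) -> np.ndarray:
    if seq.mode == "overlay":
        return overlay_to_grayscale(seq.display[t])
    return np.asarray(seq.nir[t], dtype=np.float32)


def build_grid_series(seq: FramePairSequence,
                      grid_shape: tuple[int, int] = DEFAULT_GRID
                      ) -> GridIntensitySeries:
    """Stack per-frame grid aggregates into a grid intensity time series.

    Overlay-mode sequences are converted frame-by-frame with
    :func:`overlay_to_grayscale` first. Frames whose dimensions are not
    divisible by the grid are resampled to the reference 360x480 geometry
    before gridding. Warping validity masks carry through to per-cell
    validity.
    """
    if len(seq) == 0:
        raise FormatError("empty frame sequence")
    h, w = seq.frame_shape
    rows, cols = grid_shape
    needs_resize = (h % rows != 0) or (w % cols != 0)
    target = DEFAULT_FRAME
    n = len(seq)
    values = np.empty((rows, cols, n), dtype=np.float32)
    valid = np.empty((rows, cols, n), dtype=bool)
    for t in range(n):
        frame = _fluorescence_frame(seq, t)
        if frame.shape != (h, w):
            raise FormatError("mixed frame sizes in sequence")
        vmask = None if seq.validity is None else seq.validity[t]
        if needs_resize:
            frame = resize(frame, target, order=1, preserve_range=True,
                           anti_aliasing=False).astype(np.float32)
            if vmask is not None:
                vmask = resize(vmask.astype(np.float32), target, order=0,
                               preserve_range=True) > 0.5
        values[:, :, t], valid[:, :, t] = grid_aggregate(frame, vmask,
                                                         grid_shape)
    fh = target[0] if needs_resize else h
    fw = target[1] if needs_resize else w
    return GridIntensitySeries(values=values, times=np.asarray(seq.times,
                                                               dtype=float),
                               valid=valid,
                               cell_shape=(fh // rows, fw // cols))
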