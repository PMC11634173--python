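"""Affine video stabilisation against the initial frame.

Camera jitter is estimated on the white-light channel -- the NIR channel is
dark before dye arrival and carries no stable structure -- and the same warp
is applied to the synchronous fluorescence frames, so the per-grid-cell time
series downstream read from a fixed patch of tissue.

The estimator follows the classic sparse pipeline: Shi-Tomasi corner
detection on the reference frame, local intensity-patch descriptors matched
to the moving frame by sum-of-squared-differences over a bounded search
window (with a second-minimum ratio test and parabolic sub-pixel
refinement), then a random-sample-consensus affine fit. Patch matching
rather than pyramid descriptors keeps the per-frame cost low enough to run
whole recordings on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.feature import corner_peaks, corner_shi_tomasi
from skimage.measure import ransac
from skimage.transform import AffineTransform as _SkAffine

from .containers import FramePairSequence, ICGFAError

__all__ = ["AffineTransform2D", "RegistrationFailure", "DegenerateFrameError",
           "estimate_affine", "stabilize_sequence"]


class DegenerateFrameError(ICGFAError):
    """A frame is constant (or nearly so) and cannot be registered."""


class RegistrationFailure(ICGFAError):
    """Too few reliable matches for an affine fit."""


@dataclass
class AffineTransform2D:
    """2x3 affine in pixel units mapping moving-frame (x, y) coordinates to
    reference-frame coordinates; the identity means "no motion"."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 3)
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-9:
            raise ICGFAError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    @property
    def rotation_deg(self) -> float:
        """Rotation angle of the linear part (degrees, counter-clockwise in
        image axes)."""
        return float(np.degrees(np.arctan2(self.matrix[1, 0],
                                           self.matrix[0, 0])))

    def homogeneous(self) -> np.ndarray:
        return np.vstack([self.matrix, [0.0, 0.0, 1.0]])

    def inverse(self) -> "AffineTransform2D":
        return AffineTransform2D(np.linalg.inv(self.homogeneous())[:2])

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return xy @ self.matrix[:, :2].T + self.matrix[:, 2]


@dataclass
class RegistrationResult:
    """Per-frame log entry of the sequence stabiliser."""

    transform: AffineTransform2D
    n_matches: int = 0
    n_inliers: int = 0
    residual: float = float("nan")
    fallback: bool = False


def _to_gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3:
        return frame.astype(np.float32).mean(axis=-1)
    return frame.astype(np.float32)


def _detect_corners(gray: np.ndarray, n_corners: int, margin: int) -> np.ndarray:
    """Shi-Tomasi corners as (n, 2) row/col, away from the frame border."""
    response = corner_shi_tomasi(gray, sigma=1.5)
    peaks = corner_peaks(response, min_distance=12, num_peaks=n_corners * 2,
                         threshold_rel=0.01)
    if len(peaks) == 0:
        return peaks.reshape(0, 2)
    keep = ((peaks[:, 0] >= margin) & (peaks[:, 0] < gray.shape[0] - margin)
            & (peaks[:, 1] >= margin) & (peaks[:, 1] < gray.shape[1] - margin))
    return peaks[keep][:n_corners]


def _match_patches(ref: np.ndarray, mov: np.ndarray, corners: np.ndarray,
                   patch: int, radius: int, max_ratio: float):
    """Match reference corner patches into the moving frame.

    Returns (src_xy in moving frame, dst_xy in reference frame).
    """
    hp = patch // 2
    if len(corners) == 0:
        return np.empty((0, 2)), np.empty((0, 2))
    # gather all templates and search windows in one shot
    win_size = patch + 2 * radius
    offs = np.arange(-hp, hp)
    woffs = np.arange(-hp - radius, hp + radius)
    r = corners[:, 0][:, None, None]
    c = corners[:, 1][:, None, None]
    templates = ref[r + offs[None, :, None], c + offs[None, None, :]]
    windows = mov[r + woffs[None, :, None], c + woffs[None, None, :]]
    # SSD over every integer offset for every corner at once, decomposed as
    # sum(w^2) - 2*corr(w, t) + sum(t^2); the window energies come from an
    # integral image and the correlations from one batched FFT convolution.
    cum = np.cumsum(np.cumsum(windows.astype(np.float64) ** 2, axis=1), axis=2)
    cum = np.pad(cum, ((0, 0), (1, 0), (1, 0)))
    energy = (cum[:, patch:, patch:] - cum[:, :-patch, patch:]
              - cum[:, patch:, :-patch] + cum[:, :-patch, :-patch])
    cross = fftconvolve(windows, templates[:, ::-1, ::-1], mode="valid",
                        axes=(1, 2))
    ssd = energy - 2.0 * cross + (templates ** 2).sum(axis=(1, 2))[:, None, None]
    n, side, _ = ssd.shape
    flat = ssd.reshape(n, -1)
    best_idx = flat.argmin(axis=1)
    i, j = np.unravel_index(best_idx, (side, side))
    best = flat[np.arange(n), best_idx]
    # ratio test against the best minimum away from the winner
    far = ssd.copy()
    for k in range(n):
        far[k, max(0, i[k] - 2):i[k] + 3, max(0, j[k] - 2):j[k] + 3] = np.inf
    second = far.reshape(n, -1).min(axis=1)
    ok = ~(np.isfinite(second) & (second > 0) & (best / second > max_ratio))

    def _subpixel(e_lo, e0, e_hi, at_edge):
        denom = e_lo - 2 * e0 + e_hi
        d = np.where(denom > 0, 0.5 * (e_lo - e_hi) / np.where(denom > 0, denom, 1.0), 0.0)
        return np.where(at_edge, 0.0, np.clip(d, -0.5, 0.5))

    ar = np.arange(n)
    edge_i = (i == 0) | (i == side - 1)
    edge_j = (j == 0) | (j == side - 1)
    ic = np.clip(i, 1, side - 2)
    jc = np.clip(j, 1, side - 2)
    di = _subpixel(ssd[ar, ic - 1, j], ssd[ar, ic, j], ssd[ar, ic + 1, j], edge_i)
    dj = _subpixel(ssd[ar, i, jc - 1], ssd[ar, i, jc], ssd[ar, i, jc + 1], edge_j)
    mr = corners[:, 0] - radius + i + di
    mc = corners[:, 1] - radius + j + dj
    src = np.stack([mc, mr], axis=1)[ok]                    # (x, y) moving
    dst = corners[:, ::-1].astype(float)[ok]                # (x, y) reference
    return src, dst


def estimate_affine(reference: np.ndarray, moving: np.ndarray, *,
                    n_corners: int = 60, patch_size: int = 16,
                    search_radius: int = 16, residual_threshold: float = 2.0,
                    min_matches: int = 8, max_ratio: float = 0.95,
                    seed: int = 0,
                    _ref_corners: Optional[np.ndarray] = None
                    ) -> tuple[AffineTransform2D, RegistrationResult]:
    """Estimate the affine transform mapping ``moving`` onto ``reference``.

    Raises :class:`DegenerateFrameError` for (near-)constant frames and
    :class:`RegistrationFailure` when fewer than ``min_matches`` reliable
    correspondences survive the ratio test and consensus fit.
    """
    ref = _to_gray(reference)
    mov = _to_gray(moving)
    if ref.shape != mov.shape:
        raise ICGFAError("reference and moving frames differ in shape")
    if ref.std() < 1e-3:
        raise DegenerateFrameError("reference frame is constant")
    if mov.std() < 1e-3:
        raise DegenerateFrameError("moving frame is constant")
    margin = patch_size // 2 + search_radius
    corners = (_ref_corners if _ref_corners is not None
               else _detect_corners(ref, n_corners, margin))
    if len(corners) < min_matches:
        raise RegistrationFailure(
            f"only {len(corners)} trackable corners in the reference frame")
    src, dst = _match_patches(ref, mov, corners, patch_size, search_radius,
                              max_ratio)
    if len(src) < max(min_matches, 3):
        raise RegistrationFailure(f"only {len(src)} patch matches")
    model, inliers = ransac((src, dst), _SkAffine, min_samples=3,
                            residual_threshold=residual_threshold,
                            max_trials=100, rng=seed)
    if model is None or inliers is None or inliers.sum() < 3:
        raise RegistrationFailure("consensus affine fit failed")
    residuals = np.linalg.norm(model(src[inliers]) - dst[inliers], axis=1)
    tf = AffineTransform2D(model.params[:2])
    return tf, RegistrationResult(tf, n_matches=len(src),
                                  n_inliers=int(inliers.sum()),
                                  residual=float(residuals.mean()))


def warp_frame(frame: np.ndarray, transform: AffineTransform2D,
               order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Resample ``frame`` into the reference frame of ``transform``
    (bilinear by default, zero fill outside)."""
    inv = transform.inverse().homogeneous()
    swap = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    m = swap @ inv @ swap     # (x, y) convention -> (row, col) convention
    if frame.ndim == 2:
        return ndimage.affine_transform(frame.astype(np.float32), m[:2, :2],
                                        m[:2, 2], order=order,
                                        mode="constant", cval=cval,
                                        output=np.float32)
    out = np.empty(frame.shape, dtype=np.float32)
    for c in range(frame.shape[-1]):
        out[..., c] = ndimage.affine_transform(frame[..., c].astype(np.float32),
                                               m[:2, :2], m[:2, 2],
                                               order=order, mode="constant",
                                               cval=cval, output=np.float32)
    return out


def stabilize_sequence(seq: FramePairSequence, *, warp_white: bool = True,
                       seed: int = 0, **estimate_kwargs
                       ) -> tuple[FramePairSequence, list[RegistrationResult]]:
    """Register every frame to frame 0 and warp all channels accordingly.

    Frame 0 passes through unchanged. Each later white-light frame is
    registered to the initial white-light frame; the identical warp is
    applied to the synchronous NIR (or overlay display) frame. Per-frame
    estimation failures never abort the run: the previous frame's transform
    is reused (identity for the first frame) and the log entry is marked as
    a fallback.

    Returns the stabilised sequence (fluorescence channels as float32, with
    a validity mask marking pixels warped in from outside the frame) and the
    per-frame registration log.
    """
    n = len(seq)
    h, w = seq.frame_shape
    identity = AffineTransform2D.identity()
    log: list[RegistrationResult] = [RegistrationResult(identity, fallback=False)]
    if n == 1:
        validity = np.ones((1, h, w), dtype=bool)
        return FramePairSequence(
            white=seq.white, times=seq.times, mode=seq.mode,
            nir=None if seq.nir is None else seq.nir.astype(np.float32),
            display=None if seq.display is None else seq.display.astype(np.float32),
            validity=validity, meta=dict(seq.meta, stabilized=True)), log

    ref_gray = _to_gray(seq.white[0])
    if ref_gray.std() < 1e-3:
        raise DegenerateFrameError("initial frame is constant")
    # frame-to-frame jitter is small, so a tight search window suffices
    estimate_kwargs.setdefault("search_radius", 10)
    patch = estimate_kwargs.get("patch_size", 16)
    radius = estimate_kwargs["search_radius"]
    corners = _detect_corners(ref_gray, estimate_kwargs.get("n_corners", 60),
                              patch // 2 + radius)

    nir = None if seq.nir is None else np.empty((n, h, w), dtype=np.float32)
    display = (None if seq.display is None
               else np.empty((n, h, w, 3), dtype=np.float32))
    white = seq.white.copy() if warp_white else seq.white
    validity = np.ones((n, h, w), dtype=bool)
    if nir is not None:
        nir[0] = seq.nir[0]
    if display is not None:
        display[0] = seq.display[0]

    previous = identity
    xx, yy = np.meshgrid(np.arange(w, dtype=np.float32),
                         np.arange(h, dtype=np.float32))
    for t in range(1, n):
        try:
            tf, result = estimate_affine(ref_gray, seq.white[t], seed=seed,
                                         _ref_corners=corners,
                                         **estimate_kwargs)
        except (RegistrationFailure, DegenerateFrameError):
            tf = previous
            result = RegistrationResult(tf, fallback=True)
        previous = tf
        log.append(result)
        if nir is not None:
            nir[t] = warp_frame(seq.nir[t], tf)
        if display is not None:
            display[t] = warp_frame(seq.display[t], tf)
        if warp_white:
            white[t] = np.clip(warp_frame(seq.white[t], tf), 0, 255)
        # a reference pixel is valid iff its source lies inside the moving
        # frame's bilinear support
        inv = tf.inverse().matrix
        xm = inv[0, 0] * xx + inv[0, 1] * yy + inv[0, 2]
        ym = inv[1, 0] * xx + inv[1, 1] * yy + inv[1, 2]
        validity[t] = ((xm >= 0) & (xm <= w - 1) & (ym >= 0) & (ym <= h - 1))

    out = FramePairSequence(white=white, times=seq.times, mode=seq.mode,
                            nir=nir, display=display, validity=validity,
                            meta=dict(seq.meta, stabilized=True))
    return out, log
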