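"""Line sampling, median condensation, labelling and dataset assembly.

The classifiers never see raw frames: each annotated intestinal segment is
reduced to lines crossing the fluorescent/non-fluorescent boundary. Around
each line a 35-pixel-high rectangle of grid modules (7 cells at 5 px) is
sampled, the four milestone features are condensed to one value per line
coordinate by the median across the perpendicular cells, and each
coordinate is labelled ``expert`` (inside the stapler band), ``good``
(proximal, perfused side) or ``poor`` (distal). Four lines of differing
lengths and perpendicular offsets per segment provide data augmentation;
with several experts each expert's stapling site yields its own labelled
copies.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import numpy as np

from .config import SamplingConfig
from .containers import (
    EXPERT,
    GOOD,
    POOR,
    ContractError,
    Dataset,
    FeatureGrid,
    GeometryError,
    GroundTruthAnnotation,
    ICGFAError,
    LineSample,
)

__all__ = ["sample_rectangle", "condense_median", "label_points",
           "augment_segment", "assemble_dataset", "dataset_to_csv",
           "dataset_from_csv", "AnnotationError", "line_sample_from_annotation"]


class AnnotationError(ICGFAError):
    """Annotation inconsistent with the line or frame geometry."""


def _line_module_path(line: np.ndarray, cell_shape: tuple[int, int],
                      grid_shape: tuple[int, int]):
    """Resample a pixel polyline at grid-module spacing.

    Returns (points (n, 2) pixel xy, tangents (n, 2) unit xy). Points are
    spaced one cell width apart along the arc, proximal to distal.
    """
    line = np.asarray(line, dtype=float)
    if line.ndim != 2 or line.shape[1] != 2 or len(line) < 2:
        raise GeometryError("line must be an (n>=2, 2) pixel polyline")
    seg = np.diff(line, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    step = cell_shape[1]
    stations = np.arange(0.0, arclen[-1] + 1e-9, step)
    x = np.interp(stations, arclen, line[:, 0])
    y = np.interp(stations, arclen, line[:, 1])
    pts = np.stack([x, y], axis=1)
    tang = np.gradient(pts, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True) + 1e-12
    h = grid_shape[0] * cell_shape[0]
    w = grid_shape[1] * cell_shape[1]
    if (pts[:, 0].min() < 0 or pts[:, 0].max() >= w
            or pts[:, 1].min() < 0 or pts[:, 1].max() >= h):
        raise GeometryError("line extends outside the frame")
    return pts, tang


def sample_rectangle(fg: FeatureGrid, line: np.ndarray,
                     height: int = 35,
                     cell_shape: tuple[int, int] = (5, 5)):
    """Collect per-coordinate columns of grid-module features around a line.

    For each coordinate along the line (sampled at cell spacing) the cells
    covered by a ``height``-pixel rectangle perpendicular to the local line
    direction are gathered (7 cells for the default 35 px / 5 px geometry).
    Invalid cells are returned as NaN rows.

    Returns
    -------
    coords : (n, 2) int array of on-line grid modules (row, col)
    columns : list of (m_i, 4) feature arrays, one per coordinate
    """
    rows, cols = fg.grid_shape
    pts, tang = _line_module_path(line, cell_shape, fg.grid_shape)
    n_perp = max(int(round(height / cell_shape[0])), 1)
    offsets = np.arange(n_perp) - (n_perp - 1) / 2.0
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    coords = []
    columns = []
    def cell_of(x, size):
        # tolerate sub-ulp drift from unit-vector normalisation
        return int(np.floor(x / size + 1e-6))

    for p, nvec in zip(pts, normal):
        cell_rc = (cell_of(p[1], cell_shape[0]), cell_of(p[0], cell_shape[1]))
        coords.append(cell_rc)
        seen = set()
        feats = []
        for k in offsets:
            q = p + k * cell_shape[0] * nvec
            r = cell_of(q[1], cell_shape[0])
            c = cell_of(q[0], cell_shape[1])
            if not (0 <= r < rows and 0 <= c < cols) or (r, c) in seen:
                continue
            seen.add((r, c))
            if fg.valid[r, c] and not fg.degenerate[r, c]:
                feats.append(fg.features[r, c])
            else:
                feats.append(np.full(4, np.nan))
        columns.append(np.array(feats, dtype=float))
    return np.array(coords, dtype=int), columns


def condense_median(columns: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Condense per-coordinate feature columns to one value per coordinate.

    Each of the four milestone features is reduced independently by the
    median over the valid perpendicular cells. Coordinates with no valid
    cell are marked missing and filled by linear interpolation along the
    line afterwards.

    Returns (features (n, 4), missing (n,) bool).
    """
    n = len(columns)
    out = np.full((n, 4), np.nan)
    for i, col in enumerate(columns):
        if col.size == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[i] = np.nanmedian(col, axis=0)
    missing = np.isnan(out).any(axis=1)
    if missing.all():
        raise AnnotationError("no coordinate has any valid cell")
    if missing.any():
        idx = np.arange(n)
        for f in range(4):
            bad = np.isnan(out[:, f])
            out[bad, f] = np.interp(idx[bad], idx[~bad], out[~bad, f])
    return out, missing


def label_points(n_coords: int, band: tuple[int, int]) -> np.ndarray:
    """Per-coordinate labels from a stapler band in line-index space.

    Coordinates inside the half-open ``band`` are ``expert``; proximal ones
    (before the band) are ``good``; distal ones are ``poor``.
    """
    start, end = band
    if start < 0 or end > n_coords or start >= end:
        raise AnnotationError(
            f"stapler band {band} outside the line of {n_coords} coordinates")
    if start == 0:
        warnings.warn("stapler band at the line start: no 'good' coordinates")
    if end == n_coords:
        warnings.warn("stapler band at the line end: no 'poor' coordinates")
    labels = np.full(n_coords, POOR, dtype=np.int64)
    labels[:start] = GOOD
    labels[start:end] = EXPERT
    return labels


def line_sample_from_annotation(fg: FeatureGrid,
                                annotation: GroundTruthAnnotation,
                                sampling: SamplingConfig | None = None,
                                video_id: str = "", line_id: int = 0,
                                cell_shape: tuple[int, int] = (5, 5)
                                ) -> LineSample:
    """Condense and label the annotated base line of a segment."""
    sampling = sampling or SamplingConfig()
    coords, columns = sample_rectangle(fg, annotation.line,
                                       sampling.rect_height, cell_shape)
    feats, _ = condense_median(columns)
    band = annotation.band_in_line_index()
    if band is None:
        labels = np.full(len(coords), POOR, dtype=np.int64)
    else:
        start = int(np.searchsorted(coords[:, 1], annotation.stapler_band[0]))
        end = int(np.searchsorted(coords[:, 1], annotation.stapler_band[1]))
        labels = label_points(len(coords), (start, end))
    return LineSample(coords=coords, features=feats, labels=labels,
                      video_id=video_id, expert_id=annotation.expert_id,
                      line_id=line_id)


def augment_segment(fg: FeatureGrid, annotation: GroundTruthAnnotation,
                    n_lines: int = 4,
                    rng: np.random.Generator | None = None,
                    sampling: SamplingConfig | None = None,
                    video_id: str = "",
                    cell_shape: tuple[int, int] = (5, 5)) -> list[LineSample]:
    """Sample ``n_lines`` labelled lines of differing lengths and positions
    across the boundary of one segment.

    Line 0 is the annotated base line; further lines jitter the endpoints
    by up to +/-20% of the base length and offset the line perpendicular to
    its direction by up to ``max_offset`` grid modules, always keeping the
    stapler band (plus margin) inside the line. Deterministic under a
    seeded generator.
    """
    sampling = sampling or SamplingConfig()
    rng = rng or np.random.default_rng(0)
    base = np.asarray(annotation.line, dtype=float)
    length = np.linalg.norm(base[-1] - base[0])
    direction = (base[-1] - base[0]) / (length + 1e-12)
    normal = np.array([-direction[1], direction[0]])
    rows, cols = fg.grid_shape
    h = rows * cell_shape[0]
    w = cols * cell_shape[1]

    if annotation.stapler_band is not None:
        band_px = (annotation.stapler_band[0] * cell_shape[1],
                   annotation.stapler_band[1] * cell_shape[1])
    else:
        band_px = None

    samples = []
    for li in range(n_lines):
        if li == 0:
            line = base
        else:
            # trims are drawn within the feasible range that keeps the
            # stapler band (plus margin) strictly inside the line
            margin = 2 * cell_shape[1]
            max_trim = sampling.length_jitter * length
            if band_px is not None:
                s_band0 = float((np.array([band_px[0], base[0][1]])
                                 - base[0]) @ direction)
                s_band1 = float((np.array([band_px[1], base[0][1]])
                                 - base[0]) @ direction)
                trim0_hi = min(max_trim, max(s_band0 - margin, 0.0))
                trim1_hi = min(max_trim, max(length - s_band1 - margin, 0.0))
            else:
                trim0_hi = trim1_hi = max_trim
            for _ in range(20):
                trim0 = rng.uniform(0, trim0_hi)
                trim1 = rng.uniform(0, trim1_hi)
                off = rng.integers(-sampling.max_offset,
                                   sampling.max_offset + 1)
                p0 = base[0] + trim0 * direction + off * cell_shape[0] * normal
                p1 = base[-1] - trim1 * direction + off * cell_shape[0] * normal
                if (0 <= p0[0] < w and 0 <= p1[0] < w
                        and 0 <= p0[1] < h and 0 <= p1[1] < h):
                    line = np.stack([p0, p1])
                    break
            else:
                raise GeometryError(
                    "could not place an augmentation line across the boundary")
        ann_i = GroundTruthAnnotation(
            line=line, labels=annotation.labels,
            stapler_center=annotation.stapler_center,
            stapler_band=annotation.stapler_band,
            boundary_col=annotation.boundary_col,
            line_cols=annotation.line_cols, expert_id=annotation.expert_id)
        samples.append(line_sample_from_annotation(
            fg, ann_i, sampling, video_id=video_id, line_id=li,
            cell_shape=cell_shape))
    return samples


def assemble_dataset(segments: list[dict], experts: int = 1,
                     n_lines: int = 4, split: dict[str, str] | None = None,
                     seed: int = 0,
                     sampling: SamplingConfig | None = None) -> Dataset:
    """Build a dataset from featurised segments.

    Parameters
    ----------
    segments
        Each entry: ``{"video_id": str, "feature_grid": FeatureGrid,
        "annotations": [GroundTruthAnnotation, ...]}`` with one annotation
        per expert (generated, e.g., by
        :func:`icgfa.synthetic.expert_annotations`). With ``experts = 3``
        each expert's stapler site produces its own labelled copies of the
        ``n_lines`` lines, so the sample count is
        ``videos * n_lines * experts`` exactly.
    split
        Mapping video_id -> {"train", "validation", "test"}; a video must
        not appear in two splits (enforced by construction of the mapping).
    """
    if not segments:
        raise ContractError("cannot assemble a dataset from zero videos")
    sampling = sampling or SamplingConfig()
    rng = np.random.default_rng(seed)
    samples: list[LineSample] = []
    for seg in segments:
        annotations = seg["annotations"][:experts]
        if len(annotations) < experts:
            raise AnnotationError(
                f"video {seg['video_id']} has {len(annotations)} expert "
                f"annotations, need {experts}")
        # identical line geometry across experts: draw it once per video
        state = rng.integers(0, 2 ** 31)
        for ann in annotations:
            line_rng = np.random.default_rng(state)
            samples.extend(augment_segment(
                seg["feature_grid"], ann, n_lines=n_lines, rng=line_rng,
                sampling=sampling, video_id=seg["video_id"]))
    return Dataset(samples=samples, split=dict(split or {}))


def dataset_to_csv(dataset: Dataset, path) -> None:
    """One row per coordinate: ids, position, the 4 features, label; the
    split mapping goes to a JSON manifest next to the CSV."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["video_id", "expert_id", "line_id", "position",
                         "row", "col", "i_max", "upslope", "t_max", "t_half",
                         "label"])
        for s in dataset.samples:
            for i in range(len(s)):
                label = "" if s.labels is None else int(s.labels[i])
                writer.writerow([s.video_id, s.expert_id, s.line_id, i,
                                 int(s.coords[i, 0]), int(s.coords[i, 1]),
                                 *(f"{v:.9g}" for v in s.features[i]), label])
    manifest = path.with_suffix(".manifest.json")
    with open(manifest, "w") as fh:
        json.dump({"split": dataset.split,
                   "class_counts": dataset.class_counts}, fh, indent=2)


def dataset_from_csv(path) -> Dataset:
    path = Path(path)
    groups: dict[tuple, dict] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["video_id"], int(row["expert_id"]), int(row["line_id"]))
            g = groups.setdefault(key, {"coords": [], "features": [],
                                        "labels": []})
            g["coords"].append((int(row["row"]), int(row["col"])))
            g["features"].append([float(row[k]) for k in
                                  ("i_max", "upslope", "t_max", "t_half")])
            g["labels"].append(int(row["label"]) if row["label"] != "" else -1)
    samples = []
    for (vid, eid, lid), g in groups.items():
        labels = np.array(g["labels"])
        samples.append(LineSample(
            coords=np.array(g["coords"]), features=np.array(g["features"]),
            labels=None if (labels < 0).all() else labels,
            video_id=vid, expert_id=eid, line_id=lid))
    manifest = path.with_suffix(".manifest.json")
    split = {}
    if manifest.exists():
        with open(manifest) as fh:
            split = json.load(fh).get("split", {})
    return Dataset(samples=samples, split=split)
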