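"""Expert-zone extraction, pixel-/object-level metrics and overlays.

The clinical question is binary per segment -- does the predicted "expert"
stapling zone contain the site where the surgeon actually stapled? --
backed by pixel-level metrics of the expert-vs-rest labelling along the
line. The DICE index ``2|P∩G| / (|P|+|G|)`` over expert coordinate sets
coincides with the F1 score of the binary set formulation; both are
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EvalConfig, FeatureConfig, SamplingConfig
from .containers import (
    CLASSES,
    EXPERT,
    GOOD,
    POOR,
    ContractError,
    GeometryError,
    ZonePrediction,
)

__all__ = ["extract_expert_zone", "pixel_metrics", "object_hit",
           "render_overlay", "evaluate_suite", "EvalReport"]

_TINTS = {GOOD: (255, 0, 0), EXPERT: (0, 255, 0), POOR: (0, 0, 255)}


def extract_expert_zone(labels: np.ndarray, min_run: int = 6
                        ) -> ZonePrediction:
    """Longest contiguous run of expert labels, if long enough to matter.

    Runs shorter than ``min_run`` modules (half a stapler diameter by
    default) never qualify, so single-point noise cannot create a
    transection recommendation; with no qualifying run the prediction is
    an explicit no-prediction (the display then shows only the non-expert
    zoning). Ties between equally long runs go to the proximal one.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1 or len(labels) == 0:
        raise ContractError("labels must be a non-empty 1-D sequence")
    best = None
    start = None
    for i, lab in enumerate(list(labels) + [-1]):
        if lab == EXPERT and start is None:
            start = i
        elif lab != EXPERT and start is not None:
            if best is None or (i - start) > (best[1] - best[0]):
                best = (start, i)
            start = None
    if best is None or (best[1] - best[0]) < min_run:
        return ZonePrediction(labels=labels, expert_zone=None,
                              no_prediction=True)
    return ZonePrediction(labels=labels, expert_zone=best,
                          no_prediction=False)


def pixel_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Binary expert-vs-rest metrics from pooled confusion counts.

    Returns accuracy, precision, recall, specificity, f1 and dice (the two
    are identical in this set formulation). When predicted and true expert
    sets are both empty, the overlap metrics are reported as 1 (perfect
    vacuous agreement) and ``vacuous`` is flagged.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ContractError("prediction and truth lengths differ")
    p = pred == EXPERT
    g = truth == EXPERT
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    n = tp + fp + fn + tn
    vacuous = (tp + fp + fn) == 0
    metrics = {
        "accuracy": (tp + tn) / n if n else 1.0,
        "precision": 1.0 if vacuous else (tp / (tp + fp) if tp + fp else 0.0),
        "recall": 1.0 if vacuous else (tp / (tp + fn) if tp + fn else 0.0),
        "specificity": tn / (tn + fp) if tn + fp else 1.0,
        "dice": 1.0 if vacuous else 2 * tp / (2 * tp + fp + fn),
        "vacuous": vacuous,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }
    metrics["f1"] = metrics["dice"]
    return metrics


def object_hit(zone: ZonePrediction, stapler_band: tuple[int, int],
               rule: str = "center") -> bool:
    """Did the actual stapler placement fall within the predicted zone?

    With the default ``center`` rule the stapler band centre must lie
    inside the half-open predicted interval; ``overlap`` accepts any
    intersection. A no-prediction never scores a hit.
    """
    if zone.no_prediction:
        return False
    zs, ze = zone.expert_zone
    if rule == "overlap":
        return max(stapler_band[0], zs) < min(stapler_band[1], ze)
    center = (stapler_band[0] + stapler_band[1]) / 2.0
    return zs <= center < ze


def render_overlay(white_frame: np.ndarray, coords: np.ndarray,
                   labels: np.ndarray, zone: ZonePrediction | None = None,
                   alpha: float = 0.4, cell_shape: tuple[int, int] = (5, 5),
                   band_halfwidth: int = 3) -> np.ndarray:
    """Clinical-style overlay: per-coordinate grid modules tinted green
    (expert) / red (good) / blue (poor), alpha-blended over white light.

    When a :class:`ZonePrediction` with ``no_prediction`` is given, expert
    tints are suppressed and only the non-expert zoning is drawn.
    """
    frame = np.asarray(white_frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ContractError("white_frame must be (H, W, 3)")
    ch, cw = cell_shape
    rows = frame.shape[0] // ch
    cols = frame.shape[1] // cw
    coords = np.asarray(coords)
    if np.any(coords < 0) or np.any(coords[:, 0] >= rows) \
            or np.any(coords[:, 1] >= cols):
        raise GeometryError("line coordinates outside the frame grid")
    suppress_expert = zone is not None and zone.no_prediction
    out = frame.astype(np.float32)
    for (r, c), lab in zip(coords, labels):
        lab = int(lab)
        if suppress_expert and lab == EXPERT:
            continue
        tint = np.array(_TINTS[lab], dtype=np.float32)
        r0 = max(r - band_halfwidth, 0) * ch
        r1 = min(r + band_halfwidth + 1, rows) * ch
        block = out[r0:r1, c * cw:(c + 1) * cw]
        block *= (1.0 - alpha)
        block += alpha * tint
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


@dataclass
class EvalReport:
    """Pooled pixel metrics, object-level accuracy and a per-case table."""

    metrics: dict
    object_accuracy: float
    n_objects: int
    n_hits: int
    n_no_prediction: int
    per_case: pd.DataFrame = field(repr=False, default=None)

    def to_json_dict(self) -> dict:
        return {"pixel": {k: v for k, v in self.metrics.items()},
                "object_accuracy": self.object_accuracy,
                "n_objects": self.n_objects, "n_hits": self.n_hits,
                "n_no_prediction": self.n_no_prediction}


def evaluate_suite(predict_fn, scenes: list, *,
                   eval_config: EvalConfig | None = None,
                   feature_config: FeatureConfig | None = None,
                   sampling: SamplingConfig | None = None) -> EvalReport:
    """Run the full per-scene pipeline and aggregate metrics.

    Parameters
    ----------
    predict_fn
        Callable mapping a :class:`LineSample` to per-coordinate labels
        (e.g. ``lambda s: predict_bilstm(model, s)[0]``).
    scenes
        List of ``(FramePairSequence, GroundTruthAnnotation)`` pairs (or of
        already-processed ``(LineSample, GroundTruthAnnotation)`` pairs).

    Pixel metrics are pooled over all coordinates of all test lines
    (micro-average). Object-level accuracy is the fraction of segments with
    a defined stapler band whose band centre falls inside the predicted
    expert zone; segments without a band (true poor perfusion) are excluded
    from that denominator, and for them a no-prediction is the correct
    display outcome.
    """
    from .containers import LineSample
    from .pipeline import scene_line_sample

    eval_config = eval_config or EvalConfig()
    if not scenes:
        raise ContractError("need at least one test scene with ground truth")
    rows = []
    all_pred = []
    all_truth = []
    n_obj = n_hit = n_nopred = 0
    for i, (scene, annotation) in enumerate(scenes):
        if annotation is None:
            warnings.warn(f"scene {i} has no annotation; skipped")
            continue
        if isinstance(scene, LineSample):
            sample = scene
        else:
            sample = scene_line_sample(scene, annotation,
                                       feature_config=feature_config,
                                       sampling=sampling)
        pred = np.asarray(predict_fn(sample))
        truth = _truth_labels(sample, annotation)
        zone = extract_expert_zone(pred, eval_config.min_run)
        m = pixel_metrics(pred, truth)
        all_pred.append(pred)
        all_truth.append(truth)
        band = _band_in_line(sample, annotation)
        hit = None
        if band is not None:
            n_obj += 1
            hit = object_hit(zone, band, eval_config.hit_rule)
            n_hit += int(hit)
        if zone.no_prediction:
            n_nopred += 1
        rows.append({"case": i, "n_points": len(sample),
                     "zone_start": None if zone.no_prediction
                     else zone.expert_zone[0],
                     "zone_end": None if zone.no_prediction
                     else zone.expert_zone[1],
                     "no_prediction": zone.no_prediction,
                     "object_hit": hit, **{k: m[k] for k in
                                           ("accuracy", "precision", "recall",
                                            "specificity", "f1", "dice")}})
    pooled = pixel_metrics(np.concatenate(all_pred),
                           np.concatenate(all_truth))
    return EvalReport(metrics=pooled,
                      object_accuracy=(n_hit / n_obj) if n_obj else 1.0,
                      n_objects=n_obj, n_hits=n_hit,
                      n_no_prediction=n_nopred,
                      per_case=pd.DataFrame(rows))


def _truth_labels(sample, annotation) -> np.ndarray:
    """Ground-truth labels re-derived in the sample's coordinate space."""
    if annotation.stapler_band is None:
        return np.full(len(sample), POOR, dtype=np.int64)
    cols = sample.coords[:, 1]
    return np.where(cols < annotation.stapler_band[0], GOOD,
                    np.where(cols < annotation.stapler_band[1], EXPERT,
                             POOR)).astype(np.int64)


def _band_in_line(sample, annotation):
    if annotation.stapler_band is None:
        return None
    cols = sample.coords[:, 1]
    start = int(np.searchsorted(cols, annotation.stapler_band[0]))
    end = int(np.searchsorted(cols, annotation.stapler_band[1]))
    if start >= end:
        return None
    return start, end
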