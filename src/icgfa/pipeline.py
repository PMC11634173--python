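"""End-to-end workflows: scene -> features -> lines -> models -> report.

These helpers wire the stages together the way the CLI and the experiment
scripts use them: stabilise a recording, extract the grid intensity series,
compute and normalise the milestone features, condense annotated lines, and
train/evaluate the two classifiers on collections of synthetic scenes.
"""

from __future__ import annotations

import numpy as np

from .config import FeatureConfig, LSTMConfig, RunConfig, SamplingConfig, SceneConfig
from .containers import Dataset, FeatureGrid, FramePairSequence, GroundTruthAnnotation, LineSample
from .dataset import assemble_dataset, line_sample_from_annotation
from .extraction import build_grid_series
from .features import featurize_grid, normalize_features
from .stabilization import stabilize_sequence
from .synthetic import expert_annotations, render_scene

__all__ = ["process_scene", "scene_line_sample", "sample_scene_config",
           "build_scene_set", "build_training_dataset",
           "object_accuracy_experiment"]


def process_scene(seq: FramePairSequence,
                  feature_config: FeatureConfig | None = None,
                  grid_shape: tuple[int, int] = (72, 96)) -> FeatureGrid:
    """Stabilise, extract the grid series, featurise and normalise."""
    stab, _ = stabilize_sequence(seq, warp_white=False)
    grid = build_grid_series(stab, grid_shape)
    fg = featurize_grid(grid, feature_config)
    nfg, _ = normalize_features(fg, feature_config)
    return nfg


def scene_line_sample(seq: FramePairSequence,
                      annotation: GroundTruthAnnotation,
                      feature_config: FeatureConfig | None = None,
                      sampling: SamplingConfig | None = None,
                      video_id: str = "") -> LineSample:
    """Full pipeline for one scene's annotated base line."""
    fg = process_scene(seq, feature_config)
    return line_sample_from_annotation(fg, annotation, sampling,
                                       video_id=video_id)


def sample_scene_config(rng: np.random.Generator,
                        base: SceneConfig | None = None,
                        perfusion: str = "normal") -> SceneConfig:
    """Draw one scene from the default scene distribution.

    Scene-to-scene variability: the boundary position moves within the
    central part of the field and every kinetic parameter is re-drawn from
    its zone range via the per-scene seed.
    """
    base = base or SceneConfig()
    return SceneConfig(
        frame_height=base.frame_height, frame_width=base.frame_width,
        grid_rows=base.grid_rows, grid_cols=base.grid_cols,
        fps=base.fps, duration=base.duration,
        boundary_pos=float(rng.uniform(0.40, 0.70)),
        expert_width=base.expert_width, zone_params=base.zone_params,
        baseline_range=base.baseline_range, noise_sd=base.noise_sd,
        motion_amplitude=base.motion_amplitude, perfusion=perfusion,
        band_row_range=base.band_row_range,
        seed=int(rng.integers(0, 2 ** 31)))


def build_scene_set(n_scenes: int, seed: int, *,
                    base: SceneConfig | None = None,
                    n_poor: int = 0) -> list[tuple]:
    """Render ``n_scenes`` scenes (the last ``n_poor`` mal-perfused)."""
    rng = np.random.default_rng(seed)
    scenes = []
    for i in range(n_scenes):
        perfusion = "poor" if i >= n_scenes - n_poor else "normal"
        cfg = sample_scene_config(rng, base, perfusion=perfusion)
        scenes.append(render_scene(cfg))
    return scenes


def build_training_dataset(n_train: int, n_val: int, seed: int, *,
                           experts: int = 1,
                           base: SceneConfig | None = None,
                           feature_config: FeatureConfig | None = None,
                           sampling: SamplingConfig | None = None) -> Dataset:
    """Render train/validation scenes, featurise them and assemble the
    augmented line dataset (``videos x 4 lines x experts`` samples)."""
    sampling = sampling or SamplingConfig()
    rng = np.random.default_rng(seed)
    segments = []
    split = {}
    for i in range(n_train + n_val):
        part = "train" if i < n_train else "validation"
        cfg = sample_scene_config(rng, base)
        seq, annotation = render_scene(cfg)
        fg = process_scene(seq, feature_config)
        annotations = expert_annotations(annotation, experts, rng)
        vid = f"video_{i:03d}"
        segments.append({"video_id": vid, "feature_grid": fg,
                         "annotations": annotations})
        split[vid] = part
    return assemble_dataset(segments, experts=experts,
                            n_lines=sampling.n_lines, split=split,
                            seed=seed, sampling=sampling)


def object_accuracy_experiment(seed: int, *, n_train: int = 20,
                               n_val: int = 5, n_test: int = 15,
                               n_poor: int = 3,
                               config: RunConfig | None = None) -> dict:
    """Synthetic analogue of prospective in-theatre object-level testing.

    Trains the sequence model on ``n_train`` scenes (4 lines each, with
    ``n_val`` validation scenes for early stopping), then predicts the
    expert zone on ``n_test`` held-out scenes of which ``n_poor`` are truly
    mal-perfused. Reports the percentage of perfused test scenes whose
    stapler band centre falls inside the predicted expert zone; on the
    mal-perfused scenes the correct outcome is an explicit no-prediction
    and they do not enter the hit denominator.
    """
    from .bilstm import predict_bilstm, train_bilstm
    from .evaluation import evaluate_suite

    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    ds_seed = int(rng.integers(0, 2 ** 31))
    test_seed = int(rng.integers(0, 2 ** 31))
    dataset = build_training_dataset(
        n_train, n_val, ds_seed, base=config.scene,
        feature_config=config.features, sampling=config.sampling)
    lstm_config = LSTMConfig(**{**vars(config.lstm),
                                "seed": int(rng.integers(0, 2 ** 31))})
    model = train_bilstm(dataset, lstm_config)

    test_scenes = build_scene_set(n_test, test_seed, base=config.scene,
                                  n_poor=n_poor)
    report = evaluate_suite(
        lambda s: predict_bilstm(model, s)[0], test_scenes,
        eval_config=config.evaluation, feature_config=config.features,
        sampling=config.sampling)
    poor_correct = int(report.per_case[
        report.per_case["object_hit"].isna()]["no_prediction"].sum()) \
        if n_poor else 0
    return {
        "object_accuracy_pct": 100.0 * report.object_accuracy,
        "n_perfused": report.n_objects,
        "n_hits": report.n_hits,
        "n_poor": n_poor,
        "n_poor_correct_no_prediction": poor_correct,
        "pixel": {k: report.metrics[k] for k in
                  ("accuracy", "precision", "recall", "specificity",
                   "f1", "dice")},
        "stop_epoch": model.stop_epoch,
        "report": report,
        "model": model,
        "dataset": dataset,
    }
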