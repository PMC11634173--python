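"""Small end-to-end run: train both classifiers, score a held-out scene.

Uses a reduced corpus (6 training + 2 validation scenes) so the script
finishes in a couple of minutes on one CPU; the acceptance script runs the
full 20/5/15 protocol.
"""

import numpy as np

from icgfa import (
    CLASSES,
    KNNConfig,
    LSTMConfig,
    build_training_dataset,
    evaluate_suite,
    predict_bilstm,
    train_bilstm,
    train_knn,
)
from icgfa.pipeline import build_scene_set

SEED = 17

print("rendering and featurising 8 scenes (6 train / 2 validation) ...")
dataset = build_training_dataset(6, 2, SEED)
counts = dataset.class_counts
print(f"dataset: {len(dataset.samples)} lines, per-class points {counts}")

knn = train_knn(dataset, KNNConfig(), seed=SEED)
print(f"weighted KNN 10-fold CV accuracy: "
      f"{knn.cv_report['mean_accuracy']:.3f}")

model = train_bilstm(dataset, LSTMConfig(seed=SEED))
print(f"bi-LSTM stopped at epoch {model.stop_epoch} "
      f"(best val loss {min(e['val_loss'] for e in model.training_log):.4f})")

print("evaluating on 3 held-out scenes (1 mal-perfused) ...")
scenes = build_scene_set(3, SEED + 1, n_poor=1)
report = evaluate_suite(lambda s: predict_bilstm(model, s)[0], scenes)
print(f"pixel-level (expert vs rest): accuracy "
      f"{report.metrics['accuracy']:.3f}, DICE {report.metrics['dice']:.3f}")
print(f"object-level: {report.n_hits}/{report.n_objects} stapler sites "
      f"inside the predicted zone; "
      f"{report.n_no_prediction} scene(s) without a qualifying expert zone")
print("a mal-perfused scene should appear as the no-prediction case: the "
      "model sees no stapling-quality tissue and declines to recommend a "
      "transection level.")
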