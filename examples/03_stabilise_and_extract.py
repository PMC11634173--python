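"""Stabilise a jittered recording and extract the grid intensity series.

Renders the same scene with and without camera motion, registers every
frame of the jittered version to its first frame (affine, estimated on the
white-light channel) and reports how closely the stabilised per-grid-cell
time series match the motion-free twin.
"""

import numpy as np

from icgfa import SceneConfig, build_grid_series, render_scene, stabilize_sequence

moving = SceneConfig(seed=42, noise_sd=0.0, motion_amplitude=2.5)
still = SceneConfig(seed=42, noise_sd=0.0, motion_amplitude=0.0)

seq_m, annotation = render_scene(moving)
seq_0, _ = render_scene(still)

stab, log = stabilize_sequence(seq_m, warp_white=False)
translations = np.array([e.transform.translation for e in log[1:]])
print(f"estimated per-frame translation magnitude: "
      f"mean {np.linalg.norm(translations, axis=1).mean():.2f} px, "
      f"max {np.linalg.norm(translations, axis=1).max():.2f} px")
print(f"fallback frames (registration failed): "
      f"{sum(e.fallback for e in log)}")

grid_m = build_grid_series(stab)
grid_0 = build_grid_series(seq_0)
band = slice(20, 52)   # grid rows of the bowel band
diff = np.abs(grid_m.values[band] - grid_0.values[band])
valid = grid_m.valid[band]
print(f"per-cell series error vs motion-free twin over the bowel band: "
      f"mean {diff[valid].mean():.3f}, p99 "
      f"{np.percentile(diff[valid], 99):.2f} intensity units")
print("values well below 1 unit mean the downstream curve milestones are "
      "essentially unaffected by the camera jitter.")
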