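"""Render one synthetic angiography scene and inspect its ground truth.

Builds a 90 s paired white-light/NIR recording of a bowel segment with a
perfusion gradient, camera jitter and sensor noise, then prints the label
run structure and the stapler band of the annotation.
"""

import numpy as np

from icgfa import CLASSES, SceneConfig, render_scene

config = SceneConfig(seed=7)
seq, annotation = render_scene(config)

print(f"frames: {len(seq)} of {seq.frame_shape} at {config.fps} fps "
      f"({config.duration:.0f} s)")
print(f"NIR intensity range over the recording: "
      f"{seq.nir.min()}..{seq.nir.max()}")

runs = []
labels = annotation.labels
start = 0
for i in range(1, len(labels) + 1):
    if i == len(labels) or labels[i] != labels[start]:
        runs.append((CLASSES[labels[start]], i - start))
        start = i
print("label runs along the line (class, modules):", runs)
print(f"stapler band (grid columns, half-open): {annotation.stapler_band}; "
      f"centre: {annotation.stapler_center}")
print("the band is 12 modules wide -- one stapler diameter -- and sits "
      "immediately proximal to the fluorescence boundary at column "
      f"{annotation.boundary_col}.")

# per-pixel peak brightness over the recording confirms the gradient
peak = seq.nir.astype(float).max(axis=0)
row = (config.band_row_range[0] + config.band_row_range[1]) // 2 * 5
good_cols = annotation.line_cols[labels == 0] * 5
poor_cols = annotation.line_cols[labels == 2] * 5
print(f"peak intensity, good zone: {peak[row, good_cols].mean():.1f}, "
      f"poor zone: {peak[row, poor_cols].mean():.1f} -- the inflow "
      "contrast the milestones quantify")
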