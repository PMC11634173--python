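"""Intensity-time milestones of gamma-variate inflow curves.

Simulates the dye inflow of a well-perfused and a poorly perfused location
and prints the four milestones the classifiers work from: peak intensity,
upslope, time-to-peak and time-to-half-peak.
"""

import numpy as np

from icgfa import compute_milestones, simulate_curve

times = np.arange(0, 90, 0.5)

zones = {
    "good": dict(amplitude=165, arrival=12, time_to_peak=15, shape=2.1,
                 baseline=8),
    "expert": dict(amplitude=90, arrival=16, time_to_peak=22, shape=2.1,
                   baseline=8),
    "poor": dict(amplitude=10, arrival=30, time_to_peak=35, shape=2.1,
                 baseline=8),
}

print(f"{'zone':8s} {'i_max':>7s} {'upslope':>9s} {'t_max':>7s} {'t_half':>7s}")
for name, params in zones.items():
    curve = simulate_curve(params, times)
    cf = compute_milestones(curve, times)
    print(f"{name:8s} {cf.i_max:7.1f} {cf.upslope:9.2f} {cf.t_max:7.1f} "
          f"{cf.t_half:7.1f}")

print()
print("i_max is in 0-255 intensity units, upslope in units/s, times in "
      "seconds from the window start. Well-perfused bowel peaks high and "
      "early with a steep upslope; poorly perfused bowel shows a weak, "
      "late rise -- exactly the contrast the classifiers exploit.")
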