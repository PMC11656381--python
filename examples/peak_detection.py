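"""Window-propagation peak detection, including a hidden shoulder.

Builds a two-component signal whose smaller component is only a
shoulder (no local maximum of its own), then shows that the
second-derivative candidate rule still finds both components, and how
window size and threshold trade off the number of reported peaks.
"""

import numpy as np

from specdecon import Spectrum, candidate_indices, detect_peaks
from specdecon.profiles import ProfileParams, model_sum

big = ProfileParams("gaussian", 50.0, 1.0, sigma=3.0)
small = ProfileParams("gaussian", 55.0, 0.4, sigma=2.0)
x = np.linspace(30.0, 75.0, 1801)
s = Spectrum(x, model_sum([big, small], x))

maxima = np.sum((s.y[1:-1] > s.y[:-2]) & (s.y[1:-1] > s.y[2:]))
cands = candidate_indices(s)
print(f"local maxima of the signal itself: {maxima}")
print(f"curvature candidates (-d2y/dx2 local maxima): {len(cands)} "
      f"at x = {np.round(s.x[cands], 2)}")
print("-> the shoulder at x=55 is invisible to a plain maximum search "
      "but shows up in the curvature.\n")

print("window size and threshold control how many candidates survive:")
for window, threshold in [(41, 0.02), (41, 0.45), (201, 0.02)]:
    peaks = detect_peaks(s, window, threshold=threshold, min_amplitude=0.05)
    print(f"  window={window:3d} threshold={threshold:4.2f} -> "
          f"{len(peaks)} peak(s) at {np.round(peaks.positions, 2)}")
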