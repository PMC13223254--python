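"""The adaptive mesh ternary descriptor on one image, step by step.

Shows the worked threshold arithmetic (local SD 20 with alpha = 0.2 and
offset beta = 5 gives T = 9, so a centre of 72 brackets to [63, 81]), then
extracts the full two-scale feature vector: 6 pattern images x 2 scales
x 256 histogram bins = 3072 values, each 256-bin block summing to 1.
"""

import numpy as np

from meshtex.descriptor import (ThresholdParams, adaptive_threshold,
                                center_bounds, compute_pattern_images,
                                extract_features, MeshScale)
from meshtex.imaging_io import generate_texture_fixture

params = ThresholdParams(alpha=0.2, beta_offset=5)
T = adaptive_threshold(20.0, params)
upper, lower = center_bounds(72, T)
print(f"adaptive threshold for sigma=20: T = 0.2*20 + 5 = {T:g}")
print(f"centre 72 brackets to [lower, upper] = [{lower:g}, {upper:g}]")

img = generate_texture_fixture("grating", (32, 32), seed=4)
for scale in (MeshScale(3), MeshScale(7)):
    pats = compute_pattern_images(img, scale, params)
    active = np.mean([np.count_nonzero(p.codes) / p.codes.size for p in pats])
    print(f"{scale.window}x{scale.window} scale: six pattern images of shape "
          f"{pats[0].codes.shape}, {100 * active:.0f}% nonzero codes on average")

f = extract_features(img, params=params)
print(f"feature vector: {f.size} values; first block sums to {f[:256].sum():g}")
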