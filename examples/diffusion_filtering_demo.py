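"""Show what coherence-enhancing diffusion does to a noisy line pattern.

A grid of bright lines (stand-in for the endomysial boundary network)
is corrupted with interior speckle; CED smooths the interiors while
keeping — even sharpening — the line contrast, which is exactly the
behaviour the segmentation pipeline relies on.
"""

import numpy as np

from muscleseg import DiffusionParams, GrayImage, ced

rng = np.random.default_rng(0)
n = 128
u = np.full((n, n), 0.3)
lines = np.zeros((n, n), dtype=bool)
lines[::32, :] = True
lines[:, ::32] = True
u[lines] = 0.9
u[~lines] += rng.normal(0, 0.06, (~lines).sum())
u = np.clip(u, 0, 1)

params = DiffusionParams()  # tau=1, sigma=1e-4, rho=4, c1=1e-10, c2=1e-3
out = ced(GrayImage(u), params).pixels

var_before = u[~lines].var()
var_after = out[~lines].var()
contrast_before = u[lines].mean() - u[~lines].mean()
contrast_after = out[lines].mean() - out[~lines].mean()

print(f"interior speckle variance: {var_before:.5f} -> {var_after:.5f} "
      f"({100 * (1 - var_after / var_before):.1f}% reduction)")
print(f"line-interior contrast   : {contrast_before:.3f} -> {contrast_after:.3f}")
print("CED reduces interior speckle while leaving the boundary-line "
      "contrast intact — smoothing acts along structures, never across "
      "the lines it will later threshold.")
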