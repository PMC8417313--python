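"""Generate a synthetic fundus-like image with exact vessel ground truth.

The generator grows a branching, tapering vascular tree inside a circular
field of view and renders it with low vessel/background contrast, a central
light reflex along wide vessels, and additive noise — the features that make
real fundus photographs hard to segment.
"""

import numpy as np

from vesselfuse import VesselTreeSpec, generate_tree, render_fundus

spec = VesselTreeSpec(image_size=128, n_roots=3, root_width_range=(4.0, 9.0),
                      taper_rate=1.0, seed=42)
sample = render_fundus(generate_tree(spec), noise_sd=0.03, contrast=0.25, seed=43)

mask = sample.vessel_mask.grid
widths = sample.true_width[mask == 1]
print(f"vessel pixels: {mask.sum()} "
      f"({100 * mask.sum() / sample.fov_mask.grid.sum():.1f}% of the FOV)")
print(f"caliber range: {widths.min():.1f}-{widths.max():.1f} px")
print(f"thin fraction (caliber < 2.2 px): {np.mean(widths < 2.2):.2f}")
green = sample.rgb[:, :, 1]
bg = (mask == 0) & (sample.fov_mask.grid == 1)
print(f"green-channel contrast (background - vessel): "
      f"{green[bg].mean() - green[mask == 1].mean():.3f}")
# The thin fraction is the share of capillary-scale pixels the thick/thin
# separation will route to the thin training objective; the contrast is the
# intensity gap the networks must learn to detect.
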