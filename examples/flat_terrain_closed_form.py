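"""Effort on perfectly flat terrain has a closed form — verify it.

On a constant image every section is flat: gravity vanishes, only rolling
resistance (g*m*Cr = 3.92 N at defaults) remains, so each section costs
P = 3.92*v = 43.12 W and E = 3.92 * L * meters_per_pixel joules.
"""

import numpy as np

from cyeff import EffortParams, SamplingConfig, extract_cyeff, meters_per_unit

img = np.full((300, 300), 128.0)
params = EffortParams()
cfg = SamplingConfig(seed=0)  # 500 trajectories, sections of L=2

mpu = meters_per_unit(img, params)
feats = extract_cyeff(img, cfg, params)

print(f"meters per pixel unit     : {mpu:.3f}  (200 km over the image diagonal)")
print(f"per-section power         : 43.12 W (exact closed form)")
print(f"per-section energy        : {3.92 * 2 * mpu:.2f} J")
print(f"image power feature FP    : {feats.fp:.2f} W")
print(f"image energy feature FE   : {feats.fe:.2f} J")
print()
print("FP and FE are the closed-form section values times the average number")
print("of sections per trajectory — the floor of the effort scale; any texture")
print("can only add to it.")
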