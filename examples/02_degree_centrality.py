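"""Per-subject weighted degree centrality at the five correlation thresholds.

Simulates one control subject, runs the denoising chain (discard, Friston-24
+ WM/CSF nuisance regression, 0.01-0.08 Hz band-pass) and computes
DC(i) = sum_j r_ij [r_ij > r0] inside the gray-matter mask for
r0 in {0.15, 0.2, 0.25, 0.3, 0.35}.
"""

import numpy as np

from voxelhub import DEFAULT_THRESHOLDS, SynthSpec, dc_multi_threshold, generate_subject_bold
from voxelhub.pipeline import preprocess_subject

spec = SynthSpec(seed=3)
masks = spec.masks()
gm = masks["gm"]
hub = spec.hub_masks()[0]

bold, motion = generate_subject_bold(spec, "control", subject_seed=123)
clean, _ = preprocess_subject(bold, motion, gm, masks["wm"], masks["csf"])

print(f"gray-matter mask: {gm.n_voxels} voxels; true hub: {hub.n_voxels} voxels")
print(f"{'r0':>5} {'mean DC in hub':>15} {'mean DC elsewhere':>18}")
for dm in dc_multi_threshold(clean, gm, DEFAULT_THRESHOLDS):
    in_hub = dm.dc[hub.data].mean()
    out_hub = dm.dc[gm.data & ~hub.data].mean()
    print(f"{dm.r0:5.2f} {in_hub:15.1f} {out_hub:18.1f}")
print("-> hub voxels carry more supra-threshold correlation than background at")
print("   every threshold; the z-scored map of this quantity enters group stats.")
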