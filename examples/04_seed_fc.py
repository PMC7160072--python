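"""Seed-based functional connectivity from a sphere ROI.

Extracts the mean time series of a 6-mm sphere at the implanted hub,
correlates it with every gray-matter voxel and Fisher-z transforms the
map — the per-subject input to group FC comparisons.
"""

import numpy as np

from voxelhub import RoiSpec, SynthSpec, compute_fc, extract_roi_timeseries, generate_subject_bold
from voxelhub.pipeline import preprocess_subject

spec = SynthSpec(seed=9)
masks = spec.masks()
gm = masks["gm"]
hub = spec.hub_masks()[0]

bold, motion = generate_subject_bold(spec, "control", subject_seed=77)
clean, _ = preprocess_subject(bold, motion, gm, masks["wm"], masks["csf"])

roi = RoiSpec(kind="sphere", center_mm=spec.hubs[0].center_mm, radius_mm=6.0,
              label="hub_sphere")
ts = extract_roi_timeseries(clean, roi, gm)
fc = compute_fc(clean, ts, gm, seed_label=roi.label)

in_hub = fc.r[hub.data]
background = fc.r[gm.data & ~hub.data]
print(f"seed: {roi.label} at {roi.center_mm} (r = {roi.radius_mm} mm)")
print(f"mean seed-to-voxel r inside the hub: {in_hub.mean():.3f}")
print(f"mean seed-to-voxel r elsewhere:      {background.mean():.3f}")
print(f"Fisher z range: [{fc.z[gm.data].min():.2f}, {fc.z[gm.data].max():.2f}] (finite)")
print("-> voxels sharing the hub's latent signal correlate strongly with the")
print("   seed; the z map (atanh r) is what enters the group-level GLM.")
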