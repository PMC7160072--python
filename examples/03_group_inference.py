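"""Group-level DC deficit detection with GRF cluster correction.

Runs a reduced two-group cohort (8 vs 8 subjects on a small grid, strong
implanted deficit) through preprocessing, DC z-maps, 6-mm smoothing, the
covariate-adjusted two-sample GLM and Gaussian-random-field cluster
inference, and prints the surviving clusters the way a study would table
them (peak world coordinate, peak t, extent, cluster p).
"""

import numpy as np

from voxelhub import (
    CohortTable,
    HubSpec,
    SynthSpec,
    dc_multi_threshold,
    generate_covariates,
    generate_subject_bold,
    grf_cluster_inference,
    make_group_design,
    smooth_gaussian,
    two_sample_glm,
)
from voxelhub.pipeline import preprocess_subject

spec = SynthSpec(
    shape=(20, 24, 20),
    n_frames=160,
    n_patients=8,
    n_controls=8,
    hubs=[HubSpec(center_mm=(12.0, -15.0, 3.0), radius_mm=8.0,
                  loading_control=0.9, loading_patient=0.2)],
    seed=21,
)
masks = spec.masks()
gm = masks["gm"]
cov = generate_covariates(spec, np.random.default_rng(21))
seeds = [int(s.generate_state(1)[0] % 2**31)
         for s in np.random.SeedSequence(21).spawn(len(cov))]

zmaps = []
for i, row in cov.iterrows():
    bold, motion = generate_subject_bold(
        spec, row["group"], seeds[i], hub_loadings=[float(row["hub0_loading"])]
    )
    clean, _ = preprocess_subject(bold, motion, gm, masks["wm"], masks["csf"])
    dm = dc_multi_threshold(clean, gm, [0.25])[0]
    zmaps.append(smooth_gaussian((dm.z, gm.affine), 6.0))

cohort = CohortTable(cov[["subject_id", "group", "age", "sex", "education"]])
design = make_group_design(cohort)  # age, sex, education as nuisance covariates
result = two_sample_glm(zmaps, design, gm)
table, labels = grf_cluster_inference(result, voxel_p=0.01, cluster_p=0.05)

print(f"residual smoothness: {result.smoothness.fwhm_mm.round(1)} mm FWHM, "
      f"{result.smoothness.resels:.0f} resels")
print(table.round(4).to_string(index=False))
hub = spec.hub_masks()[0].data
neg = labels < 0
print(f"true hub voxels: {hub.sum()}, significant deficit voxels: {neg.sum()}, "
      f"overlap: {(neg & hub).sum()}")
print("-> a negative-t cluster at the implanted hub survives GRF correction")
print("   (voxel p<0.01, cluster p<0.05); sign -1 marks patient < control.")
print("   A positive cluster can appear away from the hub: z-scoring within")
print("   the mask couples a hub deficit to a slight background elevation.")
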