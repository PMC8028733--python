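"""Extract the 199-feature radiomic vector from one lesion.

Shows the per-voxel kinetic parameters of a hand curve, then the grouped
feature counts for a synthetic lesion.
"""

import radiotme as rt

# kinetic parameters of a single enhancement curve: signal 100 -> 200 ->
# 180 -> 160 at minutes 0..3 peaks at the first post-contrast phase
pe, ttp, wis, wos = rt.voxel_kinetics([100, 200, 180, 160], [0, 1, 2, 3])
print(f"PE={pe:.2f} (peak relative enhancement), TTP={ttp:.0f} min, "
      f"WIS={wis:.2f}/min, WOS={wos:.2f}/min")

cfg = rt.CohortConfig(n_lesions=2, seed=3)
study, _ = rt.gen_lesion_study(cfg, 0)

static = rt.static_feature_vector(study)
kinetic = rt.kinetic_feature_vector(study)
print(f"static features: {len(static)} (shape/first-order/texture)")
print(f"kinetic features: {len(kinetic)} (aggregate/heterogeneity/textural)")
print(f"tumor volume: {static['shape_voxel_volume']:.0f} mm^3, "
      f"sphericity {static['shape_sphericity']:.2f}")
print(f"mean PE {kinetic['kin_mean_pe']:.2f}, hot spot "
      f"{kinetic['kin_hotspot_pe']:.2f}, quick-arrival proportion "
      f"{kinetic['kin_prop_quick']:.2f}")
# mean PE is the average peak enhancement over tumor voxels; the hot spot
# is the strongest 3x3x3 neighborhood and always >= mean PE.
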