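"""Frozen feature catalogs and the cell-population list.

The extractor emits exactly 199 features per lesion: 111 static radiomic
features (shape, first-order intensity, five gray-level texture-matrix
families) and 88 kinetic features (aggregate, heterogeneity, textural
kinetic).  The catalogs below are module-level constants so the counts are
enforceable: every feature vector is checked against them, and planted
associations in the synthetic generator must name catalog entries.
"""

from __future__ import annotations

# --------------------------------------------------------------------------
# Kinetic features: 10 aggregate + 21 heterogeneity + 57 textural kinetic = 88
# --------------------------------------------------------------------------

KINETIC_AGGREGATE = [
    "kin_mean_wis", "kin_sd_wis",
    "kin_mean_wos", "kin_sd_wos",
    "kin_mean_pe", "kin_sd_pe",
    "kin_mean_ttp", "kin_sd_ttp",
    "kin_mpe", "kin_hotspot_pe",
]

TTP_CLUSTERS = ["quick", "intermediate", "slow"]

KINETIC_HETEROGENEITY = [
    f"kin_{c}_{stat}_{param}"
    for c in TTP_CLUSTERS
    for param in ("wis", "wos", "pe")
    for stat in ("mean", "sd")
] + [f"kin_prop_{c}" for c in TTP_CLUSTERS]

# 13 co-occurrence descriptors + AVD + 5 histogram statistics per kinetic map
COOC_KINETIC_DESCRIPTORS = [
    "asm", "contrast", "correlation", "variance", "idm",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2",
]
HIST_DESCRIPTORS = ["hist_mean", "hist_sd", "hist_skewness", "hist_kurtosis", "hist_entropy"]

KINETIC_MAPS = ["wis", "wos", "pe"]

KINETIC_TEXTURAL = [
    f"kin_tex_{m}_{d}"
    for m in KINETIC_MAPS
    for d in COOC_KINETIC_DESCRIPTORS + ["avd"] + HIST_DESCRIPTORS
]

KINETIC_FEATURES = KINETIC_AGGREGATE + KINETIC_HETEROGENEITY + KINETIC_TEXTURAL
assert len(KINETIC_FEATURES) == 88

# --------------------------------------------------------------------------
# Static features: 14 shape + 22 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM
#                  + 14 GLDM + 5 NGTDM = 111
# --------------------------------------------------------------------------

SHAPE_FEATURES = [
    "shape_voxel_volume", "shape_mesh_volume", "shape_surface_area",
    "shape_surface_volume_ratio", "shape_sphericity", "shape_compactness",
    "shape_max_3d_diameter", "shape_major_axis_length",
    "shape_minor_axis_length", "shape_least_axis_length",
    "shape_elongation", "shape_flatness",
    "shape_equivalent_diameter", "shape_extent",
]

FIRST_ORDER_FEATURES = [
    "fo_mean", "fo_median", "fo_min", "fo_max", "fo_range",
    "fo_p10", "fo_p90", "fo_iqr", "fo_std", "fo_mad", "fo_rmad",
    "fo_rms", "fo_energy", "fo_total_energy", "fo_entropy",
    "fo_uniformity", "fo_skewness", "fo_kurtosis",
    # per-phase tumor mean intensities (pre + three post-contrast)
    "fo_mean_pre", "fo_mean_post1", "fo_mean_post2", "fo_mean_post3",
]

GLCM_DESCRIPTORS = [
    "autocorrelation", "joint_average", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_entropy", "difference_variance", "joint_energy",
    "joint_entropy", "imc1", "imc2", "idm", "idmn", "id", "idn",
    "inverse_variance", "maximum_probability", "sum_average", "sum_entropy",
    "sum_variance", "sum_squares",
]

GLRLM_DESCRIPTORS = [
    "sre", "lre", "gln", "glnn", "rln", "rlnn", "rp", "glv", "rv", "re",
    "lglre", "hglre", "srlgle", "srhgle", "lrlgle", "lrhgle",
]

GLSZM_DESCRIPTORS = [
    "sae", "lae", "gln", "glnn", "szn", "sznn", "zp", "glv", "zv", "ze",
    "lglze", "hglze", "salgle", "sahgle", "lalgle", "lahgle",
]

GLDM_DESCRIPTORS = [
    "sde", "lde", "gln", "dn", "dnn", "glv", "dv", "de",
    "lgle", "hgle", "sdlgle", "sdhgle", "ldlgle", "ldhgle",
]

NGTDM_DESCRIPTORS = ["coarseness", "contrast", "busyness", "complexity", "strength"]

STATIC_FEATURES = (
    SHAPE_FEATURES
    + FIRST_ORDER_FEATURES
    + [f"glcm_{d}" for d in GLCM_DESCRIPTORS]
    + [f"glrlm_{d}" for d in GLRLM_DESCRIPTORS]
    + [f"glszm_{d}" for d in GLSZM_DESCRIPTORS]
    + [f"gldm_{d}" for d in GLDM_DESCRIPTORS]
    + [f"ngtdm_{d}" for d in NGTDM_DESCRIPTORS]
)
assert len(STATIC_FEATURES) == 111

ALL_FEATURES = STATIC_FEATURES + KINETIC_FEATURES
assert len(ALL_FEATURES) == 199
assert len(set(ALL_FEATURES)) == 199

#: family tag per feature, used to group rows of the correlation heatmap
FEATURE_FAMILY = {}
for _name in SHAPE_FEATURES:
    FEATURE_FAMILY[_name] = "size" if _name in (
        "shape_voxel_volume", "shape_mesh_volume", "shape_surface_area",
        "shape_max_3d_diameter", "shape_major_axis_length",
        "shape_minor_axis_length", "shape_least_axis_length",
        "shape_equivalent_diameter",
    ) else "morphology"
for _name in STATIC_FEATURES:
    if _name.startswith(("fo_", "glcm_", "glrlm_", "glszm_", "gldm_", "ngtdm_")):
        FEATURE_FAMILY[_name] = "texture"
for _name in KINETIC_FEATURES:
    FEATURE_FAMILY[_name] = "kinetic"

# --------------------------------------------------------------------------
# Cell populations: 8 immune + 2 stromal
# --------------------------------------------------------------------------

POPULATIONS = [
    "T_cells",
    "CD8_T_cells",
    "Cytotoxic_lymphocytes",
    "NK_cells",
    "B_lineage",
    "Monocytic_lineage",
    "Myeloid_dendritic_cells",
    "Neutrophils",
    "Endothelial_cells",
    "Fibroblasts",
]
assert len(POPULATIONS) == 10
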