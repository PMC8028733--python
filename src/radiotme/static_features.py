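"""Static radiomic features: shape, first-order intensity, and the five
gray-level texture-matrix families, 111 features in total.

Intensity-derived families are computed on the reference phase — the first
post-contrast volume, where lesion conspicuity is highest — after the
standard preprocessing: in-mask intensities are min-max rescaled to 8 bits
(0..255) and quantized with a fixed bin width of 25, giving at most
ceil(256/25) = 11 gray levels.  Shape features depend only on the mask and
the voxel spacing.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage, stats
from scipy.spatial.distance import pdist
from skimage import measure

from . import texture
from .catalog import FIRST_ORDER_FEATURES, STATIC_FEATURES
from .datatypes import DceStudy, QuantizedRoi

logger = logging.getLogger(__name__)

REFERENCE_PHASE = 1  # first post-contrast


def rescale_quantize(
    volume: np.ndarray,
    mask: np.ndarray,
    bits: int = 8,
    bin_width: float = 25.0,
) -> QuantizedRoi:
    """Min-max rescale in-mask intensities to [0, 2^bits - 1], then bin with
    a fixed width: level(v) = floor(rescaled(v) / bin_width) + 1."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = np.asarray(volume, dtype=float)[mask]
    vmin, vmax = vals.min(), vals.max()
    top = 2 ** bits - 1
    if vmax > vmin:
        rescaled = (vals - vmin) / (vmax - vmin) * top
    else:
        rescaled = np.zeros_like(vals)
        logger.info("constant ROI: quantized to a single gray level")
    levels = np.floor(rescaled / bin_width).astype(np.int64) + 1
    n_levels = int(levels.max())
    label_volume = np.zeros(mask.shape, dtype=np.int64)
    label_volume[mask] = levels
    return QuantizedRoi(
        levels=levels, label_volume=label_volume, mask=mask,
        n_levels=n_levels, bin_width=float(bin_width),
    )


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume of a closed triangle mesh (divergence theorem)."""
    a = verts[faces[:, 0]]
    b = verts[faces[:, 1]]
    c = verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def shape_features(mask: np.ndarray, spacing) -> dict:
    """14 shape descriptors of the binary mask in physical (mm) units."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    spacing = np.asarray(spacing, dtype=float)
    voxel_vol = float(spacing.prod())
    n = int(mask.sum())
    volume = n * voxel_vol

    # the surface mesh is taken from a lightly smoothed indicator function
    # (sigma = 0.8 voxel) to suppress the staircase bias of meshing a
    # binary volume; masks too small to survive smoothing fall back to the
    # binary indicator
    padded = np.pad(mask.astype(float), 2)
    smoothed = ndimage.gaussian_filter(padded, sigma=0.8)
    if smoothed.max() <= 0.5:
        smoothed = padded
    verts, faces, _, _ = measure.marching_cubes(
        smoothed, level=0.5, spacing=tuple(spacing))
    surface = float(measure.mesh_surface_area(verts, faces))
    mesh_vol = _mesh_volume(verts, faces)

    coords = np.argwhere(mask) * spacing
    # max 3D diameter on the physical voxel centers (convex hull suffices
    # but brute pairwise is fine at lesion scale)
    if len(coords) > 1:
        if len(coords) > 2000:
            from scipy.spatial import ConvexHull
            hull = ConvexHull(coords)
            pts = coords[hull.vertices]
        else:
            pts = coords
        max_diam = float(pdist(pts).max())
    else:
        max_diam = 0.0

    if len(coords) > 1:
        cov = np.cov(coords, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        major, minor, least = (4.0 * np.sqrt(eig)).tolist()
        elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
        flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0
    else:
        major = minor = least = 0.0
        elongation = flatness = 0.0

    sphericity = float(np.pi ** (1 / 3) * (6 * mesh_vol) ** (2 / 3) / surface)
    compactness = float(mesh_vol / (np.sqrt(np.pi) * surface ** 1.5))
    equiv_diam = float((6 * volume / np.pi) ** (1 / 3))
    bbox = [(c.max() - c.min() + 1) for c in np.nonzero(mask)]
    bbox_vol = float(np.prod([b * s for b, s in zip(bbox, spacing)]))
    extent = volume / bbox_vol

    return {
        "shape_voxel_volume": volume,
        "shape_mesh_volume": mesh_vol,
        "shape_surface_area": surface,
        "shape_surface_volume_ratio": surface / mesh_vol if mesh_vol > 0 else 0.0,
        "shape_sphericity": sphericity,
        "shape_compactness": compactness,
        "shape_max_3d_diameter": max_diam,
        "shape_major_axis_length": major,
        "shape_minor_axis_length": minor,
        "shape_least_axis_length": least,
        "shape_elongation": elongation,
        "shape_flatness": flatness,
        "shape_equivalent_diameter": equiv_diam,
        "shape_extent": extent,
    }


def first_order_features(study: DceStudy, roi: QuantizedRoi | None = None) -> dict:
    """22 first-order features: 18 intensity statistics on the reference
    phase plus the tumor mean intensity of each of the four phases.

    Entropy and uniformity are computed on the quantized gray-level
    histogram; the remaining statistics use the raw in-mask intensities.
    """
    mask = study.mask
    ref = study.phases[REFERENCE_PHASE]
    if roi is None:
        roi = rescale_quantize(ref, mask)
    v = ref[mask].astype(float)
    n = v.size
    sd = float(v.std())
    p10, p90 = np.percentile(v, [10, 90])
    q1, q3 = np.percentile(v, [25, 75])
    rmad_sel = v[(v >= p10) & (v <= p90)]

    p = np.bincount(roi.levels, minlength=roi.n_levels + 1)[1:].astype(float)
    p /= p.sum()
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())

    out = {
        "fo_mean": float(v.mean()),
        "fo_median": float(np.median(v)),
        "fo_min": float(v.min()),
        "fo_max": float(v.max()),
        "fo_range": float(v.max() - v.min()),
        "fo_p10": float(p10),
        "fo_p90": float(p90),
        "fo_iqr": float(q3 - q1),
        "fo_std": sd,
        "fo_mad": float(np.abs(v - v.mean()).mean()),
        "fo_rmad": float(np.abs(rmad_sel - rmad_sel.mean()).mean()) if rmad_sel.size else 0.0,
        "fo_rms": float(np.sqrt((v ** 2).mean())),
        "fo_energy": float((v ** 2).sum()),
        "fo_total_energy": float((v ** 2).sum() * np.prod(study.spacing)),
        "fo_entropy": entropy,
        "fo_uniformity": float((p ** 2).sum()),
        "fo_skewness": float(stats.skew(v)) if sd > 0 else 0.0,
        "fo_kurtosis": float(stats.kurtosis(v, fisher=False)) if sd > 0 else 0.0,
        "fo_mean_pre": float(study.phases[0][mask].mean()),
        "fo_mean_post1": float(study.phases[1][mask].mean()),
        "fo_mean_post2": float(study.phases[2][mask].mean()),
        "fo_mean_post3": float(study.phases[3][mask].mean()),
    }
    assert list(out) == FIRST_ORDER_FEATURES
    return out


_FAMILIES = {
    "GLCM": (texture.glcm_matrix, texture.glcm_features, "glcm"),
    "GLRLM": (texture.glrlm_matrix, texture.glrlm_features, "glrlm"),
    "GLSZM": (texture.glszm_matrix, texture.glszm_features, "glszm"),
    "GLDM": (texture.gldm_matrix, texture.gldm_features, "gldm"),
}


def texture_matrix_features(roi: QuantizedRoi, family: str) -> dict:
    """Descriptor set of one texture-matrix family on a quantized ROI."""
    fam = family.upper()
    n_vox = int(roi.mask.sum())
    if fam == "NGTDM":
        n_i, p_i, s_i = texture.ngtdm_table(roi.label_volume, roi.mask, roi.n_levels)
        return {f"ngtdm_{k}": v for k, v in texture.ngtdm_features(n_i, p_i, s_i).items()}
    if fam == "GLCM":
        P = texture.glcm_matrix(roi.label_volume, roi.mask, roi.n_levels)
        return {f"glcm_{k}": v for k, v in texture.glcm_features(P).items()}
    if fam not in _FAMILIES:
        raise ValueError(f"unknown texture family: {family}")
    matrix_fn, feat_fn, prefix = _FAMILIES[fam]
    P = matrix_fn(roi.label_volume, roi.mask, roi.n_levels)
    return {f"{prefix}_{k}": v for k, v in feat_fn(P, n_vox).items()}


def static_feature_vector(
    study: DceStudy,
    bits: int = 8,
    bin_width: float = 25.0,
) -> dict:
    """All 111 static features in catalog order."""
    feats = {}
    feats.update(shape_features(study.mask, study.spacing))
    roi = rescale_quantize(study.phases[REFERENCE_PHASE], study.mask, bits, bin_width)
    feats.update(first_order_features(study, roi))
    for fam in ("GLCM", "GLRLM", "GLSZM", "GLDM", "NGTDM"):
        feats.update(texture_matrix_features(roi, fam))
    vec = {name: feats[name] for name in STATIC_FEATURES}
    bad = [k for k, v in vec.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite static features: {bad}")
    return vec


def full_feature_vector(study: DceStudy, **kinetic_kwargs) -> dict:
    """All 199 features (111 static + 88 kinetic) for one lesion."""
    from .kinetics import kinetic_feature_vector

    out = static_feature_vector(study)
    out.update(kinetic_feature_vector(study, **kinetic_kwargs))
    return out
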