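"""Gray-level texture matrices and their descriptor sets, computed in 3D.

All five matrix families (GLCM, GLRLM, GLSZM, GLDM, NGTDM) operate on an
integer level volume (levels 1..n_levels inside the mask, 0 outside) and
respect the mask: voxel pairs, runs, zones, dependencies and neighborhoods
never cross the mask boundary.

Conventions frozen here (and mirrored by the brute-force oracles in the
test suite):

* GLCM / co-occurrence: the 13 unique distance-1 3D offsets; each pair is
  counted in both directions (symmetric matrix); the 13 per-offset matrices
  are pooled and normalized once, and descriptors are computed on the
  pooled matrix.
* GLRLM: runs of equal level along the same 13 directions, broken by the
  mask; matrices pooled over directions.
* GLSZM: zones are 26-connected components of equal level.
* GLDM: dependence of a voxel = number of its 26-neighbors inside the mask
  with the same level (alpha = 0); the matrix is indexed by (level,
  dependence + 1).
* NGTDM: a voxel's neighborhood tone is the mean level of its in-mask
  26-neighbors; voxels with no in-mask neighbor contribute zero difference.

Degenerate single-level ROIs take closed-form values (ASM = 1, contrast =
0, IDM = 1, correlation defined as 0, ...) rather than NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# the 13 unique distance-1 offsets in 3D (half of the 26-neighborhood)
OFFSETS_13 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]
assert len(OFFSETS_13) == 13

OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _shifted(arr: np.ndarray, offset, fill):
    """Return out with out[v] = arr[v + offset], `fill` outside the grid."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for n, d in zip(arr.shape, offset):
        if d >= 0:
            src.append(slice(d, n))
            dst.append(slice(0, n - d))
        else:
            src.append(slice(0, n + d))
            dst.append(slice(-d, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with 0 log 0 = 0."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Pooled symmetric normalized co-occurrence matrix over the 13 offsets."""
    counts = np.zeros((n_levels, n_levels), dtype=float)
    lev = np.where(mask, levels, 0)
    for off in OFFSETS_13:
        nb = _shifted(lev, off, 0)
        both = mask & (nb > 0)
        i = lev[both] - 1
        j = nb[both] - 1
        np.add.at(counts, (i, j), 1.0)
        np.add.at(counts, (j, i), 1.0)
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


def glcm_features(P: np.ndarray) -> dict:
    """The 24-descriptor co-occurrence set on a normalized symmetric matrix."""
    n = P.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((px * i).sum())
    mu_y = float((py * i).sum())
    var_x = float((px * (i - mu_x) ** 2).sum())
    var_y = float((py * (i - mu_y) ** 2).sum())

    # diagonal (|i-j|) and cross-diagonal (i+j) distributions
    k_diff = np.arange(0, n)
    p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * n + 1)
    p_sum = np.array([P[(ii + jj) == k].sum() for k in k_sum])

    hxy = float(-_xlog2(P).sum())
    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxpy = np.outer(px, py)
    nzj = (P > 0) & (pxpy > 0)
    hxy1 = float(-(P[nzj] * np.log2(pxpy[nzj])).sum())
    hxy2 = float(-_xlog2(pxpy).sum())

    diff_avg = float((p_diff * k_diff).sum())
    sum_avg = float((p_sum * k_sum).sum())

    sigma = np.sqrt(var_x * var_y)
    if sigma > 0:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y) / sigma)
    else:
        correlation = 0.0

    denom = max(hx, hy)
    imc1 = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off_diag = ii != jj
    inv_var = float((P[off_diag] / (ii - jj)[off_diag].astype(float) ** 2).sum())

    return {
        "autocorrelation": float((ii * jj * P).sum()),
        "joint_average": mu_x,
        "cluster_prominence": float(((ii + jj - mu_x - mu_y) ** 4 * P).sum()),
        "cluster_shade": float(((ii + jj - mu_x - mu_y) ** 3 * P).sum()),
        "cluster_tendency": float(((ii + jj - mu_x - mu_y) ** 2 * P).sum()),
        "contrast": float(((ii - jj) ** 2 * P).sum()),
        "correlation": correlation,
        "difference_average": diff_avg,
        "difference_entropy": float(-_xlog2(p_diff).sum()),
        "difference_variance": float((p_diff * (k_diff - diff_avg) ** 2).sum()),
        "joint_energy": float((P ** 2).sum()),
        "joint_entropy": hxy,
        "imc1": imc1,
        "imc2": imc2,
        "idm": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "idmn": float((P / (1.0 + (ii - jj) ** 2 / n ** 2)).sum()),
        "id": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "idn": float((P / (1.0 + np.abs(ii - jj) / n)).sum()),
        "inverse_variance": inv_var,
        "maximum_probability": float(P.max()) if P.size else 0.0,
        "sum_average": sum_avg,
        "sum_entropy": float(-_xlog2(p_sum).sum()),
        "sum_variance": float((p_sum * (k_sum - sum_avg) ** 2).sum()),
        "sum_squares": float(((ii - mu_x) ** 2 * P).sum()),
    }


def cooc_kinetic_features(P: np.ndarray) -> dict:
    """13 classic co-occurrence descriptors + AVD for the kinetic maps.

    AVD (absolute value of differences) is sum_{i,j} p(i,j) |i - j|, i.e.
    the mean absolute level difference of co-occurring voxel pairs.
    """
    full = glcm_features(P)
    n = P.shape[0]
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return {
        "asm": full["joint_energy"],
        "contrast": full["contrast"],
        "correlation": full["correlation"],
        "variance": full["sum_squares"],
        "idm": full["idm"],
        "sum_average": full["sum_average"],
        "sum_variance": full["sum_variance"],
        "sum_entropy": full["sum_entropy"],
        "entropy": full["joint_entropy"],
        "difference_variance": full["difference_variance"],
        "difference_entropy": full["difference_entropy"],
        "imc1": full["imc1"],
        "imc2": full["imc2"],
        "avd": float((P * np.abs(ii - jj)).sum()),
    }


# --------------------------------------------------------------------------
# GLRLM
# --------------------------------------------------------------------------

def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length counts P[level-1, runlength-1] pooled over 13 directions."""
    lev = np.where(mask, levels, 0)
    max_len = int(np.ceil(np.sqrt(sum(s ** 2 for s in mask.shape)))) + 1
    counts = np.zeros((n_levels, max_len), dtype=float)
    strides = np.array(
        [mask.shape[1] * mask.shape[2], mask.shape[2], 1], dtype=np.int64
    )
    for off in OFFSETS_13:
        nb_mask = _shifted(mask, off, False)
        nb_lev = _shifted(lev, off, 0)
        cont = mask & nb_mask & (lev == nb_lev)          # run continues v -> v+off
        back = tuple(-d for d in off)
        prev_cont = _shifted(cont, back, False)          # run continued (v-off) -> v
        start = mask & ~prev_cont
        flat_start = np.flatnonzero(start.ravel())
        if flat_start.size == 0:
            continue
        step = int(np.dot(off, strides))
        flat_cont = cont.ravel()
        lengths = np.ones(flat_start.size, dtype=np.int64)
        cur = flat_start.copy()
        active = np.arange(flat_start.size)
        while active.size:
            go = flat_cont[cur[active]]
            active = active[go]
            cur[active] += step
            lengths[active] += 1
        run_levels = lev.ravel()[flat_start] - 1
        np.add.at(counts, (run_levels, lengths - 1), 1.0)
    last = np.flatnonzero(counts.sum(axis=0))
    if last.size:
        counts = counts[:, : last[-1] + 1]
    else:
        counts = counts[:, :1]
    return counts


def _size_family_features(P: np.ndarray, n_voxels: int, voxel_weighted_rp: bool = True) -> dict:
    """Shared descriptor algebra for run-length / size-zone style matrices.

    P holds counts indexed by (gray level i starting at 1, size j starting
    at 1).  Returns the 16 canonical descriptors keyed by generic names;
    callers rename to family-specific ones.
    """
    Nz = P.sum()
    if Nz == 0:
        return {k: 0.0 for k in (
            "small", "large", "gln", "glnn", "sn", "snn", "pct", "glv", "sv",
            "entropy", "lgl", "hgl", "sl", "sh", "ll", "lh")}
    n_lev, n_sz = P.shape
    i = np.arange(1, n_lev + 1, dtype=float)
    j = np.arange(1, n_sz + 1, dtype=float)
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    p = P / Nz
    mu_i = (pi / Nz * i).sum()
    mu_j = (pj / Nz * j).sum()
    ii = i[:, None]
    jj = j[None, :]
    return {
        "small": float((P / jj ** 2).sum() / Nz),
        "large": float((P * jj ** 2).sum() / Nz),
        "gln": float((pi ** 2).sum() / Nz),
        "glnn": float((pi ** 2).sum() / Nz ** 2),
        "sn": float((pj ** 2).sum() / Nz),
        "snn": float((pj ** 2).sum() / Nz ** 2),
        "pct": float(Nz / n_voxels),
        "glv": float(((ii - mu_i) ** 2 * p).sum()),
        "sv": float(((jj - mu_j) ** 2 * p).sum()),
        "entropy": float(-_xlog2(p).sum()),
        "lgl": float((P / ii ** 2).sum() / Nz),
        "hgl": float((P * ii ** 2).sum() / Nz),
        "sl": float((P / (ii ** 2 * jj ** 2)).sum() / Nz),
        "sh": float((P * ii ** 2 / jj ** 2).sum() / Nz),
        "ll": float((P * jj ** 2 / ii ** 2).sum() / Nz),
        "lh": float((P * ii ** 2 * jj ** 2).sum() / Nz),
    }


_GLRLM_RENAME = {
    "sre": "small", "lre": "large", "gln": "gln", "glnn": "glnn",
    "rln": "sn", "rlnn": "snn", "rp": "pct", "glv": "glv", "rv": "sv",
    "re": "entropy", "lglre": "lgl", "hglre": "hgl", "srlgle": "sl",
    "srhgle": "sh", "lrlgle": "ll", "lrhgle": "lh",
}


def glrlm_features(P: np.ndarray, n_voxels: int) -> dict:
    # runs are pooled over 13 directions, so the percentage denominator is
    # the number of voxel-direction slots
    base = _size_family_features(P, n_voxels * 13)
    return {k: base[v] for k, v in _GLRLM_RENAME.items()}


# --------------------------------------------------------------------------
# GLSZM
# --------------------------------------------------------------------------

def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone counts P[level-1, zonesize-1]; zones are 26-connected."""
    lev = np.where(mask, levels, 0)
    n_vox = int(mask.sum())
    counts = np.zeros((n_levels, n_vox), dtype=float)
    for g in range(1, n_levels + 1):
        comp, n_comp = ndimage.label(lev == g, structure=_STRUCT_26)
        if n_comp == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        for s in sizes:
            counts[g - 1, s - 1] += 1.0
    last = np.flatnonzero(counts.sum(axis=0))
    counts = counts[:, : last[-1] + 1] if last.size else counts[:, :1]
    return counts


_GLSZM_RENAME = {
    "sae": "small", "lae": "large", "gln": "gln", "glnn": "glnn",
    "szn": "sn", "sznn": "snn", "zp": "pct", "glv": "glv", "zv": "sv",
    "ze": "entropy", "lglze": "lgl", "hglze": "hgl", "salgle": "sl",
    "sahgle": "sh", "lalgle": "ll", "lahgle": "lh",
}


def glszm_features(P: np.ndarray, n_voxels: int) -> dict:
    base = _size_family_features(P, n_voxels)
    return {k: base[v] for k, v in _GLSZM_RENAME.items()}


# --------------------------------------------------------------------------
# GLDM
# --------------------------------------------------------------------------

def gldm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence counts P[level-1, dependence]; dependence = equal-level
    in-mask 26-neighbors of the voxel."""
    lev = np.where(mask, levels, 0)
    dep = np.zeros(mask.shape, dtype=np.int64)
    for off in OFFSETS_26:
        nb_lev = _shifted(lev, off, 0)
        dep += (mask & (nb_lev == lev) & (nb_lev > 0)).astype(np.int64)
    counts = np.zeros((n_levels, 27), dtype=float)
    np.add.at(counts, (lev[mask] - 1, dep[mask]), 1.0)
    last = np.flatnonzero(counts.sum(axis=0))
    counts = counts[:, : last[-1] + 1] if last.size else counts[:, :1]
    return counts


def gldm_features(P: np.ndarray, n_voxels: int) -> dict:
    # dependence j is stored 0-based; descriptors use j+1 as in the
    # size-family algebra
    base = _size_family_features(P, n_voxels)
    return {
        "sde": base["small"], "lde": base["large"], "gln": base["gln"],
        "dn": base["sn"], "dnn": base["snn"], "glv": base["glv"],
        "dv": base["sv"], "de": base["entropy"], "lgle": base["lgl"],
        "hgle": base["hgl"], "sdlgle": base["sl"], "sdhgle": base["sh"],
        "ldlgle": base["ll"], "ldhgle": base["lh"],
    }


# --------------------------------------------------------------------------
# NGTDM
# --------------------------------------------------------------------------

def ngtdm_table(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Per-level (n_i, p_i, s_i): count, probability and summed absolute
    difference from the neighborhood mean tone."""
    lev = np.where(mask, levels, 0).astype(float)
    nb_sum = np.zeros(mask.shape, dtype=float)
    nb_cnt = np.zeros(mask.shape, dtype=float)
    for off in OFFSETS_26:
        nb_sum += _shifted(lev * mask, off, 0.0)
        nb_cnt += _shifted(mask.astype(float), off, 0.0)
    has_nb = mask & (nb_cnt > 0)
    diff = np.zeros(mask.shape, dtype=float)
    diff[has_nb] = np.abs(lev[has_nb] - nb_sum[has_nb] / nb_cnt[has_nb])
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    np.add.at(n_i, (lev[mask] - 1).astype(int), 1.0)
    np.add.at(s_i, (lev[mask] - 1).astype(int), diff[mask])
    p_i = n_i / n_i.sum()
    return n_i, p_i, s_i


def ngtdm_features(n_i: np.ndarray, p_i: np.ndarray, s_i: np.ndarray) -> dict:
    n_vox = n_i.sum()
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, len(p_i) + 1, dtype=float)
    ps = float((p_i * s_i).sum())

    coarseness = 1.0 / ps if ps > 0 else 1e6

    if ngp > 1:
        iv = i[present]
        pv = p_i[present]
        sv = s_i[present]
        d2 = (iv[:, None] - iv[None, :]) ** 2
        contrast = float(
            (pv[:, None] * pv[None, :] * d2).sum()
            / (ngp * (ngp - 1))
            * (s_i.sum() / n_vox)
        )
        denom = np.abs(iv[:, None] * pv[:, None] - iv[None, :] * pv[None, :]).sum()
        busyness = float(ps / denom) if denom > 0 else 0.0
        num = (np.abs(iv[:, None] - iv[None, :])
               * (pv[:, None] * sv[:, None] + pv[None, :] * sv[None, :])
               / (pv[:, None] + pv[None, :]))
        complexity = float(num.sum() / n_vox)
        s_total = s_i.sum()
        strength = (
            float(((pv[:, None] + pv[None, :]) * d2).sum() / s_total)
            if s_total > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }
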