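"""Kinetic feature extraction from 4-phase DCE studies.

Each in-mask voxel has a 4-point enhancement curve: relative enhancement
E_t = (S_t - S_0) / max(S_0, eps) for the three post-contrast phases, with
E_0 = 0 at the pre-contrast phase.  From the curve we take the four
semi-quantitative parameters standard in breast DCE-MRI:

* PE  — peak enhancement, max_t E_t over the post-contrast phases;
* TTP — time to peak (minutes from the pre-contrast acquisition), the
  earliest maximizing phase; a flat curve is assigned the first
  post-contrast phase;
* WIS — wash-in slope, PE / TTP;
* WOS — wash-out slope, (E_last - E_peak) / (t_last - t_peak), defined as 0
  when the peak falls on the last phase.

The 88-feature kinetic vector has three groups: 10 aggregate features
(mean/SD of the four parameters, maximum PE, and the hot spot — the
highest 3x3x3-neighborhood mean PE), 21 heterogeneity features computed on
the 3-label time-to-peak characteristic map (per-sub-cluster mean/SD of
WIS/WOS/PE plus the three proportions), and 57 textural-kinetic features
(co-occurrence + histogram descriptors of the quantized WIS/WOS/PE
parameter maps).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage, stats

from .catalog import (
    HIST_DESCRIPTORS,
    KINETIC_FEATURES,
    KINETIC_MAPS,
    TTP_CLUSTERS,
)
from .datatypes import DceStudy, TtpCharacteristicMap
from .texture import cooc_kinetic_features, glcm_matrix

logger = logging.getLogger(__name__)

#: guard for non-positive pre-contrast signal, in intensity units
DEFAULT_BASELINE_EPS = 1.0


def voxel_kinetics(signal, times, baseline_eps: float = DEFAULT_BASELINE_EPS):
    """Kinetic parameters (PE, TTP, WIS, WOS) of a single 4-point curve.

    Thin wrapper over the vectorized :func:`kinetic_parameter_maps` path,
    kept for hand calculations and doctests of the stated formulas.
    """
    sig = np.asarray(signal, dtype=float).reshape(1, 4)
    pe, ttp, wis, wos = _curve_kinetics(sig, np.asarray(times, float), baseline_eps)
    return float(pe[0]), float(ttp[0]), float(wis[0]), float(wos[0])


def _curve_kinetics(signals: np.ndarray, times: np.ndarray, baseline_eps: float):
    """Vectorized kinetics for an (n, 4) array of curves."""
    s0 = signals[:, 0]
    denom = np.maximum(s0, baseline_eps)
    enh = (signals[:, 1:] - s0[:, None]) / denom[:, None]   # (n, 3)
    peak_idx = np.argmax(enh, axis=1)                       # first maximizer
    pe = enh[np.arange(len(enh)), peak_idx]
    post_times = times[1:]
    ttp = post_times[peak_idx] - times[0]
    wis = pe / ttp
    last = enh[:, -1]
    t_last = times[-1] - times[0]
    at_last = peak_idx == (len(post_times) - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        wos = np.where(at_last, 0.0, (last - pe) / (t_last - ttp))
    return pe, ttp, wis, wos


def kinetic_parameter_maps(study: DceStudy, baseline_eps: float = DEFAULT_BASELINE_EPS):
    """Per-voxel PE/TTP/WIS/WOS maps over the tumor mask.

    Returns a dict of full-grid float arrays (0 outside the mask) plus the
    integer peak-phase map (1..3 inside the mask).
    """
    mask = study.mask
    sig = study.phases[:, mask].T                          # (n_vox, 4)
    times = np.asarray(study.times, dtype=float)
    if np.any(sig[:, 0] <= 0):
        logger.warning(
            "lesion %s: %d voxels with non-positive baseline, eps=%g guard applied",
            study.lesion_id, int((sig[:, 0] <= 0).sum()), baseline_eps,
        )
    pe, ttp, wis, wos = _curve_kinetics(sig, times, baseline_eps)

    maps = {}
    for name, vals in (("pe", pe), ("ttp", ttp), ("wis", wis), ("wos", wos)):
        vol = np.zeros(mask.shape, dtype=float)
        vol[mask] = vals
        maps[name] = vol
    # peak post-contrast phase index (1..3); the TTP values map back to it
    post_times = times[1:] - times[0]
    phase_vol = np.zeros(mask.shape, dtype=np.int64)
    phase_vol[mask] = np.searchsorted(post_times, ttp) + 1
    maps["peak_phase"] = phase_vol
    return maps


def aggregate_features(study: DceStudy, baseline_eps: float = DEFAULT_BASELINE_EPS) -> dict:
    """The 10 aggregate kinetic features."""
    maps = kinetic_parameter_maps(study, baseline_eps)
    mask = study.mask
    out = {}
    for p in ("wis", "wos", "pe", "ttp"):
        vals = maps[p][mask]
        out[f"kin_mean_{p}"] = float(vals.mean())
        out[f"kin_sd_{p}"] = float(vals.std()) if vals.size > 1 else 0.0
    pe_map = maps["pe"]
    out["kin_mpe"] = float(pe_map[mask].max())
    out["kin_hotspot_pe"] = hot_spot(pe_map, mask)
    # catalog order
    return {k: out[k] for k in (
        "kin_mean_wis", "kin_sd_wis", "kin_mean_wos", "kin_sd_wos",
        "kin_mean_pe", "kin_sd_pe", "kin_mean_ttp", "kin_sd_ttp",
        "kin_mpe", "kin_hotspot_pe")}


def hot_spot(pe_map: np.ndarray, mask: np.ndarray) -> float:
    """Highest mean PE over a 3x3x3 (26-connected) neighborhood ∩ mask,
    taken over in-mask center voxels."""
    kernel = np.ones((3, 3, 3))
    sums = ndimage.convolve(pe_map * mask, kernel, mode="constant", cval=0.0)
    cnts = ndimage.convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
    means = np.where(cnts > 0, sums / np.maximum(cnts, 1e-300), 0.0)
    return float(means[mask].max())


def ttp_partition(study: DceStudy, baseline_eps: float = DEFAULT_BASELINE_EPS) -> TtpCharacteristicMap:
    """Partition the tumor into quick/intermediate/slow arrivals at peak.

    With three post-contrast phases TTP takes exactly three values, so the
    sub-clusters are the voxels peaking at post-phase 1, 2 and 3.
    """
    maps = kinetic_parameter_maps(study, baseline_eps)
    labels = maps["peak_phase"]
    n = study.n_voxels
    props = tuple(float((labels[study.mask] == k).sum()) / n for k in (1, 2, 3))
    return TtpCharacteristicMap(labels=labels, proportions=props)


def heterogeneity_features(
    study: DceStudy,
    ttp_map: TtpCharacteristicMap | None = None,
    baseline_eps: float = DEFAULT_BASELINE_EPS,
) -> dict:
    """21 heterogeneity features on the TTP characteristic map.

    Per sub-cluster: mean and SD of WIS, WOS and PE (an empty sub-cluster's
    statistics are 0), plus the three sub-cluster proportions.
    """
    if ttp_map is None:
        ttp_map = ttp_partition(study, baseline_eps)
    maps = kinetic_parameter_maps(study, baseline_eps)
    mask = study.mask
    out = {}
    for k, cluster in enumerate(TTP_CLUSTERS, start=1):
        sel = mask & (ttp_map.labels == k)
        for param in ("wis", "wos", "pe"):
            vals = maps[param][sel]
            out[f"kin_{cluster}_mean_{param}"] = float(vals.mean()) if vals.size else 0.0
            out[f"kin_{cluster}_sd_{param}"] = float(vals.std()) if vals.size > 1 else 0.0
    for cluster, p in zip(TTP_CLUSTERS, ttp_map.proportions):
        out[f"kin_prop_{cluster}"] = p
    return out


def _histogram_stats(values: np.ndarray, levels: np.ndarray, n_levels: int) -> dict:
    """Mean/SD/skewness/kurtosis of the raw in-mask values + entropy of the
    quantized level histogram (bits)."""
    sd = float(values.std())
    if sd > 0:
        skew = float(stats.skew(values))
        kurt = float(stats.kurtosis(values, fisher=False))
    else:
        skew, kurt = 0.0, 0.0
    p = np.bincount(levels, minlength=n_levels + 1)[1:].astype(float)
    p = p / p.sum()
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    return {
        "hist_mean": float(values.mean()),
        "hist_sd": sd,
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_entropy": entropy,
    }


def quantize_map(values: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width min-max quantization of in-mask values to 1..levels."""
    vmin = values.min()
    vmax = values.max()
    if vmax <= vmin:
        return np.ones(values.shape, dtype=np.int64)
    q = np.floor((values - vmin) / (vmax - vmin) * levels).astype(np.int64) + 1
    return np.clip(q, 1, levels)


def textural_kinetic_features(
    study: DceStudy,
    ttp_map: TtpCharacteristicMap | None = None,
    levels: int = 11,
    baseline_eps: float = DEFAULT_BASELINE_EPS,
) -> dict:
    """57 textural-kinetic features: per WIS/WOS/PE parameter map, 13
    co-occurrence descriptors + AVD on the quantized map, and 5 histogram
    statistics."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    maps = kinetic_parameter_maps(study, baseline_eps)
    mask = study.mask
    out = {}
    for m in KINETIC_MAPS:
        vals = maps[m][mask]
        q = quantize_map(vals, levels)
        n_lev = int(q.max())
        lev_vol = np.zeros(mask.shape, dtype=np.int64)
        lev_vol[mask] = q
        P = glcm_matrix(lev_vol, mask, n_lev)
        cooc = cooc_kinetic_features(P)
        for d, v in cooc.items():
            out[f"kin_tex_{m}_{d}"] = v
        hist = _histogram_stats(vals, q, n_lev)
        for d in HIST_DESCRIPTORS:
            out[f"kin_tex_{m}_{d}"] = hist[d]
    return out


def kinetic_feature_vector(
    study: DceStudy,
    levels: int = 11,
    baseline_eps: float = DEFAULT_BASELINE_EPS,
) -> dict:
    """All 88 kinetic features in catalog order."""
    ttp_map = ttp_partition(study, baseline_eps)
    feats = {}
    feats.update(aggregate_features(study, baseline_eps))
    feats.update(heterogeneity_features(study, ttp_map, baseline_eps))
    feats.update(textural_kinetic_features(study, ttp_map, levels, baseline_eps))
    vec = {name: feats[name] for name in KINETIC_FEATURES}
    bad = [k for k, v in vec.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite kinetic features: {bad}")
    return vec
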