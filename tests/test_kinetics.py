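"""Kinetic parameter and kinetic-feature extraction tests."""

import numpy as np
import pytest

import radiotme as rt
from radiotme.catalog import KINETIC_FEATURES
from radiotme.kinetics import hot_spot
from radiotme.synthetic import DEFAULT_ARCHETYPES, archetype_enhancement

from conftest import make_study
from oracles import oracle_hotspot


@pytest.mark.parametrize(
    "signal, expected",
    [
        # rise to phase 1 then washout: PE=1, TTP=1, WIS=1, WOS=-0.2
        ((100, 200, 180, 160), (1.0, 1.0, 1.0, -0.2)),
        # flat curve: first-post convention, everything zero
        ((100, 100, 100, 100), (0.0, 1.0, 0.0, 0.0)),
        # peak at the last phase: WOS defined as 0
        ((100, 120, 140, 200), (1.0, 3.0, 1.0 / 3.0, 0.0)),
    ],
)
def test_voxel_kinetics_hand_examples(signal, expected):
    got = rt.voxel_kinetics(signal, (0, 1, 2, 3))
    assert got == pytest.approx(expected, rel=1e-12)


def test_voxel_kinetics_nonpositive_baseline_guard():
    # S0 = 0 falls back to the eps guard instead of dividing by zero
    pe, ttp, wis, wos = rt.voxel_kinetics((0, 50, 40, 30), (0, 1, 2, 3), baseline_eps=1.0)
    assert pe == pytest.approx(50.0)
    assert np.isfinite([pe, ttp, wis, wos]).all()


def test_aggregate_homogeneous_lesion(homogeneous_study):
    feats = rt.aggregate_features(homogeneous_study)
    assert feats["kin_mean_pe"] == pytest.approx(1.0)
    assert feats["kin_sd_pe"] == pytest.approx(0.0, abs=1e-12)
    assert feats["kin_mpe"] == pytest.approx(1.0)
    assert feats["kin_hotspot_pe"] == pytest.approx(1.0)
    assert feats["kin_mean_ttp"] == pytest.approx(1.0)
    assert feats["kin_mean_wos"] == pytest.approx(-0.2)


def test_aggregate_two_isolated_voxels():
    mask = np.zeros((3, 3, 7), dtype=bool)
    mask[1, 1, 1] = True
    mask[1, 1, 5] = True  # not 26-adjacent
    phases = np.full((4, 3, 3, 7), 100.0)
    for pos, pe in (((1, 1, 1), 0.5), ((1, 1, 5), 1.5)):
        for ph, e in enumerate((0.0, pe, 0.8 * pe, 0.6 * pe)):
            phases[ph][pos] = 100.0 * (1 + e)
    study = rt.DceStudy(phases=phases, spacing=(1, 1, 1), times=(0, 1, 2, 3), mask=mask)
    feats = rt.aggregate_features(study)
    assert feats["kin_mean_pe"] == pytest.approx(1.0)
    assert feats["kin_mpe"] == pytest.approx(1.5)
    assert feats["kin_hotspot_pe"] == pytest.approx(1.5)


def test_hotspot_matches_exhaustive_scan(rng):
    mask = rng.random((8, 8, 8)) < 0.6
    mask[4, 4, 4] = True
    pe_map = np.where(mask, rng.random((8, 8, 8)), 0.0)
    assert hot_spot(pe_map, mask) == pytest.approx(oracle_hotspot(pe_map, mask), rel=1e-12)


def test_ttp_partition_counts():
    # 10 voxels in a line: 5 quick, 3 intermediate, 2 slow
    mask = np.zeros((1, 1, 10), dtype=bool)
    mask[0, 0, :] = True
    phases = np.full((4, 1, 1, 10), 100.0)
    curves = {
        1: (0.0, 1.0, 0.8, 0.6),
        2: (0.0, 0.5, 1.0, 0.8),
        3: (0.0, 0.3, 0.6, 1.0),
    }
    assign = [1] * 5 + [2] * 3 + [3] * 2
    for x, a in enumerate(assign):
        for ph in range(4):
            phases[ph, 0, 0, x] = 100.0 * (1 + curves[a][ph])
    study = rt.DceStudy(phases=phases, spacing=(1, 1, 1), times=(0, 1, 2, 3), mask=mask)
    tmap = rt.ttp_partition(study)
    assert tmap.proportions == pytest.approx((0.5, 0.3, 0.2))
    assert list(tmap.labels[0, 0, :]) == assign


def test_ttp_partition_recovers_generator_archetypes():
    cfg = rt.CohortConfig(n_lesions=2, noise_sd=0.0, seed=5)
    study, truth_labels = rt.gen_lesion_study(cfg, 0)
    tmap = rt.ttp_partition(study)
    assert np.array_equal(tmap.labels, truth_labels)


def test_single_archetype_partition():
    study = make_study({"a": (0.0, 1.0, 0.8, 0.6)})
    tmap = rt.ttp_partition(study)
    assert tmap.proportions == pytest.approx((1.0, 0.0, 0.0))


def test_heterogeneity_single_archetype_emptiness(homogeneous_study):
    feats = rt.heterogeneity_features(homogeneous_study)
    assert len(feats) == 21
    # the two empty sub-clusters contribute 12 zero statistics + 2 zero
    # proportions; quick SDs are 0 in the homogeneous lesion too
    zero = [k for k, v in feats.items() if v == 0.0]
    assert len(zero) >= 14
    assert feats["kin_prop_quick"] == pytest.approx(1.0)
    assert feats["kin_quick_mean_pe"] == pytest.approx(1.0)


def test_heterogeneity_proportions_sum_to_one(rng):
    cfg = rt.CohortConfig(n_lesions=2, seed=9)
    study, _ = rt.gen_lesion_study(cfg, 1)
    feats = rt.heterogeneity_features(study)
    total = sum(feats[f"kin_prop_{c}"] for c in ("quick", "intermediate", "slow"))
    assert total == pytest.approx(1.0, abs=1e-12)


def test_heterogeneity_closed_form_two_archetypes():
    times = (0.0, 1.0, 2.0, 3.0)
    quick = DEFAULT_ARCHETYPES["quick"]
    slow = DEFAULT_ARCHETYPES["slow"]
    cq = archetype_enhancement(quick, times)
    cs = archetype_enhancement(slow, times)
    study = make_study({"q": cq, "s": cs}, times=times)
    feats = rt.heterogeneity_features(study)
    assert feats["kin_quick_mean_wis"] == pytest.approx(quick.peak_enh / 1.0, rel=1e-9)
    assert feats["kin_quick_mean_wos"] == pytest.approx(quick.washout_rate, rel=1e-9)
    assert feats["kin_slow_mean_wis"] == pytest.approx(slow.peak_enh / 3.0, rel=1e-9)
    assert feats["kin_quick_sd_pe"] == pytest.approx(0.0, abs=1e-12)
    assert feats["kin_intermediate_mean_pe"] == 0.0  # empty sub-cluster


def test_closed_form_recovery_noiseless_phantom():
    """On a zero-noise phantom all aggregate and heterogeneity features
    equal their analytic values to 1e-9 relative tolerance."""
    cfg = rt.CohortConfig(n_lesions=2, noise_sd=0.0, seed=42)
    study, labels = rt.gen_lesion_study(cfg, 0)
    times = np.asarray(cfg.acquisition_times)
    arch = [cfg.archetype_params[c] for c in ("quick", "intermediate", "slow")]
    n = study.n_voxels
    counts = [(labels == k).sum() for k in (1, 2, 3)]
    pe = np.array([a.peak_enh for a in arch])
    ttp = np.array([float(times[a.peak_phase]) for a in arch])
    wis = pe / ttp
    wos = np.array([a.washout_rate if a.peak_phase < 3 else 0.0 for a in arch])
    w = np.array(counts) / n

    feats = rt.aggregate_features(study)
    for name, vals in (("pe", pe), ("ttp", ttp), ("wis", wis), ("wos", wos)):
        mean = (w * vals).sum()
        sd = np.sqrt((w * (vals - mean) ** 2).sum())
        assert feats[f"kin_mean_{name}"] == pytest.approx(mean, rel=1e-9, abs=1e-12)
        assert feats[f"kin_sd_{name}"] == pytest.approx(sd, rel=1e-9, abs=1e-12)
    assert feats["kin_mpe"] == pytest.approx(pe.max(), rel=1e-9)

    het = rt.heterogeneity_features(study)
    for k, cluster in enumerate(("quick", "intermediate", "slow")):
        assert het[f"kin_{cluster}_mean_wis"] == pytest.approx(wis[k], rel=1e-9)
        assert het[f"kin_{cluster}_mean_wos"] == pytest.approx(wos[k], rel=1e-9, abs=1e-12)
        assert het[f"kin_{cluster}_mean_pe"] == pytest.approx(pe[k], rel=1e-9)
        assert het[f"kin_{cluster}_sd_pe"] == pytest.approx(0.0, abs=1e-9)
        assert het[f"kin_prop_{cluster}"] == pytest.approx(w[k], rel=1e-12)


def test_kinetic_vector_catalog_and_determinism():
    cfg = rt.CohortConfig(n_lesions=2, seed=3)
    study, _ = rt.gen_lesion_study(cfg, 0)
    v1 = rt.kinetic_feature_vector(study)
    v2 = rt.kinetic_feature_vector(study)
    assert list(v1) == KINETIC_FEATURES
    assert len(v1) == 88
    assert all(np.isfinite(list(v1.values())))
    assert v1 == v2


def test_intensity_scaling_monotonicity():
    """Scaling post-contrast intensities by k scales PE, WIS, |WOS| by k
    and leaves TTP and sub-cluster proportions unchanged."""
    cfg = rt.CohortConfig(n_lesions=2, noise_sd=0.0, seed=8)
    study, _ = rt.gen_lesion_study(cfg, 1)
    k = 1.7
    phases = study.phases.copy()
    base = phases[0]
    scaled = np.concatenate([
        base[None], base[None] + k * (phases[1:] - base[None])])
    study_k = rt.DceStudy(phases=scaled, spacing=study.spacing,
                          times=study.times, mask=study.mask)
    a, b = rt.aggregate_features(study), rt.aggregate_features(study_k)
    assert b["kin_mean_pe"] == pytest.approx(k * a["kin_mean_pe"], rel=1e-9)
    assert b["kin_mean_wis"] == pytest.approx(k * a["kin_mean_wis"], rel=1e-9)
    assert b["kin_mean_wos"] == pytest.approx(k * a["kin_mean_wos"], rel=1e-9)
    assert b["kin_mean_ttp"] == pytest.approx(a["kin_mean_ttp"], rel=1e-12)
    pa = rt.ttp_partition(study).proportions
    pb = rt.ttp_partition(study_k).proportions
    assert pa == pytest.approx(pb, abs=1e-12)


def test_background_relabeling_is_irrelevant():
    cfg = rt.CohortConfig(n_lesions=2, noise_sd=0.0, seed=12)
    study, _ = rt.gen_lesion_study(cfg, 0)
    v1 = rt.kinetic_feature_vector(study)
    phases = study.phases.copy()
    phases[:, ~study.mask] = 12345.0  # arbitrary background values
    study2 = rt.DceStudy(phases=phases, spacing=study.spacing,
                         times=study.times, mask=study.mask)
    v2 = rt.kinetic_feature_vector(study2)
    assert v1 == pytest.approx(list(v2.values()) if isinstance(v2, list) else v2)
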