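"""Synthetic paired imaging + expression cohorts with planted ground truth.

The generator emulates the structure of a two-institution breast DCE-MRI /
bulk-expression study: each lesion is an ellipsoidal tumor on a 3D grid
imaged at one pre-contrast and three post-contrast phases, each voxel
following one of three enhancement archetypes (quick / intermediate / slow
time-to-peak); each sample has a bulk expression matrix whose marker-gene
levels encode the true abundance of 10 immune/stromal cell populations.

Phantom enhancement curves are piecewise linear in acquisition time: a
linear rise from zero at the pre-contrast time to the archetype's peak
enhancement at its peak phase, then a linear washout.  This makes every
semi-quantitative kinetic parameter (PE, TTP, WIS, WOS) analytically known,
so downstream extractors can be tested against closed forms.

Ground-truth couplings:

* ``planted_assoc`` — a Gaussian copula ties the lesion's enhancement
  amplitude latent to a population's true abundance at a target Pearson r;
  the realized correlation is recorded in the returned ground truth.
* ``planted_effect`` — a (population, Cohen's d) pair that shifts the
  amplitude latent by d within-group SDs for samples whose abundance is
  above its median, making high/low classification separability exact.

Two institution profiles mimic differing acquisition protocols: "A"
(axial-like: finer in-plane grid, 2 mm slices, identity intensity mapping)
and "B" (sagittal-like: coarser grid, 2.2 mm slices, and a fixed affine
intensity shift), which induces a recoverable batch effect in the feature
space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import ALL_FEATURES, POPULATIONS
from .datatypes import DceStudy

#: geometry / intensity presets per institution
INSTITUTION_PROFILES = {
    "A": {"grid_shape": (10, 32, 32), "spacing": (2.0, 0.7, 0.7),
          "intensity_scale": 1.0, "intensity_offset": 0.0},
    "B": {"grid_shape": (10, 24, 24), "spacing": (2.2, 0.9, 0.9),
          "intensity_scale": 1.12, "intensity_offset": 18.0},
}

BASELINE_SIGNAL = 100.0


@dataclass
class ArchetypeParams:
    """One TTP archetype: peak relative enhancement, the post-contrast phase
    index (1..3) at which it peaks, and the post-peak washout rate
    (enhancement per minute, <= 0)."""
    peak_enh: float
    peak_phase: int
    washout_rate: float


DEFAULT_ARCHETYPES = {
    "quick": ArchetypeParams(peak_enh=1.2, peak_phase=1, washout_rate=-0.25),
    "intermediate": ArchetypeParams(peak_enh=1.0, peak_phase=2, washout_rate=-0.15),
    "slow": ArchetypeParams(peak_enh=0.9, peak_phase=3, washout_rate=0.0),
}


@dataclass
class PlantedAssociation:
    feature: str
    population: str
    r: float


@dataclass
class CohortConfig:
    n_lesions: int = 50
    institution_profile: str = "A"
    grid_shape: Optional[tuple] = None      # from profile if None
    voxel_spacing: Optional[tuple] = None   # from profile if None
    acquisition_times: tuple = (0.0, 1.0, 2.0, 3.0)
    ttp_fractions: tuple = (1 / 3, 1 / 3, 1 / 3)
    archetype_params: dict = field(default_factory=lambda: dict(DEFAULT_ARCHETYPES))
    noise_sd: float = 2.0                   # intensity units (baseline 100)
    expr_noise_sd: float = 0.25             # log2 units on marker genes
    n_genes: int = 2000
    markers_per_population: int = 5
    marker_slope: float = 1.0               # log2 expression per abundance unit
    amp_scale: float = 0.15                 # lesion amplitude latent scale
    planted_assoc: list = field(default_factory=list)   # PlantedAssociation
    planted_effect: Optional[tuple] = None  # (population, cohen_d)
    seed: int = 0

    def __post_init__(self):
        if self.institution_profile not in INSTITUTION_PROFILES:
            raise ValueError(f"unknown institution_profile: {self.institution_profile}")
        prof = INSTITUTION_PROFILES[self.institution_profile]
        if self.grid_shape is None:
            self.grid_shape = prof["grid_shape"]
        if self.voxel_spacing is None:
            self.voxel_spacing = prof["spacing"]
        if abs(sum(self.ttp_fractions) - 1.0) > 1e-12:
            raise ValueError("ttp_fractions must sum to 1")
        if len(self.ttp_fractions) != 3 or any(f < 0 for f in self.ttp_fractions):
            raise ValueError("ttp_fractions must be a non-negative triple")
        if self.n_lesions < 2:
            raise ValueError("n_lesions must be >= 2")
        t = np.asarray(self.acquisition_times, dtype=float)
        if len(t) != 4 or not np.all(np.diff(t) > 0):
            raise ValueError("acquisition_times must be 4 strictly increasing values")
        self.planted_assoc = [
            p if isinstance(p, PlantedAssociation) else PlantedAssociation(*p)
            for p in self.planted_assoc
        ]
        for p in self.planted_assoc:
            if p.feature not in ALL_FEATURES:
                raise ValueError(
                    f"planted feature {p.feature!r} is not in the 199-feature "
                    f"catalog; valid names include {ALL_FEATURES[:3]} ... "
                    f"{ALL_FEATURES[-3:]} ({len(ALL_FEATURES)} total)"
                )
            if p.population not in POPULATIONS:
                raise ValueError(
                    f"unknown population {p.population!r}; valid: {POPULATIONS}")
            if not -1.0 <= p.r <= 1.0:
                raise ValueError("planted correlation must be in [-1, 1]")
        if self.planted_effect is not None:
            pop, d = self.planted_effect
            if pop not in POPULATIONS:
                raise ValueError(f"unknown population {pop!r}; valid: {POPULATIONS}")


@dataclass
class GroundTruth:
    """Cohort-level ground truth: per-lesion archetype label maps (1 quick,
    2 intermediate, 3 slow, 0 background), true abundance per sample and
    population, the lesion amplitude latents, and the realized correlation
    of each planted association."""
    archetype_maps: list
    abundance: pd.DataFrame
    amplitudes: np.ndarray
    realized_correlations: dict = field(default_factory=dict)


def _lesion_rng(config: CohortConfig, lesion_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, 1, lesion_index])


def _ellipsoid_mask(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    shape = np.asarray(config.grid_shape)
    if np.any(shape < 5):
        raise ValueError(
            f"grid_shape {config.grid_shape} too small for an ellipsoid mask "
            "of >= 30 voxels")
    center = shape / 2.0 + rng.uniform(-0.05, 0.05, size=3) * shape
    lo = np.maximum(2.0, shape * 0.18)
    hi = np.maximum(lo + 0.5, shape * 0.38)
    semi = rng.uniform(lo, hi)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )
    mask = d2 <= 1.0
    if mask.sum() < 30:
        raise ValueError(
            f"grid_shape {config.grid_shape} yields a mask of {int(mask.sum())} "
            "voxels (< 30); enlarge grid_shape")
    return mask


def archetype_enhancement(arch: ArchetypeParams, times, amplitude: float = 1.0) -> np.ndarray:
    """Closed-form enhancement curve of one archetype at the 4 acquisition
    times: linear rise to amplitude * peak_enh at the peak phase, then
    linear washout."""
    t = np.asarray(times, dtype=float)
    peak = amplitude * arch.peak_enh
    t_peak = t[arch.peak_phase]
    e = np.empty(4)
    for k in range(4):
        if t[k] <= t_peak:
            e[k] = peak * (t[k] - t[0]) / (t_peak - t[0])
        else:
            e[k] = peak + arch.washout_rate * (t[k] - t_peak)
    return e


def gen_lesion_study(
    config: CohortConfig,
    lesion_index: int,
    amplitude: float = 1.0,
):
    """Generate one 4-phase lesion study plus its archetype label map.

    Deterministic in (config.seed, lesion_index); cohort-level couplings
    enter only through ``amplitude``.
    """
    rng = _lesion_rng(config, lesion_index)
    mask = _ellipsoid_mask(config, rng)
    n_vox = int(mask.sum())

    labels = np.zeros(config.grid_shape, dtype=np.int64)
    draw = rng.choice(3, size=n_vox, p=np.asarray(config.ttp_fractions))
    labels[mask] = draw + 1

    times = np.asarray(config.acquisition_times, dtype=float)
    curves = {
        k + 1: archetype_enhancement(config.archetype_params[name], times, amplitude)
        for k, name in enumerate(("quick", "intermediate", "slow"))
    }

    prof = INSTITUTION_PROFILES[config.institution_profile]
    phases = np.full((4,) + tuple(config.grid_shape), BASELINE_SIGNAL, dtype=float)
    for k, curve in curves.items():
        sel = labels == k
        for ph in range(4):
            phases[ph][sel] = BASELINE_SIGNAL * (1.0 + curve[ph])
    phases = prof["intensity_scale"] * phases + prof["intensity_offset"]
    if config.noise_sd > 0:
        phases = phases + rng.normal(0.0, config.noise_sd, size=phases.shape)

    study = DceStudy(
        phases=phases,
        spacing=tuple(config.voxel_spacing),
        times=tuple(times),
        mask=mask,
        lesion_id=f"S{lesion_index:03d}",
        institution=config.institution_profile,
    )
    return study, labels


def _cohort_latents(config: CohortConfig):
    """Amplitudes and true abundances, with planted couplings."""
    rng = np.random.default_rng([config.seed, 2])
    n = config.n_lesions
    abundance = pd.DataFrame(
        rng.normal(4.0, 1.0, size=(n, len(POPULATIONS))),
        index=[f"S{i:03d}" for i in range(n)],
        columns=POPULATIONS,
    )
    z_img = rng.normal(size=n)
    for pa in config.planted_assoc:
        eps = rng.normal(size=n)
        z_ab = pa.r * z_img + np.sqrt(max(0.0, 1.0 - pa.r ** 2)) * eps
        abundance[pa.population] = 4.0 + z_ab
    if config.planted_effect is not None:
        pop, d = config.planted_effect
        ab = rng.normal(4.0, 1.0, size=n)
        abundance[pop] = ab
        hi = ab >= np.median(ab)
        z_img = rng.normal(size=n) + d * hi
    amplitudes = np.clip(1.0 + config.amp_scale * z_img, 0.05, None)
    return amplitudes, abundance


def gen_expression(config: CohortConfig, abundance: pd.DataFrame) -> pd.DataFrame:
    """Bulk expression matrix (genes x samples) encoding true abundances.

    Marker genes of population k have log2(1 + count) = base +
    marker_slope * abundance_k + noise; background genes are
    abundance-independent.  Counts are strictly positive.
    """
    markers = default_marker_sets(config.markers_per_population)
    seen = {}
    for pop, genes in markers.items():
        for g in genes:
            if g in seen:
                warnings.warn(
                    f"marker gene {g} shared by {seen[g]} and {pop}", stacklevel=2)
            seen[g] = pop

    rng = np.random.default_rng([config.seed, 3])
    samples = list(abundance.index)
    n = len(samples)
    rows = []
    names = []
    for pop in POPULATIONS:
        ab = abundance[pop].to_numpy()
        for g in markers[pop]:
            loc = 5.0 + config.marker_slope * ab
            if config.expr_noise_sd > 0:
                loc = loc + rng.normal(0.0, config.expr_noise_sd, size=n)
            rows.append(loc)
            names.append(g)
    n_marker = len(names)
    n_bg = max(0, config.n_genes - n_marker)
    gene_base = rng.uniform(3.0, 8.0, size=n_bg)
    for i in range(n_bg):
        rows.append(gene_base[i] + rng.normal(0.0, 1.0, size=n))
        names.append(f"BG{i:04d}")
    loc = np.clip(np.asarray(rows), 0.01, None)
    counts = np.power(2.0, loc) - 1.0
    counts = np.maximum(counts, 1e-9)
    return pd.DataFrame(counts, index=names, columns=samples)


def default_marker_sets(markers_per_population: int = 5) -> dict:
    """Synthetic marker gene sets matching the generator's gene naming."""
    return {
        pop: [f"{pop}_MK{j + 1}" for j in range(markers_per_population)]
        for pop in POPULATIONS
    }


def make_planted_classification(
    n_samples: int = 60,
    n_informative: int = 5,
    n_noise: int = 95,
    effect_d: float = 2.0,
    seed: int = 0,
):
    """Feature-space classification problem with a planted group effect.

    Balanced binary labels; each informative feature is shifted by
    ``effect_d`` within-group SDs between the classes, noise features are
    standard normal.  This is the ground-truth problem for exercising
    feature selection and classifier evaluation directly, without the
    imaging round-trip.
    """
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], [n_samples - n_samples // 2, n_samples // 2])
    rng.shuffle(y)
    X = rng.normal(size=(n_samples, n_informative + n_noise))
    X[:, :n_informative] += effect_d * y[:, None]
    cols = [f"inf{i}" for i in range(n_informative)] + [
        f"noise{i}" for i in range(n_noise)]
    return pd.DataFrame(X, columns=cols,
                        index=[f"S{i:03d}" for i in range(n_samples)]), y


def gen_cohort(config: CohortConfig):
    """Generate the full paired cohort.

    Returns (studies, expression, truth): a list of DceStudy, the genes x
    samples expression DataFrame, and the GroundTruth record including the
    realized correlation of every planted association.
    """
    amplitudes, abundance = _cohort_latents(config)
    studies = []
    archetype_maps = []
    for i in range(config.n_lesions):
        study, labels = gen_lesion_study(config, i, amplitude=float(amplitudes[i]))
        studies.append(study)
        archetype_maps.append(labels)
    expr = gen_expression(config, abundance)
    realized = {}
    for pa in config.planted_assoc:
        r = float(np.corrcoef(amplitudes, abundance[pa.population])[0, 1])
        realized[(pa.feature, pa.population)] = r
    truth = GroundTruth(
        archetype_maps=archetype_maps,
        abundance=abundance,
        amplitudes=amplitudes,
        realized_correlations=realized,
    )
    return studies, expr, truth
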