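"""Core data containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import ALL_FEATURES, POPULATIONS


@dataclass
class DceStudy:
    """A 4-phase dynamic contrast-enhanced study of one lesion.

    ``phases`` holds one pre-contrast and three post-contrast volumes on a
    shared grid as a (4, Z, Y, X) array; ``times`` are the acquisition times
    in minutes (strictly increasing, ``times[0]`` is the pre-contrast time);
    ``mask`` is the binary tumor segmentation on the same grid.
    """

    phases: np.ndarray          # (4, Z, Y, X) float
    spacing: tuple              # (dz, dy, dx) in mm
    times: tuple                # minutes, length 4
    mask: np.ndarray            # (Z, Y, X) bool
    lesion_id: str = "lesion"
    institution: str = "A"

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.phases.ndim != 4 or self.phases.shape[0] != 4:
            raise ValueError("phases must be a (4, Z, Y, X) array")
        if self.phases.shape[1:] != self.mask.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match phase grid "
                f"{self.phases.shape[1:]}"
            )
        if len(self.times) != 4:
            raise ValueError("times must have length 4")
        t = np.asarray(self.times, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.mask.any():
            raise ValueError("mask has no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class TtpCharacteristicMap:
    """3-label partition of the tumor by time-to-peak.

    ``labels`` is an integer volume: 0 background, 1 quick, 2 intermediate,
    3 slow (peak at the first / second / third post-contrast phase).
    """

    labels: np.ndarray
    proportions: tuple  # (quick, intermediate, slow), sums to 1

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1")


@dataclass
class QuantizedRoi:
    """In-mask voxel values after 8-bit rescale and fixed-bin-width binning."""

    levels: np.ndarray          # integer level per in-mask voxel, 1..n_levels
    label_volume: np.ndarray    # level per voxel in the full grid, 0 outside
    mask: np.ndarray
    n_levels: int
    bin_width: float


@dataclass
class AbundanceTable:
    """Per-sample abundance scores for the 10 cell populations.

    ``labels`` / ``thresholds`` are filled by median stratification; a label
    is "high" iff the score is >= the population's median over the samples
    being labelled.
    """

    scores: pd.DataFrame                       # samples x populations
    labels: Optional[pd.DataFrame] = None      # "high"/"low"
    thresholds: Optional[pd.Series] = None

    def __post_init__(self):
        missing = [p for p in POPULATIONS if p not in self.scores.columns]
        if missing:
            raise ValueError(f"scores missing populations: {missing}")


@dataclass
class ModelEval:
    """Evaluation record for one population's high/low classifier."""

    population: str
    selected_features: list
    loocv_auc: float
    external_auc: Optional[float] = None
    roc_loocv: Optional[np.ndarray] = None      # (n, 2) FPR, TPR
    roc_external: Optional[np.ndarray] = None
    seed: Optional[int] = None
    hyperparams: dict = field(default_factory=dict)
    selection_mode: str = "selection_outside_loocv"


def validate_feature_table(features: pd.DataFrame, require_full: bool = False) -> None:
    """Check a lesions x features table against the frozen catalog."""
    unknown = [c for c in features.columns if c not in ALL_FEATURES]
    if unknown:
        raise ValueError(f"unknown feature columns: {unknown[:5]}")
    if require_full and len(features.columns) != len(ALL_FEATURES):
        raise ValueError(
            f"expected {len(ALL_FEATURES)} feature columns, got {len(features.columns)}"
        )
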