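"""End-to-end orchestration of the six analysis stages.

extract (static + kinetic) -> abundance scoring -> median stratification ->
univariate association scan -> per-population classification -> PCA batch
check.  Every stage writes its CSV/JSON artifact plus one log line with
row counts; the run records the seed and a config hash for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import load_marker_sets, score_abundance, stratify_median
from .association import correlation_matrix, stratified_feature_ttests, univariate_scan
from .catalog import ALL_FEATURES, POPULATIONS
from .prediction import (
    DEFAULT_CANDIDATE_SIZES,
    DEFAULT_HYPERPARAMS,
    evaluate_cohort,
    pca_batch_check,
)
from .static_features import full_feature_vector

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    # quantization
    bits: int = 8
    bin_width: float = 25.0
    kinetic_levels: int = 11
    # statistics
    adjust_within_population: bool = False
    # classification
    candidate_sizes: tuple = DEFAULT_CANDIDATE_SIZES
    hyperparams: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_HYPERPARAMS))
    nested_selection: bool = False
    rfe_cv_folds: int = 5
    rfe_cv_repeats: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def extract_features(studies, bits=8, bin_width=25.0, kinetic_levels=11) -> pd.DataFrame:
    """Lesions x 199 feature table in catalog order."""
    rows = {}
    for study in studies:
        rows[study.lesion_id] = full_feature_vector(study, levels=kinetic_levels)
    table = pd.DataFrame.from_dict(rows, orient="index")[list(ALL_FEATURES)]
    logger.info("extracted %d x %d feature table", *table.shape)
    return table


def run_full(
    config: PipelineConfig,
    studies_train,
    expr_train: pd.DataFrame,
    studies_test=None,
    expr_test: pd.DataFrame | None = None,
    markers: dict | None = None,
) -> dict:
    """Run the full analysis and write the report bundle to config.out_dir.

    Returns the in-memory bundle: feature tables, abundance tables, the
    association scan, per-population evaluations, and (when a test cohort
    is given) the PCA batch diagnostic.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if markers is None:
        markers = load_marker_sets()

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    features = _stage("extract", lambda: extract_features(
        studies_train, config.bits, config.bin_width, config.kinetic_levels))
    features.to_csv(out / "features_train.csv", index_label="lesion_id")

    scored = _stage("score", lambda: score_abundance(expr_train, markers))
    stratified = _stage("stratify", lambda: stratify_median(scored))
    stratified.scores.to_csv(out / "abundance_train.csv", index_label="sample")
    stratified.labels.to_csv(out / "labels_train.csv", index_label="sample")

    scan = _stage("associate", lambda: univariate_scan(
        features, stratified, config.adjust_within_population))
    scan.to_csv(out / "associations.csv", index=False)
    corr = correlation_matrix(features, stratified, scan)
    corr.to_csv(out / "correlation_matrix.csv", index_label="feature")
    ttests = stratified_feature_ttests(features, stratified)
    ttests.to_csv(out / "two_feature_ttests.csv", index=False)
    logger.info("association scan: %d rows (%d features x %d populations)",
                len(scan), features.shape[1], len(POPULATIONS))

    features_test = None
    stratified_test = None
    batch = None
    if studies_test is not None and expr_test is not None:
        features_test = _stage("extract-test", lambda: extract_features(
            studies_test, config.bits, config.bin_width, config.kinetic_levels))
        features_test.to_csv(out / "features_test.csv", index_label="lesion_id")
        stratified_test = stratify_median(score_abundance(expr_test, markers))
        coords, sil = pca_batch_check(features, features_test)
        batch = {"silhouette": sil}
        np.savetxt(out / "pca_coords.csv", coords, delimiter=",",
                   header="pc1,pc2", comments="")
        logger.info("PCA batch check: silhouette=%.3f", sil)

    evals = _stage("classify", lambda: evaluate_cohort(
        features, stratified, features_test, stratified_test,
        config.candidate_sizes, config.hyperparams, config.seed,
        config.nested_selection, config.rfe_cv_folds, config.rfe_cv_repeats))
    eval_records = []
    for ev in evals:
        rec = {
            "population": ev.population,
            "selected_features": ev.selected_features,
            "n_selected": len(ev.selected_features),
            "loocv_auc": ev.loocv_auc,
            "external_auc": ev.external_auc,
            "seed": ev.seed,
            "hyperparams": ev.hyperparams,
            "selection_mode": ev.selection_mode,
        }
        eval_records.append(rec)
        if ev.roc_loocv is not None:
            np.savetxt(out / f"roc_loocv_{ev.population}.csv", ev.roc_loocv,
                       delimiter=",", header="fpr,tpr", comments="")
    with open(out / "evaluations.json", "w") as fh:
        json.dump(eval_records, fh, indent=2)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "n_train": len(features),
        "n_test": None if features_test is None else len(features_test),
        "n_features": features.shape[1],
        "n_association_rows": len(scan),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "features_train": features,
        "features_test": features_test,
        "abundance_train": stratified,
        "abundance_test": stratified_test,
        "associations": scan,
        "correlation_matrix": corr,
        "ttests": ttests,
        "evaluations": evals,
        "batch": batch,
        "manifest": manifest,
    }
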