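"""Univariate feature-abundance association scan with FDR control.

For every (radiomic feature, cell population) pair we fit a simple linear
regression of abundance on the feature and test the slope (two-sided t);
the p-value is algebraically identical to the Pearson-correlation test for
the pair.  P-values are corrected with the Benjamini-Hochberg step-up
procedure, by default jointly over all pairs (199 x 10 = 1990 tests on the
full catalog), optionally within each population.

Also provided: the features x populations Pearson correlation matrix for
heatmap-style summaries, and the Welch two-sided t-tests comparing a
feature between high- and low-infiltration groups.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import FEATURE_FAMILY, POPULATIONS
from .datatypes import AbundanceTable

logger = logging.getLogger(__name__)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def univariate_scan(
    features: pd.DataFrame,
    abundance: AbundanceTable | pd.DataFrame,
    adjust_within_population: bool = False,
) -> pd.DataFrame:
    """Per-pair linear regression scan.

    Returns a long-format frame (feature, population, slope, r, p, p_adj,
    degenerate): one row per pair, zero-variance features annotated as
    degenerate (NaN statistics) rather than silently dropped.
    """
    scores = abundance.scores if isinstance(abundance, AbundanceTable) else abundance
    common = features.index.intersection(scores.index)
    if len(common) < 4:
        raise ValueError(f"need >= 4 common samples, got {len(common)}")
    X = features.loc[common]
    Y = scores.loc[common]

    rows = []
    for feat in X.columns:
        x = X[feat].to_numpy(dtype=float)
        degenerate = bool(np.std(x) == 0)
        if degenerate:
            logger.warning("feature %s has zero variance; annotated as degenerate", feat)
        for pop in Y.columns:
            if degenerate:
                rows.append((feat, pop, np.nan, np.nan, np.nan, True))
                continue
            res = stats.linregress(x, Y[pop].to_numpy(dtype=float))
            rows.append((feat, pop, res.slope, res.rvalue, res.pvalue, False))
    out = pd.DataFrame(
        rows, columns=["feature", "population", "slope", "r", "p", "degenerate"])

    out["p_adj"] = np.nan
    if adjust_within_population:
        for pop in Y.columns:
            sel = (out["population"] == pop) & ~out["degenerate"]
            out.loc[sel, "p_adj"] = bh_adjust(out.loc[sel, "p"])
    else:
        sel = ~out["degenerate"]
        out.loc[sel, "p_adj"] = bh_adjust(out.loc[sel, "p"])
    return out[["feature", "population", "slope", "r", "p", "p_adj", "degenerate"]]


def correlation_matrix(
    features: pd.DataFrame,
    abundance: AbundanceTable | pd.DataFrame,
    scan: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Features x populations Pearson-r matrix, rows ordered by feature
    family (size, morphology, kinetic, texture) for heatmap output."""
    if scan is None:
        scan = univariate_scan(features, abundance)
    mat = scan.pivot(index="feature", columns="population", values="r")
    order = sorted(
        mat.index,
        key=lambda f: (
            ["size", "morphology", "kinetic", "texture"].index(
                FEATURE_FAMILY.get(f, "texture")),
            list(features.columns).index(f),
        ),
    )
    cols = [p for p in POPULATIONS if p in mat.columns]
    return mat.loc[order, cols]


def group_ttest(values, labels) -> tuple:
    """Welch two-sided t-test of a feature between "high" and "low" groups.

    Returns (t, p).  Both groups must have >= 2 members.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = set(labels.tolist())
    if classes - {"high", "low"}:
        raise ValueError(f"labels must be 'high'/'low', got {sorted(classes)}")
    hi = values[labels == "high"]
    lo = values[labels == "low"]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("both groups need >= 2 members")
    if np.std(hi) == 0 and np.std(lo) == 0 and hi.mean() == lo.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(hi, lo, equal_var=False)
    return float(t), float(p)


def stratified_feature_ttests(
    features: pd.DataFrame,
    stratified: AbundanceTable,
    feature_names=("shape_voxel_volume", "kin_mean_pe"),
) -> pd.DataFrame:
    """For each chosen feature, test high vs low across the 10 populations
    and BH-adjust the 10 p-values within the feature.

    The default pair mirrors the contrast between a visually assessable
    phenotype (tumor volume) and an abstract kinetic one (mean peak
    enhancement).
    """
    if stratified.labels is None:
        raise ValueError("abundance table is not stratified; call stratify_median first")
    common = features.index.intersection(stratified.labels.index)
    rows = []
    for feat in feature_names:
        pvals = []
        for pop in POPULATIONS:
            t, p = group_ttest(
                features.loc[common, feat], stratified.labels.loc[common, pop])
            rows.append({"feature": feat, "population": pop, "t": t, "p": p})
            pvals.append(p)
        adj = bh_adjust(pvals)
        for k, pop in enumerate(POPULATIONS):
            rows[-10 + k]["p_adj"] = adj[k]
    return pd.DataFrame(rows)
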