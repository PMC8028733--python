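"""Marker-based abundance scoring for 10 immune/stromal cell populations.

Scoring follows the MCP-counter idea: a population's abundance score in a
sample is the mean log-scale expression of its marker genes, here
log2(1 + count) averaged over the markers present in the matrix.  Scores
are comparable across samples within a population (not across populations).

Samples are stratified into "high"/"low" infiltration per population by
the median score over the dataset being labelled; a score equal to the
median is "high".
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd

from .catalog import POPULATIONS
from .datatypes import AbundanceTable

logger = logging.getLogger(__name__)


def load_marker_sets(path=None) -> dict:
    """Read a two-column (population, gene) TSV into marker sets.

    Without a path, loads the shipped synthetic marker fixture (the
    published marker lists are proprietary to their source; the fixture
    matches the synthetic generator's gene naming and is user-replaceable).
    """
    if path is None:
        src = resources.files("radiotme.data") / "synthetic_markers.tsv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["population", "gene"]:
        raise ValueError("marker table must have columns: population, gene")
    markers = {pop: grp["gene"].tolist() for pop, grp in df.groupby("population")}
    missing = [p for p in POPULATIONS if p not in markers]
    if missing:
        raise ValueError(f"marker table missing populations: {missing}")
    empty = [p for p, g in markers.items() if not g]
    if empty:
        raise ValueError(f"empty marker lists for: {empty}")
    return {p: markers[p] for p in POPULATIONS}


def score_abundance(expr: pd.DataFrame, markers: dict | None = None) -> AbundanceTable:
    """Score the 10 populations on a genes x samples expression matrix.

    score(sample, population) = mean over the population's markers found in
    the matrix of log2(1 + count).  Markers absent from the matrix are
    dropped with a warning; a population with no matching marker is an
    error.
    """
    if markers is None:
        markers = load_marker_sets()
    if (np.asarray(expr, dtype=float) < 0).any():
        raise ValueError("expression matrix must be non-negative")
    if expr.index.duplicated().any() or expr.columns.duplicated().any():
        raise ValueError("gene and sample IDs must be unique")
    log_expr = np.log2(1.0 + expr)
    scores = {}
    for pop in POPULATIONS:
        genes = markers[pop]
        present = [g for g in genes if g in expr.index]
        dropped = set(genes) - set(present)
        if dropped:
            logger.warning("population %s: markers not in matrix, dropped: %s",
                           pop, sorted(dropped))
        if not present:
            raise ValueError(f"no marker genes of population {pop!r} found in matrix")
        scores[pop] = log_expr.loc[present].mean(axis=0)
    table = pd.DataFrame(scores, columns=POPULATIONS)
    table.index = expr.columns
    return AbundanceTable(scores=table)


def stratify_median(table: AbundanceTable) -> AbundanceTable:
    """Median high/low stratification per population.

    The threshold is each population's median score over the samples being
    labelled (an external cohort therefore gets its own medians); label is
    "high" iff score >= threshold.
    """
    scores = table.scores
    if len(scores) < 2:
        raise ValueError("stratification needs >= 2 samples")
    thresholds = scores.median(axis=0)
    labels = pd.DataFrame(
        np.where(scores.to_numpy() >= thresholds.to_numpy()[None, :], "high", "low"),
        index=scores.index,
        columns=scores.columns,
    )
    for pop in POPULATIONS:
        if (labels[pop] == "high").all():
            logger.warning(
                "population %s: all scores equal the median -> all 'high'", pop)
    return AbundanceTable(scores=scores, labels=labels, thresholds=thresholds)


def abundance_to_frame(table: AbundanceTable) -> pd.DataFrame:
    """Long-format (sample, population, score, label, threshold) frame."""
    rows = []
    for pop in POPULATIONS:
        for sample in table.scores.index:
            rows.append({
                "sample": sample,
                "population": pop,
                "score": table.scores.loc[sample, pop],
                "label": table.labels.loc[sample, pop] if table.labels is not None else "",
                "threshold": table.thresholds[pop] if table.thresholds is not None else np.nan,
            })
    return pd.DataFrame(rows)
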