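"""Repertoire-level diversity metrics and cohort-level comparisons.

Clonality is defined as ``1 - J`` with Pielou's evenness
``J = H' / log2(S)``: ``H'`` the Shannon index in bits and ``S`` the
clonotype richness. A clonality of 1 means the sample holds a single
clonotype; 0 means a perfectly even repertoire. For ``S = 1`` evenness is
undefined (``log2 1 = 0``); by convention the single-clone sample gets
``J = 0`` and clonality 1. No read-depth normalization or rarefaction is
applied; richness, clonality and Shannon diversity are essentially
uncorrelated with total read count, which
:func:`metric_readcount_correlation` lets callers verify on their cohort.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .repertoire_io import Repertoire

#: Number of most-frequent clonotypes over which the top-n SHM rate runs.
TOP_N_SHM = 10

#: Significance level of the pairwise Mann-Whitney comparisons.
ALPHA = 0.05


@dataclass
class RepertoireMetrics:
    """Scalar metrics of one repertoire."""

    sample_id: str
    label: str
    richness: int
    shannon: float
    evenness: float
    clonality: float
    shm_fraction: float
    topn_shm_fraction: float
    total_reads: int


def _check_fractions(fractions: np.ndarray) -> np.ndarray:
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size == 0:
        raise ValidationError("fraction vector must be non-empty")
    if np.any(fractions < 0):
        raise ValidationError("fractions must be non-negative")
    if abs(fractions.sum() - 1.0) > 1e-6:
        raise ValidationError(
            f"fractions must sum to 1 (got {fractions.sum():.8f})"
        )
    return fractions


def shannon_index(fractions) -> float:
    """Shannon diversity H' in bits, with the 0*log(0) := 0 convention."""
    p = _check_fractions(fractions)
    p = p[p > 0]
    return float(stats.entropy(p, base=2))


def evenness(fractions) -> float:
    """Pielou's evenness J = H'/log2(S); 0 by convention for S = 1."""
    p = _check_fractions(fractions)
    s = p.size
    if s == 1:
        return 0.0
    return float(np.clip(shannon_index(p) / np.log2(s), 0.0, 1.0))


def clonality(fractions) -> float:
    """Clonality = 1 - Pielou's evenness; 1 for a single-clone sample."""
    return 1.0 - evenness(fractions)


def compute_metrics(repertoire: Repertoire) -> RepertoireMetrics:
    """All scalar metrics of one repertoire.

    SHM fractions count clonotypes, not reads: ``shm_fraction`` is the
    share of clonotypes flagged hypermutated, ``topn_shm_fraction`` the
    same over the ``min(10, S)`` most frequent clonotypes.
    """
    p = repertoire.fractions
    hyper = repertoire.clonotypes["is_hypermutated"].to_numpy()
    s = repertoire.richness
    j = evenness(p)
    top = min(TOP_N_SHM, s)
    return RepertoireMetrics(
        sample_id=repertoire.sample_id,
        label=repertoire.label,
        richness=s,
        shannon=shannon_index(p),
        evenness=j,
        clonality=1.0 - j,
        shm_fraction=float(hyper.mean()),
        topn_shm_fraction=float(hyper[:top].mean()),
        total_reads=repertoire.total_reads,
    )


def metrics_table(repertoires: list[Repertoire]) -> pd.DataFrame:
    """One metrics row per repertoire, in input order."""
    return pd.DataFrame([vars(compute_metrics(r)) for r in repertoires])


def compare_metric_between_groups(
    values_by_class: dict[str, "np.ndarray | list[float]"],
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests between class value vectors.

    Exact p-values for small samples without ties, tie-corrected normal
    approximation otherwise (scipy's automatic policy). Significance is
    flagged at alpha = 0.05 with no multiple-testing correction.
    """
    if len(values_by_class) < 2:
        raise ValidationError("need at least two classes to compare")
    for name, vals in values_by_class.items():
        if len(np.atleast_1d(vals)) == 0:
            raise ValidationError(f"class {name!r} has no values")
    rows = []
    for a, b in itertools.combinations(values_by_class, 2):
        res = stats.mannwhitneyu(
            values_by_class[a], values_by_class[b],
            alternative="two-sided", method="auto",
        )
        rows.append({
            "class_a": a,
            "class_b": b,
            "u_statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "significant": bool(res.pvalue < ALPHA),
        })
    return pd.DataFrame(rows)


def metric_readcount_correlation(
    metrics: pd.DataFrame,
    metric_columns: tuple[str, ...] = ("richness", "clonality", "shannon"),
) -> pd.DataFrame:
    """Pearson correlation of each metric with total read count.

    A constant metric (or constant read counts) yields an undefined
    correlation, reported as NaN with ``defined = False`` rather than an
    exception.
    """
    if len(metrics) < 3:
        raise ValidationError(
            f"need at least 3 samples for a correlation, got {len(metrics)}"
        )
    reads = metrics["total_reads"].to_numpy(dtype=float)
    rows = []
    for col in metric_columns:
        vals = metrics[col].to_numpy(dtype=float)
        if np.ptp(vals) == 0 or np.ptp(reads) == 0:
            rows.append({"metric": col, "r": np.nan, "p_value": np.nan,
                         "defined": False})
            continue
        r, p = stats.pearsonr(vals, reads)
        rows.append({"metric": col, "r": float(r), "p_value": float(p),
                     "defined": True})
    return pd.DataFrame(rows)
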