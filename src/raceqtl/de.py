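"""Race-stratified pairwise differential expression.

Counts are library-size normalized to a fixed target library and log2
transformed with a pseudocount of one; each pairwise comparison is a
two-sided Welch unequal-variance t-test per gene with Benjamini-Hochberg
adjustment within the comparison.  log2 fold change is the difference of
group means of the normalized values (group minus reference), so a 1.5-fold
criterion corresponds to |log2FC| >= log2(1.5) ~ 0.585 and a 2.0-fold
criterion to |log2FC| >= 1.

This is a deliberately self-contained, seedable test: no empirical-Bayes
variance moderation or NB dispersion modelling.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from raceqtl.errors import ConfigError
from raceqtl.sim import CountMatrix

DEFAULT_TARGET_LIBRARY = 40_000_000
DEFAULT_LFC_THRESHOLD = 0.585  # 1.5-fold on the log2 scale, as conventionally rounded
DEFAULT_ALPHA = 0.05

#: The three pairwise race comparisons, (group, reference).  CA is the
#: reference for AS vs CA and AA vs CA; AA is the reference for AS vs AA.
STANDARD_COMPARISONS = (("AS", "CA"), ("AS", "AA"), ("AA", "CA"))


def fold_change_to_log2(fold: float) -> float:
    """log2-scale cutoff equivalent to a fold-change criterion (e.g. 1.5 -> ~0.585)."""
    if fold <= 0:
        raise ConfigError("fold change must be > 0")
    return math.log2(fold)


def normalize_log2(
    counts: CountMatrix | pd.DataFrame, target_library: int = DEFAULT_TARGET_LIBRARY
) -> pd.DataFrame:
    """log2(count * target_library / column_sum + 1) per cell.

    Zero counts map to exactly 0, and samples with proportional count
    columns map to identical normalized columns (scale invariance).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    colsum = mat.sum(axis=0)
    if (colsum <= 0).any():
        bad = list(colsum.index[colsum <= 0])
        raise ConfigError(f"all-zero sample columns cannot be normalized: {bad}")
    scaled = mat * (target_library / colsum)
    return np.log2(scaled + 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ConfigError("empty p-value list")
    if ((p <= 0) | (p > 1)).any():
        raise ConfigError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    norm_matrix: pd.DataFrame,
    samples_a,
    samples_b,
    comparison: tuple[str, str] = ("A", "B"),
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-gene Welch t-test of group A against reference group B.

    Returns a frame with gene_id index and columns log2fc (mean A minus
    mean B), p, padj (BH within this comparison), and direction in
    {up, down, nde} under the fold-change and adjusted-p thresholds.
    Genes with zero variance in both groups get p = 1.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ConfigError("both groups need at least 2 samples")
    if set(samples_a) & set(samples_b):
        raise ConfigError("groups must be disjoint")
    a = norm_matrix[samples_a].to_numpy()
    b = norm_matrix[samples_b].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # both groups constant -> no evidence
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    padj = bh_adjust(p)
    direction = np.where(
        (padj <= alpha) & (log2fc >= lfc_threshold),
        "up",
        np.where((padj <= alpha) & (log2fc <= -lfc_threshold), "down", "nde"),
    )
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "direction": direction,
            "comparison": f"{comparison[0]}_vs_{comparison[1]}",
        },
        index=norm_matrix.index.rename("gene_id"),
    )


def filter_degs(
    results: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> set[tuple[str, str]]:
    """Retain (gene, direction) pairs meeting both thresholds."""
    if lfc_threshold <= 0 or alpha <= 0:
        raise ConfigError("thresholds must be > 0")
    keep = (results["padj"] <= alpha) & (results["log2fc"].abs() >= lfc_threshold)
    sub = results[keep]
    return {
        (g, "up" if fc > 0 else "down")
        for g, fc in zip(sub.index, sub["log2fc"])
    }


def intersect_comparisons(deg_sets: dict[str, set]) -> dict:
    """Venn region counts and the triple-intersection gene list for 3 sets."""
    if len(deg_sets) != 3:
        raise ConfigError("expected exactly three named DEG sets")
    names = list(deg_sets)
    sets = [set(deg_sets[n]) for n in names]
    regions = {}
    for mask in itertools.product([False, True], repeat=3):
        if not any(mask):
            continue
        region = set.intersection(*(s for s, m in zip(sets, mask) if m))
        for s, m in zip(sets, mask):
            if not m:
                region = region - s
        key = "&".join(n for n, m in zip(names, mask) if m)
        regions[key] = len(region)
    triple = set.intersection(*sets)
    return {"regions": regions, "intersection": sorted(triple)}


def run_standard_comparisons(
    norm_matrix: pd.DataFrame,
    sample_race: pd.Series,
    comparisons=STANDARD_COMPARISONS,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> dict[tuple[str, str], pd.DataFrame]:
    """The three pairwise race comparisons on one normalized matrix."""
    out = {}
    for group, ref in comparisons:
        ga = list(sample_race.index[sample_race == group])
        gb = list(sample_race.index[sample_race == ref])
        out[(group, ref)] = de_test(
            norm_matrix, ga, gb, comparison=(group, ref),
            lfc_threshold=lfc_threshold, alpha=alpha,
        )
    return out
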