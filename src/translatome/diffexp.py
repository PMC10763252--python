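"""Negative-binomial Wald differential expression for tRNA count tables.

Median-of-ratios size factors, method-of-moments dispersion, a log-link NB
regression on condition with size-factor offsets, Wald z tests and
Benjamini-Hochberg correction. Tests run at any level of the tRNA hierarchy
(isodecoder, anticodon or amino acid) after aggregation.

Dispersion is estimated by the method of moments on normalised counts
(alpha = (s^2 - m) / m^2, variances pooled within conditions, floored at
1e-8) and then averaged across features into a single common dispersion, in
the spirit of classic common-dispersion NB testing. No empirical-Bayes
shrinkage toward a mean-dispersion trend is performed; this is the main
numerical divergence from current DE tools and is documented in the methods
note.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._nbglm import fit_nb_glm, pooled_dispersion
from .io import CountMatrix
from .reference import aggregate_counts

__all__ = [
    "size_factors_median_of_ratios",
    "nb_wald_test",
    "bh_adjust",
    "run_pairwise_de",
]

LN2 = np.log(2.0)


def size_factors_median_of_ratios(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each feature with positive counts in every sample, the geometric mean
    across samples is the pseudo-reference; a sample's factor is the median of
    its count/reference ratios over those features.
    """
    data = counts.data if isinstance(counts, CountMatrix) else counts
    if data.shape[1] == 1:
        return pd.Series([1.0], index=data.columns, name="size_factor")
    arr = data.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; cannot compute "
            "median-of-ratios size factors")
    arr = arr[positive]
    log_geomean = np.log(arr).mean(axis=1)
    ratios = np.log(arr) - log_geomean[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=data.columns, name="size_factor")


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs are passed through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def nb_wald_test(
    counts: pd.DataFrame | CountMatrix,
    condition_labels: Sequence[str],
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature NB Wald test between exactly two conditions.

    Returns a DataFrame with baseMean (mean of normalised counts), log2fc
    (condition 2 vs condition 1), wald_stat, pvalue and padj. Features that
    are all-zero, or whose fit does not converge, carry NaN statistics.
    Features where one condition is all-zero get a log2fc from 0.5-pseudocount
    normalised means.
    """
    data = counts.data if isinstance(counts, CountMatrix) else counts
    labels = np.asarray(condition_labels)
    if len(labels) != data.shape[1]:
        raise ValueError("one condition label per sample column is required")
    conds = pd.unique(labels)
    if len(conds) != 2:
        raise ValueError(f"exactly 2 conditions required, got {list(conds)}")
    for c in conds:
        if (labels == c).sum() < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 replicates")
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(data)
    sf = size_factors.reindex(data.columns).to_numpy(dtype=float)
    offset = np.log(sf)
    x = (labels == conds[1]).astype(float)
    X = np.column_stack([np.ones_like(x), x])

    # common dispersion pooled across features: precise enough to justify the
    # normal reference of the Wald test even at 3 replicates per condition
    norm_all = data.to_numpy(dtype=float) / sf
    alpha = pooled_dispersion(norm_all, labels)

    rows = []
    for feature, y in data.iterrows():
        y = y.to_numpy(dtype=float)
        norm = y / sf
        base_mean = norm.mean()
        row = {"feature": feature, "baseMean": base_mean,
               "log2fc": np.nan, "wald_stat": np.nan,
               "pvalue": np.nan, "converged": False}
        if (y == 0).all():
            rows.append(row)
            continue
        m1 = norm[x == 0].mean()
        m2 = norm[x == 1].mean()
        fit = fit_nb_glm(y, X, alpha=alpha, offset=offset)
        if m1 == 0 or m2 == 0:
            # one condition all zero: report a pseudocounted effect size
            row["log2fc"] = float(np.log2((m2 + 0.5) / (m1 + 0.5)))
        else:
            row["log2fc"] = float(fit.coef[1] / LN2)
        if fit.converged:
            z, p = fit.wald(1)
            row.update(wald_stat=z, pvalue=p, converged=True)
        rows.append(row)

    out = pd.DataFrame(rows).set_index("feature")
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def run_pairwise_de(
    counts: CountMatrix,
    condition_labels: Sequence[str],
    level: str = "isodecoder",
    q: float = 0.05,
) -> pd.DataFrame:
    """Aggregate to a hierarchy level, normalise, test and adjust.

    Adds a ``significant`` flag at BH-adjusted p <= q.
    """
    if level not in ("isodecoder", "anticodon", "amino_acid"):
        raise ValueError(f"unknown level {level!r}")
    agg = aggregate_counts(counts, level)
    result = nb_wald_test(agg, condition_labels)
    result["significant"] = result["padj"] <= q
    return result
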