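"""Translational-efficiency analysis and regulatory-class assignment.

Matched RNA-seq and Ribo-seq count tables are modelled per gene with a
log-link negative-binomial regression on the 2x2 design assay x condition,
with per-assay median-of-ratios size factors as offsets. The condition
coefficient in the RNA assay is the transcriptional change (dRNA); the
assay:condition interaction is the change in translational efficiency (dTE);
the RPF-only condition contrast gives dRPF. Genes are then classified:

    padj_rna <= q, padj_te >  q  ->  RNA        (transcriptional only)
    padj_rna >  q, padj_te <= q  ->  Ribo       (translational only)
    both <= q                    ->  Ribo&RNA
    otherwise                    ->  none

TE itself is the per-sample ratio of RPKM-normalised RPF to RPKM-normalised
RNA counts.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._nbglm import fit_nb_glm, pooled_dispersion
from .diffexp import LN2, bh_adjust, size_factors_median_of_ratios
from .io import CountMatrix

__all__ = [
    "rpkm",
    "translational_efficiency",
    "delta_te_fit",
    "classify_regulation",
    "class_proportions",
    "te_vs_deltate_check",
]

CLASSES = ("RNA", "Ribo", "Ribo&RNA", "none")


def rpkm(counts: pd.DataFrame | CountMatrix,
         gene_lengths: Mapping[str, float] | pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    value = count * 1e9 / (length_nt * library_total), per sample column.
    """
    data = counts.data if isinstance(counts, CountMatrix) else counts
    lengths = pd.Series(gene_lengths).reindex(data.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene lengths for: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = data.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("sample with zero library total")
    return data.mul(1e9, axis=0).div(lengths, axis=0).div(totals, axis=1)


def translational_efficiency(rpf_rpkm: pd.DataFrame,
                             rna_rpkm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-sample TE = RPF RPKM / RNA RPKM (NaN where RNA is 0)."""
    if not rpf_rpkm.columns.equals(rna_rpkm.columns):
        raise ValueError("RPF and RNA matrices must share matched sample columns")
    rna = rna_rpkm.reindex(rpf_rpkm.index)
    te = rpf_rpkm / rna.where(rna > 0)
    return te


def delta_te_fit(
    rna_counts: pd.DataFrame | CountMatrix,
    rpf_counts: pd.DataFrame | CountMatrix,
    condition_labels: Sequence[str],
) -> pd.DataFrame:
    """Interaction-model effect table for matched RNA/RPF counts.

    ``condition_labels`` gives the condition of each sample column (shared by
    both assays). Per gene a single NB GLM is fitted on the stacked 12-or-so
    observations with design [intercept, assay(rpf), condition, assay:cond]
    and log size-factor offsets computed per assay; a common method-of-
    moments dispersion is pooled within the four design cells and averaged
    across genes. Returns log2
    effects and BH-adjusted Wald p-values per coefficient, plus the RPF-only
    condition contrast (dRPF). Genes whose fits do not converge carry NaN
    p-values rather than raising.
    """
    rna = rna_counts.data if isinstance(rna_counts, CountMatrix) else rna_counts
    rpf = rpf_counts.data if isinstance(rpf_counts, CountMatrix) else rpf_counts
    if not rna.index.equals(rpf.index):
        raise ValueError("RNA and RPF tables must share the same genes")
    if rna.shape[1] != len(condition_labels) or rpf.shape[1] != len(condition_labels):
        raise ValueError("one condition label per sample column is required")
    labels = np.asarray(condition_labels)
    conds = pd.unique(labels)
    if len(conds) != 2:
        raise ValueError(f"exactly 2 conditions required, got {list(conds)}")
    for c in conds:
        if (labels == c).sum() < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 replicates")

    sf_rna = size_factors_median_of_ratios(rna).to_numpy(dtype=float)
    sf_rpf = size_factors_median_of_ratios(rpf).to_numpy(dtype=float)
    offset = np.log(np.concatenate([sf_rna, sf_rpf]))
    cond = np.tile((labels == conds[1]).astype(float), 2)
    assay = np.repeat([0.0, 1.0], len(labels))
    X = np.column_stack([np.ones_like(cond), assay, cond, assay * cond])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular interaction design")
    cells = np.char.add(assay.astype(int).astype(str), cond.astype(int).astype(str))
    # RPF-only sub-design for the dRPF contrast
    X_rpf = np.column_stack([np.ones(len(labels)),
                             (labels == conds[1]).astype(float)])
    off_rpf = np.log(sf_rpf)

    # common dispersions pooled across genes (within design cells), so the
    # normal-reference Wald tests stay calibrated at 3 replicates per cell
    stacked = np.hstack([rna.to_numpy(dtype=float) / sf_rna,
                         rpf.to_numpy(dtype=float) / sf_rpf])
    alpha = pooled_dispersion(stacked, cells)
    alpha_rpf = pooled_dispersion(rpf.to_numpy(dtype=float) / sf_rpf, labels)

    rows = []
    for gene in rna.index:
        y = np.concatenate([rna.loc[gene].to_numpy(dtype=float),
                            rpf.loc[gene].to_numpy(dtype=float)])
        row = {"gene": gene, "lfc_rna": np.nan, "pvalue_rna": np.nan,
               "lfc_rpf": np.nan, "pvalue_rpf": np.nan,
               "lfc_te": np.nan, "pvalue_te": np.nan, "converged": False}
        if (y == 0).all():
            rows.append(row)
            continue
        fit = fit_nb_glm(y, X, alpha=alpha, offset=offset)
        if fit.converged:
            row["lfc_rna"] = float(fit.coef[2] / LN2)
            row["lfc_te"] = float(fit.coef[3] / LN2)
            row["pvalue_rna"] = fit.wald(2)[1]
            row["pvalue_te"] = fit.wald(3)[1]
            row["converged"] = True
        y_rpf = rpf.loc[gene].to_numpy(dtype=float)
        if not (y_rpf == 0).all():
            fit_rpf = fit_nb_glm(y_rpf, X_rpf, alpha=alpha_rpf, offset=off_rpf)
            if fit_rpf.converged:
                row["lfc_rpf"] = float(fit_rpf.coef[1] / LN2)
                row["pvalue_rpf"] = fit_rpf.wald(1)[1]
        rows.append(row)

    out = pd.DataFrame(rows).set_index("gene")
    for coef in ("rna", "rpf", "te"):
        out[f"padj_{coef}"] = bh_adjust(out[f"pvalue_{coef}"].to_numpy())
    return out


def classify_regulation(effects: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Assign each gene a regulatory class from (padj_rna, padj_te) at FDR q."""
    rna_sig = effects["padj_rna"] <= q
    te_sig = effects["padj_te"] <= q
    label = np.select(
        [rna_sig & te_sig, te_sig, rna_sig],
        ["Ribo&RNA", "Ribo", "RNA"],
        default="none",
    )
    out = effects.copy()
    out["regulatory_class"] = label
    return out


def class_proportions(results: pd.DataFrame) -> pd.Series:
    """Percentages of regulated genes per class (RNA / Ribo / Ribo&RNA)."""
    regulated = results[results["regulatory_class"] != "none"]
    if regulated.empty:
        raise ValueError("no regulated genes")
    pct = (regulated["regulatory_class"].value_counts(normalize=True) * 100.0)
    return pct.reindex(["RNA", "Ribo", "Ribo&RNA"], fill_value=0.0)


def te_vs_deltate_check(
    te: pd.DataFrame,
    effects: pd.DataFrame,
    condition_labels: Sequence[str],
) -> dict[str, float]:
    """Rank correlation between the fitted dTE and the observed TE ratio.

    The observed quantity is log2 of the ratio of condition-mean TE values.
    Returns Spearman rho, its p-value and n (NaN rho when degenerate).
    """
    labels = np.asarray(condition_labels)
    conds = pd.unique(labels)
    te1 = te.loc[:, labels == conds[0]].mean(axis=1)
    te2 = te.loc[:, labels == conds[1]].mean(axis=1)
    obs = np.log2(te2 / te1)
    paired = pd.DataFrame({"lfc_te": effects["lfc_te"], "obs": obs}).dropna()
    paired = paired[np.isfinite(paired["obs"])]
    if len(paired) < 3 or paired["obs"].nunique() == 1 \
            or paired["lfc_te"].nunique() == 1:
        return {"rho": np.nan, "pvalue": np.nan, "n": len(paired)}
    rho, p = stats.spearmanr(paired["lfc_te"], paired["obs"])
    return {"rho": float(rho), "pvalue": float(p), "n": len(paired)}
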