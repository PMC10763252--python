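"""Codon-level ribosome occupancy at the E/P/A sites.

The P-site codon index of an in-frame read is (psite - cds_start) / 3; the
A-site is the next codon and the E-site the previous one. Occupancy counts
are normalised by codon frequency in the background transcriptome (the CDSs
of transcripts that received at least one P-site), so a codon's occupancy
reflects dwell per codon occurrence rather than codon abundance, and is
reported as a percentage over codons.

Tissue contrasts use the all-replicate-pairs ratio of log2(CPM+1) A-site
counts (a quotient of log-scale values, with 1 meaning equal enrichment) and
Welch's unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._codons import CODON_TO_AA3, STOP_CODONS

__all__ = [
    "OccupancyProfile",
    "site_codons",
    "codon_background",
    "codon_occupancy",
    "aggregate_by_amino_acid",
    "log2_mean_center",
    "relative_enrichment",
    "welch_t_test",
]

SITES = ("E", "P", "A")
_SITE_SHIFT = {"E": -1, "P": 0, "A": 1}


@dataclass
class OccupancyProfile:
    """Codon occupancy of one ribosomal site in one sample."""

    site: str
    counts: dict[str, float]
    normalized: dict[str, float]  # percentages; sum to 100
    sample_id: str | None = None


def site_codons(
    annotations: pd.DataFrame,
    models: pd.DataFrame,
    sequences: Mapping[str, str],
    site: str = "A",
) -> pd.Series:
    """Codon identity at the requested site for every usable read.

    Only in-frame (frame 0) CDS P-sites are used: out-of-frame P-sites have
    no unambiguous codon. Site indices falling outside the CDS codon range
    are dropped (e.g. the E-site of a read whose P-site is the start codon).
    Returns a Series of codons indexed like the retained annotation rows.
    """
    if site not in _SITE_SHIFT:
        raise ValueError(f"site must be one of {SITES}, got {site!r}")
    m = models.set_index("transcript_id")
    for tid, row in m.iterrows():
        if tid in sequences and len(sequences[tid]) != row["length"]:
            raise ValueError(
                f"{tid}: sequence length {len(sequences[tid])} does not match "
                f"model length {row['length']}")
    ann = annotations[(annotations["region"] == "cds")
                      & (annotations["frame"] == 0)]
    cds_start = ann["transcript_id"].map(m["cds_start"]).to_numpy()
    cds_end = ann["transcript_id"].map(m["cds_end"]).to_numpy()
    n_codons = (cds_end - cds_start) // 3
    idx = (ann["psite_pos"].to_numpy() - cds_start) // 3 + _SITE_SHIFT[site]
    keep = (idx >= 0) & (idx < n_codons)
    ann = ann[keep]
    pos = cds_start[keep] + 3 * idx[keep]
    codons = [sequences[t][p:p + 3]
              for t, p in zip(ann["transcript_id"], pos)]
    return pd.Series(codons, index=ann.index, name=f"{site}_site_codon")


def codon_background(
    models: pd.DataFrame,
    sequences: Mapping[str, str],
    transcripts: set[str] | None = None,
) -> pd.Series:
    """Codon occurrence counts over the CDSs of the given transcripts.

    ``transcripts`` defaults to all modelled transcripts; pass the set with at
    least one assigned P-site to build the frequency-normalisation background.
    """
    counts: dict[str, int] = {}
    for _, row in models.iterrows():
        tid = row["transcript_id"]
        if transcripts is not None and tid not in transcripts:
            continue
        cds = sequences[tid][int(row["cds_start"]):int(row["cds_end"])]
        for i in range(0, len(cds), 3):
            c = cds[i:i + 3]
            counts[c] = counts.get(c, 0) + 1
    return pd.Series(counts, name="background").sort_index()


def codon_occupancy(
    site_codon_counts: Mapping[str, float] | pd.Series,
    background: Mapping[str, float] | pd.Series,
    site: str = "A",
    sample_id: str | None = None,
) -> OccupancyProfile:
    """Frequency-normalised codon occupancy as percentages.

    occ_c = N_c / F_c over codons present in the background; the profile is
    scaled to sum to 100. Codons absent from the background are excluded.
    """
    counts = dict(site_codon_counts)
    bg = dict(background)
    usable = {c: counts.get(c, 0.0) for c in bg if bg[c] > 0}
    if not usable or sum(usable.values()) == 0:
        raise ValueError("all-zero site codon counts")
    occ = {c: n / bg[c] for c, n in usable.items()}
    total = sum(occ.values())
    normalized = {c: 100.0 * v / total for c, v in occ.items()}
    return OccupancyProfile(site=site, counts=usable,
                            normalized=normalized, sample_id=sample_id)


def aggregate_by_amino_acid(profile: OccupancyProfile) -> dict[str, float]:
    """Sum codon percentages into amino-acid families (stops excluded),
    renormalised to 100."""
    sums: dict[str, float] = {}
    for codon, pct in profile.normalized.items():
        if codon in STOP_CODONS:
            continue
        aa = CODON_TO_AA3[codon]
        sums[aa] = sums.get(aa, 0.0) + pct
    total = sum(sums.values())
    if total == 0:
        raise ValueError("no sense-codon signal to aggregate")
    return {aa: 100.0 * v / total for aa, v in sums.items()}


def log2_mean_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2-transform then centre each column (codon) at zero mean.

    Input must be strictly positive (apply a pseudocount upstream).
    """
    if (matrix.to_numpy() <= 0).any():
        raise ValueError("log2_mean_center requires strictly positive entries")
    y = np.log2(matrix)
    return y - y.mean(axis=0)


def relative_enrichment(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-codon mean and SE of the A/B ratio of log2(CPM+pseudocount).

    Columns of ``counts_a``/``counts_b`` are replicates of the two tissues
    (codons on the index). Every replicate pair (i, j) contributes one ratio
    logCPM_A,i / logCPM_B,j, giving n_A * n_B ratios per codon; 1 means equal
    enrichment. Codons with any non-positive denominator logCPM are excluded
    from the ratio (flagged=True, NaN statistics).
    """
    if counts_a.shape[1] < 1 or counts_b.shape[1] < 1:
        raise ValueError("at least one replicate per tissue is required")
    codons = counts_a.index.intersection(counts_b.index)

    def logcpm(df: pd.DataFrame) -> pd.DataFrame:
        totals = df.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("replicate with zero total counts")
        return np.log2(df * 1e6 / totals + pseudocount)

    la = logcpm(counts_a.loc[codons])
    lb = logcpm(counts_b.loc[codons])
    rows = []
    for codon in codons:
        a = la.loc[codon].to_numpy(dtype=float)
        b = lb.loc[codon].to_numpy(dtype=float)
        if (b <= 0).any():
            rows.append({"codon": codon, "mean_ratio": np.nan,
                         "se": np.nan, "n_pairs": 0, "flagged": True})
            continue
        ratios = (a[:, None] / b[None, :]).ravel()
        se = (ratios.std(ddof=1) / np.sqrt(ratios.size)
              if ratios.size > 1 else 0.0)
        rows.append({"codon": codon, "mean_ratio": float(ratios.mean()),
                     "se": float(se), "n_pairs": ratios.size,
                     "flagged": False})
    return pd.DataFrame(rows).set_index("codon")


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns (t, df, two-sided p).

    t = (mA - mB) / sqrt(sA^2/nA + sB^2/nB) with Welch-Satterthwaite degrees
    of freedom. Degenerate edge: if both groups have zero variance, p is 1
    for equal means and 0 otherwise (t reported as 0 or +/-inf).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t-test needs at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        if diff == 0:
            return 0.0, float(na + nb - 2), 1.0
        return float(np.sign(diff) * np.inf), float(na + nb - 2), 0.0
    se2 = va / na + vb / nb
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
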