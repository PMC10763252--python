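"""Relative synonymous codon usage and its correlation with tRNA abundance.

RSCU_c = x_c * n / sum(x over the synonymous family of size n): the observed
count of a codon over its expected count under uniform synonymous usage.
Stop codons are excluded. RSCU is computed per gene and averaged unweighted
across genes. For comparison with tRNA expression, both RSCU and tRNA values
are renormalised so every amino-acid family totals 100 %, codons are paired
with their exact Watson-Crick cognate anticodons (wobble decoding is not
modelled), and a pooled Pearson correlation is reported. Codons whose cognate
anticodon is absent from the tRNA reference are kept with a tRNA percentage
of 0 so the vectors stay alignable.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from ._codons import (AA_FAMILIES, CODON_TO_AA3, SENSE_CODONS, STOP_CODONS,
                      codon_to_anticodon)

__all__ = [
    "extract_cds",
    "rscu",
    "average_over_genes",
    "family_percent",
    "codon_to_anticodon",
    "correlate_rscu_trna",
]


def extract_cds(sequences: Mapping[str, str],
                models: pd.DataFrame) -> dict[str, str]:
    """Cut CDS substrings out of transcript sequences using the model table.

    CDS length must be divisible by 3; a CDS not starting with ATG warns but
    is kept (annotation oddities happen in real transcript sets).
    """
    out: dict[str, str] = {}
    for _, row in models.iterrows():
        tid = row["transcript_id"]
        if tid not in sequences:
            raise ValueError(f"missing transcript sequence: {tid}")
        cds = sequences[tid][int(row["cds_start"]):int(row["cds_end"])]
        if len(cds) % 3 != 0:
            raise ValueError(f"{tid}: CDS length {len(cds)} not divisible by 3")
        if not cds.startswith("ATG"):
            warnings.warn(f"{tid}: CDS does not start with ATG")
        out[tid] = cds
    return out


def rscu(cds_set: Mapping[str, str] | Iterable[str] | str) -> pd.DataFrame:
    """Codon count, frequency and RSCU over one or more CDS strings.

    Stop codons are excluded from counting. Families with zero total usage
    get RSCU 0 for all members. Frequencies sum to 1 over sense codons.
    """
    if isinstance(cds_set, str):
        cds_iter: Iterable[str] = [cds_set]
    elif isinstance(cds_set, Mapping):
        cds_iter = cds_set.values()
    else:
        cds_iter = cds_set
    counts = {c: 0 for c in SENSE_CODONS}
    total = 0
    for cds in cds_iter:
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i:i + 3]
            if codon in STOP_CODONS or codon not in counts:
                continue
            counts[codon] += 1
            total += 1
    if total == 0:
        raise ValueError("no sense codons counted")
    rows = []
    for aa, family in AA_FAMILIES.items():
        fam_total = sum(counts[c] for c in family)
        n = len(family)
        for c in family:
            rows.append({
                "codon": c,
                "amino_acid": aa,
                "count": counts[c],
                "frequency": counts[c] / total,
                "rscu": (counts[c] * n / fam_total) if fam_total > 0 else 0.0,
            })
    return pd.DataFrame(rows).set_index("codon").sort_index()


def average_over_genes(per_gene: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Unweighted mean of per-gene frequency and RSCU tables.

    A gene that does not use a family contributes zeros to that family's mean.
    """
    tables = list(per_gene)
    if not tables:
        raise ValueError("no per-gene tables to average")
    freq = pd.concat([t["frequency"] for t in tables], axis=1).mean(axis=1)
    rs = pd.concat([t["rscu"] for t in tables], axis=1).mean(axis=1)
    out = tables[0][["amino_acid"]].copy()
    out["frequency"] = freq
    out["rscu"] = rs
    return out


def family_percent(
    values: Mapping[str, float] | pd.Series,
    grouping: Mapping[str, str] | None = None,
) -> pd.Series:
    """Renormalise non-negative values so each amino-acid family sums to 100.

    ``grouping`` maps key -> family; defaults to the standard code with codon
    keys. Zero-total families are dropped with a warning.
    """
    values = pd.Series(values, dtype=float)
    if (values < 0).any():
        raise ValueError("family_percent requires non-negative values")
    if grouping is None:
        grouping = CODON_TO_AA3
    fam = values.index.map(lambda k: grouping[k])
    totals = values.groupby(fam).transform("sum")
    zero = totals == 0
    if zero.any():
        dropped = sorted(set(fam[zero]))
        warnings.warn(f"dropping zero-total families: {dropped}")
    out = values[~zero] * 100.0 / totals[~zero]
    return out


def correlate_rscu_trna(
    rscu_percent: Mapping[str, float] | pd.Series,
    trna_percent: Mapping[str, float] | pd.Series,
    pairing: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Pooled Pearson correlation between family-percent RSCU and tRNA values.

    ``rscu_percent`` is keyed by codon, ``trna_percent`` by anticodon.
    ``pairing`` maps codon -> cognate anticodon (default exact Watson-Crick
    reverse complement). Codons whose cognate anticodon is missing from the
    tRNA table contribute a tRNA percentage of 0. Returns r, the two-sided
    p-value and n, the number of paired codons.
    """
    rscu_percent = pd.Series(rscu_percent, dtype=float)
    trna_percent = pd.Series(trna_percent, dtype=float)
    if pairing is None:
        pairing = {c: codon_to_anticodon(c) for c in rscu_percent.index}
    x, y = [], []
    for codon, r_val in rscu_percent.items():
        anticodon = pairing[codon]
        x.append(r_val)
        y.append(float(trna_percent.get(anticodon, 0.0)))
    if len(x) < 3:
        raise ValueError("need at least 3 paired codons to correlate")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "pvalue": float(p), "n": len(x)}
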