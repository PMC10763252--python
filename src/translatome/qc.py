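"""Ribosome-footprint quality control.

Read-length distributions, per-length P-site offset estimation from reads
overlapping the start codon, P-site annotation into transcript regions, and
trinucleotide (frame) periodicity. Transcript coordinates are 0-based and
half-open; frames are labelled 0/1/2 with frame 0 the in-frame signal.

Offsets are estimated with a start-codon-overlap modal rule: among the reads
of each length whose span covers the first CDS nucleotide with the 5' end
strictly upstream of it, the offset is the mode of (cds_start -
five_prime_pos). Initiating ribosomes pile up on the start codon, so that
mode identifies the true 5'->P-site distance. Lengths with too few such reads
inherit the global modal offset; ties break toward the smaller offset.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "read_length_distribution",
    "estimate_psite_offsets",
    "annotate_psites",
    "region_fractions",
    "frame_fractions_by_length",
]


def read_length_distribution(footprints: pd.DataFrame) -> pd.Series:
    """Fraction of reads per footprint length (sums to 1)."""
    if footprints.empty:
        raise ValueError("no footprints")
    frac = footprints["length"].value_counts(normalize=True).sort_index()
    frac.index.name = "length"
    return frac.rename("fraction")


def _mode_smallest(values: np.ndarray) -> int:
    """Modal value; ties broken toward the smallest."""
    uniq, counts = np.unique(values, return_counts=True)
    return int(uniq[np.argmax(counts)])  # np.unique sorts, argmax takes first


def estimate_psite_offsets(
    footprints: pd.DataFrame,
    models: pd.DataFrame,
    min_reads_per_length: int = 50,
) -> dict[int, int]:
    """Per-length 5'->P-site offsets from start-codon-overlapping reads."""
    cds_start = models.set_index("transcript_id")["cds_start"]
    missing = set(footprints["transcript_id"]) - set(cds_start.index)
    if missing:
        raise ValueError(f"transcripts without models: {sorted(missing)[:5]}")
    start = footprints["transcript_id"].map(cds_start).to_numpy()
    five = footprints["five_prime_pos"].to_numpy()
    length = footprints["length"].to_numpy()
    overlap = (five < start) & (five + length > start)
    if not overlap.any():
        raise ValueError("no reads overlap a start codon; cannot estimate offsets")
    dist = (start - five)[overlap]
    len_ov = length[overlap]
    global_mode = _mode_smallest(dist)
    offsets: dict[int, int] = {}
    for L in np.unique(length):
        d = dist[len_ov == L]
        if d.size >= min_reads_per_length:
            offsets[int(L)] = _mode_smallest(d)
        else:
            offsets[int(L)] = global_mode
    return offsets


def annotate_psites(
    footprints: pd.DataFrame,
    offsets: Mapping[int, int],
    models: pd.DataFrame,
) -> pd.DataFrame:
    """P-site position, region (utr5/cds/utr3) and frame for every read.

    Region uses half-open comparison: psite < cds_start is utr5,
    cds_start <= psite < cds_end is cds, else utr3. Frame is defined only in
    the CDS as (psite - cds_start) mod 3.
    """
    observed = set(footprints["length"].unique())
    missing = observed - set(offsets)
    if missing:
        raise ValueError(f"no offset for observed lengths: {sorted(missing)}")
    m = models.set_index("transcript_id")
    cds_start = footprints["transcript_id"].map(m["cds_start"]).to_numpy()
    cds_end = footprints["transcript_id"].map(m["cds_end"]).to_numpy()
    psite = footprints["five_prime_pos"].to_numpy() + \
        footprints["length"].map(offsets).to_numpy()
    region = np.where(psite < cds_start, "utr5",
                      np.where(psite < cds_end, "cds", "utr3"))
    frame = np.where(region == "cds", (psite - cds_start) % 3, -1)
    out = footprints.copy()
    out["psite_pos"] = psite
    out["region"] = region
    out["frame"] = frame
    return out


def region_fractions(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-sample percentage of P-sites in 5'UTR, CDS and 3'UTR (sums to 100)."""
    if annotations.empty:
        raise ValueError("no annotated P-sites")
    tab = (annotations.groupby("sample_id")["region"]
           .value_counts(normalize=True).unstack(fill_value=0.0) * 100.0)
    for col in ("utr5", "cds", "utr3"):
        if col not in tab:
            tab[col] = 0.0
    return tab[["utr5", "cds", "utr3"]]


def frame_fractions_by_length(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per read length, the fraction of CDS P-sites in each frame (rows sum to 1)."""
    cds = annotations[annotations["region"] == "cds"]
    if cds.empty:
        raise ValueError("no CDS P-sites")
    tab = (cds.groupby("length")["frame"]
           .value_counts(normalize=True).unstack(fill_value=0.0))
    for f in (0, 1, 2):
        if f not in tab:
            tab[f] = 0.0
    return tab[[0, 1, 2]]
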