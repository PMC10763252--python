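"""Readers, writers and validated containers for the pipeline's file formats.

All tables are plain TSV with a header row; sequences are FASTA. Transcript
coordinates are 0-based, half-open throughout. Sequences are normalised to the
uppercase DNA alphabet (U -> T) on load so RNA- and DNA-alphabet inputs behave
identically downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: feature levels a count matrix may be tagged with
COUNT_LEVELS = ("isodecoder", "anticodon", "amino_acid", "gene", "codon")

FOOTPRINT_COLUMNS = ["transcript_id", "five_prime_pos", "length", "sample_id"]
MODEL_COLUMNS = ["transcript_id", "length", "cds_start", "cds_end"]


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T) alphabet."""
    return str(seq).upper().replace("U", "T")


@dataclass
class CountMatrix:
    """Samples x features non-negative counts with a feature-level tag.

    ``data`` is a features-by-samples DataFrame (features on the index,
    sample ids as columns), matching the orientation of the TSV interchange
    format (one row per feature, one column per sample).
    """

    data: pd.DataFrame
    level: str = "gene"

    def __post_init__(self) -> None:
        if self.level not in COUNT_LEVELS:
            raise ValueError(
                f"unknown count level {self.level!r}; expected one of {COUNT_LEVELS}"
            )
        if (self.data.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative values")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path: str | Path, level: str) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature")
        return cls(df, level=level)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered name -> sequence mapping.

    Sequences are normalised to uppercase DNA. Duplicate names are an error.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record name: {rec.id}")
        records[rec.id] = normalize_sequence(str(rec.seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: Mapping[str, str] | Iterable[tuple[str, str]],
                path: str | Path) -> None:
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(recs, str(path), "fasta")


def validate_transcript_models(models: pd.DataFrame) -> pd.DataFrame:
    """Check the transcript-model invariants; returns the validated frame."""
    missing = [c for c in MODEL_COLUMNS if c not in models.columns]
    if missing:
        raise ValueError(f"transcript model table missing columns: {missing}")
    for _, row in models.iterrows():
        tid = row["transcript_id"]
        if not (0 <= row["cds_start"] < row["cds_end"] <= row["length"]):
            raise ValueError(
                f"{tid}: require 0 <= cds_start < cds_end <= length, got "
                f"({row['cds_start']}, {row['cds_end']}, {row['length']})"
            )
        if (row["cds_end"] - row["cds_start"]) % 3 != 0:
            raise ValueError(f"{tid}: CDS length not divisible by 3")
    return models


def read_transcript_models(path: str | Path) -> pd.DataFrame:
    models = pd.read_csv(path, sep="\t")
    return validate_transcript_models(models)


def write_transcript_models(models: pd.DataFrame, path: str | Path) -> None:
    validate_transcript_models(models)
    models.to_csv(path, sep="\t", index=False)


def validate_footprints(footprints: pd.DataFrame,
                        models: pd.DataFrame | None = None) -> pd.DataFrame:
    missing = [c for c in FOOTPRINT_COLUMNS if c not in footprints.columns]
    if missing:
        raise ValueError(f"footprint table missing columns: {missing}")
    if (footprints["five_prime_pos"] < 0).any():
        raise ValueError("footprint with negative 5' position")
    if models is not None:
        lengths = models.set_index("transcript_id")["length"]
        unknown = set(footprints["transcript_id"]) - set(lengths.index)
        if unknown:
            raise ValueError(f"footprints on unknown transcripts: {sorted(unknown)[:5]}")
        tlen = footprints["transcript_id"].map(lengths)
        if (footprints["five_prime_pos"] + footprints["length"] > tlen).any():
            raise ValueError("footprint extends past its transcript end")
    return footprints


def read_footprints(path: str | Path,
                    models: pd.DataFrame | None = None) -> pd.DataFrame:
    fp = pd.read_csv(path, sep="\t")
    return validate_footprints(fp, models)


def write_footprints(footprints: pd.DataFrame, path: str | Path) -> None:
    validate_footprints(footprints)
    footprints.to_csv(path, sep="\t", index=False)
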