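"""Collapsed mature-tRNA reference: nomenclature, collapsing, read assignment
and count aggregation over the isodecoder -> anticodon -> amino-acid hierarchy.

tRNA gene families are heavily duplicated: many distinct genes carry
byte-identical mature sequences, so reads cannot be attributed to individual
gene copies. The reference therefore collapses identical sequences into a
single representative (the lexicographically smallest member name), and read
assignment works by exact substring matching against the collapsed set, with
reads matching k records counted 1/k to each.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import CountMatrix, normalize_sequence

__all__ = [
    "TrnaRecord",
    "TrnaReference",
    "parse_trna_name",
    "collapse_identical",
    "assign_reads",
    "aggregate_counts",
    "cpm_normalize",
    "compartment_fractions",
]

# gtRNAdb: tRNA-<Aa>-<Anticodon>-<family>-<copy>; mitotRNAdb: MT-tRNA-<Aa>-<Anticodon>
_NAME_RE = re.compile(
    r"^(?P<mt>MT-)?tRNA-(?P<aa>[A-Za-z]{3,4})-(?P<ac>[ACGTN]{3})"
    r"(?:-(?P<family>\d+)-(?P<copy>\d+))?$"
)


def parse_trna_name(name: str):
    """Parse a tRNA gene name into (amino_acid, anticodon, family, copy, origin).

    Cytoplasmic names carry a family/copy suffix ("tRNA-Arg-TCG-3-1");
    mitochondrial names are prefixed "MT-" and have none ("MT-tRNA-Ile-GAT").
    Amino-acid codes include the specials iMet, SeC and Und.
    """
    if not name:
        raise ValueError("empty tRNA name")
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"unparseable tRNA name: {name!r}")
    origin = "mitochondrial" if m.group("mt") else "cytoplasmic"
    family = int(m.group("family")) if m.group("family") else None
    copy = int(m.group("copy")) if m.group("copy") else None
    if origin == "cytoplasmic" and family is None:
        raise ValueError(
            f"cytoplasmic tRNA name missing family/copy suffix: {name!r}")
    return m.group("aa"), m.group("ac"), family, copy, origin


@dataclass
class TrnaRecord:
    """One collapsed reference entry and the source gene names behind it."""

    name: str
    sequence: str
    amino_acid: str
    anticodon: str
    origin: str
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.anticodon) != 3 or set(self.anticodon) - set("ACGTN"):
            raise ValueError(f"bad anticodon {self.anticodon!r} in {self.name}")
        if not self.members:
            raise ValueError(f"record {self.name} has no members")


@dataclass
class TrnaReference:
    """The collapsed reference set: unique sequences, disjoint member lists."""

    records: list[TrnaRecord]

    def __post_init__(self) -> None:
        seqs = [r.sequence for r in self.records]
        if len(set(seqs)) != len(seqs):
            raise ValueError("reference contains duplicate sequences")
        members = [m for r in self.records for m in r.members]
        if len(set(members)) != len(members):
            raise ValueError("a member name appears in more than one record")

    def __len__(self) -> int:
        return len(self.records)

    def by_name(self) -> dict[str, TrnaRecord]:
        return {r.name: r for r in self.records}

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "representative": r.name,
                "members": ",".join(sorted(r.members)),
                "amino_acid": r.amino_acid,
                "anticodon": r.anticodon,
                "origin": r.origin,
            }
            for r in self.records
        ])


def collapse_identical(
    records: Mapping[str, str] | Iterable[tuple[str, str]],
) -> TrnaReference:
    """Collapse byte-identical tRNA sequences into single representatives.

    The representative is the lexicographically smallest member name; its
    parsed annotation labels the record. Identical sequences annotated with
    conflicting anticodons indicate malformed input and raise.
    """
    items = list(records.items() if isinstance(records, Mapping) else records)
    if not items:
        raise ValueError("no tRNA records to collapse")
    groups: dict[str, list[str]] = {}
    for name, seq in items:
        groups.setdefault(normalize_sequence(seq), []).append(name)

    out = []
    for seq, members in groups.items():
        parsed = {name: parse_trna_name(name) for name in members}
        anticodons = {p[1] for p in parsed.values()}
        if len(anticodons) > 1:
            raise ValueError(
                f"identical sequences with conflicting anticodon annotations: "
                f"{sorted(members)} -> {sorted(anticodons)}")
        rep = min(members)
        aa, ac, _, _, origin = parsed[rep]
        out.append(TrnaRecord(rep, seq, aa, ac, origin, sorted(members)))
    out.sort(key=lambda r: r.name)
    return TrnaReference(out)


def assign_reads(
    reads: Mapping[str, Iterable[str]] | Iterable[str],
    reference: TrnaReference,
    min_len: int = 15,
) -> CountMatrix:
    """Assign reads to reference records by exact substring matching.

    Reads shorter than ``min_len`` nt are discarded (truncated reverse-
    transcription products below that length are uninformative). A read equal
    to or contained in exactly one record counts 1; a read contained in k
    records counts 1/k to each; unmatched reads count nowhere, so total
    assigned mass is at most the number of kept reads.
    """
    if not reference.records:
        raise ValueError("empty tRNA reference")
    if not isinstance(reads, Mapping):
        reads = {"sample_1": reads}
    names = [r.name for r in reference.records]
    seqs = [r.sequence for r in reference.records]
    cols = {}
    for sample, sample_reads in reads.items():
        counts = np.zeros(len(names))
        for read in sample_reads:
            read = normalize_sequence(read)
            if len(read) < min_len:
                continue
            hits = [i for i, s in enumerate(seqs) if read in s]
            if hits:
                share = 1.0 / len(hits)
                for i in hits:
                    counts[i] += share
        cols[sample] = counts
    data = pd.DataFrame(cols, index=pd.Index(names, name="feature"))
    return CountMatrix(data, level="isodecoder")


def _feature_key(name: str, level: str) -> str:
    aa, ac, _, _, origin = parse_trna_name(name)
    prefix = "MT-" if origin == "mitochondrial" else ""
    if level == "anticodon":
        return f"{prefix}{aa}-{ac}"
    if level == "amino_acid":
        return f"{prefix}{aa}"
    raise ValueError(f"unknown aggregation level {level!r}")


def aggregate_counts(counts: CountMatrix, level: str) -> CountMatrix:
    """Sum isodecoder counts up the hierarchy (anticodon or amino acid).

    Mitochondrial features keep their "MT-" prefix so compartments are never
    merged. Column totals are preserved exactly.
    """
    if counts.level == level:
        return counts
    if counts.level == "anticodon" and level == "amino_acid":
        keys = [k.rsplit("-", 1)[0] if not k.startswith("MT-")
                else "MT-" + k[3:].rsplit("-", 1)[0]
                for k in counts.features]
    elif counts.level == "isodecoder":
        keys = [_feature_key(n, level) for n in counts.features]
    else:
        raise ValueError(
            f"cannot aggregate level {counts.level!r} to {level!r}")
    data = counts.data.groupby(pd.Index(keys, name="feature")).sum()
    return CountMatrix(data, level=level)


def cpm_normalize(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million scaling: each sample column sums to 1e6."""
    data = counts.data if isinstance(counts, CountMatrix) else counts
    totals = data.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero column total in samples: {bad}")
    return data * 1e6 / totals


def compartment_fractions(
    counts: CountMatrix, reference: TrnaReference | None = None,
) -> pd.DataFrame:
    """Per-sample percentage of counts on cytoplasmic vs mitochondrial tRNAs."""
    origins = []
    by_name = reference.by_name() if reference is not None else {}
    for name in counts.features:
        if name in by_name:
            origins.append(by_name[name].origin)
        else:
            origins.append(
                "mitochondrial" if str(name).startswith("MT-") else "cytoplasmic")
    origins = pd.Index(origins)
    totals = counts.data.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("sample with zero total counts")
    mito = counts.data.loc[np.array(origins == "mitochondrial")].sum(axis=0)
    out = pd.DataFrame({
        "cytoplasmic_pct": 100.0 * (totals - mito) / totals,
        "mitochondrial_pct": 100.0 * mito / totals,
    })
    out.index.name = "sample_id"
    return out
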