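"""Standard genetic-code tables shared across modules (DNA alphabet)."""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: the 61 sense codons of the standard code
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))

#: codon -> three-letter amino-acid code (sense codons only)
CODON_TO_AA3: dict[str, str] = {
    c: seq3(aa) for c, aa in _TABLE.forward_table.items()
}

#: three-letter amino-acid code -> synonymous codon family
AA_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    AA_FAMILIES.setdefault(CODON_TO_AA3[_codon], ())
AA_FAMILIES = {
    aa: tuple(sorted(c for c in SENSE_CODONS if CODON_TO_AA3[c] == aa))
    for aa in AA_FAMILIES
}


def reverse_complement(seq: str) -> str:
    if set(seq) - set("ACGT"):
        raise ValueError(
            f"non-DNA characters in {seq!r}; normalise to the DNA alphabet first"
        )
    return str(Seq(seq).reverse_complement())


def codon_to_anticodon(codon: str) -> str:
    """Cognate anticodon (5'->3') of a DNA codon under exact Watson-Crick pairing."""
    if len(codon) != 3:
        raise ValueError(f"codon must be 3 nt, got {codon!r}")
    return reverse_complement(codon)
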