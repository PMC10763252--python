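"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: a handful of
tissues with three replicates each, mature tRNA genes with duplicated
sequences, negative-binomial count noise (Var = mu + alpha*mu^2), ribosome
footprints 25-35 nt long whose 5' ends sit at a fixed offset upstream of the
ribosomal P-site, codon-dependent dwell, and matched RNA/RPF count tables with
genes planted in transcriptional-only, translational-only and combined
regulatory classes.

Ribosome positions are sampled in proportion to the dwell weight of the codon
in the A-site by default (``dwell_site="A"``): decoding of the A-site codon is
the rate-limiting step of elongation, so pausing signal lives there. A
configurable initiation peak (``start_codon_enrichment``) concentrates density
on the start codon, which is what makes the start-overlap P-site offset
estimator identifiable.

All randomness flows from ``SimulationConfig.seed``; each generator draws from
an independent, deterministically derived stream, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._codons import CODON_TO_AA3, SENSE_CODONS, STOP_CODONS, codon_to_anticodon
from .io import CountMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PlantedEffect",
    "make_planted_classes",
    "generate_transcriptome",
    "generate_trna_geneset",
    "simulate_trna_counts",
    "simulate_footprints",
    "simulate_matched_counts",
    "simulate_occupancy_counts",
    "DEFAULT_MISSING_ANTICODONS",
    "DEFAULT_MITO_TRNAS",
]

# anticodons absent from high-confidence tRNA references in cattle; excluded
# from the default cytoplasmic gene set so the synthetic reference mirrors the
# 54-anticodon structure of real data
DEFAULT_MISSING_ANTICODONS: tuple[tuple[str, str], ...] = (
    ("Ala", "GGC"), ("Arg", "GCG"), ("Asn", "ATT"), ("Gly", "ACC"),
    ("His", "ATG"), ("Leu", "GAG"), ("Pro", "GGG"), ("Tyr", "ATA"),
)

# typical vertebrate mitochondrial tRNA set (22 genes, one per anticodon)
DEFAULT_MITO_TRNAS: tuple[tuple[str, str], ...] = (
    ("Ala", "TGC"), ("Arg", "TCG"), ("Asn", "GTT"), ("Asp", "GTC"),
    ("Cys", "GCA"), ("Gln", "TTG"), ("Glu", "TTC"), ("Gly", "TCC"),
    ("His", "GTG"), ("Ile", "GAT"), ("Leu", "TAA"), ("Leu", "TAG"),
    ("Lys", "TTT"), ("Met", "CAT"), ("Phe", "GAA"), ("Pro", "TGG"),
    ("Ser", "TGA"), ("Ser", "GCT"), ("Thr", "TGT"), ("Trp", "TCA"),
    ("Tyr", "GTA"), ("Val", "TAC"),
)

# RPF length distribution: peaked around 29-31 nt within the 25-35 nt window
_DEFAULT_LENGTH_WEIGHTS = {
    25: 1, 26: 2, 27: 4, 28: 7, 29: 10, 30: 12,
    31: 10, 32: 7, 33: 4, 34: 2, 35: 1,
}

# per-length 5'->P-site offsets seen in real libraries: 12 nt for short
# footprints, 13 nt for 30 nt and longer
DEFAULT_PSITE_OFFSETS: dict[int, int] = {
    L: (12 if L <= 29 else 13) for L in range(25, 36)
}

_NT = np.array(list("ACGT"))


def default_cyto_anticodons() -> list[tuple[str, str]]:
    """Cytoplasmic (amino acid, anticodon) pairs for the default gene set.

    One pair per sense codon plus selenocysteine (SeC-TCA, decoding UGA),
    minus the eight anticodons absent from high-confidence references: 54
    distinct anticodons in total.
    """
    pairs = [(CODON_TO_AA3[c], codon_to_anticodon(c)) for c in SENSE_CODONS]
    pairs.append(("SeC", "TCA"))
    missing = set(DEFAULT_MISSING_ANTICODONS)
    return sorted(p for p in pairs if p not in missing)


@dataclass
class PlantedEffect:
    """Planted regulatory change for one gene (log2 fold changes, cond2/cond1)."""

    kind: str  # none | rna_only | ribo_only | both
    lfc_rna: float = 0.0
    lfc_rpf: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "rna_only", "ribo_only", "both"):
            raise ValueError(f"unknown regulatory class {self.kind!r}")
        if self.kind == "none" and (self.lfc_rna or self.lfc_rpf):
            raise ValueError("class 'none' requires zero fold changes")
        if self.kind == "rna_only" and not math.isclose(self.lfc_rna, self.lfc_rpf):
            raise ValueError("class 'rna_only' shifts RNA and RPF equally")
        if self.kind == "ribo_only" and self.lfc_rna != 0.0:
            raise ValueError("class 'ribo_only' shifts RPF only")

    @property
    def lfc_te(self) -> float:
        return self.lfc_rpf - self.lfc_rna


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    true_dwell: dict[str, float] = field(default_factory=dict)
    true_offsets: dict[int, int] = field(default_factory=dict)
    true_class: dict[str, str] = field(default_factory=dict)
    true_trna_lfc: dict[str, float] = field(default_factory=dict)
    planted_effects: dict[str, PlantedEffect] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, mirroring the emulated experiment.

    Defaults are the study conditions: 2 conditions x 3 replicates,
    NB dispersion 0.05, footprints 25-35 nt with offsets 12-13 nt, 5 %
    UTR noise, and a 10x initiation peak on the start codon.
    """

    seed: int = 0
    n_genes: int = 100
    cds_codons_range: tuple[int, int] = (50, 200)  # incl. start + stop codons
    utr5_len: int = 50
    utr3_len: int = 50
    conditions: tuple[str, str] = ("tissueA", "tissueB")
    n_replicates_per_condition: int = 3
    nb_dispersion: float = 0.05
    dwell_weights: dict[str, float] | None = None  # None -> uniform
    dwell_site: str = "A"  # which ribosomal site the dwell weight indexes
    stop_dwell: float = 1.0  # dwell weight of stop codons in the A-site
    psite_offset: int | Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_PSITE_OFFSETS))
    read_length_probs: dict[int, float] = field(default_factory=lambda: {
        L: w / sum(_DEFAULT_LENGTH_WEIGHTS.values())
        for L, w in _DEFAULT_LENGTH_WEIGHTS.items()
    })
    codon_weights: dict[str, float] | None = None  # CDS composition; None -> uniform
    utr_noise_fraction: float = 0.05
    start_codon_enrichment: float = 10.0
    reads_per_sample: int = 50_000
    # tRNA count model: per-isodecoder means ~ logNormal(log_mean, log_sd)
    trna_log_mean: float = math.log(200.0)
    trna_log_sd: float = 1.0
    trna_lfc: dict[str, float] = field(default_factory=dict)
    # matched RNA/RPF count model
    gene_log_mean: float = math.log(200.0)
    gene_log_sd: float = 1.0
    planted_classes: dict[str, PlantedEffect] | None = None
    # synthetic tRNA gene set
    cyto_anticodons: Sequence[tuple[str, str]] | None = None
    mito_anticodons: Sequence[tuple[str, str]] | None = None
    n_identical_copies: int = 2  # identical-sequence copies of the first family

    def validate(self) -> None:
        total = sum(self.read_length_probs.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"read_length_probs must sum to 1, got {total}")
        if any(p < 0 for p in self.read_length_probs.values()):
            raise ValueError("read_length_probs must be non-negative")
        dwell = self.resolved_dwell()
        if set(dwell) < set(SENSE_CODONS):
            raise ValueError("dwell_weights must cover all 61 sense codons")
        if any(w <= 0 for w in dwell.values()):
            raise ValueError("dwell_weights must be strictly positive")
        if self.dwell_site not in ("A", "P"):
            raise ValueError("dwell_site must be 'A' or 'P'")
        if not 0 <= self.utr_noise_fraction < 1:
            raise ValueError("utr_noise_fraction must be in [0, 1)")

    def resolved_dwell(self) -> dict[str, float]:
        if self.dwell_weights is None:
            return {c: 1.0 for c in SENSE_CODONS}
        return dict(self.dwell_weights)

    def offset_for_length(self, length: int) -> int:
        if isinstance(self.psite_offset, Mapping):
            try:
                return int(self.psite_offset[length])
            except KeyError:
                raise ValueError(f"no P-site offset configured for length {length}")
        return int(self.psite_offset)

    def sample_ids(self) -> list[str]:
        return [f"{cond}_{r + 1}"
                for cond in self.conditions
                for r in range(self.n_replicates_per_condition)]


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def make_planted_classes(
    n_per_class: Mapping[str, int],
    magnitude: float = 2.0,
    rng: np.random.Generator | int | None = None,
) -> dict[str, PlantedEffect]:
    """Assign genes to regulatory classes with |log2 fold change| = magnitude.

    Signs are drawn at random; 'both' genes get independent RNA and TE shifts
    so their RNA and RPF changes differ.
    """
    rng = np.random.default_rng(rng)
    effects: dict[str, PlantedEffect] = {}
    i = 0
    for kind in ("none", "rna_only", "ribo_only", "both"):
        for _ in range(n_per_class.get(kind, 0)):
            i += 1
            gene = f"G{i:05d}"
            s1 = rng.choice([-1.0, 1.0])
            s2 = rng.choice([-1.0, 1.0])
            if kind == "none":
                effects[gene] = PlantedEffect("none")
            elif kind == "rna_only":
                effects[gene] = PlantedEffect(
                    "rna_only", s1 * magnitude, s1 * magnitude)
            elif kind == "ribo_only":
                effects[gene] = PlantedEffect("ribo_only", 0.0, s1 * magnitude)
            else:  # both: RNA shift plus an additional TE shift
                effects[gene] = PlantedEffect(
                    "both", s1 * magnitude, s1 * magnitude + s2 * magnitude)
    return effects


# ---------------------------------------------------------------------------
# transcriptome


def generate_transcriptome(
    config: SimulationConfig,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random transcripts: 5'UTR + (ATG ... stop) CDS + 3'UTR.

    Internal codons are drawn from ``config.codon_weights`` (uniform over the
    61 sense codons by default). Returns (name -> sequence, transcript model
    table with 0-based half-open CDS coordinates).
    """
    config.validate()
    lo, hi = config.cds_codons_range
    if lo < 2:
        raise ValueError(
            "cds_codons_range minimum must be >= 2 (start + stop codon)")
    rng = _rng(config, 1)
    weights = config.codon_weights or {c: 1.0 for c in SENSE_CODONS}
    codons = sorted(weights)
    p = np.array([weights[c] for c in codons], dtype=float)
    if (p <= 0).any():
        raise ValueError("codon_weights must be strictly positive")
    p /= p.sum()

    sequences: dict[str, str] = {}
    rows = []
    for g in range(config.n_genes):
        name = f"TX{g + 1:04d}"
        n_codons = int(rng.integers(lo, hi + 1))
        internal = rng.choice(len(codons), size=n_codons - 2, p=p)
        cds = "ATG" + "".join(codons[i] for i in internal) + \
            str(rng.choice(STOP_CODONS))
        seq = _random_nt(rng, config.utr5_len) + cds + \
            _random_nt(rng, config.utr3_len)
        sequences[name] = seq
        rows.append({
            "transcript_id": name,
            "length": len(seq),
            "cds_start": config.utr5_len,
            "cds_end": config.utr5_len + 3 * n_codons,
        })
    return sequences, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tRNA gene set


def generate_trna_geneset(config: SimulationConfig) -> dict[str, str]:
    """Mock mature tRNA genes with gtRNAdb-style names.

    Cytoplasmic genes are named ``tRNA-<Aa>-<Anticodon>-<family>-<copy>``,
    mitochondrial genes ``MT-tRNA-<Aa>-<Anticodon>``. The anticodon is
    embedded at positions 34-36 (0-based 33-35) of a random 72-87 nt body so
    name/sequence consistency is checkable. The first family is emitted as
    ``n_identical_copies`` byte-identical copies (exercising reference
    collapsing) and the second family as two distinct-sequence copies.
    """
    rng = _rng(config, 2)
    cyto = list(config.cyto_anticodons
                if config.cyto_anticodons is not None
                else default_cyto_anticodons())
    mito = list(config.mito_anticodons
                if config.mito_anticodons is not None
                else DEFAULT_MITO_TRNAS)

    def body(anticodon: str) -> str:
        n = int(rng.integers(72, 88))
        seq = list(_random_nt(rng, n))
        seq[33:36] = list(anticodon)
        return "".join(seq)

    records: dict[str, str] = {}
    for idx, (aa, ac) in enumerate(cyto):
        if idx == 0 and config.n_identical_copies > 1:
            seq = body(ac)
            for copy_family in range(1, config.n_identical_copies + 1):
                records[f"tRNA-{aa}-{ac}-{copy_family}-1"] = seq
        elif idx == 1:
            records[f"tRNA-{aa}-{ac}-1-1"] = body(ac)
            records[f"tRNA-{aa}-{ac}-2-1"] = body(ac)
        else:
            records[f"tRNA-{aa}-{ac}-1-1"] = body(ac)
    for aa, ac in mito:
        records[f"MT-tRNA-{aa}-{ac}"] = body(ac)
    return records


# ---------------------------------------------------------------------------
# counts


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               alpha: float) -> np.ndarray:
    """NB2 draws: Var = mu + alpha * mu^2 (Poisson limit for tiny alpha)."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mean)
    size_param = 1.0 / alpha
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_trna_counts(
    reference, config: SimulationConfig,
) -> tuple[CountMatrix, GroundTruth]:
    """Tissue-specific isodecoder counts with planted log2 fold changes.

    ``reference`` is either an iterable of isodecoder names or an object with
    a ``records`` attribute (e.g. a collapsed tRNA reference).
    """
    if hasattr(reference, "records"):
        names = [r.name for r in reference.records]
    else:
        names = list(reference)
    if not names:
        raise ValueError("empty tRNA reference")
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    if config.n_replicates_per_condition < 1:
        raise ValueError("need at least one replicate per condition")

    rng = _rng(config, 3)
    base = rng.lognormal(config.trna_log_mean, config.trna_log_sd,
                         size=len(names))
    lfc = np.array([config.trna_lfc.get(n, 0.0) for n in names])

    cols = {}
    for ci, cond in enumerate(config.conditions):
        mean = base * (2.0 ** lfc if ci == 1 else 1.0)
        for r in range(config.n_replicates_per_condition):
            cols[f"{cond}_{r + 1}"] = _nb_sample(rng, mean, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(names, name="feature"))
    truth = GroundTruth(true_trna_lfc={n: float(l) for n, l in zip(names, lfc)})
    return CountMatrix(counts, level="isodecoder"), truth


# ---------------------------------------------------------------------------
# footprints


def _position_table(sequences: Mapping[str, str], models: pd.DataFrame,
                    dwell: Mapping[str, float], dwell_site: str,
                    stop_dwell: float, start_enrichment: float):
    """Flattened (transcript, P-site position, weight) over all CDS codons."""
    tids, psites, weights = [], [], []
    for _, row in models.iterrows():
        tid = row["transcript_id"]
        seq = sequences[tid]
        cds_start, cds_end = int(row["cds_start"]), int(row["cds_end"])
        m = (cds_end - cds_start) // 3
        if m < 3:
            raise ValueError(f"{tid}: CDS must span at least 3 codons")
        cds = seq[cds_start:cds_end]
        codons = [cds[3 * i:3 * i + 3] for i in range(m)]
        # ribosome P-site on codon i (sense codons only); A-site codon is i+1
        for i in range(m - 1):
            key = codons[i + 1] if dwell_site == "A" else codons[i]
            w = dwell.get(key, stop_dwell)
            if i == 0:
                w *= start_enrichment
            tids.append(tid)
            psites.append(cds_start + 3 * i)
            weights.append(w)
    return (np.array(tids), np.array(psites, dtype=int),
            np.array(weights, dtype=float))


def simulate_footprints(
    sequences: Mapping[str, str],
    models: pd.DataFrame,
    config: SimulationConfig,
    samples: Sequence[str] | None = None,
    sample_dwell: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Place ribosome footprints on transcripts with known offsets and dwell.

    Each read's P-site is a CDS codon sampled with probability proportional to
    the dwell weight of the codon in ``config.dwell_site`` (default the
    A-site), with the start codon boosted ``start_codon_enrichment``-fold; a
    fraction ``utr_noise_fraction`` of P-sites lands uniformly in the UTRs.
    The 5' end is the P-site minus the per-length offset. ``sample_dwell``
    optionally overrides the dwell map per sample (e.g. tissue-specific
    pausing).
    """
    config.validate()
    lengths = sorted(L for L, p in config.read_length_probs.items() if p > 0)
    length_p = np.array([config.read_length_probs[L] for L in lengths])
    length_p = length_p / length_p.sum()
    for L in lengths:
        if config.offset_for_length(L) >= L:
            raise ValueError(
                f"P-site offset {config.offset_for_length(L)} must be smaller "
                f"than the read length {L}")
    offsets = np.array([config.offset_for_length(L) for L in lengths])
    tlen = models.set_index("transcript_id")["length"].to_dict()

    if samples is None:
        samples = config.sample_ids()
    rng = _rng(config, 4)
    base_dwell = config.resolved_dwell()

    # UTR positions for noise reads
    utr_tids, utr_pos = [], []
    for _, row in models.iterrows():
        tid = row["transcript_id"]
        for p in range(0, int(row["cds_start"])):
            utr_tids.append(tid)
            utr_pos.append(p)
        for p in range(int(row["cds_end"]), int(row["length"])):
            utr_tids.append(tid)
            utr_pos.append(p)
    utr_tids = np.array(utr_tids)
    utr_pos = np.array(utr_pos, dtype=int)

    frames = []
    truth_dwell = dict(base_dwell)
    for sample in samples:
        dwell = dict(base_dwell)
        if sample_dwell and sample in sample_dwell:
            dwell.update(sample_dwell[sample])
        tids, psites, weights = _position_table(
            sequences, models, dwell, config.dwell_site,
            config.stop_dwell, config.start_codon_enrichment)
        p = weights / weights.sum()

        n = config.reads_per_sample
        n_noise = int(round(config.utr_noise_fraction * n))
        n_cds = n - n_noise

        def draw(pool_tids, pool_pos, pool_p, k):
            """Sample k (transcript, psite, length) triples that fit."""
            out_t = np.empty(k, dtype=object)
            out_ps = np.empty(k, dtype=int)
            out_len = np.empty(k, dtype=int)
            todo = np.arange(k)
            for _ in range(100):
                idx = rng.choice(len(pool_pos), size=todo.size, p=pool_p)
                li = rng.choice(len(lengths), size=todo.size, p=length_p)
                t = pool_tids[idx]
                ps = pool_pos[idx]
                L = np.array(lengths)[li]
                off = offsets[li]
                five = ps - off
                limit = np.array([tlen[x] for x in t])
                ok = (five >= 0) & (five + L <= limit)
                sel = todo[ok]
                out_t[sel] = t[ok]
                out_ps[sel] = ps[ok]
                out_len[sel] = L[ok]
                todo = todo[~ok]
                if todo.size == 0:
                    return out_t, out_ps, out_len
            raise ValueError(
                "could not place all footprints; UTRs too short for the "
                "configured read lengths and offsets")

        t_cds, ps_cds, len_cds = draw(tids, psites, p, n_cds)
        parts = [(t_cds, ps_cds, len_cds)]
        if n_noise:
            if utr_pos.size == 0:
                raise ValueError("UTR noise requested but transcripts have no UTRs")
            utr_p = np.full(utr_pos.size, 1.0 / utr_pos.size)
            parts.append(draw(utr_tids, utr_pos, utr_p, n_noise))
        t_all = np.concatenate([a for a, _, _ in parts])
        ps_all = np.concatenate([b for _, b, _ in parts])
        len_all = np.concatenate([c for _, _, c in parts])
        off_all = np.array([config.offset_for_length(L) for L in len_all])
        frames.append(pd.DataFrame({
            "transcript_id": t_all,
            "five_prime_pos": ps_all - off_all,
            "length": len_all,
            "sample_id": sample,
        }))

    table = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        true_dwell=truth_dwell,
        true_offsets={L: config.offset_for_length(L) for L in lengths},
    )
    return table, truth


# ---------------------------------------------------------------------------
# matched RNA / RPF counts


def simulate_matched_counts(
    config: SimulationConfig,
) -> tuple[dict[str, CountMatrix], GroundTruth]:
    """Matched gene-level RNA-seq and Ribo-seq counts with planted classes.

    Returns ``{"rna": CountMatrix, "rpf": CountMatrix}`` sharing gene index
    and sample columns, plus the planted ground truth. RNA-only genes shift
    both assays equally (no TE change), Ribo-only genes shift RPF only, and
    'both' genes shift the assays by different amounts.
    """
    if config.planted_classes is None:
        raise ValueError("planted_classes must be defined")
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    effects = config.planted_classes
    genes = list(effects)
    rng = _rng(config, 5)
    base = rng.lognormal(config.gene_log_mean, config.gene_log_sd,
                         size=len(genes))
    # baseline translational efficiency varies moderately across genes
    te_base = rng.lognormal(0.0, 0.25, size=len(genes))
    lfc_rna = np.array([effects[g].lfc_rna for g in genes])
    lfc_rpf = np.array([effects[g].lfc_rpf for g in genes])

    rna_cols, rpf_cols = {}, {}
    for ci, cond in enumerate(config.conditions):
        rna_mean = base * (2.0 ** lfc_rna if ci == 1 else 1.0)
        rpf_mean = base * te_base * (2.0 ** lfc_rpf if ci == 1 else 1.0)
        for r in range(config.n_replicates_per_condition):
            # modest library-depth variation; size factors must absorb it
            depth_rna = rng.lognormal(0.0, 0.15)
            depth_rpf = rng.lognormal(0.0, 0.15)
            sid = f"{cond}_{r + 1}"
            rna_cols[sid] = _nb_sample(rng, rna_mean * depth_rna,
                                       config.nb_dispersion)
            rpf_cols[sid] = _nb_sample(rng, rpf_mean * depth_rpf,
                                       config.nb_dispersion)
    idx = pd.Index(genes, name="feature")
    truth = GroundTruth(
        true_class={g: effects[g].kind for g in genes},
        planted_effects=dict(effects),
    )
    return (
        {
            "rna": CountMatrix(pd.DataFrame(rna_cols, index=idx), level="gene"),
            "rpf": CountMatrix(pd.DataFrame(rpf_cols, index=idx), level="gene"),
        },
        truth,
    )


# ---------------------------------------------------------------------------
# direct codon-level occupancy counts (for calibration studies)


def simulate_occupancy_counts(
    config: SimulationConfig,
    dwell: Mapping[str, float] | None = None,
    samples: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """NB codon-level A-site count tables drawn directly from dwell weights.

    A shortcut around full footprint placement for calibration experiments
    that need many replicate datasets: per sample, codon counts are NB draws
    with means proportional to the dwell weights, totalling
    ``reads_per_sample`` in expectation.
    """
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    dwell = dict(dwell) if dwell is not None else config.resolved_dwell()
    codons = sorted(dwell)
    w = np.array([dwell[c] for c in codons], dtype=float)
    mean = config.reads_per_sample * w / w.sum()
    if samples is None:
        samples = config.sample_ids()
    rng = _rng(config, 6)
    cols = {s: _nb_sample(rng, mean, config.nb_dispersion) for s in samples}
    counts = pd.DataFrame(cols, index=pd.Index(codons, name="feature"))
    return counts, GroundTruth(true_dwell=dict(dwell))
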