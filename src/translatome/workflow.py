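"""End-to-end orchestration: configuration, stage sequencing and manifests.

``run_pipeline`` wires the stages together on a synthetic dataset: tRNA
reference construction and quantification, differential expression at three
hierarchy levels, footprint QC, codon occupancy and tissue enrichment,
interaction-model regulatory classification, and the RSCU-vs-tRNA
correlation. Every output is a TSV next to a JSON manifest recording the
package version, seed, parameters and stage outputs; when ground truth is
available the classification confusion matrix is logged and stored.

All randomness flows from the single seed in the configuration; generators
derive independent streams from it, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._codons import CODON_TO_AA3, codon_to_anticodon
from .diffexp import run_pairwise_de
from .io import write_fasta, write_footprints, write_transcript_models
from .occupancy import (codon_background, codon_occupancy, log2_mean_center,
                        relative_enrichment, site_codons, welch_t_test)
from .qc import (annotate_psites, estimate_psite_offsets,
                 frame_fractions_by_length, read_length_distribution,
                 region_fractions)
from .reference import (aggregate_counts, assign_reads, collapse_identical,
                        compartment_fractions, cpm_normalize)
from .regulation import (class_proportions, classify_regulation, delta_te_fit,
                         rpkm, te_vs_deltate_check, translational_efficiency)
from .synthetic import (SimulationConfig, generate_transcriptome,
                        generate_trna_geneset, make_planted_classes,
                        simulate_footprints, simulate_matched_counts,
                        simulate_trna_counts)
from .usage import (average_over_genes, correlate_rscu_trna, extract_cds,
                    family_percent, rscu)

logger = logging.getLogger("translatome")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and the embedded simulation settings for a pipeline run."""

    seed: int = 0
    q: float = 0.05                # FDR threshold for all significance calls
    min_read_length: int = 15      # tRNA reads shorter than this are discarded
    min_reads_per_length: int = 50  # per-length support for offset estimation
    pseudocount: float = 1.0       # inside log2(CPM + pseudocount)
    offset_bounds: tuple[int, int] = (10, 14)  # plausible P-site offsets, nt
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.min_read_length < 1:
            raise ValueError("min_read_length must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.offset_bounds[0] > self.offset_bounds[1]:
            raise ValueError("offset_bounds must be (low, high)")
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        sim = d["simulation"]
        if sim["planted_classes"] is not None:
            sim["planted_classes"] = {
                g: dataclasses.asdict(e)
                for g, e in self.simulation.planted_classes.items()
            }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.pop("simulation", {})
        from .synthetic import PlantedEffect
        if sim.get("planted_classes") is not None:
            sim["planted_classes"] = {
                g: PlantedEffect(**e) for g, e in sim["planted_classes"].items()
            }
        for key in ("cds_codons_range",):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(sim[key])
        if "conditions" in sim:
            sim["conditions"] = tuple(sim["conditions"])
        if "psite_offset" in sim and isinstance(sim["psite_offset"], dict):
            sim["psite_offset"] = {int(k): int(v)
                                   for k, v in sim["psite_offset"].items()}
        if "read_length_probs" in sim:
            sim["read_length_probs"] = {int(k): float(v)
                                        for k, v in sim["read_length_probs"].items()}
        d["offset_bounds"] = tuple(d.get("offset_bounds", (10, 14)))
        return cls(simulation=SimulationConfig(**sim), **d)


def _write(df: pd.DataFrame, path: Path, outputs: dict, key: str,
           **kwargs) -> None:
    df.to_csv(path, sep="\t", **kwargs)
    outputs[key] = path.name


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a synthetic dataset; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    outputs: dict[str, str] = {}
    manifest: dict = {
        "package": "translatome",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "q": config.q,
            "min_read_length": config.min_read_length,
            "min_reads_per_length": config.min_reads_per_length,
            "pseudocount": config.pseudocount,
            "offset_bounds": list(config.offset_bounds),
        },
        "outputs": outputs,
    }

    current_stage = {"name": "setup"}

    def stage(name):
        current_stage["name"] = name
        logger.info("stage %s", name)

    try:
        # ------------------------------------------------------- tRNA stages
        stage("trna-reference")
        genes = generate_trna_geneset(sim)
        write_fasta(genes, outdir / "trna_genes.fasta")
        outputs["trna_genes"] = "trna_genes.fasta"
        reference = collapse_identical(genes)
        write_fasta({r.name: r.sequence for r in reference.records},
                    outdir / "trna_reference.fasta")
        outputs["trna_reference"] = "trna_reference.fasta"
        _write(reference.to_table(), outdir / "trna_reference.tsv",
               outputs, "trna_reference_table", index=False)
        manifest["n_trna_genes"] = len(genes)
        manifest["n_trna_collapsed"] = len(reference)

        # exercise exact-match read assignment on reads cut from the genes
        stage("trna-assign")
        read_rng = np.random.default_rng(np.random.SeedSequence([sim.seed, 7]))
        reads = []
        names = list(genes)
        for _ in range(300):
            name = names[read_rng.integers(len(names))]
            seq = genes[name]
            trunc = int(read_rng.integers(10, len(seq) + 1))
            reads.append(seq[:trunc])
        assigned = assign_reads(reads, reference,
                                min_len=config.min_read_length)
        _write(assigned.data, outdir / "trna_assigned_counts.tsv",
               outputs, "trna_assigned_counts", index_label="feature")

        stage("trna-count")
        trna_counts, trna_truth = simulate_trna_counts(reference, sim)
        _write(trna_counts.data, outdir / "trna_counts.tsv",
               outputs, "trna_counts", index_label="feature")
        _write(cpm_normalize(trna_counts), outdir / "trna_cpm.tsv",
               outputs, "trna_cpm", index_label="feature")
        comp = compartment_fractions(trna_counts, reference)
        _write(comp, outdir / "trna_compartments.tsv",
               outputs, "trna_compartments")

        stage("trna-de")
        labels = [s.rsplit("_", 1)[0] for s in trna_counts.samples]
        for level in ("isodecoder", "anticodon", "amino_acid"):
            de = run_pairwise_de(trna_counts, labels, level=level, q=config.q)
            _write(de, outdir / f"trna_de_{level}.tsv",
                   outputs, f"trna_de_{level}")

        # ------------------------------------------------------- ribo stages
        stage("ribo-simulate")
        sequences, models = generate_transcriptome(sim)
        write_fasta(sequences, outdir / "transcripts.fasta")
        outputs["transcripts"] = "transcripts.fasta"
        write_transcript_models(models, outdir / "transcript_models.tsv")
        outputs["transcript_models"] = "transcript_models.tsv"
        footprints, fp_truth = simulate_footprints(sequences, models, sim)
        write_footprints(footprints, outdir / "footprints.tsv")
        outputs["footprints"] = "footprints.tsv"

        stage("ribo-qc")
        _write(read_length_distribution(footprints).to_frame(),
               outdir / "read_length_distribution.tsv", outputs,
               "read_length_distribution")
        offsets = estimate_psite_offsets(
            footprints, models,
            min_reads_per_length=config.min_reads_per_length)
        lo, hi = config.offset_bounds
        outside = {L: o for L, o in offsets.items() if not lo <= o <= hi}
        if outside:
            logger.warning("offsets outside expected bounds: %s", outside)
        _write(pd.Series(offsets, name="offset").rename_axis("length").to_frame(),
               outdir / "psite_offsets.tsv", outputs, "psite_offsets")
        ann = annotate_psites(footprints, offsets, models)
        _write(ann, outdir / "psite_annotations.tsv",
               outputs, "psite_annotations", index=False)
        _write(region_fractions(ann), outdir / "region_fractions.tsv",
               outputs, "region_fractions")
        _write(frame_fractions_by_length(ann), outdir / "frame_fractions.tsv",
               outputs, "frame_fractions")

        stage("occupancy")
        samples = sorted(ann["sample_id"].unique())
        norm_cols = {}
        for s in samples:
            sub = ann[ann["sample_id"] == s]
            codons = site_codons(sub, models, sequences, site="A")
            bg = codon_background(models, sequences,
                                  set(sub["transcript_id"]))
            prof = codon_occupancy(codons.value_counts().to_dict(), bg,
                                   site="A", sample_id=s)
            norm_cols[s] = pd.Series(prof.normalized)
        occ = pd.DataFrame(norm_cols).fillna(0.0).rename_axis("codon")
        _write(occ, outdir / "asite_occupancy.tsv", outputs, "asite_occupancy")
        _write(log2_mean_center(occ.T + config.pseudocount),
               outdir / "asite_occupancy_log2centered.tsv",
               outputs, "asite_occupancy_log2centered")

        stage("enrich")
        cond_a, cond_b = sim.conditions
        counts_by_cond = {c: {} for c in sim.conditions}
        for s in samples:
            sub = ann[ann["sample_id"] == s]
            codons = site_codons(sub, models, sequences, site="A")
            counts_by_cond[s.rsplit("_", 1)[0]][s] = codons.value_counts()
        ca = pd.DataFrame(counts_by_cond[cond_a]).fillna(0.0)
        cb = pd.DataFrame(counts_by_cond[cond_b]).fillna(0.0)
        enr = relative_enrichment(ca, cb, pseudocount=config.pseudocount)
        welch = []
        la = np.log2(ca * 1e6 / ca.sum(axis=0) + config.pseudocount)
        lb = np.log2(cb * 1e6 / cb.sum(axis=0) + config.pseudocount)
        for codon in enr.index:
            t, df, p = welch_t_test(la.loc[codon], lb.loc[codon])
            welch.append({"codon": codon, "t": t, "df": df, "pvalue": p})
        enr = enr.join(pd.DataFrame(welch).set_index("codon"))
        enr["significant"] = enr["pvalue"] <= config.q
        _write(enr, outdir / "asite_enrichment.tsv", outputs,
               "asite_enrichment")

        # ------------------------------------------------ integration stages
        stage("deltate")
        sim_m = sim
        if sim_m.planted_classes is None:
            plant_rng = np.random.default_rng(
                np.random.SeedSequence([sim.seed, 8]))
            sim_m = dataclasses.replace(
                sim, planted_classes=make_planted_classes(
                    {"none": 40, "rna_only": 20, "ribo_only": 20, "both": 20},
                    magnitude=2.0, rng=plant_rng))
        matched, matched_truth = simulate_matched_counts(sim_m)
        for assay in ("rna", "rpf"):
            _write(matched[assay].data, outdir / f"{assay}_counts.tsv",
                   outputs, f"{assay}_counts", index_label="feature")
        cond_labels = [s.rsplit("_", 1)[0] for s in matched["rna"].samples]
        effects = delta_te_fit(matched["rna"], matched["rpf"], cond_labels)
        results = classify_regulation(effects, q=config.q)
        _write(results, outdir / "regulatory_classes.tsv",
               outputs, "regulatory_classes")
        props = class_proportions(results)
        _write(props.rename("percent").to_frame(),
               outdir / "class_proportions.tsv", outputs, "class_proportions")

        truth_series = pd.Series(matched_truth.true_class).map({
            "none": "none", "rna_only": "RNA", "ribo_only": "Ribo",
            "both": "Ribo&RNA"})
        confusion = pd.crosstab(truth_series,
                                results["regulatory_class"],
                                rownames=["truth"], colnames=["called"])
        manifest["classification_confusion"] = {
            str(t): {str(c): int(v) for c, v in row.items()}
            for t, row in confusion.iterrows()
        }
        logger.info("classification confusion matrix:\n%s", confusion)

        # TE and its agreement with the interaction effect
        len_rng = np.random.default_rng(np.random.SeedSequence([sim.seed, 9]))
        gene_lengths = pd.Series(
            len_rng.integers(500, 3001, size=len(matched["rna"].features)),
            index=matched["rna"].features, name="length_nt")
        te = translational_efficiency(
            rpkm(matched["rpf"], gene_lengths), rpkm(matched["rna"], gene_lengths))
        _write(te, outdir / "translational_efficiency.tsv",
               outputs, "translational_efficiency", index_label="feature")
        manifest["te_vs_deltate"] = te_vs_deltate_check(te, effects, cond_labels)

        stage("rscu")
        cds = extract_cds(sequences, models)
        per_gene = [rscu(c) for c in cds.values()]
        avg = average_over_genes(per_gene)
        _write(avg, outdir / "rscu.tsv", outputs, "rscu",
               index_label="codon")
        rscu_pct = family_percent(avg["rscu"])

        stage("correlate")
        anticodon_counts = aggregate_counts(trna_counts, "anticodon")
        cyto = anticodon_counts.data.loc[
            [f for f in anticodon_counts.features if not f.startswith("MT-")]]
        cpm = cpm_normalize(cyto)
        mean_cpm = cpm.mean(axis=1)
        mean_cpm.index = [f.rsplit("-", 1)[1] for f in mean_cpm.index]
        trna_group = {ac: CODON_TO_AA3.get(codon_to_anticodon(ac), "SeC")
                      for ac in mean_cpm.index}
        trna_pct = family_percent(mean_cpm, grouping=trna_group)
        corr = correlate_rscu_trna(rscu_pct, trna_pct)
        manifest["rscu_trna_correlation"] = corr
        _write(pd.DataFrame([corr]), outdir / "rscu_trna_correlation.tsv",
               outputs, "rscu_trna_correlation", index=False)
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {current_stage['name']!r}: {err}"
        ) from err

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = "manifest.json"
    return manifest
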