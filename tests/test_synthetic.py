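"""Generator correctness: determinism, arithmetic, planted-signal recovery."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from translatome.io import write_fasta
from translatome.synthetic import (PlantedEffect, SimulationConfig,
                                   default_cyto_anticodons,
                                   generate_transcriptome,
                                   generate_trna_geneset,
                                   make_planted_classes, simulate_footprints,
                                   simulate_matched_counts,
                                   simulate_trna_counts)


class TestTranscriptome:
    def test_length_arithmetic(self):
        cfg = SimulationConfig(seed=1, n_genes=1, cds_codons_range=(10, 10),
                               utr5_len=30, utr3_len=20)
        seqs, models = generate_transcriptome(cfg)
        (seq,) = seqs.values()
        assert len(seq) == 30 + 30 + 20
        row = models.iloc[0]
        assert (row["cds_start"], row["cds_end"]) == (30, 60)
        cds = seq[30:60]
        assert cds.startswith("ATG")
        assert cds[-3:] in ("TAA", "TAG", "TGA")

    def test_deterministic_fasta_bytes(self, tmp_path):
        cfg = SimulationConfig(seed=42, n_genes=5)
        for name in ("a.fasta", "b.fasta"):
            seqs, _ = generate_transcriptome(cfg)
            write_fasta(seqs, tmp_path / name)
        assert (tmp_path / "a.fasta").read_bytes() == \
            (tmp_path / "b.fasta").read_bytes()

    def test_codon_weights_respected(self):
        weights = {c: 1e-6 for c in SimulationConfig().resolved_dwell()}
        weights["GCT"] = 1.0
        cfg = SimulationConfig(seed=2, n_genes=10, cds_codons_range=(102, 102),
                               codon_weights=weights)
        seqs, models = generate_transcriptome(cfg)
        internal = []
        for (tid, seq), (_, row) in zip(seqs.items(), models.iterrows()):
            cds = seq[row["cds_start"]:row["cds_end"]]
            internal += [cds[i:i + 3] for i in range(3, len(cds) - 3, 3)]
        assert len(internal) == 1000
        frac_gct = sum(c == "GCT" for c in internal) / len(internal)
        assert frac_gct >= 0.95

    def test_min_codons_error(self):
        cfg = SimulationConfig(cds_codons_range=(1, 5))
        with pytest.raises(ValueError, match="start"):
            generate_transcriptome(cfg)


class TestTrnaGeneset:
    def test_identical_copy_pair_present(self):
        genes = generate_trna_geneset(SimulationConfig(seed=3))
        by_seq = Counter(genes.values())
        dup_seqs = [s for s, n in by_seq.items() if n > 1]
        assert dup_seqs, "expected at least one pair of identical sequences"

    def test_default_anticodon_count_is_54(self):
        genes = generate_trna_geneset(SimulationConfig(seed=3))
        cyto_acs = {name.split("-")[2] + "/" + name.split("-")[1]
                    for name in genes if not name.startswith("MT-")}
        assert len(cyto_acs) == 54
        assert len(default_cyto_anticodons()) == 54

    def test_anticodon_embedded_at_mock_position(self):
        genes = generate_trna_geneset(SimulationConfig(seed=3))
        for name, seq in genes.items():
            ac = name.replace("MT-", "").split("-")[2]
            assert seq[33:36] == ac

    def test_empty_mito_request(self):
        genes = generate_trna_geneset(
            SimulationConfig(seed=3, mito_anticodons=[]))
        assert not any(n.startswith("MT-") for n in genes)


class TestTrnaCounts:
    def test_no_effect_means_match_across_conditions(self):
        cfg = SimulationConfig(seed=4, nb_dispersion=1e-6,
                               n_replicates_per_condition=50,
                               trna_log_mean=np.log(5000), trna_log_sd=0.0)
        counts, _ = simulate_trna_counts([f"tRNA-Ala-AGC-{i}-1"
                                          for i in range(1, 11)], cfg)
        a = counts.data.filter(like="tissueA").mean(axis=1)
        b = counts.data.filter(like="tissueB").mean(axis=1)
        assert ((b / a).between(0.95, 1.05)).all()

    def test_planted_lfc_recovered_in_mean_ratio(self):
        cfg = SimulationConfig(seed=5, nb_dispersion=0.05,
                               n_replicates_per_condition=50,
                               trna_log_mean=np.log(500), trna_log_sd=0.0,
                               trna_lfc={"tRNA-Ala-AGC-1-1": 2.0})
        counts, truth = simulate_trna_counts(
            ["tRNA-Ala-AGC-1-1", "tRNA-Gly-GCC-1-1"], cfg)
        row = counts.data.loc["tRNA-Ala-AGC-1-1"]
        ratio = row.filter(like="tissueB").mean() / \
            row.filter(like="tissueA").mean()
        assert 3.0 <= ratio <= 5.3
        assert truth.true_trna_lfc["tRNA-Ala-AGC-1-1"] == 2.0

    def test_invalid_requests_raise(self):
        with pytest.raises(ValueError, match="replicate"):
            simulate_trna_counts(["tRNA-Ala-AGC-1-1"],
                                 SimulationConfig(n_replicates_per_condition=0))
        with pytest.raises(ValueError, match="dispersion"):
            simulate_trna_counts(["tRNA-Ala-AGC-1-1"],
                                 SimulationConfig(nb_dispersion=0.0))
        with pytest.raises(ValueError, match="empty"):
            simulate_trna_counts([], SimulationConfig())


class TestFootprints:
    def test_conservation_and_pure_cds_placement(self, small_transcriptome):
        seqs, models = small_transcriptome
        cfg = SimulationConfig(seed=6, utr_noise_fraction=0.0,
                               reads_per_sample=2000)
        fp, _ = simulate_footprints(seqs, models, cfg, samples=["S1"])
        assert len(fp) == 2000
        m = models.set_index("transcript_id")
        psite = fp["five_prime_pos"] + fp["length"].map(
            cfg.offset_for_length)
        start = fp["transcript_id"].map(m["cds_start"])
        end = fp["transcript_id"].map(m["cds_end"])
        assert ((psite >= start) & (psite < end)).all()

    def test_fixed_offset_five_prime_ends(self, small_transcriptome):
        seqs, models = small_transcriptome
        cfg = SimulationConfig(seed=7, psite_offset=12,
                               read_length_probs={30: 1.0},
                               utr_noise_fraction=0.0, reads_per_sample=500)
        fp, truth = simulate_footprints(seqs, models, cfg, samples=["S1"])
        assert (fp["length"] == 30).all()
        assert truth.true_offsets == {30: 12}
        m = models.set_index("transcript_id")
        psite = fp["five_prime_pos"] + 12
        rel = psite - fp["transcript_id"].map(m["cds_start"])
        assert (rel % 3 == 0).all()

    def test_offset_not_smaller_than_read_length_raises(
            self, small_transcriptome):
        seqs, models = small_transcriptome
        cfg = SimulationConfig(psite_offset=30, read_length_probs={30: 1.0})
        with pytest.raises(ValueError, match="offset"):
            simulate_footprints(seqs, models, cfg, samples=["S1"])

    def test_dwell_sampling_matches_multinomial_oracle(self):
        # 3-codon toy CDS: ribosome positions i=0,1 weighted by the A-site
        # codon (GAA, then stop) and the start-codon boost on i=0
        seqs = {"T1": "A" * 20 + "ATGGAATAA" + "C" * 20}
        models = __import__("pandas").DataFrame([
            {"transcript_id": "T1", "length": 49,
             "cds_start": 20, "cds_end": 29}])
        cfg = SimulationConfig(seed=8, utr_noise_fraction=0.0,
                               start_codon_enrichment=10.0, stop_dwell=1.0,
                               reads_per_sample=10_000)
        fp, _ = simulate_footprints(seqs, models, cfg, samples=["S1"])
        psite = fp["five_prime_pos"] + fp["length"].map(cfg.offset_for_length)
        observed = psite.value_counts().reindex([20, 23], fill_value=0)
        expected = np.array([10.0, 1.0]) / 11.0 * len(fp)
        assert stats.chisquare(observed, expected).pvalue > 0.001

    def test_asite_dwell_share_matches_multinomial(self):
        dwell = {c: 1.0 for c in SimulationConfig().resolved_dwell()}
        dwell["GAA"] = 10.0
        cfg = SimulationConfig(seed=9, n_genes=30, dwell_weights=dwell,
                               start_codon_enrichment=1.0, stop_dwell=1.0,
                               utr_noise_fraction=0.0,
                               reads_per_sample=100_000)
        seqs, models = generate_transcriptome(cfg)
        fp, _ = simulate_footprints(seqs, models, cfg, samples=["S1"])
        # exact expected share from the placement weights themselves
        w_gaa = w_tot = 0.0
        for _, row in models.iterrows():
            cds = seqs[row["transcript_id"]][row["cds_start"]:row["cds_end"]]
            codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
            for i in range(len(codons) - 1):
                w = dwell.get(codons[i + 1], 1.0)
                w_tot += w
                if codons[i + 1] == "GAA":
                    w_gaa += w
        p = w_gaa / w_tot
        psite = fp["five_prime_pos"] + fp["length"].map(cfg.offset_for_length)
        acod = [seqs[t][a:a + 3]
                for t, a in zip(fp["transcript_id"], psite + 3)]
        share = sum(c == "GAA" for c in acod) / len(acod)
        sigma = np.sqrt(p * (1 - p) / len(fp))
        assert abs(share - p) <= 3 * sigma


class TestMatchedCounts:
    def _config(self, effects, **kw):
        return SimulationConfig(seed=10, planted_classes=effects,
                                n_replicates_per_condition=10,
                                gene_log_mean=np.log(2000), gene_log_sd=0.0,
                                **kw)

    def test_class_none_means_equal(self):
        cfg = self._config({"G1": PlantedEffect("none")}, nb_dispersion=1e-6)
        matched, _ = simulate_matched_counts(cfg)
        for assay in ("rna", "rpf"):
            row = matched[assay].data.loc["G1"]
            ratio = row.filter(like="tissueB").mean() / \
                row.filter(like="tissueA").mean()
            assert 0.8 <= ratio <= 1.25  # depth noise only

    def test_ribo_only_shifts_rpf_not_rna(self):
        cfg = self._config({"G1": PlantedEffect("ribo_only", 0.0, 2.0)},
                           nb_dispersion=1e-6)
        matched, truth = simulate_matched_counts(cfg)
        rna = matched["rna"].data.loc["G1"]
        rpf = matched["rpf"].data.loc["G1"]
        rna_ratio = rna.filter(like="tissueB").mean() / \
            rna.filter(like="tissueA").mean()
        rpf_ratio = rpf.filter(like="tissueB").mean() / \
            rpf.filter(like="tissueA").mean()
        assert 0.8 <= rna_ratio <= 1.25
        assert 3.0 <= rpf_ratio <= 5.3
        assert truth.true_class["G1"] == "ribo_only"

    def test_rna_only_preserves_te(self):
        cfg = self._config({"G1": PlantedEffect("rna_only", 1.0, 1.0)},
                           nb_dispersion=1e-6)
        matched, _ = simulate_matched_counts(cfg)
        te_ratio = 1.0
        for assay, power in (("rpf", 1), ("rna", -1)):
            row = matched[assay].data.loc["G1"]
            te_ratio *= (row.filter(like="tissueB").mean() /
                         row.filter(like="tissueA").mean()) ** power
        assert 0.7 <= te_ratio <= 1.4

    def test_planted_effect_validation(self):
        with pytest.raises(ValueError):
            PlantedEffect("rna_only", 1.0, 2.0)
        with pytest.raises(ValueError):
            PlantedEffect("ribo_only", 1.0, 2.0)
        with pytest.raises(ValueError):
            PlantedEffect("wobbly")

    def test_make_planted_classes_counts_and_magnitudes(self):
        eff = make_planted_classes({"none": 3, "rna_only": 4,
                                    "ribo_only": 5, "both": 6},
                                   magnitude=2.0, rng=0)
        kinds = Counter(e.kind for e in eff.values())
        assert kinds == {"none": 3, "rna_only": 4, "ribo_only": 5, "both": 6}
        for e in eff.values():
            if e.kind == "ribo_only":
                assert abs(e.lfc_te) == 2.0
            if e.kind == "both":
                assert abs(e.lfc_rna) == 2.0 and abs(e.lfc_te) == 2.0


def test_config_invariant_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        SimulationConfig(read_length_probs={30: 0.5}).validate()
    bad_dwell = {"GCT": 1.0}
    with pytest.raises(ValueError, match="61 sense"):
        SimulationConfig(dwell_weights=bad_dwell).validate()
    neg = SimulationConfig().resolved_dwell()
    neg["GCT"] = -1.0
    with pytest.raises(ValueError, match="positive"):
        SimulationConfig(dwell_weights=neg).validate()
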