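"""tRNA nomenclature, reference collapsing, read assignment, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from translatome.io import CountMatrix
from translatome.reference import (aggregate_counts, assign_reads,
                                   collapse_identical, compartment_fractions,
                                   cpm_normalize, parse_trna_name)


class TestParseName:
    @pytest.mark.parametrize("name, expected", [
        ("tRNA-Leu-TAA-4-1", ("Leu", "TAA", 4, 1, "cytoplasmic")),
        ("tRNA-Arg-TCG-3-1", ("Arg", "TCG", 3, 1, "cytoplasmic")),
        ("MT-tRNA-Ile-GAT", ("Ile", "GAT", None, None, "mitochondrial")),
        ("tRNA-iMet-CAT-1-1", ("iMet", "CAT", 1, 1, "cytoplasmic")),
        ("tRNA-SeC-TCA-1-1", ("SeC", "TCA", 1, 1, "cytoplasmic")),
    ])
    def test_examples(self, name, expected):
        assert parse_trna_name(name) == expected

    @pytest.mark.parametrize("bad", ["foo", "", "tRNA-Ala-AGC",
                                     "tRNA-Ala-XYZ-1-1"])
    def test_unparseable_raises_with_name(self, bad):
        with pytest.raises(ValueError):
            parse_trna_name(bad)
        if bad:
            with pytest.raises(ValueError, match="foo") if bad == "foo" \
                    else pytest.raises(ValueError):
                parse_trna_name(bad)


class TestCollapse:
    def test_identical_pair_collapsed(self):
        recs = {
            "tRNA-Ala-AGC-1-1": "ACGTACGTACGT",
            "tRNA-Ala-AGC-2-1": "ACGTACGTACGT",
            "tRNA-Gly-GCC-1-1": "TTTTACGTACGT",
        }
        ref = collapse_identical(recs)
        assert len(ref) == 2
        rec = ref.by_name()["tRNA-Ala-AGC-1-1"]
        assert sorted(rec.members) == ["tRNA-Ala-AGC-1-1", "tRNA-Ala-AGC-2-1"]

    def test_all_distinct_is_identity(self):
        recs = {"tRNA-Ala-AGC-1-1": "AAAA", "tRNA-Gly-GCC-1-1": "CCCC"}
        ref = collapse_identical(recs)
        assert {r.name for r in ref.records} == set(recs)
        assert all(len(r.members) == 1 for r in ref.records)

    def test_rna_alphabet_input_collapses_with_dna(self):
        ref = collapse_identical({"tRNA-Ala-AGC-1-1": "ACGU",
                                  "tRNA-Ala-AGC-2-1": "ACGT"})
        assert len(ref) == 1

    def test_conflicting_anticodons_raise(self):
        with pytest.raises(ValueError, match="conflicting"):
            collapse_identical({"tRNA-Ala-AGC-1-1": "ACGT",
                                "tRNA-Ala-TGC-1-1": "ACGT"})

    def test_order_insensitive_and_idempotent(self):
        items = [("tRNA-Ala-AGC-2-1", "ACGTAA"), ("tRNA-Ala-AGC-1-1", "ACGTAA"),
                 ("tRNA-Gly-GCC-1-1", "GGGTAA")]
        a = collapse_identical(items)
        b = collapse_identical(items[::-1])
        assert [(r.name, r.sequence, r.members) for r in a.records] == \
            [(r.name, r.sequence, r.members) for r in b.records]
        again = collapse_identical({r.name: r.sequence for r in a.records})
        assert len(again) == len(a)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(1, 8), st.sampled_from(["AAAA", "CCCC", "GGGG",
                                                      "TTTT", "ACGT"])),
        min_size=1, max_size=8, unique_by=lambda t: t[0]))
    def test_members_partition_property(self, items):
        recs = {f"tRNA-Ala-AGC-{i}-1": seq for i, seq in items}
        ref = collapse_identical(recs)
        members = [m for r in ref.records for m in r.members]
        assert sorted(members) == sorted(recs)  # every input name exactly once
        assert len({r.sequence for r in ref.records}) == len(ref.records)
        for r in ref.records:
            assert r.name == min(r.members)


@pytest.fixture()
def two_record_reference():
    return collapse_identical({
        "tRNA-Ala-AGC-1-1": "AAAACGTACGTACGTTTTT",
        "tRNA-Gly-GCC-1-1": "AAAACGTACGTACGTCCCC",
        "MT-tRNA-Ile-GAT": "GGGGGTTTTTCCCCCAAAAA",
    })


class TestAssignReads:
    def test_full_length_unique_read(self, two_record_reference):
        cm = assign_reads(["AAAACGTACGTACGTTTTT"], two_record_reference)
        assert cm.data.loc["tRNA-Ala-AGC-1-1"].iloc[0] == 1.0
        assert cm.data.sum().sum() == 1.0

    def test_short_read_discarded(self, two_record_reference):
        cm = assign_reads(["AAAACGTACGTACG"], two_record_reference, min_len=15)
        assert cm.data.sum().sum() == 0.0

    def test_multimapping_read_split_fractionally(self, two_record_reference):
        cm = assign_reads(["AAAACGTACGTACGT"], two_record_reference)
        assert cm.data.loc["tRNA-Ala-AGC-1-1"].iloc[0] == pytest.approx(0.5)
        assert cm.data.loc["tRNA-Gly-GCC-1-1"].iloc[0] == pytest.approx(0.5)

    def test_mass_conservation_when_all_match(self, two_record_reference):
        reads = ["AAAACGTACGTACGTTTTT", "AAAACGTACGTACGTCCCC",
                 "GGGGGTTTTTCCCCC", "AAAACGTACGTACGT"]
        cm = assign_reads(reads, two_record_reference)
        assert cm.data.sum().sum() == pytest.approx(len(reads))

    def test_empty_reference_raises(self):
        from translatome.reference import TrnaReference
        with pytest.raises(ValueError, match="empty"):
            assign_reads(["ACGT"], TrnaReference([]))


class TestAggregation:
    @pytest.fixture()
    def isodecoder_counts(self):
        data = pd.DataFrame(
            {"s1": [10.0, 5.0, 5.0, 7.0], "s2": [1.0, 2.0, 3.0, 4.0]},
            index=pd.Index(["tRNA-Arg-TCG-1-1", "tRNA-Arg-TCG-3-1",
                            "tRNA-Arg-ACG-1-1", "MT-tRNA-Ile-GAT"],
                           name="feature"))
        return CountMatrix(data, level="isodecoder")

    def test_anticodon_sums(self, isodecoder_counts):
        agg = aggregate_counts(isodecoder_counts, "anticodon")
        assert agg.data.loc["Arg-TCG", "s1"] == 15.0
        assert agg.data.loc["Arg-ACG", "s1"] == 5.0
        assert agg.data.loc["MT-Ile-GAT", "s1"] == 7.0

    def test_amino_acid_sums(self, isodecoder_counts):
        agg = aggregate_counts(isodecoder_counts, "amino_acid")
        assert agg.data.loc["Arg", "s1"] == 20.0
        assert agg.data.loc["MT-Ile", "s1"] == 7.0

    def test_column_totals_conserved_at_every_level(self, isodecoder_counts):
        for level in ("anticodon", "amino_acid"):
            agg = aggregate_counts(isodecoder_counts, level)
            pd.testing.assert_series_equal(agg.data.sum(),
                                           isodecoder_counts.data.sum())

    def test_single_isodecoder_identity(self):
        cm = CountMatrix(pd.DataFrame({"s1": [3.0]},
                                      index=pd.Index(["tRNA-Arg-TCG-1-1"],
                                                     name="feature")),
                         level="isodecoder")
        agg = aggregate_counts(cm, "anticodon")
        assert agg.data.iloc[0, 0] == 3.0
        assert len(agg.data) == 1

    def test_unknown_level_raises(self, isodecoder_counts):
        with pytest.raises(ValueError):
            aggregate_counts(isodecoder_counts, "codon")


class TestCpmAndCompartments:
    def test_cpm_values(self):
        df = pd.DataFrame({"s1": [25.0, 75.0]}, index=["a", "b"])
        out = cpm_normalize(df)
        assert out.loc["a", "s1"] == pytest.approx(250_000)
        assert out.loc["b", "s1"] == pytest.approx(750_000)

    def test_cpm_single_feature(self):
        df = pd.DataFrame({"s1": [50.0]}, index=["a"])
        assert cpm_normalize(df).iloc[0, 0] == pytest.approx(1e6)

    def test_cpm_zero_column_raises(self):
        df = pd.DataFrame({"s1": [0.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="zero column"):
            cpm_normalize(df)

    def test_cpm_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.integers(1, 100, (20, 4)).astype(float))
        np.testing.assert_allclose(cpm_normalize(df).sum(), 1e6, rtol=1e-6)

    def test_compartment_percentages(self):
        data = pd.DataFrame({"s1": [90.0, 10.0], "s2": [50.0, 0.0]},
                            index=pd.Index(["tRNA-Ala-AGC-1-1",
                                            "MT-tRNA-Ile-GAT"],
                                           name="feature"))
        out = compartment_fractions(CountMatrix(data, level="isodecoder"))
        assert out.loc["s1", "cytoplasmic_pct"] == pytest.approx(90.0)
        assert out.loc["s1", "mitochondrial_pct"] == pytest.approx(10.0)
        assert out.loc["s2", "cytoplasmic_pct"] == pytest.approx(100.0)
        np.testing.assert_allclose(out.sum(axis=1), 100.0)
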