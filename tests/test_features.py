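"""Feature engineering: GO log-ratio, AAindex lookups, sequence profile, omega."""

import io as _io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pathoforest.features import (
    FeatureBuilder,
    FeatureTable,
    GOFeatureContext,
    aaindex1_delta,
    aaindex_matrix_value,
    build_go_context,
    filter_complete_indices,
    go_log_ratio,
    sequence_profile,
    surrogate_omega,
)
from pathoforest.io import Dataset, VariantRecord, read_aaindex, read_msa, read_obo


def _variant(vid, protein, label, position=1):
    return VariantRecord(vid, protein, position, "A", "V", label)


class TestGoContext:
    def test_single_pathogenic_variant_counts_once(self, toy_obo_file):
        ont = read_obo(toy_obo_file)
        ds = Dataset(records=[_variant("v1", "P1", "pathogenic")])
        ctx = build_go_context(ds, {"P1": ["GO:0000001"]}, ont)
        assert ctx.pathogenic_term_freq["GO:0000001"] == 1
        assert ctx.neutral_term_freq["GO:0000001"] == 0

    def test_per_variant_counting_counts_protein_terms_per_variant(self, toy_obo_file):
        ont = read_obo(toy_obo_file)
        ds = Dataset(
            records=[
                _variant("v1", "P1", "pathogenic", 1),
                _variant("v2", "P1", "pathogenic", 2),
            ]
        )
        ctx = build_go_context(ds, {"P1": ["GO:0000002"]}, ont)
        # two variants in the same protein: terms counted once per variant
        assert ctx.pathogenic_term_freq["GO:0000002"] == 2
        assert ctx.pathogenic_term_freq["GO:0000001"] == 2  # ancestor-expanded
        ctx_protein = build_go_context(ds, {"P1": ["GO:0000002"]}, ont, counting="protein")
        assert ctx_protein.pathogenic_term_freq["GO:0000002"] == 1

    def test_ancestor_reachable_twice_counted_once_per_protein(self, toy_obo_file):
        ont = read_obo(toy_obo_file)
        ds = Dataset(records=[_variant("v1", "P1", "pathogenic")])
        # root reachable via both parents of the leaf; still counted once
        ctx = build_go_context(ds, {"P1": ["GO:0000004"]}, ont)
        assert ctx.pathogenic_term_freq["GO:0000001"] == 1

    def test_empty_training_set_rejected(self, toy_obo_file):
        with pytest.raises(ValueError, match="empty"):
            build_go_context(Dataset(records=[]), {}, read_obo(toy_obo_file))


class TestGoLogRatio:
    def test_unseen_term_contributes_zero(self):
        assert go_log_ratio({"t"}, GOFeatureContext()) == 0.0

    def test_direct_arithmetic_natural_log(self):
        ctx = GOFeatureContext()
        ctx.pathogenic_term_freq["t"] = 9
        ctx.neutral_term_freq["t"] = 4
        assert go_log_ratio({"t"}, ctx) == pytest.approx(math.log(10 / 5))

    def test_two_term_symmetry_cancels(self):
        ctx = GOFeatureContext()
        ctx.pathogenic_term_freq.update({"a": 1, "b": 3})
        ctx.neutral_term_freq.update({"a": 3, "b": 1})
        assert go_log_ratio({"a", "b"}, ctx) == pytest.approx(0.0)

    def test_empty_term_set_is_missing(self):
        assert go_log_ratio(set(), GOFeatureContext()) is None

    @given(
        st.dictionaries(
            st.sampled_from(["a", "b", "c", "d"]),
            st.tuples(st.integers(0, 50), st.integers(0, 50)),
            min_size=1,
        )
    )
    def test_antisymmetric_under_class_swap(self, freqs):
        ctx = GOFeatureContext()
        swapped = GOFeatureContext()
        for t, (p, n) in freqs.items():
            ctx.pathogenic_term_freq[t] = p
            ctx.neutral_term_freq[t] = n
            swapped.pathogenic_term_freq[t] = n
            swapped.neutral_term_freq[t] = p
        terms = set(freqs)
        assert go_log_ratio(terms, ctx) == pytest.approx(-go_log_ratio(terms, swapped))

    def test_balanced_term_leaves_lr_unchanged(self):
        ctx = GOFeatureContext()
        ctx.pathogenic_term_freq.update({"a": 5, "bal": 7})
        ctx.neutral_term_freq.update({"a": 2, "bal": 7})
        assert go_log_ratio({"a", "bal"}, ctx) == pytest.approx(go_log_ratio({"a"}, ctx))


class TestAAIndexFeatures:
    def test_delta_hand_arithmetic(self):
        index = {"A": 1.8, "W": -0.9}
        assert aaindex1_delta(index, "A", "W") == pytest.approx(2.7)
        assert aaindex1_delta(index, "W", "A") == pytest.approx(-2.7)

    def test_delta_missing_residue_is_none(self):
        assert aaindex1_delta({"A": 1.0}, "A", "W") is None
        assert aaindex1_delta({"A": 1.0, "W": math.nan}, "A", "W") is None

    @given(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"), st.sampled_from("ACDEFGHIKLMNPQRSTVWY"))
    def test_delta_antisymmetric(self, a, b):
        index = {aa: float(i) ** 1.5 for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")}
        assert aaindex1_delta(index, a, b) == pytest.approx(-aaindex1_delta(index, b, a))

    def test_matrix_lookup_and_symmetry(self, aaindex2_file):
        entries = read_aaindex(aaindex2_file, section=2)
        m = entries["KOSJ950114"].matrix
        assert aaindex_matrix_value(m, "A", "C") == aaindex_matrix_value(m, "C", "A")
        assert aaindex_matrix_value(m, "A", "A") == pytest.approx(0.0)  # stored diagonal
        # named-accession round trip against the flat-file cell (row W, col A)
        assert aaindex_matrix_value(m, "W", "A") == pytest.approx(17 * 2.0)

    def test_matrix_na_cell_is_none(self):
        m = pd.DataFrame([[1.0, np.nan], [np.nan, 2.0]], index=["A", "C"], columns=["A", "C"])
        assert aaindex_matrix_value(m, "A", "C") is None

    def test_filter_complete_indices(self, aaindex1_file):
        entries = read_aaindex(aaindex1_file, section=1)
        kept = filter_complete_indices(entries)
        assert set(kept) == {"FAKE000001", "FAKE000003"}
        assert filter_complete_indices(kept) == kept


class TestSequenceProfile:
    def _aln(self, tmp_path, rows):
        p = tmp_path / "a.fasta"
        p.write_text("".join(f">{'ref' if i == 0 else f's{i}'}\n{r}\n" for i, r in enumerate(rows)))
        return read_msa(p, "ref")

    def test_fully_conserved_column(self, tmp_path):
        aln = self._aln(tmp_path, ["AAAA", "AAAA", "AAAA", "AAAA"])
        prof = sequence_profile(aln, 2, "A", "V")
        assert (prof.f_ref, prof.f_var, prof.n_seq) == (1.0, 0.0, 4)

    def test_gap_counted_in_denominator(self, tmp_path):
        aln = self._aln(tmp_path, ["CAC", "CAC", "CVC", "C-C"])
        prof = sequence_profile(aln, 2, "A", "V")
        assert prof.f_ref == pytest.approx(0.5)
        assert prof.f_var == pytest.approx(0.25)
        assert prof.n_seq == 4
        # gap-excluding convention available
        prof2 = sequence_profile(aln, 2, "A", "V", count_gaps=False)
        assert prof2.f_ref == pytest.approx(2 / 3)

    def test_single_sequence_alignment(self, tmp_path):
        aln = self._aln(tmp_path, ["ACD"])
        prof = sequence_profile(aln, 1, "A", "V")
        assert (prof.f_ref, prof.f_var, prof.n_seq) == (1.0, 0.0, 1)

    def test_proportions_bounded(self, tmp_path):
        aln = self._aln(tmp_path, ["AVC", "VVC", "A-C", "CCC"])
        for pos, (ref, var) in [(1, ("A", "V")), (2, ("V", "C")), (3, ("C", "A"))]:
            prof = sequence_profile(aln, pos, ref, var)
            assert 0.0 <= prof.f_ref <= 1.0
            assert 0.0 <= prof.f_var <= 1.0
            assert prof.f_ref + prof.f_var <= 1.0


class TestSurrogateOmega:
    def test_identical_column_missing(self):
        assert surrogate_omega(["GAAGCT", "GAAGCT", "GAAGCT"], 1) is None

    def test_synonymous_only_gives_zero(self):
        # GAA -> GAG both encode Glu
        assert surrogate_omega(["GAA", "GAG"], 1) == 0.0

    def test_nonsynonymous_only_is_missing(self):
        # GAA (Glu) -> GAC (Asp): only a non-synonymous difference, zero
        # synonymous rate, so the ratio is undefined
        assert surrogate_omega(["GAA", "GAC"], 1) is None

    def test_mixed_differences_positive(self):
        # GAA vs GCG differs at two positions; pathway-averaged counts give
        # both a syn and a non-syn component
        val = surrogate_omega(["GAA", "GCG"], 1)
        assert val is not None and val > 0

    def test_frame_error(self):
        with pytest.raises(ValueError):
            surrogate_omega(["GAAG", "GAAG"], 1)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            surrogate_omega(["TAA", "GAA"], 1)


class TestAssemble:
    def test_missing_go_is_masked_and_omega_passes_through(self, toy_obo_file):
        ont = read_obo(toy_obo_file)
        recs = [
            VariantRecord("v1", "P1", 1, "A", "V", "pathogenic"),
            VariantRecord("v2", "P2", 1, "A", "V", "neutral"),
        ]
        ds = Dataset(records=recs)
        ds.extras = pd.DataFrame(
            {"omega": [0.25, np.nan]}, index=pd.Index(["v1", "v2"], name="variant_id")
        )
        ctx = build_go_context(ds, {"P1": ["GO:0000002"]}, ont)
        builder = FeatureBuilder(go_context=ctx, go_annotations={"P1": ["GO:0000002"]}, ontology=ont)
        table = builder.assemble(ds)
        assert not table.mask.at["v1", "go_lr"]
        assert table.mask.at["v2", "go_lr"]  # P2 has no GO annotation
        assert table.values.at["v1", "omega"] == pytest.approx(0.25)
        assert table.mask.at["v2", "omega"]
        # masked cells are NaN, never silent zeros
        assert math.isnan(table.values.at["v2", "go_lr"])

    def test_synthetic_table_is_fully_dense(self, separable_data):
        assert not separable_data.features.mask.to_numpy().any()

    def test_duplicate_feature_names_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], columns=["x", "x"])
        with pytest.raises(ValueError, match="duplicate"):
            FeatureTable(df)
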