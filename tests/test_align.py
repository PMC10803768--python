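import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import affine_nw_score
from temarker.align import (
    MutationCatalog,
    PairwiseAlignment,
    apply_catalog,
    catalog_identity,
    extract_catalog,
    global_align,
    identity_matrix,
    percent_identity,
    reference_pivot_msa,
    shared_signature,
)
from temarker.io import SequenceSet

dna = st.text(alphabet="ACGT", min_size=1, max_size=14)


class TestGlobalAlign:
    def test_identity_case(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.ref_row == aln.qry_row == "ACGT"
        assert aln.score == 20.0

    def test_single_deletion(self):
        aln = global_align("ACGTACGT", "ACGACGT")
        cat = extract_catalog(aln)
        assert cat.substitutions == []
        assert cat.insertions == []
        assert len(cat.deletions) == 1 and cat.deletions[0][1] == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_gapped_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("AC-T", "ACGT")

    def test_score_matches_bruteforce_dp_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n, m = rng.integers(3, 13, size=2)
            a = "".join(rng.choice(list("ACGT"), size=n))
            b = "".join(rng.choice(list("ACGT"), size=m))
            assert global_align(a, b).score == pytest.approx(affine_nw_score(a, b))

    @given(a=dna, b=dna)
    @settings(max_examples=60, deadline=None)
    def test_rows_degap_to_inputs(self, a, b):
        aln = global_align(a, b)
        assert aln.ref == a and aln.qry == b


class TestPercentIdentity:
    def test_identical_rows(self):
        assert percent_identity("ACGT", "ACGT") == 100.0

    def test_one_mismatch_in_hundred(self):
        a = "A" * 100
        b = "A" * 99 + "C"
        assert percent_identity(a, b) == pytest.approx(99.0)

    def test_gap_excluded_versus_gap_counted(self):
        a, b = "AC-T", "ACGT"
        assert percent_identity(a, b) == pytest.approx(100.0)
        assert percent_identity(a, b, count_gaps=True) == pytest.approx(75.0)

    def test_no_comparable_columns_is_error(self):
        with pytest.raises(ValueError, match="comparable"):
            percent_identity("--AA", "GG--")

    @given(st.lists(st.sampled_from(["A", "C", "G", "T", "-"]), min_size=4, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, cols):
        a = "".join(cols)
        b = "".join(reversed(cols))
        try:
            assert percent_identity(a, b) == pytest.approx(percent_identity(b, a))
        except ValueError:
            pass  # all-gap overlap: no comparable columns either way

    def test_identity_100_iff_identical_on_comparable_columns(self):
        assert percent_identity("AC-TA", "ACG-A") == 100.0
        assert percent_identity("ACCTA", "ACGTA") < 100.0


class TestIdentityMatrix:
    def test_three_identical_rows(self):
        msa = SequenceSet(entries=[("a", "ACGT"), ("b", "ACGT"), ("c", "ACGT")],
                          aligned=True)
        m = identity_matrix(msa)
        assert (m.values == 100.0).all()

    def test_matches_pairwise_calls(self):
        msa = SequenceSet(
            entries=[("a", "ACGTT"), ("b", "ACCTT"), ("c", "A-GTT")], aligned=True
        )
        m = identity_matrix(msa)
        for i in msa.ids:
            for j in msa.ids:
                if i != j:
                    assert m.loc[i, j] == pytest.approx(
                        percent_identity(msa[i], msa[j])
                    )

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            identity_matrix(SequenceSet(entries=[("a", "ACGT")], aligned=True))


class TestMutationCatalog:
    def test_identical_pair_empty_catalog(self):
        cat = extract_catalog(global_align("ACGTACGT", "ACGTACGT"))
        assert not cat.substitutions and not cat.deletions and not cat.insertions

    def test_two_bp_insertion_event(self):
        cat = extract_catalog(PairwiseAlignment("AC--GT", "ACTTGT", 0.0))
        assert cat.insertions == [(2, "TT")]
        assert not cat.deletions and not cat.substitutions

    def test_gap_runs_become_single_events(self):
        cat = extract_catalog(PairwiseAlignment("ACGTTTACGT", "ACG---AGGT", 0.0))
        assert cat.deletions == [(4, 3)]
        assert cat.substitutions == [(8, "C", "G")]

    def test_total_deleted_is_sum_of_lengths(self):
        cat = MutationCatalog(ref_length=50, deletions=[(3, 4), (20, 10)])
        assert cat.n_deleted == 14

    def test_overlap_rejected(self):
        cat = MutationCatalog(ref_length=50, deletions=[(3, 4), (5, 2)])
        with pytest.raises(ValueError, match="overlap"):
            cat.validate()

    @given(a=st.text(alphabet="ACGT", min_size=2, max_size=25),
           b=st.text(alphabet="ACGT", min_size=2, max_size=25))
    @settings(max_examples=80, deadline=None)
    def test_apply_catalog_reconstructs_query(self, a, b):
        cat = extract_catalog(global_align(a, b))
        assert apply_catalog(a, cat) == b

    def test_catalog_identity_equals_row_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=60))
            b = "".join(rng.choice(list("ACGT"), size=55))
            aln = global_align(a, b)
            cat = extract_catalog(aln)
            assert catalog_identity(cat) == pytest.approx(
                percent_identity(aln.ref_row, aln.qry_row)
            )


class TestSharedSignature:
    def test_identical_catalogs_fully_shared(self):
        cat = MutationCatalog(ref_length=100, substitutions=[(5, "A", "G")],
                              deletions=[(10, 4)], insertions=[(50, "TT")])
        table = shared_signature({"x": cat, "y": cat})
        assert len(table) == 3
        assert (table["n_strains"] == 2).all()
        assert set(table["strains"]) == {"x,y"}

    def test_disjoint_catalogs_share_nothing(self):
        a = MutationCatalog(ref_length=100, substitutions=[(5, "A", "G")])
        b = MutationCatalog(ref_length=100, substitutions=[(6, "C", "T")])
        table = shared_signature({"x": a, "y": b})
        assert (table["n_strains"] == 1).all()

    def test_mixed_references_rejected(self):
        a = MutationCatalog(ref_length=100)
        b = MutationCatalog(ref_length=99)
        with pytest.raises(ValueError, match="different references"):
            shared_signature({"x": a, "y": b})

    def test_ancestral_deletion_shared_by_all_descendants(self):
        """Only branch-shared events appear in every strain's catalogue."""
        import dendropy

        from temarker.simulate import DecayParams, simulate_decay

        tree = dendropy.Tree.get(
            data="((D1:0,D2:0):4000000);", schema="newick", preserve_underscores=True
        )
        params = DecayParams(strain_tree=tree, element_len=400, flank_len5=20,
                             flank_len3=20, indel_rate=2e-9, seed=13)
        _, truth = simulate_decay(params)
        assert truth.catalogs["D1"].deletions  # shared branch did delete something
        table = shared_signature(truth.catalogs)
        assert (table["n_strains"] == 2).all()


class TestReferencePivot:
    def test_rows_project_onto_reference_coordinates(self):
        ref = "ACGTACGT"
        cat = extract_catalog(global_align(ref, "ACCTACG"))
        msa = reference_pivot_msa("ref", ref, {"s": cat})
        assert len(msa["s"]) == len(ref)
        assert msa["ref"] == ref
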