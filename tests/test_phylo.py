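import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from temarker.evodist import pairwise_distance_matrix
from temarker.io import SequenceSet
from temarker.phylo import (
    GTRGammaModel,
    bootstrap_support,
    gtr_gamma_loglik,
    neighbor_joining,
    optimize_branch_lengths,
)

ADDITIVE = pd.DataFrame(
    [[0, 3, 7, 8], [3, 0, 8, 9], [7, 8, 0, 5], [8, 9, 5, 0]],
    index=list("ABCD"), columns=list("ABCD"), dtype=float,
)


def leaf_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    labels = sorted(tx)
    return {
        (a, b): pdm.distance(tx[a], tx[b]) for a in labels for b in labels if a < b
    }


class TestNeighborJoining:
    def test_additive_matrix_recovered_exactly(self):
        tree = neighbor_joining(ADDITIVE)
        dist = leaf_distances(tree)
        for (a, b), d in dist.items():
            assert d == pytest.approx(ADDITIVE.loc[a, b], abs=1e-9)
        # the (A,B) | (C,D) split is present
        masks = {
            frozenset(leaf.taxon.label for leaf in node.leaf_iter())
            for node in tree.preorder_internal_node_iter()
        }
        assert {"A", "B"} in masks or {"C", "D"} in masks

    def test_ultrametric_three_taxon_star(self):
        D = pd.DataFrame([[0, 2, 2], [2, 0, 2], [2, 2, 0]],
                         index=list("XYZ"), columns=list("XYZ"), dtype=float)
        tree = neighbor_joining(D)
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(1.0)

    def test_fewer_than_three_taxa_rejected(self):
        D = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(D)

    def test_asymmetric_matrix_rejected(self):
        D = ADDITIVE.copy()
        D.iloc[0, 1] = 99
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(D)

    def test_no_negative_branch_lengths_on_noisy_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = 6
            pts = rng.random((n, 1))
            D = np.abs(pts - pts.T) + rng.random((n, n)) * 0.05
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            labels = [f"t{i}" for i in range(n)]
            tree = neighbor_joining(pd.DataFrame(D, index=labels, columns=labels))
            for node in tree.preorder_node_iter():
                if node.parent_node is not None:
                    assert node.edge.length >= 0


class TestBootstrap:
    def test_identical_sequences_give_star(self):
        msa = SequenceSet(
            entries=[(s, "ACGTACGTACGT") for s in ("a", "b", "c", "d")], aligned=True
        )
        tree = bootstrap_support(msa, n_reps=20, seed=1)
        internal = [
            n for n in tree.preorder_internal_node_iter() if n.parent_node is not None
        ]
        assert internal == []  # star: nothing to support

    def test_deep_split_strongly_supported(self):
        from temarker.align import reference_pivot_msa
        from temarker.simulate import DecayParams, simulate_decay, two_clade_tree

        # two clades separated by a deep internal branch (~60 informative
        # sites on a 1 kb element), shallow within-clade divergence
        params = DecayParams(
            strain_tree=two_clade_tree(3, 3, stem_a=5e6, stem_b=5e6, tip_len=1e5),
            element_len=1000, flank_len5=10, flank_len3=10, indel_rate=0.0, seed=5,
        )
        _, truth = simulate_decay(params)
        msa = reference_pivot_msa("anc", truth.ancestral_element, truth.catalogs)
        msa = SequenceSet(
            entries=[e for e in msa.entries if e[0] != "anc"], aligned=True
        )
        tree = bootstrap_support(msa, n_reps=200, seed=5)
        supports = [
            n.support
            for n in tree.preorder_internal_node_iter()
            if n.parent_node is not None
        ]
        assert supports and max(supports) >= 95

    def test_deterministic_given_seed(self, tiny_sim):
        from temarker.align import reference_pivot_msa

        _, truth = tiny_sim
        msa = reference_pivot_msa("anc", truth.ancestral_element, truth.catalogs)
        t1 = bootstrap_support(msa, n_reps=50, seed=42)
        t2 = bootstrap_support(msa, n_reps=50, seed=42)
        s1 = t1.as_string(schema="newick")
        s2 = t2.as_string(schema="newick")
        assert s1 == s2

    def test_supports_within_range(self, tiny_sim):
        from temarker.align import reference_pivot_msa

        _, truth = tiny_sim
        msa = reference_pivot_msa("anc", truth.ancestral_element, truth.catalogs)
        tree = bootstrap_support(msa, n_reps=50, seed=3)
        for n in tree.preorder_internal_node_iter():
            if n.parent_node is not None:
                assert 0 <= n.support <= 100


def two_taxon_loglik(seq_x, seq_y, t_total, model):
    """Closed-form pairwise likelihood: sum over Gamma categories of
    pi_i P_ij(r_k * t)."""
    pi = np.array(model.base_freqs)
    Q = model.rate_matrix()
    idx = {c: i for i, c in enumerate("ACGT")}
    ll = 0.0
    for x, y in zip(seq_x, seq_y):
        site = 0.0
        for r in model.category_rates():
            P = expm(Q * r * t_total)
            site += pi[idx[x]] * P[idx[x], idx[y]] / model.n_categories
        ll += np.log(site)
    return ll


class TestGtrGammaLoglik:
    MSA2 = SequenceSet(
        entries=[("X", "ACGTACGTACGTTTGA"), ("Y", "ACGTACTTACGTTTGA")], aligned=True
    )

    def _tree2(self):
        return dendropy.Tree.get(data="(X:0.03,Y:0.09);", schema="newick")

    def test_two_taxon_closed_form_single_category(self):
        model = GTRGammaModel(n_categories=1)
        ll = gtr_gamma_loglik(self.MSA2, self._tree2(), model)
        expected = two_taxon_loglik(self.MSA2["X"], self.MSA2["Y"], 0.12, model)
        assert ll == pytest.approx(expected, rel=1e-8)

    def test_two_taxon_closed_form_gamma_mixture(self):
        model = GTRGammaModel(
            exchangeabilities=(1.2, 3.0, 0.8, 0.9, 3.5, 1.0),
            base_freqs=(0.3, 0.2, 0.2, 0.3),
            gamma_shape=3.4437,
            n_categories=5,
        )
        ll = gtr_gamma_loglik(self.MSA2, self._tree2(), model)
        expected = two_taxon_loglik(self.MSA2["X"], self.MSA2["Y"], 0.12, model)
        assert ll == pytest.approx(expected, rel=1e-8)

    def test_collapses_to_jukes_cantor(self):
        model = GTRGammaModel(n_categories=1)
        t = 0.12
        matches = sum(x == y for x, y in zip(self.MSA2["X"], self.MSA2["Y"]))
        n = len(self.MSA2["X"])
        p_same = 0.25 + 0.75 * np.exp(-4 * t / 3)
        p_diff = 0.25 - 0.25 * np.exp(-4 * t / 3)
        expected = (
            matches * np.log(0.25 * p_same) + (n - matches) * np.log(0.25 * p_diff)
        )
        ll = gtr_gamma_loglik(self.MSA2, self._tree2(), model)
        assert ll == pytest.approx(expected, rel=1e-8)

    def test_gap_columns_marginalized(self):
        model = GTRGammaModel(n_categories=1)
        msa = SequenceSet(entries=[("X", "ACGT-"), ("Y", "ACTTN")], aligned=True)
        msa_trim = SequenceSet(entries=[("X", "ACGT"), ("Y", "ACTT")], aligned=True)
        t = self._tree2()
        assert gtr_gamma_loglik(msa, t, model) == pytest.approx(
            gtr_gamma_loglik(msa_trim, self._tree2(), model)
        )

    def test_invariant_under_rerooting(self, tiny_sim):
        from temarker.align import reference_pivot_msa

        _, truth = tiny_sim
        msa = reference_pivot_msa("anc", truth.ancestral_element, truth.catalogs)
        msa = SequenceSet(
            entries=[(s, seq.replace("-", "N")) for s, seq in msa.entries
                     if s != "anc"],
            aligned=True,
        )
        tree = dendropy.Tree.get(
            data="((T1:0.01,T2:0.012):0.02,(T3:0.011,T4:0.009):0.018);",
            schema="newick", preserve_underscores=True,
        )
        model = GTRGammaModel()
        ll1 = gtr_gamma_loglik(msa, tree, model)
        node = [n for n in tree.preorder_internal_node_iter()
                if n.parent_node is not None][0]
        tree.reroot_at_edge(node.edge, length1=node.edge.length / 2,
                            length2=node.edge.length / 2, update_bipartitions=False)
        ll2 = gtr_gamma_loglik(msa, tree, model)
        assert ll1 == pytest.approx(ll2, rel=1e-10)

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            GTRGammaModel(base_freqs=(0.5, 0.5, 0.1, 0.1))
        with pytest.raises(ValueError):
            GTRGammaModel(exchangeabilities=(1, 1, 1, 1, 1, -1))
        with pytest.raises(ValueError):
            GTRGammaModel(n_categories=0)

    def test_category_rates_mean_one(self):
        for k in (1, 4, 5, 8):
            rates = GTRGammaModel(n_categories=k).category_rates()
            assert rates.mean() == pytest.approx(1.0)
            assert (np.diff(rates) >= 0).all()

    def test_branch_perturbation_reduces_optimized_likelihood(self, tiny_sim):
        from temarker.align import reference_pivot_msa

        _, truth = tiny_sim
        msa = reference_pivot_msa("anc", truth.ancestral_element, truth.catalogs)
        msa = SequenceSet(
            entries=[(s, seq.replace("-", "N")) for s, seq in msa.entries
                     if s != "anc"],
            aligned=True,
        )
        tree = dendropy.Tree.get(
            data="((T1:0.01,T2:0.01):0.02,(T3:0.01,T4:0.01):0.02);",
            schema="newick", preserve_underscores=True,
        )
        model = GTRGammaModel(n_categories=2)
        best = optimize_branch_lengths(msa, tree, model, max_sweeps=3)
        edge = [n.edge for n in tree.preorder_node_iter()
                if n.parent_node is not None][0]
        opt_len = edge.length
        for factor in (0.2, 5.0):
            edge.length = max(opt_len, 1e-6) * factor
            assert gtr_gamma_loglik(msa, tree, model) <= best + 1e-6
        edge.length = opt_len
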