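"""Distances, BIONJ construction and bootstrap supports."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paradiv.phylo import (
    DistanceError,
    DistanceMatrix,
    bootstrap_support,
    build_bionj,
    distance_matrix,
    p_distance,
    poisson_correct,
)
from paradiv.seqio import AlignedSet
from paradiv.simulate import SimParams, protein_alignment, simulate_family

from conftest import random_unrooted_tree


class TestPDistance:
    def test_identical_rows(self):
        msa = AlignedSet({"a": "MKLV", "b": "MKLV"})
        assert p_distance(msa, "a", "b") == 0.0

    def test_one_in_four(self):
        msa = AlignedSet({"a": "AAAA", "b": "AAAT"})
        assert p_distance(msa, "a", "b") == 0.25

    def test_pairwise_deletion_skips_gap_and_x_columns(self):
        msa = AlignedSet({"a": "AA-A", "b": "AATA"})
        assert p_distance(msa, "a", "b") == 0.0
        msa2 = AlignedSet({"a": "AXTA", "b": "AATA"})
        assert p_distance(msa2, "a", "b") == 0.0

    def test_no_comparable_columns_is_error(self):
        msa = AlignedSet({"a": "--AA", "b": "TT--"})
        with pytest.raises(DistanceError, match="no comparable"):
            p_distance(msa, "a", "b")


class TestPoisson:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0, 0.0), (1 - math.exp(-1), 1.0), (0.3, -math.log(0.7))],
    )
    def test_closed_form(self, p, expected):
        assert poisson_correct(p) == pytest.approx(expected, abs=1e-12)

    def test_saturated_rejected(self):
        with pytest.raises(DistanceError):
            poisson_correct(1.0)

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(d=st.floats(min_value=0.0, max_value=10.0, allow_nan=False))
    def test_inverts_expected_saturation(self, d):
        """poisson_correct is the exact inverse of p = 1 - exp(-d), and is
        monotone increasing on [0, 1)."""
        p = 1.0 - math.exp(-d)
        assert poisson_correct(p) == pytest.approx(d, rel=1e-9, abs=1e-9)


class TestDistanceMatrix:
    def test_matches_per_pair_calls(self):
        msa = AlignedSet({"a": "MKLV", "b": "MKLA", "c": "MALA"})
        dm = distance_matrix(msa, "observed")
        for x in "abc":
            for y in "abc":
                if x != y:
                    assert dm.get(x, y) == pytest.approx(p_distance(msa, x, y))

    def test_tsv_roundtrip(self, tmp_path):
        msa = AlignedSet({"a": "MKLV", "b": "MKLA", "c": "MALA"})
        dm = distance_matrix(msa, "poisson")
        p = tmp_path / "d.tsv"
        dm.to_tsv(p)
        back = DistanceMatrix.from_tsv(p, model="poisson")
        assert back.labels == dm.labels
        assert np.allclose(back.d, dm.d)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(DistanceError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestBionj:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = build_bionj(DistanceMatrix(list("ABC"), d))
        lengths = {leaf.name: leaf.length for leaf in t.leaves()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_additive(self):
        labels = list("ABCD")
        d = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float
        )
        t = build_bionj(DistanceMatrix(labels, d))
        assert frozenset(["A", "B"]) in t.bipartitions()
        lab, dm = t.path_distances()
        idx = [lab.index(x) for x in labels]
        assert np.allclose(dm[np.ix_(idx, idx)], d, atol=1e-9)

    def test_additive_matrices_recovered_exactly(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 11))
            source = random_unrooted_tree(n, rng)
            labels, d = source.path_distances()
            rebuilt = build_bionj(DistanceMatrix(labels, d))
            assert rebuilt.bipartitions() == source.bipartitions()
            lab2, d2 = rebuilt.path_distances()
            idx = [lab2.index(x) for x in labels]
            assert np.allclose(d, d2[np.ix_(idx, idx)], atol=1e-9)

    def test_label_permutation_changes_nothing_but_order(self, rng):
        source = random_unrooted_tree(7, rng)
        labels, d = source.path_distances()
        perm = list(rng.permutation(len(labels)))
        labels_p = [labels[i] for i in perm]
        d_p = d[np.ix_(perm, perm)]
        t1 = build_bionj(DistanceMatrix(labels, d))
        t2 = build_bionj(DistanceMatrix(labels_p, d_p))
        assert t1.bipartitions() == t2.bipartitions()

    def test_too_few_taxa_rejected(self):
        with pytest.raises(DistanceError):
            build_bionj(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_path_lengths_correlate_with_input_on_simulated_data(self):
        truth = simulate_family(SimParams(n_species=8, codon_length=300, seed=21))
        prot = protein_alignment(truth.alignment)
        dm = distance_matrix(prot, "poisson")
        tree = build_bionj(dm)
        lab, dt = tree.path_distances()
        idx = [lab.index(x) for x in dm.labels]
        dt = dt[np.ix_(idx, idx)]
        iu = np.triu_indices(len(dm.labels), k=1)
        r = np.corrcoef(dm.d[iu], dt[iu])[0, 1]
        assert r >= 0.99


class TestBootstrap:
    def test_constant_alignment_gives_full_support_or_star(self):
        # identical replicate matrices -> identical trees -> supports 100 on
        # every internal edge the point tree has
        msa = AlignedSet({"a": "MKLVMKLV", "b": "MKLVMKLV",
                          "c": "MKLVMKLV", "d": "MKLVMKLV"})
        tree = bootstrap_support(msa, model="observed", n_reps=20, seed=1)
        sups = [n.support for n in tree.postorder()
                if not n.is_leaf and n is not tree.root and n.support is not None]
        assert all(s == 100.0 for s in sups)

    def test_supports_are_percentages(self):
        truth = simulate_family(SimParams(n_species=5, codon_length=200, seed=22))
        prot = protein_alignment(truth.alignment)
        tree = bootstrap_support(prot, n_reps=25, seed=3)
        sups = [n.support for n in tree.postorder() if n.support is not None]
        assert sups and all(0.0 <= s <= 100.0 for s in sups)

    def test_long_internal_branch_has_high_support(self):
        # the duplication split (clade A vs clade B) is the deepest, strongly
        # supported bipartition in simulated families
        truth = simulate_family(SimParams(n_species=5, codon_length=400, seed=23))
        prot = protein_alignment(truth.alignment)
        tree = bootstrap_support(prot, n_reps=100, seed=4)
        clade_a = frozenset(n for n in prot.ids if n.endswith("_A"))
        leafset = frozenset(prot.ids)
        target = min(clade_a, leafset - clade_a, key=lambda s: (len(s), sorted(s)))
        support = None

        def walk(node):
            nonlocal support
            below = frozenset()
            if node.is_leaf:
                return frozenset([node.name])
            for c in node.children:
                below |= walk(c)
            canon = min(below, leafset - below, key=lambda s: (len(s), sorted(s)))
            if canon == target and node.support is not None:
                support = node.support
            return below

        walk(tree.root)
        assert support is not None and support >= 95.0
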