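"""NG86 counting, Fitch ancestors, SLAC-style aggregation, partitions."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paradiv.kaks import (
    KaKsError,
    back_translate,
    codon_pair_differences,
    dataset_kaks_ng86,
    dataset_kaks_slac,
    fitch_ancestral,
    jukes_cantor,
    ng86_pair,
    ng86_sites,
    partition_kaks,
)
from paradiv.seqio import (
    SENSE_CODONS,
    STOP_CODONS,
    AlignedSet,
    CodingSequence,
    Partition,
    PartitionTable,
)
from paradiv.tree import PhyloTree

from conftest import exhaustive_parsimony_score, random_binary_rooted_tree


class TestSites:
    @pytest.mark.parametrize(
        "codon,s,n",
        [
            ("TTT", 1 / 3, 8 / 3),  # Phe: one synonymous neighbor
            ("TTA", 2 / 3, 5 / 3),  # Leu: two stop neighbors dropped
            ("TGG", 0.0, 7 / 3),    # Trp: no synonymous neighbor, two stops
        ],
    )
    def test_enumerated_examples(self, codon, s, n):
        assert ng86_sites(codon) == pytest.approx((s, n))

    def test_all_sense_codons_sum_to_at_most_three(self):
        """s + n <= 3 with equality exactly when no neighbor is a stop codon."""
        for codon in SENSE_CODONS:
            s, n = ng86_sites(codon)
            has_stop_neighbor = any(
                codon[:p] + nt + codon[p + 1 :] in STOP_CODONS
                for p in range(3)
                for nt in "ACGT"
                if nt != codon[p]
            )
            if has_stop_neighbor:
                assert s + n < 3 - 1e-12
            else:
                assert s + n == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(KaKsError):
            ng86_sites("TAA")


class TestPairDifferences:
    def test_single_step_classified_directly(self):
        assert codon_pair_differences("AAA", "AAG") == (1.0, 0.0)  # Lys->Lys
        assert codon_pair_differences("TTT", "TTA") == (0.0, 1.0)  # Phe->Leu

    def test_two_step_codon_averages_orderings(self):
        # TTT -> GTA: paths via GTT (Val) and TTA (Leu); both nonsynonymous
        sd, nd = codon_pair_differences("TTT", "GTA")
        assert sd + nd == pytest.approx(2.0)

    @settings(derandomize=True, deadline=None, max_examples=150)
    @given(
        a=st.sampled_from(SENSE_CODONS),
        b=st.sampled_from(SENSE_CODONS),
    )
    def test_symmetry_and_step_conservation(self, a, b):
        """Difference counts are direction-free, and when at least one
        stop-free path exists the averaged steps total the nucleotide
        difference count."""
        forward = codon_pair_differences(a, b)
        assert forward == codon_pair_differences(b, a)
        if forward is not None:
            ndiff = sum(x != y for x, y in zip(a, b))
            assert forward[0] + forward[1] == pytest.approx(ndiff)

    def test_path_count_conservation(self):
        # averaged steps always total the nucleotide difference count when at
        # least one stop-free path exists
        for a, b in itertools.product(["ATG", "TGG", "CAA"], ["CCC", "GGG"]):
            counts = codon_pair_differences(a, b)
            ndiff = sum(x != y for x, y in zip(a, b))
            if counts is not None:
                assert counts[0] + counts[1] == pytest.approx(ndiff)


class TestNg86Pair:
    def test_identical_rows_flag_undefined_ratio(self):
        res = ng86_pair("ATGAAA", "ATGAAA")
        assert res.sd == res.nd == 0
        assert res.ratio is None and "ks_zero_ratio_undefined" in res.flags

    def test_single_codon_example(self):
        res = ng86_pair("TTT", "TTA")
        assert res.sd == 0 and res.nd == 1
        assert res.s_sites == pytest.approx(0.5)
        assert res.n_sites == pytest.approx(13 / 6)

    def test_gap_codons_skipped_pairwise(self):
        res = ng86_pair("ATG---AAA", "ATGCTGAAG")
        assert res.n_codons == 2
        assert res.sd == pytest.approx(1.0)  # AAA vs AAG, synonymous

    def test_row_swap_symmetry(self):
        a, b = "ATGAAATTTCCC", "ATGAAGTTACCA"
        r1, r2 = ng86_pair(a, b), ng86_pair(b, a)
        assert (r1.sd, r1.nd, r1.s_sites, r1.n_sites) == (
            r2.sd, r2.nd, r2.s_sites, r2.n_sites
        )

    def test_jc_small_p_expansion(self):
        p = 1e-4
        k = jukes_cantor(p)
        series = p * (1 + 2 * p / 3)
        assert abs(k - series) / series < 1e-3


class TestDataset:
    def test_two_rows_equal_pairwise(self):
        msa = AlignedSet({"a": "ATGAAATTT", "b": "ATGAAGTTA"}, alphabet_kind="codon")
        agg, per_pair = dataset_kaks_ng86(msa)
        single = ng86_pair(msa.rows["a"], msa.rows["b"])
        assert agg.ka == pytest.approx(single.ka)
        assert agg.ks == pytest.approx(single.ks)
        assert len(per_pair) == 1

    def test_identical_rows_flagged(self):
        msa = AlignedSet({"a": "ATGAAA", "b": "ATGAAA", "c": "ATGAAA"},
                         alphabet_kind="codon")
        agg, _ = dataset_kaks_ng86(msa)
        assert agg.ratio is None


class TestBackTranslate:
    def test_gap_expansion(self):
        msa = AlignedSet({"a": "M-K", "b": "MLK"})
        cds = {
            "a": CodingSequence("a", "ATGAAA"),
            "b": CodingSequence("b", "ATGCTGAAA"),
        }
        out = back_translate(msa, cds)
        assert out.rows["a"] == "ATG---AAA"

    def test_mismatch_names_position(self):
        msa = AlignedSet({"a": "MK", "b": "MK"})
        cds = {
            "a": CodingSequence("a", "ATGCTG"),  # translates to ML, not MK
            "b": CodingSequence("b", "ATGAAA"),
        }
        with pytest.raises(KaKsError, match="residue 2"):
            back_translate(msa, cds)

    def test_simulator_roundtrip(self):
        from paradiv.simulate import SimParams, protein_alignment, simulate_family

        truth = simulate_family(SimParams(n_species=4, codon_length=60, seed=31))
        prot = protein_alignment(truth.alignment)
        cds = {
            rid: CodingSequence(rid, truth.alignment.rows[rid])
            for rid in truth.alignment.ids
        }
        assert back_translate(prot, cds).rows == truth.alignment.rows


class TestFitch:
    def test_uniform_leaves_propagate(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        msa = AlignedSet({x: "ATG" for x in "ABCD"}, alphabet_kind="codon")
        anc, _, score = fitch_ancestral(tree, msa)
        assert score == 0
        assert set(anc.values()) == {"ATG"}

    def test_hand_parsimony_four_leaves(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        msa = AlignedSet({"A": "AAA", "B": "AAA", "C": "AAG", "D": "AAG"},
                         alphabet_kind="codon")
        anc, _, score = fitch_ancestral(tree, msa)
        assert score == 1
        assert sorted(anc.values()) == ["AAA", "AAA", "AAG"]

    def test_score_matches_exhaustive_oracle(self, rng):
        """Fitch equals the brute-force minimum over all internal labelings
        (a 40-case sample here; the full 200-case sweep runs in the
        acceptance suite)."""
        for _ in range(40):
            n_leaves = int(rng.integers(3, 7))
            n_codons = int(rng.integers(1, 6))
            tree = random_binary_rooted_tree(n_leaves, rng)
            leaves = tree.leaf_names()
            rows = {
                name: "".join(rng.choice(SENSE_CODONS, size=n_codons))
                for name in leaves
            }
            msa = AlignedSet(rows, alphabet_kind="codon")
            _, _, score = fitch_ancestral(tree, msa)
            assert score == exhaustive_parsimony_score(tree, rows)


class TestSlac:
    def test_star_of_identical_sequences(self):
        tree = PhyloTree.from_newick("(A:1,B:1,C:1);")
        msa = AlignedSet({x: "ATGAAA" for x in "ABC"}, alphabet_kind="codon")
        res = dataset_kaks_slac(tree, msa)
        assert res.sd == res.nd == 0

    def test_hand_counts_synonymous_branch(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        msa = AlignedSet({"A": "AAA", "B": "AAA", "C": "AAG", "D": "AAG"},
                         alphabet_kind="codon")
        res = dataset_kaks_slac(tree, msa)
        assert res.sd == pytest.approx(1.0)  # AAA<->AAG is Lys<->Lys
        assert res.nd == pytest.approx(0.0)
        assert res.ratio == pytest.approx(0.0)


class TestPartitions:
    def _toy(self):
        rows = {
            "a": "ATGAAATTTCCCGGG",
            "b": "ATGAAGTTACCAGGG",
            "c": "ATGAAATTTCCAGGA",
        }
        return AlignedSet(rows, alphabet_kind="codon")

    def test_full_span_equals_dataset(self):
        msa = self._toy()
        table = PartitionTable([Partition("everything", 1, 5)])
        df = partition_kaks(msa, table, reference_id="a", method="ng86")
        all_row = df[df.partition == "All"].iloc[0]
        full = df[df.partition == "everything"].iloc[0]
        assert all_row["Sd"] == full["Sd"] and all_row["Nd"] == full["Nd"]

    def test_partition_counts_tile_to_whole(self):
        msa = self._toy()
        table = PartitionTable([Partition("head", 1, 2), Partition("tail", 3, 5)])
        df = partition_kaks(msa, table, reference_id="a", method="ng86")
        by = df.set_index("partition")
        assert by.loc["head", "Sd"] + by.loc["tail", "Sd"] == pytest.approx(
            by.loc["All", "Sd"]
        )
        assert by.loc["head", "Nd"] + by.loc["tail", "Nd"] == pytest.approx(
            by.loc["All", "Nd"]
        )

    def test_partition_beyond_reference_rejected(self):
        msa = self._toy()
        table = PartitionTable([Partition("bad", 1, 6)])
        with pytest.raises(KaKsError, match="beyond reference"):
            partition_kaks(msa, table, reference_id="a", method="ng86")

    def test_gapped_reference_coordinates_map_through_gaps(self):
        rows = {
            "a": "ATG---AAATTT",
            "b": "ATGCTGAAGTTA",
        }
        msa = AlignedSet(rows, alphabet_kind="codon")
        table = PartitionTable([Partition("late", 2, 3)])  # residues K, F of 'a'
        df = partition_kaks(msa, table, reference_id="a", method="ng86")
        row = df[df.partition == "late"].iloc[0]
        assert row["n_codons"] == 2
        # AAA vs AAG synonymous, TTT vs TTA nonsynonymous
        assert row["Sd"] == pytest.approx(1.0)
        assert row["Nd"] == pytest.approx(1.0)

    def test_table3_layout_row_count(self):
        """Nine exons + six domains + the whole gene give 16 rows per method,
        the layout of a per-gene Ka/Ks results table."""
        rng = np.random.default_rng(9)
        codons = ["".join(rng.choice(SENSE_CODONS, size=180)) for _ in range(2)]
        msa = AlignedSet({"x": codons[0], "y": codons[1]}, alphabet_kind="codon")
        bounds = np.linspace(0, 180, 10, dtype=int)
        exons = [
            Partition(f"Exon {i+1}", int(bounds[i]) + 1, int(bounds[i + 1]))
            for i in range(9)
        ]
        domains = [
            Partition(name, s, e)
            for name, s, e in [
                ("Signal", 1, 21), ("Propeptide", 22, 45), ("Chain", 46, 180),
                ("Extracellular", 46, 150), ("Transmembrane", 151, 170),
                ("Intracellular", 171, 180),
            ]
        ]
        table = PartitionTable(exons + domains)
        df = partition_kaks(msa, table, reference_id="x", method="ng86")
        assert len(df) == 16
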