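"""Hydropathy features, motif matching, RBH and the triage classifier."""

import numpy as np
import pytest

from paradiv.seqio import Sequence
from paradiv.triage import (
    KD_SCALE,
    PS00141,
    TriageCriteria,
    classify,
    find_active_site_motifs,
    hydropathy_profile,
    predict_ctm,
    predict_signal_peptide,
    presence_absence,
    prosite_to_regex,
    reciprocal_best_hit,
)


class TestHydropathy:
    def test_poly_isoleucine(self):
        prof = hydropathy_profile("I" * 30, window=9)
        assert np.allclose(prof, 4.5)

    def test_poly_arginine(self):
        prof = hydropathy_profile("R" * 30, window=9)
        assert np.allclose(prof, -4.5)

    def test_mixed_9mer_center_matches_hand_sum(self):
        s = "MKIVLFDGR"
        prof = hydropathy_profile(s, window=9)
        assert prof[4] == pytest.approx(sum(KD_SCALE[c] for c in s) / 9)

    def test_window_must_fit(self):
        with pytest.raises(ValueError):
            hydropathy_profile("MK", window=9)


class TestTerminalFeatures:
    def test_hydrophobic_n_terminus_is_signal(self):
        s = "M" + "L" * 9 + "V" + "DEKR" * 20
        present, span = predict_signal_peptide(s)
        assert present and span[0] <= 33

    def test_acidic_n_terminus_is_not_signal(self):
        s = "DE" * 20 + "LIVLIVLIVLIVLIVLIVL" + "DE" * 20
        assert not predict_signal_peptide(s)[0]

    def test_ctm_requires_hydrophobic_window_near_c_terminus(self):
        polar = "DEKRST" * 40
        with_tm = polar + "L" * 21 + "KRDE" * 5
        without = polar + "KRDE" * 10
        assert predict_ctm(with_tm)[0]
        assert not predict_ctm(without)[0]

    def test_hydrophobic_stretch_far_from_c_terminus_does_not_count(self):
        s = "M" + "L" * 25 + "DEKRST" * 50
        assert not predict_ctm(s)[0]


class TestProsite:
    def test_regex_conversion(self):
        assert prosite_to_regex("[AC]-x-V-x(4)-{ED}") == "[AC].V.{4}[^ED]"

    def test_malformed_pattern_rejected(self):
        with pytest.raises(ValueError):
            prosite_to_regex("[AC-x")

    def test_active_site_motif_hits_and_asp_position(self):
        body = "G" * 80
        seq = body + "ILVDTGSSNFAV" + "G" * 60 + "AIVDSGTSNLGV" + "G" * 40
        hits = find_active_site_motifs(seq, PS00141)
        assert [h.start for h in hits] == [81, 153]
        assert hits[0].asp_position == 84  # the catalytic Asp of the D-T-G core
        assert hits[0].matched == "ILVDTGSSNFAV"

    def test_broken_flank_is_not_matched(self):
        seq = "G" * 80 + "KSIVDSGTTNLR" + "G" * 80
        assert find_active_site_motifs(seq, PS00141) == []


class TestReciprocalBestHit:
    def test_identical_member_is_reciprocal_best(self, bace_decoys):
        query = bace_decoys[0]
        db = [Sequence("copy", query.residues)] + list(bace_decoys[5:8])
        hit, _, reciprocal = reciprocal_best_hit(query, db)
        assert hit.id == "copy" and reciprocal

    def test_unrelated_query_not_reciprocal(self, rng, bace_decoys):
        # a random sequence against a family db: the family member's best
        # friend is another family member, not the random query
        random_seq = Sequence(
            "rnd", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        )
        hit, _, reciprocal = reciprocal_best_hit(
            random_seq, list(bace_decoys[:5]), home_db=[random_seq] + list(bace_decoys[5:10])
        )
        assert not reciprocal


class TestClassify:
    def test_bace_decoy_is_bace_like(self, bace_decoys, triage_references):
        ref_bace, ref_caths = triage_references
        verdict = classify(bace_decoys[0], ref_bace, ref_caths)
        assert verdict.label == "bace-like"
        assert all(verdict.checks.values())

    def test_cathepsin_decoy_fails_ctm_and_length(self, cathepsin_decoys,
                                                  triage_references):
        ref_bace, ref_caths = triage_references
        verdict = classify(cathepsin_decoys[0], ref_bace, ref_caths)
        assert verdict.label == "cathepsin-like"
        assert not verdict.checks["ctm"]
        assert not verdict.checks["length_delta"]

    def test_candidate_without_corroboration_is_borderline(self, bace_decoys,
                                                           triage_references):
        """A candidate passing the mandatory similarity/CTM evidence but
        lacking corroboration (here: no predicted signal peptide) is recorded
        as borderline rather than bace-like."""
        ref_bace, ref_caths = triage_references
        full = bace_decoys[1]
        no_sp = Sequence("nosp", "DE" * 20 + full.residues[40:])
        verdict = classify(no_sp, ref_bace, ref_caths)
        assert verdict.label == "borderline"
        assert verdict.checks["rbh"] and verdict.checks["identity"]
        assert verdict.checks["ctm"]
        assert not verdict.checks["signal_peptide"]

    def test_relaxing_thresholds_never_demotes(self, bace_decoys, cathepsin_decoys,
                                               triage_references):
        """Monotonicity: relaxing any threshold can only move labels toward
        bace-like, never from bace-like to cathepsin-like."""
        ref_bace, ref_caths = triage_references
        strict = TriageCriteria()
        relaxed = TriageCriteria(
            min_identity_pct=10.0, min_coverage_frac=0.2, max_gap_pct=60.0,
            min_length_delta=0,
        )
        order = {"cathepsin-like": 0, "borderline": 1, "bace-like": 2}
        for cand in [bace_decoys[2], cathepsin_decoys[2]]:
            a = classify(cand, ref_bace, ref_caths, strict).label
            b = classify(cand, ref_bace, ref_caths, relaxed).label
            assert order[b] >= order[a]

    def test_exon_metadata_is_corroborative_only(self, bace_decoys, triage_references):
        ref_bace, ref_caths = triage_references
        verdict = classify(bace_decoys[3], ref_bace, ref_caths,
                           metadata={"n_exons": 4})
        assert verdict.label == "borderline"  # mandatory met, exon count unmet
        verdict2 = classify(bace_decoys[3], ref_bace, ref_caths,
                            metadata={"n_exons": 9})
        assert verdict2.label == "bace-like"


class TestPresenceAbsence:
    def test_verbatim_substrate_is_present(self, bace_decoys):
        substrate = Sequence("sub1", bace_decoys[0].residues)
        proteomes = {"org1": [bace_decoys[0], bace_decoys[1]]}
        df = presence_absence([substrate], proteomes)
        assert bool(df.iloc[0]["present"])

    def test_empty_proteome_all_absent(self, bace_decoys):
        substrate = Sequence("sub1", bace_decoys[0].residues)
        df = presence_absence([substrate], {"empty": []})
        assert not df["present"].any()

    def test_unrelated_proteome_absent(self, rng, bace_decoys):
        substrate = Sequence("sub1", bace_decoys[0].residues)
        junk = [
            Sequence(f"j{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300)))
            for i in range(3)
        ]
        df = presence_absence([substrate], {"junkome": junk})
        assert not df["present"].any()
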