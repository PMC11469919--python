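import itertools

import pytest

from dcsminer.active_site import (MutationEffect, Product, load_reference_fixture,
                                  locate_sites, predict_product)
from dcsminer.motif_engine import (BUILTIN_MOTIFS, ClassIStatus,
                                   ClassIIStatus, MotifStatus, Region,
                                   classify_motif_status, scan_motifs)
from dcsminer.seqio import ProteinRecord


@pytest.fixture(scope="module")
def reference():
    return load_reference_fixture()


@pytest.fixture(scope="module")
def reference_status(reference):
    ref, _ = reference
    regions = {Region.GB_REGION: (1, 540), Region.ALPHA_REGION: (541, 840)}
    return classify_motif_status(scan_motifs(ref, BUILTIN_MOTIFS.values(),
                                             regions))


class TestLocateSites:
    def test_reference_maps_onto_itself_unchanged(self, reference):
        ref, anns = reference
        profile = locate_sites(ref, ref, anns)
        assert (profile.dyad_his, profile.dyad_asn) == (187, 253)
        assert (profile.bacterial_type_position, profile.plant_type_ile) == (726, 730)
        assert profile.context_mismatch == frozenset()
        assert profile.residue_states["dyad_his"] == "H"

    def test_nterminal_extension_shifts_all_positions(self, reference):
        ref, anns = reference
        query = ProteinRecord("q", "M" * 10 + ref.residues)
        profile = locate_sites(query, ref, anns)
        assert (profile.dyad_his, profile.dyad_asn) == (197, 263)
        assert profile.plant_type_ile == 740
        assert profile.bacterial_type_position == 736

    def test_deleted_dyad_his_reported_absent(self, reference):
        ref, anns = reference
        # remove a 30-residue block containing His187
        residues = ref.residues[:170] + ref.residues[200:]
        profile = locate_sites(ProteinRecord("q", residues), ref, anns)
        assert profile.dyad_his is None
        assert profile.dyad_asn == 253 - 30

    def test_substituted_context_flagged_as_mismatch(self, reference):
        ref, anns = reference
        # mutate the L of the LHS context; the His itself stays
        residues = ref.residues[:185] + "G" + ref.residues[186:]
        profile = locate_sites(ProteinRecord("q", residues), ref, anns)
        assert "dyad_his" in profile.context_mismatch

    def test_inverse_consistency_on_gap_free_alignment(self, reference):
        ref, anns = reference
        profile = locate_sites(ref, ref, anns)
        # map back: with a gap-free self alignment positions are fixed points
        back = locate_sites(ref, ref, anns)
        assert (back.dyad_his, back.dyad_asn, back.plant_type_ile) == \
            (profile.dyad_his, profile.dyad_asn, profile.plant_type_ile)

    def test_reference_without_annotations_rejected(self, reference):
        ref, _ = reference
        with pytest.raises(ValueError, match="annotations"):
            locate_sites(ref, ref, [])


class TestPredictProduct:
    def test_wild_type_makes_kaurene(self, reference, reference_status):
        ref, anns = reference
        profile = locate_sites(ref, ref, anns)
        pred = predict_product(profile, reference_status)
        assert pred.products == (Product.ENT_KAURENE,)

    @pytest.mark.parametrize("mutations, expected", [
        ({MutationEffect.CLASS_I_KNOCKOUT}, (Product.ENT_CPP,)),
        ({MutationEffect.DYAD_HIS_ALA}, (Product.ENT_EPI_MANOYL_OXIDE,)),
        ({MutationEffect.DYAD_ASN_ALA},
         (Product.ENT_EPI_MANOYL_OXIDE, Product.ENT_KAURENE)),
        ({MutationEffect.DYAD_HIS_ALA, MutationEffect.CLASS_I_KNOCKOUT},
         (Product.ENT_LPP,)),
        ({MutationEffect.DYAD_ASN_ALA, MutationEffect.CLASS_I_KNOCKOUT},
         (Product.ENT_LPP,)),
        ({MutationEffect.BACTERIAL_ILE_THR}, (Product.ENT_PIMARADIENE,)),
        ({MutationEffect.PLANT_ILE_THR},
         (Product.HYDROXY_ENT_PIMARENE, Product.ENT_KAURENE)),
    ])
    def test_mutant_rules(self, reference, reference_status, mutations, expected):
        ref, anns = reference
        profile = locate_sites(ref, ref, anns)
        assert predict_product(profile, reference_status, mutations).products \
            == expected

    def test_unmatched_combination_flagged_no_rule(self, reference,
                                                   reference_status):
        ref, anns = reference
        profile = locate_sites(ref, ref, anns)
        pred = predict_product(profile, reference_status,
                               {MutationEffect.BACTERIAL_ILE_THR,
                                MutationEffect.PLANT_ILE_THR})
        assert pred.no_rule and pred.products == (Product.NONE,)

    def test_class_ii_absent_precondition(self, reference):
        ref, anns = reference
        profile = locate_sites(ref, ref, anns)
        status = MotifStatus(ClassIIStatus.ABSENT, ClassIStatus.INTACT)
        with pytest.raises(ValueError):
            predict_product(profile, status)

    def test_rules_are_mutually_exclusive_over_full_state_space(
            self, reference):
        """Enumerate the finite mutation-state space (five mutation flags x
        Class I status) against an independent restatement of the rule
        conditions: no state may satisfy more than one condition, and the
        matched rule must be the one predict_product reports."""
        ref, anns = reference
        profile = locate_sites(ref, ref, anns)
        E = MutationEffect
        conditions = {
            "wild_type": lambda m, intact: not m and intact,
            "class_i_knockout": lambda m, intact:
                m == {E.CLASS_I_KNOCKOUT},
            "dyad_his_ala": lambda m, intact:
                m == {E.DYAD_HIS_ALA} and intact,
            "dyad_asn_ala": lambda m, intact:
                m == {E.DYAD_ASN_ALA} and intact,
            "dyad_plus_knockout": lambda m, intact:
                E.CLASS_I_KNOCKOUT in m
                and (m - {E.CLASS_I_KNOCKOUT})
                and m <= {E.CLASS_I_KNOCKOUT, E.DYAD_HIS_ALA, E.DYAD_ASN_ALA},
            "bacterial_ile_thr": lambda m, intact:
                m == {E.BACTERIAL_ILE_THR} and intact,
            "plant_ile_thr": lambda m, intact:
                m == {E.PLANT_ILE_THR} and intact,
        }
        for class_i in ClassIStatus:
            status = MotifStatus(ClassIIStatus.INTACT, class_i)
            intact = class_i is ClassIStatus.INTACT
            for bits in itertools.product([0, 1], repeat=5):
                muts = {e for e, b in zip(MutationEffect, bits) if b}
                matching = [name for name, cond in conditions.items()
                            if cond(muts, intact)]
                assert len(matching) <= 1, (muts, class_i, matching)
                pred = predict_product(profile, status, muts)
                if matching:
                    assert pred.rule == matching[0]
                else:
                    assert pred.no_rule
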