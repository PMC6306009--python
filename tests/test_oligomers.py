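"""Oligomer mass bookkeeping, ester-fragment and chain-cleavage prediction."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cutinseq.chem import MONOISOTOPIC_MASS, WATER, printed_mz
from cutinseq.monomers import default_catalog
from cutinseq.oligomers import (
    Oligomer,
    OligomerError,
    precursor_mz,
    predict_chain_cleavage_ions,
    predict_ester_fragments,
)

CATALOG = default_catalog()
OH_ACIDS = [m for m in CATALOG.acids() if m.hydroxyls]


def oligo(*ids):
    return Oligomer(tuple(CATALOG.get(i) for i in ids))


# distinct monomers so every cleavage span maps to a unique predicted peak
random_oligomers = st.lists(
    st.sampled_from(sorted(m.id for m in OH_ACIDS)),
    min_size=2,
    max_size=5,
    unique=True,
).map(lambda ids: oligo(*ids))


class TestOligomerModel:
    def test_formula_is_monomer_sum_minus_ester_waters(self):
        tri = oligo("16-hydroxy-16:0", "10,16-dihydroxy-16:0", "18-hydroxy-18:3")
        expected = (
            tri.monomers[0].formula + tri.monomers[1].formula + tri.monomers[2].formula
            - 2 * WATER
        )
        assert tri.formula == expected

    def test_singleton_equals_the_monomer_ion(self):
        single = oligo("18-hydroxy-18:3")
        assert printed_mz(precursor_mz(single)) == 293.21

    def test_linkage_site_must_be_a_hydroxyl_of_the_host(self):
        with pytest.raises(OligomerError):
            Oligomer(
                (CATALOG.get("16-hydroxy-16:0"), CATALOG.get("18:0")),
                linkage_sites=(10,),
            )

    def test_hydroxyl_free_monomer_cannot_host_an_ester(self):
        with pytest.raises(OligomerError):
            oligo("16:0", "18-hydroxy-18:2")

    def test_first_monomer_must_carry_a_carboxyl(self):
        with pytest.raises(OligomerError):
            Oligomer((CATALOG.get("26:0-ol"), CATALOG.get("16-hydroxy-16:0")), (1,))

    def test_default_linkage_is_the_omega_hydroxyl(self):
        dimer = oligo("9,10,18-trihydroxy-18:0", "16-hydroxy-16:0")
        assert dimer.linkage_sites == (18,)

    def test_free_hydroxyl_count(self):
        tri = oligo(
            "18-hydroxy-9,10-epoxy-18:1", "10,16-dihydroxy-16:0", "18-hydroxy-18:3"
        )
        assert tri.free_hydroxyl_count == 1 + 2 + 1 - 2


class TestPrecursor:
    @pytest.mark.parametrize(
        "ids, printed",
        [
            (("16-hydroxy-16:0", "9,10,18-trihydroxy-18:0"), 585.47),
            (
                ("18-hydroxy-9,10-epoxy-18:1", "10,16-dihydroxy-16:0", "18-hydroxy-18:3"),
                857.65,
            ),
            (("18-hydroxy-18:3", "18-hydroxy-18:2", "16-hydroxy-16:0"), 825.66),
            (("18-hydroxy-18:3",), 293.21),
        ],
    )
    def test_printed_values(self, ids, printed):
        assert printed_mz(precursor_mz(oligo(*ids), "[M-H]-")) == printed


class TestEsterFragments:
    TRIMER = ("18-hydroxy-9,10-epoxy-18:1", "10,16-dihydroxy-16:0", "18-hydroxy-18:3")
    TETRAMER = (
        "18-hydroxy-9,10-epoxy-18:1",
        "18-hydroxy-18:2",
        "18-hydroxy-9,10-epoxy-18:0",
        "18-hydroxy-18:3",
    )

    @pytest.mark.parametrize(
        "ids, daughter",
        [
            (TRIMER, 581.44),  # prefix dimer, intact
            (TRIMER, 563.43),  # suffix dimer (also prefix dimer minus water)
            (TRIMER, 275.20),  # terminal monomer minus water
            (TETRAMER, 589.45),  # prefix and suffix dimers are isobaric here
            (TETRAMER, 885.68),  # prefix trimer
        ],
    )
    def test_printed_daughters_predicted(self, ids, daughter):
        peaks = predict_ester_fragments(oligo(*ids), "[M-H]-", max_water_loss=2)
        assert daughter in {printed_mz(p.mz) for p in peaks}

    def test_dimer_fragments_contain_both_monomer_ions(self):
        dimer = oligo("16-hydroxy-16:0", "9,10,18-trihydroxy-18:0")
        mzs = {printed_mz(p.mz) for p in predict_ester_fragments(dimer)}
        assert {271.23, 331.25} <= mzs  # both constituent [M-H]- ions

    @given(o=random_oligomers)
    def test_mass_conservation_of_complementary_pairs(self, o):
        peaks = {
            p.span: p.mz
            for p in predict_ester_fragments(o, max_water_loss=0)
            if p.n_water_losses == 0
        }
        parent = o.neutral_mass
        water = WATER.mass
        proton = MONOISOTOPIC_MASS["H"]
        length = len(o)
        for cut in range(1, length):
            prefix = peaks[(0, cut - 1)] + proton
            suffix = peaks[(cut, length - 1)] + proton
            assert prefix + suffix == pytest.approx(parent + water, abs=1e-9)

    @given(o=random_oligomers)
    def test_water_losses_never_exceed_free_hydroxyls(self, o):
        for p in predict_ester_fragments(o, max_water_loss=3):
            members = [CATALOG.get(mid) for mid in p.monomer_ids]
            free_oh = sum(len(m.hydroxyls) for m in members) - (len(members) - 1)
            assert 0 <= p.n_water_losses <= free_oh

    def test_internal_fragments_are_opt_in(self):
        tet = oligo(*self.TETRAMER)
        spans_default = {p.span for p in predict_ester_fragments(tet)}
        spans_internal = {
            p.span for p in predict_ester_fragments(tet, include_internal=True)
        }
        assert (1, 2) not in spans_default
        assert (1, 2) in spans_internal

    def test_deterministic_mz_ordering(self):
        tri = oligo(*self.TRIMER)
        peaks = predict_ester_fragments(tri)
        assert [p.mz for p in peaks] == sorted(p.mz for p in peaks)

    def test_homotrimer_deduplicates_repeated_species(self):
        tri = oligo(*(["9,10,18-trihydroxy-18:0"] * 3))
        peaks = predict_ester_fragments(tri, max_water_loss=0)
        # prefix and suffix dimers coincide -> one peak, not two
        dimer_peaks = [p for p in peaks if len(p.monomer_ids) == 2]
        assert len(dimer_peaks) == 1


class TestChainCleavage:
    def test_epoxy_diagnostic_ions_are_covered(self, mono):
        ions = predict_chain_cleavage_ions(mono("18-hydroxy-9,10-epoxy-18:0"))
        mzs = [p.mz for p in ions]
        for observed in (171.11, 157.12, 155.12, 141.12, 127.12):
            assert min(abs(mz - observed) for mz in mzs) <= 0.03

    def test_monomer_without_midchain_oxygen_is_empty(self, mono):
        assert predict_chain_cleavage_ions(mono("16:0")) == ()
        # an omega hydroxyl alone is terminal, not mid-chain
        assert predict_chain_cleavage_ions(mono("16-hydroxy-16:0")) == ()

    def test_candidate_set_matches_brute_force_enumeration(self, mono):
        """Independent oracle: direct enumeration for 9,10,18-trihydroxy-18:0.

        Mid-chain OH carbons 9 and 10 flank bonds 8-9, 9-10 and 10-11.  For a
        cut at bond k|k+1 of the saturated acid, the acid side is
        C_k H_2k O_(2 + #OH<=k) and the distal side C_(18-k) H_(2(18-k))
        O_(#OH>k); offsets of -1/0/+1 H and 0-1 water losses apply.
        """
        hydrogen = MONOISOTOPIC_MASS["H"]
        carbon = 12.0
        oxygen = MONOISOTOPIC_MASS["O"]
        water = 2 * hydrogen + oxygen
        oh_positions = {9, 10, 18}
        expected = set()
        for k in (8, 9, 10):
            sides = [
                (k, 2 * k, 2 + sum(1 for p in oh_positions if p <= k)),
                (18 - k, 2 * (18 - k), sum(1 for p in oh_positions if p > k)),
            ]
            for n_c, n_h, n_o in sides:
                for off in (-1, 0, 1):
                    for w in (0, 1):
                        h = n_h + off - 2 * w
                        o = n_o - w
                        if h < 1 or o < 0:
                            continue
                        neutral = n_c * carbon + h * hydrogen + o * oxygen
                        expected.add(round(neutral - hydrogen, 4))
        ions = predict_chain_cleavage_ions(mono("9,10,18-trihydroxy-18:0"))
        assert {round(p.mz, 4) for p in ions} == expected
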