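"""Precursor decomposition, ordering inference, and overlap assembly."""

import itertools
import json

import numpy as np
import pytest

from cutinseq.chem import ADDUCTS, WATER, neutral_mass_for_ion
from cutinseq.monomers import default_catalog
from cutinseq.oligomers import Oligomer
from cutinseq.sequencing import (
    SequencingParams,
    Spectrum,
    assemble_overlaps,
    decompose_precursor,
    length_window,
    score_ordering,
    sequence_spectrum,
)
from cutinseq.simulate import build_polymer, simulate_spectrum

NEG = ADDUCTS["[M-H]-"]
CATALOG = default_catalog()


def oligo(*ids):
    return Oligomer(tuple(CATALOG.get(i) for i in ids))


def spectrum(precursor, mzs, source="test"):
    return Spectrum(precursor, NEG, tuple((mz, 1.0) for mz in mzs), source)


class TestLengthWindows:
    @pytest.mark.parametrize(
        "length, window",
        [(2, (328, 662)), (3, (492, 993)), (4, (656, 1324))],
    )
    def test_windows_scale_with_length(self, length, window):
        assert length_window(length) == window


class TestDecompose:
    def test_dimer_example(self):
        cands = decompose_precursor(585.47, NEG, CATALOG, 2, 2, tol=0.02)
        assert ("16-hydroxy-16:0", "9,10,18-trihydroxy-18:0") in {c.ids for c in cands}

    def test_isobaric_dimer_candidates_are_flagged(self):
        cands = decompose_precursor(589.45, NEG, CATALOG, 2, 2, tol=0.02)
        ids = {c.ids for c in cands}
        assert ("18-hydroxy-18:2", "18-hydroxy-9,10-epoxy-18:1") in ids
        assert ("18-hydroxy-18:3", "18-hydroxy-9,10-epoxy-18:0") in ids
        assert all(c.isobar for c in cands if len(ids) > 1)

    def test_zero_tolerance_yields_nothing_for_a_rounded_mass(self):
        assert decompose_precursor(585.47, NEG, CATALOG, 2, 2, tol=0.0) == []

    def test_sorted_by_absolute_error(self):
        cands = decompose_precursor(857.65, NEG, CATALOG, 3, 3, tol=0.02)
        errors = [abs(c.error_da) for c in cands]
        assert errors == sorted(errors)

    def test_empty_catalog_rejected(self):
        from cutinseq.monomers import MonomerCatalog

        with pytest.raises(ValueError):
            decompose_precursor(585.47, NEG, MonomerCatalog([]), 1, 2)

    def test_alcohols_excluded_by_default(self):
        # 26:0-ol [M-H]- would be 381.41; no acid composition sits there
        assert decompose_precursor(381.41, NEG, CATALOG, 1, 1, tol=0.02) == []
        hits = decompose_precursor(
            381.41, NEG, CATALOG, 1, 1, tol=0.02, include_alcohols=True
        )
        assert [c.ids for c in hits] == [("26:0-ol",)]

    def test_matches_exhaustive_enumeration(self):
        """Completeness oracle on a batch of random precursors."""
        pool = [m for m in CATALOG if not m.alcohol_only]
        water = WATER.mass
        combos = []
        for length in range(1, 5):
            for combo in itertools.combinations_with_replacement(pool, length):
                mass = sum(m.neutral_mass for m in combo) - (length - 1) * water
                combos.append((tuple(sorted(m.id for m in combo)), mass))
        rng = np.random.default_rng(42)
        for mz in rng.uniform(250.0, 1350.0, 60):
            target = neutral_mass_for_ion(mz, NEG)
            brute = sorted(ids for ids, mass in combos if abs(mass - target) <= 0.02)
            mine = sorted(c.ids for c in decompose_precursor(mz, NEG, CATALOG, 1, 4, 0.02))
            assert mine == brute


class TestScoreOrdering:
    TRIMER_PEAKS = [581.44, 563.43, 311.21, 287.22, 293.20, 275.20]

    def test_empty_spectrum_scores_zero(self):
        s = spectrum(857.65, [])
        result = score_ordering(oligo(*self.true_trimer()), s)
        assert result.score == 0 and result.matches == ()

    @staticmethod
    def true_trimer():
        return (
            "18-hydroxy-9,10-epoxy-18:1",
            "10,16-dihydroxy-16:0",
            "18-hydroxy-18:3",
        )

    def test_true_trimer_ordering_is_maximal(self):
        s = spectrum(857.65, self.TRIMER_PEAKS)
        true_score = score_ordering(oligo(*self.true_trimer()), s).score
        for perm in itertools.permutations(self.true_trimer()):
            assert score_ordering(oligo(*perm), s).score <= true_score

    def test_simulated_noiseless_trimer_true_vs_wrong(self):
        true = oligo("16-hydroxy-16:0", "10,16-dihydroxy-16:0", "18-hydroxy-18:3")
        s = simulate_spectrum(true, mass_error_ppm_sigma=0, n_noise_peaks=0, seed=0)
        true_score = score_ordering(true, s).score
        for perm in itertools.permutations(true.ids):
            if perm == true.ids:
                continue
            assert score_ordering(oligo(*perm), s).score <= true_score

    def test_reversal_ties_are_intrinsic(self):
        """Ester-only fragments carry no direction: a sequence and its
        reversal predict identical m/z sets and must score identically."""
        true = oligo(*self.true_trimer())
        s = simulate_spectrum(true, mass_error_ppm_sigma=0, n_noise_peaks=0, seed=3)
        assert score_ordering(true, s).score == score_ordering(true.reversed(), s).score


class TestSequenceSpectrum:
    def test_trimer_central_monomer_deduction(self):
        s = spectrum(857.65, TestScoreOrdering.TRIMER_PEAKS, "trimer")
        result = sequence_spectrum(s, CATALOG)
        top = result.top
        assert top.oligomer.ids == TestScoreOrdering.true_trimer()
        assert top.oligomer.monomers[1].id == "10,16-dihydroxy-16:0"
        evidence = result.central_monomer_evidence
        assert evidence is not None
        assert evidence.monomer_id == "10,16-dihydroxy-16:0"
        assert set(evidence.dimer_mzs) == {581.44, 563.43}

    def test_tetramer_ordering(self):
        true = oligo(
            "18-hydroxy-9,10-epoxy-18:1",
            "18-hydroxy-18:2",
            "18-hydroxy-9,10-epoxy-18:0",
            "18-hydroxy-18:3",
        )
        peaks = [885.69, 867.63, 571.43, 589.45, 311.24, 295.23, 313.22, 293.21]
        s = spectrum(true.mz(NEG), peaks, "tetramer")
        result = sequence_spectrum(s, CATALOG)
        assert result.top.oligomer.ids == true.ids
        assert result.ambiguous  # the reversal is mass-identical

    def test_homodimer_is_unambiguous(self):
        homo = oligo("10,16-dihydroxy-16:0", "10,16-dihydroxy-16:0")
        s = simulate_spectrum(homo, mass_error_ppm_sigma=0, n_noise_peaks=0, seed=0)
        result = sequence_spectrum(s, CATALOG)
        homodimer_orderings = [
            o for o in result.orderings if o.oligomer.ids == homo.ids
        ]
        assert len(homodimer_orderings) == 1
        assert result.top.oligomer.ids == homo.ids
        assert not result.ambiguous

    def test_no_composition_returns_diagnostic_not_exception(self):
        s = spectrum(999.99, [500.0])
        result = sequence_spectrum(s, CATALOG)
        assert result.orderings == []
        assert "no monomer composition" in result.diagnostic

    def test_ranks_are_nonincreasing_and_shared_on_ties(self):
        s = spectrum(857.65, TestScoreOrdering.TRIMER_PEAKS)
        result = sequence_spectrum(s, CATALOG)
        scores = [o.score for o in result.orderings]
        assert scores == sorted(scores, reverse=True)
        for a, b in zip(result.orderings, result.orderings[1:]):
            if a.score == b.score:
                assert a.rank == b.rank

    def test_deterministic_reports(self):
        s = spectrum(857.65, TestScoreOrdering.TRIMER_PEAKS, "det")
        first = json.dumps(sequence_spectrum(s, CATALOG).to_dict())
        second = json.dumps(sequence_spectrum(s, CATALOG).to_dict())
        assert first == second


class TestAssembleOverlaps:
    def test_suffix_prefix_merge(self):
        merges = assemble_overlaps([("X", "Y", "Z"), ("Y", "Z", "W")], min_overlap=1)
        best = merges[0]
        assert best.merged == ("X", "Y", "Z", "W")
        assert best.overlap == 2

    def test_disjoint_fragments_do_not_merge(self):
        assert assemble_overlaps([("X", "Y"), ("Z", "W")]) == []

    def test_sorted_by_overlap_descending(self):
        frags = [("A", "B", "C"), ("B", "C", "D"), ("C", "D")]
        merges = assemble_overlaps(frags, min_overlap=1)
        overlaps = [m.overlap for m in merges]
        assert overlaps == sorted(overlaps, reverse=True)

    def test_min_overlap_validated(self):
        with pytest.raises(ValueError):
            assemble_overlaps([("X",)], min_overlap=0)

    def test_windows_of_simulated_polymers_reassemble(self):
        """Sliding 3-mer windows with 2-monomer overlaps rebuild the chain."""
        successes = 0
        n_seeds = 40
        for seed in range(n_seeds):
            polymer = build_polymer(CATALOG, n_monomers=6, seed=seed)
            truth = polymer.fragment_oligomer().ids
            windows = [truth[i : i + 3] for i in range(len(truth) - 2)]
            current = windows[0]
            for window in windows[1:]:
                merges = assemble_overlaps([current, window], min_overlap=2)
                forward = [m for m in merges if m.left_index == 0]
                if forward:
                    current = forward[0].merged
            if any(
                current[i : i + len(truth)] == truth
                for i in range(len(current) - len(truth) + 1)
            ):
                successes += 1
        assert successes / n_seeds >= 0.95
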