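"""Precursor decomposition, ordering inference and overlap assembly.

The deductive procedure mirrors how cutin oligomer structures are read from
negative-mode MS/MS data: the precursor mass is decomposed into monomer
multisets (each ester bond costs one water), every distinct ordering of each
multiset is scored by how many of its predicted ester-cleavage daughters are
present in the spectrum, and for trimers the monomer shared by two matched
dimer daughters is reported as the central monomer.

The score is a presence/absence count of matched predicted peaks; intensity
is recorded but unused by default because the underlying deduction argues
only from which daughter ions exist.  An oligomer and its reversal predict
identical fragment masses under ester-only cleavage, so the direction of a
sequence is intrinsically ambiguous to MS: score ties share a rank, are
flagged ambiguous, and are ordered deterministically only for presentation
(fewest invoked water losses, then lexicographic symbolic form).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .chem import AdductSpec, get_adduct, ion_mz, neutral_mass_for_ion, WATER
from .monomers import Monomer, MonomerCatalog, render_symbolic
from .oligomers import Oligomer, TheoreticalPeak, predict_ester_fragments

__all__ = [
    "CompositionCandidate",
    "MergeCandidate",
    "OrderingScore",
    "PeakMatchEvidence",
    "SequencingParams",
    "SequencingResult",
    "Spectrum",
    "assemble_overlaps",
    "decompose_precursor",
    "length_window",
    "score_ordering",
    "sequence_spectrum",
]

_WATER_MASS = WATER.mass

#: Observed m/z windows per oligomer length for [M-H]- ions: monomers span
#: 164-331, so an L-mer precursor is expected within L times that window.
_MONOMER_WINDOW = (164.0, 331.0)


def length_window(length: int) -> tuple[float, float]:
    """Expected precursor m/z window for an oligomer of ``length`` monomers."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return (_MONOMER_WINDOW[0] * length, _MONOMER_WINDOW[1] * length)


def lengths_for_precursor(mz: float, max_len: int = 6) -> tuple[int, int]:
    """Smallest and largest oligomer lengths whose window contains ``mz``."""
    lengths = [L for L in range(1, max_len + 1) if length_window(L)[0] <= mz <= length_window(L)[1]]
    if not lengths:
        return (1, max_len)
    return (min(lengths), max(lengths))


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS/MS spectrum: precursor descriptor plus peak list."""

    precursor_mz: float
    adduct: AdductSpec
    peaks: tuple[tuple[float, float], ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        peaks = tuple(sorted((float(mz), float(inten)) for mz, inten in self.peaks))
        if any(mz <= 0 for mz, _ in peaks):
            raise ValueError("peak m/z values must be positive")
        if any(inten < 0 for _, inten in peaks):
            raise ValueError("peak intensities must be non-negative")
        object.__setattr__(self, "peaks", peaks)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([mz for mz, _ in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([inten for _, inten in self.peaks], dtype=float)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class CompositionCandidate:
    """A monomer multiset whose dehydrated sum matches a precursor mass."""

    monomers: tuple[Monomer, ...]  # sorted by id
    theoretical_mz: float
    error_da: float
    error_ppm: float
    isobar: bool = False

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.monomers)

    def __len__(self) -> int:
        return len(self.monomers)


def decompose_precursor(
    mz: float,
    adduct: AdductSpec | str,
    catalog: MonomerCatalog,
    min_len: int = 1,
    max_len: int = 4,
    tol: float = 0.02,
    include_alcohols: bool = False,
) -> list[CompositionCandidate]:
    """All monomer multisets matching a precursor m/z within ``tol`` Da.

    Complete by construction: a depth-first search over mass-sorted
    monomers with an additive lower bound prunes only branches that already
    exceed the target, so no multiset within tolerance is missed (verified
    against exhaustive enumeration in the test-suite).  Candidates are
    sorted by absolute mass error; multisets whose elemental formulas
    coincide with another candidate are flagged as isobars.
    """
    if len(catalog) == 0:
        raise ValueError("cannot decompose against an empty catalog")
    if not 1 <= min_len <= max_len:
        raise ValueError(f"need 1 <= min_len <= max_len, got {min_len}..{max_len}")
    if max_len > 6:
        raise ValueError("max_len is capped at 6 (combinatorial bound)")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    adduct = get_adduct(adduct)
    target = neutral_mass_for_ion(mz, adduct)
    pool = [m for m in catalog if include_alcohols or not m.alcohol_only]
    pool.sort(key=lambda m: (m.neutral_mass, m.id))

    results: list[tuple[Monomer, ...]] = []
    chosen: list[Monomer] = []

    def recurse(start: int, dehydrated_sum: float) -> None:
        k = len(chosen)
        if k >= min_len and abs(dehydrated_sum - target) <= tol:
            results.append(tuple(chosen))
        if k == max_len:
            return
        for idx in range(start, len(pool)):
            m = pool[idx]
            added = dehydrated_sum + m.neutral_mass - (_WATER_MASS if k else 0.0)
            if added - target > tol:
                break  # pool is mass-sorted; every later branch is heavier
            chosen.append(m)
            recurse(idx, added)
            chosen.pop()

    recurse(0, 0.0)

    candidates = []
    for combo in results:
        monomers = tuple(sorted(combo, key=lambda m: m.id))
        neutral = sum(m.neutral_mass for m in monomers) - (len(monomers) - 1) * _WATER_MASS
        theo = (neutral + adduct.delta_mass) / abs(adduct.charge)
        err = mz - theo
        candidates.append(
            CompositionCandidate(monomers, theo, err, err / theo * 1e6)
        )
    # flag isobaric candidate pairs (identical elemental formulas)
    formulas = {}
    for cand in candidates:
        f = _composition_formula(cand.monomers)
        formulas.setdefault(f, []).append(cand)
    flagged = []
    for cand in candidates:
        f = _composition_formula(cand.monomers)
        flagged.append(replace(cand, isobar=len(formulas[f]) > 1))
    flagged.sort(key=lambda c: (abs(c.error_da), c.ids))
    return flagged


def _composition_formula(monomers: tuple[Monomer, ...]):
    f = monomers[0].formula
    for m in monomers[1:]:
        f = f + m.formula
    return f - (len(monomers) - 1) * WATER


@dataclass(frozen=True)
class PeakMatchEvidence:
    """One predicted peak matched by one observed peak."""

    predicted: TheoreticalPeak
    observed_mz: float
    observed_intensity: float
    error_da: float
    error_ppm: float


@dataclass(frozen=True)
class OrderingScore:
    """Match evidence for one candidate ordering of a composition."""

    oligomer: Oligomer
    score: int
    water_losses_used: int
    matches: tuple[PeakMatchEvidence, ...]
    unmatched_predicted: tuple[TheoreticalPeak, ...]
    rank: int = 0

    @property
    def symbolic(self) -> str:
        return self.oligomer.symbolic


def _match_peaks(
    predicted: tuple[TheoreticalPeak, ...],
    spectrum: Spectrum,
    tol_da: float,
    tol_ppm: float,
) -> tuple[list[PeakMatchEvidence], list[TheoreticalPeak]]:
    obs = spectrum.mz_array
    intens = spectrum.intensity_array
    matches: list[PeakMatchEvidence] = []
    unmatched: list[TheoreticalPeak] = []
    for peak in predicted:
        if obs.size == 0:
            unmatched.append(peak)
            continue
        idx = int(np.argmin(np.abs(obs - peak.mz)))
        err = float(obs[idx] - peak.mz)
        err_ppm = err / peak.mz * 1e6
        if abs(err) <= tol_da or abs(err_ppm) <= tol_ppm:
            matches.append(
                PeakMatchEvidence(peak, float(obs[idx]), float(intens[idx]), err, err_ppm)
            )
        else:
            unmatched.append(peak)
    return matches, unmatched


def score_ordering(
    o: Oligomer,
    spectrum: Spectrum,
    tol_da: float = 0.02,
    tol_ppm: float = 10.0,
    max_water_loss: int = 2,
) -> OrderingScore:
    """Count how many predicted daughters of ``o`` appear in the spectrum."""
    predicted = predict_ester_fragments(o, spectrum.adduct, max_water_loss)
    matches, unmatched = _match_peaks(predicted, spectrum, tol_da, tol_ppm)
    return OrderingScore(
        oligomer=o,
        score=len(matches),
        water_losses_used=sum(ev.predicted.n_water_losses for ev in matches),
        matches=tuple(matches),
        unmatched_predicted=tuple(unmatched),
    )


@dataclass(frozen=True)
class CentralMonomerEvidence:
    """Trimer deduction: the monomer shared by two matched dimer daughters."""

    monomer_id: str
    dimer_species: tuple[str, str]
    dimer_mzs: tuple[float, float]


@dataclass
class SequencingParams:
    """Tunable knobs for :func:`sequence_spectrum`."""

    min_len: int | None = None
    max_len: int | None = None
    tol_da: float = 0.02
    tol_ppm: float = 10.0
    max_water_loss: int = 2
    include_alcohols: bool = False
    hard_max_len: int = 6

    def length_bounds(self, precursor_mz: float) -> tuple[int, int]:
        lo, hi = lengths_for_precursor(precursor_mz, self.hard_max_len)
        return (self.min_len or lo, self.max_len or hi)


@dataclass
class SequencingResult:
    """Ranked candidate orderings with per-peak evidence and ambiguity flags."""

    source_id: str
    precursor_mz: float
    adduct: str
    compositions: list[CompositionCandidate] = field(default_factory=list)
    orderings: list[OrderingScore] = field(default_factory=list)
    ambiguous: bool = False
    tied_top: tuple[str, ...] = ()
    central_monomer_evidence: CentralMonomerEvidence | None = None
    diagnostic: str = ""

    @property
    def top(self) -> OrderingScore | None:
        return self.orderings[0] if self.orderings else None

    def to_dict(self) -> dict:
        """JSON-ready report with deterministic field order."""
        return {
            "source_id": self.source_id,
            "precursor_mz": round(self.precursor_mz, 4),
            "adduct": self.adduct,
            "diagnostic": self.diagnostic,
            "ambiguous": self.ambiguous,
            "tied_top": list(self.tied_top),
            "central_monomer": (
                None
                if self.central_monomer_evidence is None
                else {
                    "monomer_id": self.central_monomer_evidence.monomer_id,
                    "dimer_species": list(self.central_monomer_evidence.dimer_species),
                    "dimer_mzs": [round(x, 4) for x in self.central_monomer_evidence.dimer_mzs],
                }
            ),
            "compositions": [
                {
                    "monomers": list(c.ids),
                    "theoretical_mz": round(c.theoretical_mz, 4),
                    "error_da": round(c.error_da, 4),
                    "error_ppm": round(c.error_ppm, 2),
                    "isobar": c.isobar,
                }
                for c in self.compositions
            ],
            "orderings": [
                {
                    "rank": s.rank,
                    "sequence": list(s.oligomer.ids),
                    "symbolic": s.symbolic,
                    "score": s.score,
                    "water_losses_used": s.water_losses_used,
                    "matched_peaks": [
                        {
                            "species": ev.predicted.species,
                            "theoretical_mz": round(ev.predicted.mz, 4),
                            "observed_mz": round(ev.observed_mz, 4),
                            "error_da": round(ev.error_da, 4),
                        }
                        for ev in s.matches
                    ],
                    "unmatched_predicted": [
                        {"species": p.species, "theoretical_mz": round(p.mz, 4)}
                        for p in s.unmatched_predicted
                    ],
                }
                for s in self.orderings
            ],
        }


def _distinct_orderings(monomers: tuple[Monomer, ...]) -> list[tuple[Monomer, ...]]:
    """Distinct permutations of a monomer multiset (multinomial, not factorial)."""
    by_id = {m.id: m for m in monomers}
    perms = sorted(set(itertools.permutations(tuple(m.id for m in monomers))))
    return [tuple(by_id[mid] for mid in perm) for perm in perms]


def _valid_ordering(seq: tuple[Monomer, ...]) -> bool:
    if not seq[0].carboxyls:
        return False
    return all(
        m.hydroxyls and seq[i + 1].carboxyls for i, m in enumerate(seq[:-1])
    )


def sequence_spectrum(
    spectrum: Spectrum,
    catalog: MonomerCatalog,
    params: SequencingParams | None = None,
) -> SequencingResult:
    """De novo sequencing of one MS/MS spectrum.

    Decomposes the precursor, enumerates every distinct valid ordering of
    each composition, scores them all, and ranks by score.  Equal scores
    share a (competition) rank and are flagged ambiguous -- ester-only
    fragmentation cannot, for example, distinguish a sequence from its
    reversal.  Deterministic for identical inputs.
    """
    params = params or SequencingParams()
    min_len, max_len = params.length_bounds(spectrum.precursor_mz)
    result = SequencingResult(
        source_id=spectrum.source_id,
        precursor_mz=spectrum.precursor_mz,
        adduct=get_adduct(spectrum.adduct).name,
    )
    result.compositions = decompose_precursor(
        spectrum.precursor_mz,
        spectrum.adduct,
        catalog,
        min_len=min_len,
        max_len=max_len,
        tol=params.tol_da,
        include_alcohols=params.include_alcohols,
    )
    if not result.compositions:
        result.diagnostic = (
            f"no monomer composition within {params.tol_da} Da of precursor "
            f"{spectrum.precursor_mz:.4f} (lengths {min_len}-{max_len})"
        )
        return result

    entries: list[OrderingScore] = []
    for comp in result.compositions:
        for seq in _distinct_orderings(comp.monomers):
            if not _valid_ordering(seq):
                continue
            entries.append(
                score_ordering(
                    Oligomer(seq),
                    spectrum,
                    tol_da=params.tol_da,
                    tol_ppm=params.tol_ppm,
                    max_water_loss=params.max_water_loss,
                )
            )
    if not entries:
        result.diagnostic = "compositions found but no structurally valid ordering"
        return result

    entries.sort(key=lambda s: (-s.score, s.water_losses_used, s.symbolic))
    ranked = []
    for s in entries:
        rank = 1 + sum(1 for other in entries if other.score > s.score)
        ranked.append(replace(s, rank=rank))
    result.orderings = ranked
    top_score = ranked[0].score
    top_set = [s for s in ranked if s.score == top_score]
    result.ambiguous = len(top_set) > 1
    result.tied_top = tuple(s.symbolic for s in top_set)
    result.central_monomer_evidence = _central_evidence(ranked[0])
    return result


def _central_evidence(top: OrderingScore) -> CentralMonomerEvidence | None:
    """For trimers: the monomer common to both matched dimer daughters."""
    if len(top.oligomer) != 3:
        return None
    dimer_matches: dict[tuple[int, int], PeakMatchEvidence] = {}
    for ev in top.matches:
        span = ev.predicted.span
        if span is not None and span[1] - span[0] == 1:
            best = dimer_matches.get(span)
            # prefer the intact (fewest-water-loss) dimer ion as evidence
            if best is None or ev.predicted.n_water_losses < best.predicted.n_water_losses:
                dimer_matches[span] = ev
    if {(0, 1), (1, 2)} <= set(dimer_matches):
        first, second = dimer_matches[(0, 1)], dimer_matches[(1, 2)]
        return CentralMonomerEvidence(
            monomer_id=top.oligomer.monomers[1].id,
            dimer_species=(first.predicted.species, second.predicted.species),
            dimer_mzs=(first.observed_mz, second.observed_mz),
        )
    return None


@dataclass(frozen=True)
class MergeCandidate:
    """Two fragments merged on a shared terminal run of monomers."""

    merged: tuple[str, ...]
    left_index: int
    right_index: int
    overlap: int


def assemble_overlaps(
    fragments: list[Oligomer] | list[tuple[str, ...]],
    min_overlap: int = 1,
) -> list[MergeCandidate]:
    """Merge fragment pairs whose terminal monomer runs overlap.

    For every ordered pair (u, v) where a suffix of u equals a prefix of v
    over k >= ``min_overlap`` monomers, the merged supersequence is emitted
    with confidence rank k (a longer overlap gives greater confidence that
    the fragments adjoin in the intact polymer).  Sorted by overlap length,
    descending.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seqs: list[tuple[str, ...]] = [
        f.ids if isinstance(f, Oligomer) else tuple(f) for f in fragments
    ]
    merges: list[MergeCandidate] = []
    for i, u in enumerate(seqs):
        for j, v in enumerate(seqs):
            if i == j:
                continue
            best_k = 0
            for k in range(min(len(u), len(v)), min_overlap - 1, -1):
                if u[-k:] == v[:k]:
                    best_k = k
                    break
            if best_k:
                merges.append(MergeCandidate(u + v[best_k:], i, j, best_k))
    merges.sort(key=lambda m: (-m.overlap, m.left_index, m.right_index))
    return merges
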