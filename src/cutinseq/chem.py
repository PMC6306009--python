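"""Elemental-formula arithmetic and exact-mass bookkeeping.

All mass arithmetic in this package is done on *neutral* elemental formulas;
ion m/z values are always derived from a neutral species plus an
:class:`AdductSpec`.  This is deliberate: summing deprotonated [M-H]- values
directly double-counts the lost proton, whereas neutral-based arithmetic
reproduces printed ester-oligomer ion values exactly.

Only monoisotopic masses are handled (no isotope envelopes), and fragment
charge states are restricted to |z| = 1, which is what electrospray of
fatty-acid oligomers produces in practice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterator, Mapping

__all__ = [
    "ADDUCTS",
    "AdductSpec",
    "DerivatizationTag",
    "Formula",
    "FormulaError",
    "MassMatch",
    "TAGS",
    "WATER",
    "combine",
    "get_adduct",
    "get_tag",
    "ion_mz",
    "mass_match",
    "monoisotopic_mass",
    "neutral_mass_for_ion",
    "printed_mz",
]

#: Monoisotopic atomic masses (Da) of the elements this package uses.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207100,
    "Li": 7.01600455,
    "Na": 22.98976928,
}

#: Mass of a hydrogen atom; used for (de)protonation (electron mass is below
#: the printed precision of Q-TOF data and is not corrected for).
HYDROGEN = MONOISOTOPIC_MASS["H"]


class FormulaError(ValueError):
    """Raised for invalid elemental-formula arithmetic or parsing."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping[str, int]):
    """An elemental formula: an immutable element -> count mapping.

    Supports ``+``, ``-`` (raising :class:`FormulaError` if a count would go
    negative) and ``*`` by a non-negative integer.  The empty formula has
    mass 0.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for elem, count in (counts or {}).items():
            if elem not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {elem!r}")
            if not isinstance(count, int):
                raise FormulaError(f"count for {elem} must be an integer, got {count!r}")
            if count < 0:
                raise FormulaError(f"negative count for element {elem}: {count}")
            if count:
                clean[elem] = count
        self._counts = clean

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse Hill-style text such as ``"C18H32O4"`` or ``"H2O"``."""
        text = text.strip()
        if not text:
            return cls()
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
            if not match.group(0):
                break
            elem, digits = match.group(1), match.group(2)
            if elem not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol {elem!r} in {text!r}")
            counts[elem] = counts.get(elem, 0) + (int(digits) if digits else 1)
            pos = match.end()
            if pos == len(text):
                break
        if pos != len(text):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, elem: str) -> int:
        return self._counts[elem]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, elem: str, default: int = 0) -> int:  # type: ignore[override]
        return self._counts.get(elem, default)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for elem, count in other.items():
            counts[elem] = counts.get(elem, 0) + count
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for elem, count in other.items():
            new = counts.get(elem, 0) - count
            if new < 0:
                raise FormulaError(
                    f"subtraction would give {new} atoms of {elem} "
                    f"({self.hill()} - {other.hill()})"
                )
            counts[elem] = new
        return Formula(counts)

    def __mul__(self, k: int) -> "Formula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError(f"formula multiplier must be a non-negative integer, got {k!r}")
        return Formula({elem: count * k for elem, count in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"

    # -- rendering and mass ----------------------------------------------
    def hill(self) -> str:
        """Serialize in Hill order: C, H, then remaining elements alphabetically."""
        parts = []
        for elem in ("C", "H"):
            if elem in self._counts:
                n = self._counts[elem]
                parts.append(elem + (str(n) if n != 1 else ""))
        for elem in sorted(set(self._counts) - {"C", "H"}):
            n = self._counts[elem]
            parts.append(elem + (str(n) if n != 1 else ""))
        return "".join(parts)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return sum(MONOISOTOPIC_MASS[elem] * count for elem, count in self._counts.items())


WATER = Formula({"H": 2, "O": 1})


def combine(a: Formula, b: Formula, sign: int = +1) -> Formula:
    """Elementwise combination ``a + sign*b`` with ``sign`` in {+1, -1}."""
    if sign == +1:
        return a + b
    if sign == -1:
        return a - b
    raise FormulaError(f"sign must be +1 or -1, got {sign!r}")


def monoisotopic_mass(f: Formula | str) -> float:
    """Monoisotopic mass (Da) of a formula or Hill-style formula text."""
    if isinstance(f, str):
        f = Formula.parse(f)
    return f.mass


@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: a signed formula change plus a charge.

    ``formula_delta`` maps element -> signed count change relative to the
    neutral molecule, e.g. ``{"H": -1}`` for [M-H]-.
    """

    name: str
    formula_delta: tuple[tuple[str, int], ...]
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")

    def apply(self, neutral: Formula) -> Formula:
        """Formula of the ionized species (still book-kept as atoms)."""
        out = neutral
        for elem, delta in self.formula_delta:
            if delta >= 0:
                out = out + Formula({elem: delta})
            else:
                out = out - Formula({elem: -delta})
        return out

    @property
    def delta_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[elem] * d for elem, d in self.formula_delta)


#: Built-in adducts.  Negative-mode spectra are assumed singly charged and
#: adduct ions are ignored in negative mode; the lithium adducts cover
#: Li-doped MALDI acquisition.
ADDUCTS: dict[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", (("H", -1),), -1),
    "[M+H]+": AdductSpec("[M+H]+", (("H", 1),), +1),
    "[M+Li]+": AdductSpec("[M+Li]+", (("Li", 1),), +1),
    "[M+2Li-H]+": AdductSpec("[M+2Li-H]+", (("Li", 2), ("H", -1)), +1),
}


def get_adduct(adduct: AdductSpec | str) -> AdductSpec:
    if isinstance(adduct, AdductSpec):
        return adduct
    try:
        return ADDUCTS[adduct]
    except KeyError:
        raise KeyError(
            f"unknown adduct {adduct!r}; built-ins: {', '.join(ADDUCTS)}"
        ) from None


def ion_mz(neutral: Formula, adduct: AdductSpec | str) -> float:
    """m/z of ``neutral`` ionized as ``adduct`` (full float precision)."""
    spec = get_adduct(adduct)
    return spec.apply(neutral).mass / abs(spec.charge)


def neutral_mass_for_ion(mz: float, adduct: AdductSpec | str) -> float:
    """Neutral monoisotopic mass implied by an observed ion m/z."""
    spec = get_adduct(adduct)
    return mz * abs(spec.charge) - spec.delta_mass


def printed_mz(mz: float, ndigits: int = 2) -> float:
    """Round half-away-from-zero, matching how instrument software prints m/z."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(mz)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MassMatch:
    """Result of comparing an observed against a theoretical m/z."""

    observed: float
    theoretical: float
    error_da: float
    error_ppm: float
    within_tolerance: bool


def mass_match(
    observed: float,
    theoretical: float,
    tol_ppm: float | None = 10.0,
    tol_da: float | None = 0.02,
) -> MassMatch:
    """Compare two m/z values; a match passes if EITHER tolerance is satisfied.

    Defaults (10 ppm or 0.02 Da) absorb the drift of printed Q-TOF values
    from theory, which reaches ~0.02 Da.
    """
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    for tol in (tol_ppm, tol_da):
        if tol is not None and tol < 0:
            raise ValueError("tolerances must be non-negative")
    error_da = observed - theoretical
    error_ppm = error_da / theoretical * 1e6
    ok = False
    if tol_ppm is not None and abs(error_ppm) <= tol_ppm:
        ok = True
    if tol_da is not None and abs(error_da) <= tol_da:
        ok = True
    return MassMatch(observed, theoretical, error_da, error_ppm, ok)


@dataclass(frozen=True)
class DerivatizationTag:
    """A group-specific chemical label adding a fixed formula per site.

    ``site_class`` is ``"hydroxyl"`` or ``"carboxyl"``: hydroxyl tags report
    free (non-esterified) OH groups of the intact polymer, carboxyl tags
    report free acid ends.
    """

    name: str
    site_class: str
    formula_delta: Formula

    def __post_init__(self) -> None:
        if self.site_class not in ("hydroxyl", "carboxyl"):
            raise ValueError(f"site_class must be 'hydroxyl' or 'carboxyl', got {self.site_class!r}")


#: Built-in derivatization chemistries.  Deltas are reagent-minus-leaving-group:
#: dansyl chloride on OH adds C12H11NO2S, benzylation (2-benzyloxy-1-methyl-
#: pyridinium triflate) adds C7H6 as a benzyl ether, and DmPA bromide
#: esterifies a free carboxyl adding C10H11NO.
TAGS: dict[str, DerivatizationTag] = {
    "dansyl": DerivatizationTag("dansyl", "hydroxyl", Formula.parse("C12H11NO2S")),
    "benzyl": DerivatizationTag("benzyl", "hydroxyl", Formula.parse("C7H6")),
    "DmPA": DerivatizationTag("DmPA", "carboxyl", Formula.parse("C10H11NO")),
}


def get_tag(tag: DerivatizationTag | str) -> DerivatizationTag:
    if isinstance(tag, DerivatizationTag):
        return tag
    try:
        return TAGS[tag]
    except KeyError:
        raise KeyError(f"unknown derivatization tag {tag!r}; built-ins: {', '.join(TAGS)}") from None
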