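"""Ordered cutin oligomers and MS/MS fragment prediction.

An oligomer is an ordered sequence of monomers joined by ester bonds.  Index
0 (position 1) is the free-carboxyl terminus; monomer ``i+1`` esterifies a
hydroxyl of monomer ``i`` with its own carboxyl group.  "A acylated by B"
therefore reads as the sequence ``[A, B]``.  Linkage sites default to the
omega hydroxyl of the host monomer; a mid-chain linkage changes free-OH
counts but not fragment masses, which is why MS alone cannot fix linkage
regiochemistry.

Collision-induced ester cleavage is modeled as hydrolysis-form fragments on
both sides of every broken bond (full acid and alcohol termini), each with
up to ``max_water_loss`` serial neutral water losses bounded by the
fragment's free hydroxyl count.  This single rule reproduces the observed
dimer/trimer daughter ions of cutin oligomers without modeling acid/ketene
channels explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import (
    WATER,
    AdductSpec,
    DerivatizationTag,
    Formula,
    get_adduct,
    ion_mz,
)
from .monomers import Monomer, render_symbolic

__all__ = [
    "Oligomer",
    "OligomerError",
    "TheoreticalPeak",
    "precursor_mz",
    "predict_chain_cleavage_ions",
    "predict_ester_fragments",
]


class OligomerError(ValueError):
    """Raised for structurally invalid oligomers."""


@dataclass(frozen=True)
class Oligomer:
    """An ordered ester-linked chain of monomers.

    ``linkage_sites[i]`` is the hydroxyl position on ``monomers[i]``
    esterified by the carboxyl of ``monomers[i+1]``; ``tags`` attaches
    derivatization labels to (monomer index, tag) pairs.
    """

    monomers: tuple[Monomer, ...]
    linkage_sites: tuple[int, ...] = ()
    tags: tuple[tuple[int, DerivatizationTag], ...] = ()

    def __post_init__(self) -> None:
        if not self.monomers:
            raise OligomerError("an oligomer needs at least one monomer")
        sites = self.linkage_sites
        if not sites and len(self.monomers) > 1:
            sites = tuple(self._default_site(m) for m in self.monomers[:-1])
            object.__setattr__(self, "linkage_sites", sites)
        if len(sites) != len(self.monomers) - 1:
            raise OligomerError(
                f"need {len(self.monomers) - 1} linkage sites, got {len(sites)}"
            )
        if not self.monomers[0].carboxyls:
            raise OligomerError(
                "the first monomer must retain a free carboxyl "
                f"({self.monomers[0].id} has none)"
            )
        for i, site in enumerate(sites):
            host = self.monomers[i]
            if site not in host.hydroxyls:
                raise OligomerError(
                    f"linkage site {site} is not a hydroxyl of {host.id}"
                )
            if not self.monomers[i + 1].carboxyls:
                raise OligomerError(
                    f"{self.monomers[i + 1].id} has no carboxyl to form the ester at "
                    f"position {i + 2}"
                )
        for idx, tag in self.tags:
            if not 0 <= idx < len(self.monomers):
                raise OligomerError(f"tag index {idx} out of range")

    @staticmethod
    def _default_site(m: Monomer) -> int:
        site = m.omega_hydroxyl
        if site is None:
            raise OligomerError(f"{m.id} has no hydroxyl to accept an ester bond")
        return site

    def __len__(self) -> int:
        return len(self.monomers)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.monomers)

    @property
    def formula(self) -> Formula:
        """Neutral formula: monomer sum minus one water per ester bond."""
        f = Formula()
        for m in self.monomers:
            f = f + m.formula
        f = f - (len(self.monomers) - 1) * WATER
        for _, tag in self.tags:
            f = f + tag.formula_delta
        return f

    @property
    def neutral_mass(self) -> float:
        return self.formula.mass

    @property
    def free_hydroxyl_count(self) -> int:
        """Hydroxyls not consumed by internal ester bonds."""
        return sum(len(m.hydroxyls) for m in self.monomers) - (len(self.monomers) - 1)

    def mz(self, adduct: AdductSpec | str = "[M-H]-") -> float:
        return ion_mz(self.formula, adduct)

    @property
    def symbolic(self) -> str:
        return render_symbolic(self)

    def reversed(self) -> "Oligomer":
        """The same monomers read from the opposite terminus (default sites)."""
        return Oligomer(tuple(reversed(self.monomers)))

    def __str__(self) -> str:
        return "/".join(self.ids)


def precursor_mz(o: Oligomer, adduct: AdductSpec | str = "[M-H]-") -> float:
    """Precursor m/z of an oligomer; equals the monomer ion for length 1."""
    return o.mz(adduct)


@dataclass(frozen=True)
class TheoreticalPeak:
    """A predicted fragment ion."""

    mz: float
    species: str
    monomer_ids: tuple[str, ...]
    n_water_losses: int
    cleavage: str
    span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("theoretical peak m/z must be positive")


def predict_ester_fragments(
    o: Oligomer,
    adduct: AdductSpec | str = "[M-H]-",
    max_water_loss: int = 2,
    include_internal: bool | None = None,
) -> tuple[TheoreticalPeak, ...]:
    """Predict ester-cleavage daughter ions of an oligomer.

    Every contiguous subsequence reachable by cleaving ester bonds is emitted
    in hydrolysis form with 0..min(``max_water_loss``, free OH) additional
    water losses; single monomers are always included.  Internal fragments
    (requiring two cleavages) are opt-in via ``include_internal``: they are
    weak in practice -- observed daughter ions of cutin oligomers are
    explained by terminal (single-cleavage) fragments -- and their
    mass coincidences with water-loss forms of terminal fragments degrade
    ordering discrimination.  Peaks are deduplicated by (rounded m/z,
    ordered species) and sorted by m/z; the combinatorial cost is bounded
    by the hard length cap of 6.
    """
    if max_water_loss < 0:
        raise ValueError("max_water_loss must be >= 0")
    length = len(o)
    if include_internal is None:
        include_internal = False
    adduct = get_adduct(adduct)
    tag_by_index: dict[int, list[DerivatizationTag]] = {}
    for idx, tag in o.tags:
        tag_by_index.setdefault(idx, []).append(tag)

    seen: dict[tuple[float, tuple[str, ...]], TheoreticalPeak] = {}
    for i in range(length):
        for j in range(i, length):
            is_terminal = i == 0 or j == length - 1
            if not (is_terminal or i == j or include_internal):
                continue
            members = o.monomers[i : j + 1]
            sub_len = j - i + 1
            base = Formula()
            for m in members:
                base = base + m.formula
            base = base - (sub_len - 1) * WATER
            for idx in range(i, j + 1):
                for tag in tag_by_index.get(idx, ()):
                    base = base + tag.formula_delta
            free_oh = sum(len(m.hydroxyls) for m in members) - (sub_len - 1)
            ids = tuple(m.id for m in members)
            if i == 0 and j == length - 1:
                cleavage = "intact"
            elif i == 0:
                cleavage = f"ester {j + 1}-{j + 2}"
            elif j == length - 1:
                cleavage = f"ester {i}-{i + 1}"
            else:
                cleavage = f"esters {i}-{i + 1} and {j + 1}-{j + 2}"
            for w in range(0, min(max_water_loss, free_oh) + 1):
                mz = ion_mz(base - w * WATER, adduct)
                key = (round(mz, 4), ids)
                if key in seen:
                    continue
                seen[key] = TheoreticalPeak(
                    mz=mz,
                    species="/".join(ids) + (f" -{w}H2O" if w else ""),
                    monomer_ids=ids,
                    n_water_losses=w,
                    cleavage=cleavage,
                    span=(i, j),
                )
    return tuple(sorted(seen.values(), key=lambda p: (p.mz, p.species)))


def _chain_side_formulas(
    m: Monomer, k: int, side: str
) -> list[Formula]:
    """Candidate neutral formulas for one side of a C(k)-C(k+1) chain cut.

    The acid side keeps the carboxyl; hydroxyls contribute +O, intact
    epoxides +O -2H.  An epoxide split by the cut donates its oxygen to
    either side, arriving as a hydroxyl (+O) or a carbonyl (+O -2H).
    Hydrogen-transfer offsets of -1/0/+1 H and an optional water loss are
    applied by the caller.  Double bonds (positions untracked) are assigned
    to each side in every feasible number, since candidates -- not
    assertions -- are wanted.
    """
    n = m.n
    if side == "acid":
        carbons = range(1, k + 1)
        n_carb = k
        base_h = 2 * k
    else:
        carbons = range(k + 1, n + 1)
        n_carb = n - k
        base_h = 2 * n_carb
    carbon_set = set(carbons)
    oxygens = 2 * sum(1 for c in m.carboxyls if c in carbon_set)
    oxygens += sum(1 for p in m.hydroxyls if p in carbon_set)
    h = base_h
    split_epoxy = False
    for p, q in m.epoxies:
        if p in carbon_set and q in carbon_set:
            oxygens += 1
            h -= 2
        elif p in carbon_set or q in carbon_set:
            split_epoxy = True
    variants: list[tuple[int, int]] = [(oxygens, h)]
    if split_epoxy:
        variants.append((oxygens + 1, h))      # epoxide O arrives as hydroxyl
        variants.append((oxygens + 1, h - 2))  # epoxide O arrives as carbonyl
    out = []
    for o_count, h_count in variants:
        for db_on_side in range(0, m.d + 1):
            hh = h_count - 2 * db_on_side
            if hh > 0 and n_carb > 0:
                out.append(Formula({"C": n_carb, "H": hh, "O": o_count}))
    return out


def predict_chain_cleavage_ions(
    m: Monomer, adduct: AdductSpec | str = "[M-H]-"
) -> tuple[TheoreticalPeak, ...]:
    """Candidate C-C cleavage diagnostic ions localizing mid-chain oxygens.

    For every C-C bond adjacent to (or inside the span of) a mid-chain
    oxygen-bearing carbon, both cleavage-side formulas are generated with
    hydrogen-transfer offsets in {-1, 0, +1} H and 0-1 water losses.  These
    are candidates to match against observed peaks (at a looser tolerance,
    typically 0.03 Da), not asserted assignments.  A monomer without
    mid-chain oxygens yields an empty result.
    """
    adduct = get_adduct(adduct)
    mid_ox: set[int] = {p for p in m.hydroxyls if 1 < p < m.n}
    for span in m.epoxies:
        mid_ox.update(c for c in span if 1 < c < m.n)
    if not mid_ox:
        return ()
    bonds: set[tuple[int, int]] = set()
    for c in mid_ox:
        if c - 1 >= 1:
            bonds.add((c - 1, c))
        if c + 1 <= m.n:
            bonds.add((c, c + 1))
    seen: dict[float, TheoreticalPeak] = {}
    for k, k1 in sorted(bonds):
        for side in ("acid", "distal"):
            for base in _chain_side_formulas(m, k, side):
                for h_off in (-1, 0, 1):
                    try:
                        shifted = (
                            base + Formula({"H": h_off})
                            if h_off >= 0
                            else base - Formula({"H": -h_off})
                        )
                    except Exception:
                        continue
                    for w in (0, 1):
                        try:
                            f = shifted - w * WATER
                        except Exception:
                            continue
                        if not f.get("C") or f.get("H", 0) < 1:
                            continue
                        try:
                            mz = ion_mz(f, adduct)
                        except Exception:
                            continue
                        if mz <= 0:
                            continue
                        key = round(mz, 4)
                        if key in seen:
                            continue
                        seen[key] = TheoreticalPeak(
                            mz=mz,
                            species=f.hill(),
                            monomer_ids=(m.id,),
                            n_water_losses=w,
                            cleavage=f"C{k}-C{k1} {side} side",
                        )
    return tuple(sorted(seen.values(), key=lambda p: p.mz))
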