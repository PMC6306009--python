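"""Cutin monomer descriptors, shorthand grammar, and the monomer catalog.

A cutin monomer is a C16-C30 acyl chain described by its carbon count ``n``,
number of double bonds ``d``, hydroxyl positions, epoxy spans, and carboxyl
positions.  Carbons are numbered 1-based from the carboxyl carbon, so the
omega (chain-end) carbon is ``n``.  Fatty alcohols (no carboxyl) are
supported as catalog entries but never appear in negative-mode oligomers,
which require a free carboxyl to ionize.

The neutral formula follows from the descriptors alone::

    C_n H_(2n - 2d - 2*n_epoxy - 2*(n_carboxyl - 1)) O_(2*n_carboxyl + n_OH + n_epoxy)

for acids, and ``C_n H_(2n + 2 - 2d - 2*n_epoxy) O_(n_OH + n_epoxy)`` for
alcohols.  Epoxides are modeled as +O -2H across adjacent carbons;
double-bond positions and epoxide stereochemistry are not represented
because single-stage MS cannot resolve them.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Sequence

from .chem import ADDUCTS, AdductSpec, Formula, get_adduct, ion_mz, neutral_mass_for_ion

__all__ = [
    "Monomer",
    "MonomerCatalog",
    "MonomerError",
    "default_catalog",
    "monomer",
    "parse_shorthand",
    "parse_symbolic",
    "render_shorthand",
    "render_symbolic",
]


class MonomerError(ValueError):
    """Raised for invalid monomer descriptors or unparseable shorthand."""


_HYDROXY_PREFIX = {1: "hydroxy", 2: "dihydroxy", 3: "trihydroxy", 4: "tetrahydroxy"}
_PREFIX_COUNT = {v: k for k, v in _HYDROXY_PREFIX.items()}


@dataclass(frozen=True)
class Monomer:
    """A cutin building block (hydroxy/epoxy fatty acid, diacid or alcohol)."""

    id: str
    n: int
    d: int
    hydroxyls: frozenset[int] = frozenset()
    epoxies: frozenset[tuple[int, int]] = frozenset()
    carboxyls: frozenset[int] = frozenset({1})

    def __post_init__(self) -> None:
        if self.n < 2:
            raise MonomerError(f"{self.id}: chain length must be >= 2, got {self.n}")
        if self.d < 0:
            raise MonomerError(f"{self.id}: double-bond count must be >= 0")
        if self.carboxyls and 1 not in self.carboxyls:
            raise MonomerError(f"{self.id}: carboxyl set of an acid must contain position 1")
        if not self.carboxyls <= {1, self.n}:
            raise MonomerError(f"{self.id}: carboxyls restricted to positions 1 and {self.n}")
        lo = 1 if self.alcohol_only else 2
        epoxy_carbons: set[int] = set()
        for span in self.epoxies:
            if len(span) != 2 or span[1] != span[0] + 1:
                raise MonomerError(f"{self.id}: epoxy span {span} must be adjacent carbons (p, p+1)")
            epoxy_carbons.update(span)
        positions = set(self.hydroxyls) | epoxy_carbons
        carboxyl_extra = self.carboxyls - {1}
        if any(p < lo or p > self.n for p in positions):
            raise MonomerError(f"{self.id}: substituent positions must lie in [{lo}, {self.n}]")
        if self.hydroxyls & epoxy_carbons or positions & carboxyl_extra:
            raise MonomerError(f"{self.id}: hydroxyl, epoxy and carboxyl positions must be disjoint")
        h = self._hydrogens()
        if h < 0:
            raise MonomerError(f"{self.id}: descriptors imply a negative hydrogen count")

    # -- derived chemistry ------------------------------------------------
    @property
    def alcohol_only(self) -> bool:
        """True for fatty alcohols (no carboxyl group)."""
        return not self.carboxyls

    def _hydrogens(self) -> int:
        if self.alcohol_only:
            return 2 * self.n + 2 - 2 * self.d - 2 * len(self.epoxies)
        return 2 * self.n - 2 * self.d - 2 * len(self.epoxies) - 2 * (len(self.carboxyls) - 1)

    @property
    def formula(self) -> Formula:
        oxygens = len(self.hydroxyls) + len(self.epoxies) + 2 * len(self.carboxyls)
        return Formula({"C": self.n, "H": self._hydrogens(), "O": oxygens})

    @property
    def neutral_mass(self) -> float:
        return self.formula.mass

    def mz(self, adduct: AdductSpec | str = "[M-H]-") -> float:
        return ion_mz(self.formula, adduct)

    @property
    def omega_hydroxyl(self) -> int | None:
        """Default ester-linkage donor site: the omega OH, else the highest OH."""
        if not self.hydroxyls:
            return None
        return self.n if self.n in self.hydroxyls else max(self.hydroxyls)

    def __str__(self) -> str:
        return self.id


def formula_from_descriptors(m: Monomer) -> Formula:
    """Neutral elemental formula implied by a monomer's descriptors."""
    return m.formula


def monomer(
    n: int,
    d: int = 0,
    hydroxyls: Iterable[int] = (),
    epoxies: Iterable[tuple[int, int]] = (),
    carboxyls: Iterable[int] = (1,),
) -> Monomer:
    """Build a monomer with a canonical shorthand id derived from the fields."""
    m = Monomer(
        id="",
        n=n,
        d=d,
        hydroxyls=frozenset(hydroxyls),
        epoxies=frozenset(tuple(s) for s in epoxies),
        carboxyls=frozenset(carboxyls),
    )
    return Monomer(render_shorthand(m), m.n, m.d, m.hydroxyls, m.epoxies, m.carboxyls)


# ---------------------------------------------------------------------------
# shorthand grammar: "<positions>-<prefix>-...-<n>:<d>[-diacid|-ol]"
# e.g. "9,10,18-trihydroxy-18:0", "18-hydroxy-9,10-epoxy-18:1", "16:0",
#      "16:0-diacid", "26:0-ol"
# ---------------------------------------------------------------------------

_BASE_RE = re.compile(r"^(\d+):(\d+)$")


def render_shorthand(m: Monomer) -> str:
    """Canonical shorthand for a monomer (hydroxyls first, then epoxies)."""
    parts = []
    shown_oh = set(m.hydroxyls)
    if m.alcohol_only:
        shown_oh.discard(1)  # the "-ol" suffix implies the 1-OH
    if shown_oh:
        oh = sorted(shown_oh)
        prefix = _HYDROXY_PREFIX.get(len(oh))
        if prefix is None:
            raise MonomerError(f"no shorthand prefix for {len(oh)} hydroxyls")
        parts.append(f"{','.join(map(str, oh))}-{prefix}")
    for span in sorted(m.epoxies):
        parts.append(f"{span[0]},{span[1]}-epoxy")
    base = f"{m.n}:{m.d}"
    if m.alcohol_only:
        base += "-ol"
    elif len(m.carboxyls) == 2:
        base += "-diacid"
    parts.append(base)
    return "-".join(parts)


def parse_shorthand(text: str) -> Monomer:
    """Parse shorthand such as ``"9,10,18-trihydroxy-18:0"`` into a monomer.

    Round-trips with :func:`render_shorthand`: ``render(parse(s))`` is the
    canonical form of ``s``.
    """
    tokens = text.strip().split("-")
    if not tokens or not tokens[0]:
        raise MonomerError(f"cannot parse monomer shorthand {text!r}")
    suffix = None
    if tokens[-1] in ("diacid", "ol"):
        suffix = tokens.pop()
    if not tokens:
        raise MonomerError(f"cannot parse monomer shorthand {text!r}")
    base = _BASE_RE.match(tokens.pop())
    if base is None:
        raise MonomerError(f"cannot parse monomer shorthand {text!r}: missing '<n>:<d>' tail")
    n, d = int(base.group(1)), int(base.group(2))
    if len(tokens) % 2:
        raise MonomerError(f"cannot parse monomer shorthand {text!r}")
    hydroxyls: set[int] = set()
    epoxies: set[tuple[int, int]] = set()
    for positions_text, keyword in zip(tokens[0::2], tokens[1::2]):
        try:
            positions = [int(p) for p in positions_text.split(",")]
        except ValueError:
            raise MonomerError(f"bad position list {positions_text!r} in {text!r}") from None
        if keyword == "epoxy":
            if len(positions) != 2:
                raise MonomerError(f"epoxy span needs exactly two positions in {text!r}")
            epoxies.add((min(positions), max(positions)))
        elif keyword in _PREFIX_COUNT:
            if len(positions) != _PREFIX_COUNT[keyword]:
                raise MonomerError(
                    f"{keyword!r} expects {_PREFIX_COUNT[keyword]} positions, "
                    f"got {len(positions)} in {text!r}"
                )
            hydroxyls.update(positions)
        else:
            raise MonomerError(f"unknown substituent keyword {keyword!r} in {text!r}")
    if suffix == "ol":
        carboxyls: frozenset[int] = frozenset()
        hydroxyls.add(1)  # primary fatty alcohol
    elif suffix == "diacid":
        carboxyls = frozenset({1, n})
    else:
        carboxyls = frozenset({1})
    return monomer(n, d, hydroxyls, epoxies, carboxyls)


# ---------------------------------------------------------------------------
# symbolic (one-line schematic) grammar
#   monomer  := "[<n>:<d>|COOH@1{,n}|OH@p1,p2,...|EP@p-q]"   (empty fields omitted)
#   oligomer := monomers joined by " <=(pos)= ", left to right from the
#               free-carboxyl terminus; pos is the esterified hydroxyl
#               position on the left monomer.
# ---------------------------------------------------------------------------

_SYM_MONOMER_RE = re.compile(r"^\[(\d+):(\d+)((?:\|[A-Z]+@[\d,\-]+)*)\]$")
_SYM_LINK_RE = re.compile(r"\s*<=\((\d+)\)=\s*")


def render_symbolic(obj) -> str:
    """One-line schematic encoding of a monomer or an ordered oligomer."""
    from .oligomers import Oligomer  # local import to avoid a cycle

    if isinstance(obj, Monomer):
        fields = [f"{obj.n}:{obj.d}"]
        if obj.carboxyls:
            fields.append("COOH@" + ",".join(map(str, sorted(obj.carboxyls))))
        if obj.hydroxyls:
            fields.append("OH@" + ",".join(map(str, sorted(obj.hydroxyls))))
        for span in sorted(obj.epoxies):
            fields.append(f"EP@{span[0]}-{span[1]}")
        return "[" + "|".join(fields) + "]"
    if isinstance(obj, Oligomer):
        parts = [render_symbolic(obj.monomers[0])]
        for site, mono in zip(obj.linkage_sites, obj.monomers[1:]):
            parts.append(f" <=({site})= ")
            parts.append(render_symbolic(mono))
        return "".join(parts)
    raise TypeError(f"cannot render {type(obj).__name__} symbolically")


def _parse_symbolic_monomer(text: str) -> Monomer:
    match = _SYM_MONOMER_RE.match(text.strip())
    if match is None:
        raise MonomerError(f"cannot parse symbolic monomer {text!r}")
    n, d = int(match.group(1)), int(match.group(2))
    hydroxyls: set[int] = set()
    epoxies: set[tuple[int, int]] = set()
    carboxyls: set[int] = set()
    for item in match.group(3).split("|"):
        if not item:
            continue
        key, _, value = item.partition("@")
        if key == "COOH":
            carboxyls.update(int(p) for p in value.split(","))
        elif key == "OH":
            hydroxyls.update(int(p) for p in value.split(","))
        elif key == "EP":
            p, q = value.split("-")
            epoxies.add((int(p), int(q)))
        else:
            raise MonomerError(f"unknown symbolic field {key!r} in {text!r}")
    return monomer(n, d, hydroxyls, epoxies, carboxyls)


def parse_symbolic(text: str):
    """Parse the symbolic grammar back into a Monomer or Oligomer."""
    from .oligomers import Oligomer

    pieces = _SYM_LINK_RE.split(text.strip())
    monomers = [_parse_symbolic_monomer(p) for p in pieces[0::2]]
    sites = [int(s) for s in pieces[1::2]]
    if len(monomers) == 1:
        return monomers[0]
    return Oligomer(tuple(monomers), tuple(sites))


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("id", "n", "d", "oh_positions", "epoxy_spans", "carboxyls")


class MonomerCatalog:
    """An ordered, id-unique collection of monomers with mass lookup.

    Isobaric entries (identical formulas) are never merged: mass lookup
    returns every entry within tolerance.
    """

    def __init__(self, monomers: Iterable[Monomer]):
        self._monomers: list[Monomer] = []
        self._by_id: dict[str, Monomer] = {}
        for m in monomers:
            if m.id in self._by_id:
                raise MonomerError(f"duplicate monomer id in catalog: {m.id!r}")
            self._monomers.append(m)
            self._by_id[m.id] = m

    def __iter__(self) -> Iterator[Monomer]:
        return iter(self._monomers)

    def __len__(self) -> int:
        return len(self._monomers)

    def __contains__(self, monomer_id: str) -> bool:
        return monomer_id in self._by_id

    def get(self, monomer_id: str) -> Monomer:
        try:
            return self._by_id[monomer_id]
        except KeyError:
            raise KeyError(f"monomer {monomer_id!r} not in catalog") from None

    def acids(self) -> "MonomerCatalog":
        """The catalog restricted to carboxyl-bearing entries (no alcohols)."""
        return MonomerCatalog(m for m in self if not m.alcohol_only)

    def lookup_neutral_mass(self, mass: float, tol_da: float = 0.01) -> list[Monomer]:
        """All entries whose neutral mass lies within ``tol_da`` of ``mass``."""
        return [m for m in self if abs(m.neutral_mass - mass) <= tol_da]

    def lookup_ion_mz(
        self, mz: float, adduct: AdductSpec | str = "[M-H]-", tol_da: float = 0.01
    ) -> list[Monomer]:
        """All entries matching an observed ion m/z within ``tol_da``."""
        return self.lookup_neutral_mass(neutral_mass_for_ion(mz, adduct), tol_da)

    # -- TSV interchange --------------------------------------------------
    @classmethod
    def from_tsv(cls, source) -> "MonomerCatalog":
        """Read a catalog from TSV with columns id, n, d, oh_positions,
        epoxy_spans, carboxyls (comma-separated position lists, epoxy spans
        as ``p-q``; empty carboxyls marks a fatty alcohol)."""
        if hasattr(source, "read"):
            lines = source.read().splitlines()
        else:
            with open(source, encoding="utf-8") as fh:
                lines = fh.read().splitlines()
        rows = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
        if not rows:
            return cls([])
        header = tuple(rows[0].rstrip("\n").split("\t"))
        if header != _TSV_COLUMNS:
            raise MonomerError(f"catalog TSV header must be {_TSV_COLUMNS}, got {header}")
        out = []
        for ln in rows[1:]:
            cells = ln.split("\t")
            if len(cells) != len(_TSV_COLUMNS):
                raise MonomerError(f"catalog TSV row has {len(cells)} cells: {ln!r}")
            rid, n, d, oh, ep, cooh = (c.strip() for c in cells)
            hydroxyls = frozenset(int(p) for p in oh.split(",") if p)
            epoxies = frozenset(
                tuple(int(p) for p in span.split("-")) for span in ep.split(",") if span
            )
            carboxyls = frozenset(int(p) for p in cooh.split(",") if p)
            m = Monomer(rid, int(n), int(d), hydroxyls, epoxies, carboxyls)
            canonical = render_shorthand(m)
            if rid != canonical:
                raise MonomerError(f"catalog id {rid!r} is not canonical (expected {canonical!r})")
            out.append(m)
        return cls(out)

    def to_tsv(self, dest=None) -> str:
        """Serialize to canonical TSV text; optionally also write to ``dest``."""
        lines = ["\t".join(_TSV_COLUMNS)]
        for m in self:
            lines.append(
                "\t".join(
                    (
                        m.id,
                        str(m.n),
                        str(m.d),
                        ",".join(map(str, sorted(m.hydroxyls))),
                        ",".join(f"{p}-{q}" for p, q in sorted(m.epoxies)),
                        ",".join(map(str, sorted(m.carboxyls))),
                    )
                )
            )
        text = "\n".join(lines) + "\n"
        if dest is not None:
            if hasattr(dest, "write"):
                dest.write(text)
            else:
                with open(dest, "w", encoding="utf-8") as fh:
                    fh.write(text)
        return text

    def checksum(self) -> str:
        """SHA-256 of the canonical TSV serialization (report provenance)."""
        return hashlib.sha256(self.to_tsv().encode("utf-8")).hexdigest()


def default_catalog() -> MonomerCatalog:
    """The built-in apple-cutin monomer catalog.

    Covers the quantified hydroxy/epoxy C16-C18 acids plus the extended set
    (diacids, 2-hydroxy acids, very-long-chain acids and fatty alcohols).
    Alcohols are catalog entries but participate in sequencing only when
    explicitly enabled, since they cannot carry the free carboxyl that
    negative-mode detection requires.
    """
    text = resources.files("cutinseq.data").joinpath("default_catalog.tsv").read_text("utf-8")
    return MonomerCatalog.from_tsv(_stdio.StringIO(text))
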