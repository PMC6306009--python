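"""Interpretation of group-specific derivatization experiments.

Dansylation and benzyl-O-alkylation label hydroxyls that were free (not
esterified) in the intact polymer; DmPA esterification labels free
carboxyls.  After depolymerization, a monomer recovered WITH the tag had
that group free in the polymer, and recovered WITHOUT it had the group
engaged in an ester bond.  The free/esterified abundance ratio per monomer
is summarized as a log2 ratio with a delta-method (first-order error
propagation) standard error:

    se_log2 = (1/ln 2) * sqrt((se_fr/fr)^2 + (se_es/es)^2)

Internal-standard quantification (heptadecanoic acid, 10 ug by default)
scales analyte peak areas linearly against the standard's area.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Iterable, Sequence

from .chem import AdductSpec, DerivatizationTag, get_adduct, get_tag, ion_mz
from .monomers import Monomer

__all__ = [
    "LabelObservation",
    "LabelRatioResult",
    "aggregate_label_ratios",
    "derivatized_mz",
    "log_ratio_stats",
    "quantify_internal_standard",
]

_LN2 = math.log(2.0)


def derivatized_mz(
    m: Monomer,
    tag: DerivatizationTag | str,
    n_sites: int = 1,
    adduct: AdductSpec | str = "[M+H]+",
) -> float:
    """m/z of a monomer carrying ``n_sites`` copies of a derivatization tag.

    Positive mode is the default because dansylated and DmPA products are
    detected as [M+H]+.  ``n_sites`` may not exceed the number of free sites
    of the tag's class on the monomer; ``n_sites=0`` returns the unmodified
    ion.
    """
    tag = get_tag(tag)
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    available = len(m.hydroxyls) if tag.site_class == "hydroxyl" else len(m.carboxyls)
    if n_sites > available:
        raise ValueError(
            f"{m.id} has only {available} free {tag.site_class} site(s); "
            f"cannot attach {n_sites} {tag.name} tag(s)"
        )
    return ion_mz(m.formula + n_sites * tag.formula_delta, adduct)


@dataclass(frozen=True)
class LabelObservation:
    """One measured abundance of a (possibly tagged) monomer in a replicate."""

    monomer_id: str
    tag: str | None
    abundance: float
    replicate: str

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")


@dataclass(frozen=True)
class LabelRatioResult:
    """Free-vs-esterified summary for one monomer."""

    monomer_id: str
    mean_free: float
    mean_esterified: float
    se_free: float
    se_esterified: float
    log2_ratio: float
    se_log2: float
    n_free: int = 0
    n_esterified: int = 0


def log_ratio_stats(
    fr: float,
    se_fr: float,
    es: float,
    se_es: float,
    monomer_id: str = "",
    n_free: int = 0,
    n_esterified: int = 0,
) -> LabelRatioResult:
    """log2(fr/es) with its delta-method standard error.

    Scale-invariant: multiplying all four inputs by a common factor leaves
    both the ratio and its SE unchanged.
    """
    if fr <= 0 or es <= 0:
        raise ValueError(f"free and esterified means must be positive, got fr={fr}, es={es}")
    if se_fr < 0 or se_es < 0:
        raise ValueError("standard errors must be non-negative")
    log2_ratio = math.log2(fr / es)
    se_log2 = math.sqrt((se_fr / fr) ** 2 + (se_es / es) ** 2) / _LN2
    return LabelRatioResult(
        monomer_id, fr, es, se_fr, se_es, log2_ratio, se_log2, n_free, n_esterified
    )


def aggregate_label_ratios(
    observations: Iterable[LabelObservation],
) -> list[LabelRatioResult]:
    """Per-monomer free/esterified ratios from a stream of observations.

    Tagged observations count toward the free pool, untagged ones toward
    the esterified pool; replicate values are averaged and the standard
    error of the mean is propagated through :func:`log_ratio_stats`.
    Monomers lacking either pool are skipped (the ratio is undefined).
    """
    free: dict[str, list[float]] = defaultdict(list)
    esterified: dict[str, list[float]] = defaultdict(list)
    for obs in observations:
        pool = free if obs.tag else esterified
        pool[obs.monomer_id].append(obs.abundance)
    out = []
    for monomer_id in sorted(set(free) & set(esterified)):
        fr_vals, es_vals = free[monomer_id], esterified[monomer_id]
        fr, es = mean(fr_vals), mean(es_vals)
        if fr <= 0 or es <= 0:
            continue
        se_fr = stdev(fr_vals) / math.sqrt(len(fr_vals)) if len(fr_vals) > 1 else 0.0
        se_es = stdev(es_vals) / math.sqrt(len(es_vals)) if len(es_vals) > 1 else 0.0
        out.append(
            log_ratio_stats(
                fr, se_fr, es, se_es,
                monomer_id=monomer_id,
                n_free=len(fr_vals),
                n_esterified=len(es_vals),
            )
        )
    return out


def quantify_internal_standard(
    area_analyte: float,
    area_is: float,
    amount_is: float = 10.0,
) -> float:
    """Absolute amount by linear comparison to an internal standard.

    ``amount_is`` defaults to 10 (ug of heptadecanoic acid, the spiked-in
    GC-MS standard); the result carries the same unit.
    """
    if area_is <= 0:
        raise ValueError("internal-standard area must be positive")
    if area_analyte < 0:
        raise ValueError("analyte area must be non-negative")
    return amount_is * area_analyte / area_is
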