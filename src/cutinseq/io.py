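"""File formats, run configuration and report generation.

Spectra are interchanged as MGF (Mascot Generic Format) via pyteomics;
monomer catalogs as TSV; label-observation tables as CSV; results as JSON
or CSV.  Every report embeds the run configuration and the catalog checksum
so a result can be reproduced from the report alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from .chem import AdductSpec, get_adduct
from .labeling import LabelObservation, LabelRatioResult
from .sequencing import SequencingResult, Spectrum

__all__ = [
    "MgfError",
    "RunConfig",
    "read_label_observations",
    "read_mgf",
    "write_label_report",
    "write_mgf",
    "write_sequencing_report",
]

logger = logging.getLogger("cutinseq")


class MgfError(ValueError):
    """Raised for malformed MGF input."""


@dataclass
class RunConfig:
    """Validated run parameters; serialized into every report."""

    adduct: str = "[M-H]-"
    tol_da: float = 0.02
    tol_ppm: float = 10.0
    min_len: int | None = None
    max_len: int | None = None
    max_water_loss: int = 2
    include_alcohols: bool = False
    catalog_path: str | None = None
    catalog_checksum: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        get_adduct(self.adduct)  # validates the name
        if self.tol_da < 0 or self.tol_ppm < 0:
            raise ValueError("tolerances must be non-negative")
        if self.max_water_loss < 0:
            raise ValueError("max_water_loss must be >= 0")
        for bound in (self.min_len, self.max_len):
            if bound is not None and bound < 1:
                raise ValueError("length bounds must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(path, adduct: AdductSpec | str = "[M-H]-") -> list[Spectrum]:
    """Read centroided spectra from an MGF file.

    PEPMASS is required per block; the adduct (MGF does not carry one) is
    supplied by the caller and attached to every spectrum.  An empty file
    yields an empty list with a warning.
    """
    adduct = get_adduct(adduct)
    path = Path(path)
    if path.stat().st_size == 0:
        logger.warning("MGF file %s is empty", path)
        return []
    spectra: list[Spectrum] = []
    try:
        with _mgf.read(str(path), use_index=False) as reader:
            for i, entry in enumerate(reader):
                params = entry.get("params", {})
                if "pepmass" not in params or params["pepmass"][0] is None:
                    raise MgfError(f"{path}: block {i + 1} lacks a PEPMASS line")
                precursor = float(params["pepmass"][0])
                peaks = tuple(
                    zip(
                        (float(x) for x in entry["m/z array"]),
                        (float(x) for x in entry["intensity array"]),
                    )
                )
                spectra.append(
                    Spectrum(
                        precursor_mz=precursor,
                        adduct=adduct,
                        peaks=peaks,
                        source_id=str(params.get("title", f"{path.name}#{i + 1}")),
                    )
                )
    except MgfError:
        raise
    except Exception as exc:  # pyteomics raises various parser errors
        raise MgfError(f"cannot parse MGF file {path}: {exc}") from exc
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra as MGF; round-trips with :func:`read_mgf`."""
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.mz_array,
                "intensity array": s.intensity_array,
                "params": {
                    "title": s.source_id,
                    "pepmass": s.precursor_mz,
                    "charge": s.adduct.charge,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _sequencing_rows(result: SequencingResult) -> list[dict]:
    rows = []
    for s in result.orderings:
        rows.append(
            {
                "source_id": result.source_id,
                "precursor_mz": round(result.precursor_mz, 4),
                "rank": s.rank,
                "score": s.score,
                "water_losses_used": s.water_losses_used,
                "sequence": "/".join(s.oligomer.ids),
                "symbolic": s.symbolic,
                "n_matched": len(s.matches),
                "n_predicted": len(s.matches) + len(s.unmatched_predicted),
            }
        )
    return rows


def write_sequencing_report(
    results: Sequence[SequencingResult],
    path,
    fmt: str = "json",
    config: RunConfig | None = None,
) -> None:
    """Write sequencing results as JSON (full evidence) or CSV (ranking)."""
    path = Path(path)
    config = config or RunConfig()
    if fmt == "json":
        payload = {
            "config": config.to_dict(),
            "results": [r.to_dict() for r in results],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n", "utf-8")
    elif fmt == "csv":
        rows = [row for r in results for row in _sequencing_rows(r)]
        frame = pd.DataFrame(
            rows,
            columns=[
                "source_id", "precursor_mz", "rank", "score", "water_losses_used",
                "sequence", "symbolic", "n_matched", "n_predicted",
            ],
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# config: {json.dumps(config.to_dict(), sort_keys=True)}\n")
            frame.to_csv(fh, index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r} (use 'json' or 'csv')")


def read_label_observations(path) -> list[LabelObservation]:
    """Read a label-observation CSV: monomer_id, tag, abundance, replicate."""
    frame = pd.read_csv(path, dtype={"monomer_id": str, "replicate": str})
    required = {"monomer_id", "tag", "abundance", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"label CSV {path} lacks columns: {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        tag = None if pd.isna(row.tag) or str(row.tag).lower() in ("", "none") else str(row.tag)
        out.append(
            LabelObservation(
                monomer_id=str(row.monomer_id),
                tag=tag,
                abundance=float(row.abundance),
                replicate=str(row.replicate),
            )
        )
    return out


def write_label_report(
    results: Sequence[LabelRatioResult],
    path,
    fmt: str = "csv",
    config: RunConfig | None = None,
) -> None:
    """Write per-monomer log2 free/esterified ratios with SEs."""
    path = Path(path)
    config = config or RunConfig()
    rows = [
        {
            "monomer_id": r.monomer_id,
            "mean_free": r.mean_free,
            "mean_esterified": r.mean_esterified,
            "se_free": r.se_free,
            "se_esterified": r.se_esterified,
            "log2_ratio": r.log2_ratio,
            "se_log2": r.se_log2,
            "n_free": r.n_free,
            "n_esterified": r.n_esterified,
        }
        for r in results
    ]
    if fmt == "csv":
        frame = pd.DataFrame(
            rows,
            columns=[
                "monomer_id", "mean_free", "mean_esterified", "se_free",
                "se_esterified", "log2_ratio", "se_log2", "n_free", "n_esterified",
            ],
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# config: {json.dumps(config.to_dict(), sort_keys=True)}\n")
            frame.to_csv(fh, index=False)
    elif fmt == "json":
        payload = {"config": config.to_dict(), "results": rows}
        path.write_text(json.dumps(payload, indent=2) + "\n", "utf-8")
    else:
        raise ValueError(f"unknown report format {fmt!r} (use 'json' or 'csv')")
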