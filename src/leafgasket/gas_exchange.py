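"""Correct per-area gas exchange parameters for the true enclosed leaf area.

Portable photosynthesis systems report net photosynthesis (P_N),
stomatal conductance (g_s) and transpiration (E) per unit leaf area,
assuming by default that the leaf fills the chamber gasket (area S = A_G).
When the true enclosed area A_L is smaller, every per-area rate must be
rescaled by the factor S / A_L; the molar flux itself (rate x area) is
conserved.  Intrinsic water-use efficiency iWUE = P_N / g_s is invariant
under the correction.  Mole-fraction quantities (C_i) and fluorescence
ratios (Phi_PSII) are carried through unchanged.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InvalidAreaError,
    JoinError,
    OversizedAreaError,
    SchemaError,
    UndefinedIWUEError,
)
from .geometry import AreaEstimate, GasketSpec, width_based_area

#: Default column mapping for common LI-6400-style log headers.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "area": "Area",
    "photo": "Photo",
    "cond": "Cond",
    "trans": "Trmmol",
    "ci": "Ci",
    "phipsii": "PhiPS2",
    "label": "Label",
}

MANDATORY_FIELDS = ("area", "photo", "cond")


@dataclass(frozen=True)
class GasExchangeRecord:
    """One instrument log row (per-area rates as reported)."""

    assumed_area_S: float  # cm^2, the area the instrument divided by
    photo_PN: float  # umol CO2 m-2 s-1
    cond_gs: float  # mol H2O m-2 s-1
    trans_E: float | None = None  # mmol H2O m-2 s-1
    Ci: float | None = None  # umol mol-1
    PhiPSII: float | None = None  # dimensionless, [0, 1]
    label: str | None = None
    row_number: int | None = None

    def __post_init__(self) -> None:
        if not self.assumed_area_S > 0:
            raise InvalidAreaError(
                f"assumed area must be positive, got {self.assumed_area_S!r}"
            )
        if self.PhiPSII is not None and not 0.0 <= self.PhiPSII <= 1.0:
            raise InvalidAreaError(
                f"PhiPSII must lie in [0, 1], got {self.PhiPSII!r}"
            )


@dataclass(frozen=True)
class CorrectedRecord:
    """A record rescaled to the measured enclosed area A_L."""

    original: GasExchangeRecord
    measured_area_AL: float
    correction_factor: float
    photo_PN: float
    cond_gs: float
    trans_E: float | None
    Ci: float | None
    PhiPSII: float | None
    iWUE: float | None
    ci_uncorrected: bool = True  # C_i is passed through, not recomputed


def iwue(photo_PN: float, cond_gs: float) -> float:
    """Intrinsic water-use efficiency P_N / g_s (umol CO2 / mol H2O)."""
    if not cond_gs > 0:
        raise UndefinedIWUEError(
            f"iWUE undefined for stomatal conductance {cond_gs!r} (must be > 0)"
        )
    return photo_PN / cond_gs


def correct_record(record: GasExchangeRecord, area) -> CorrectedRecord:
    """Rescale per-area rates by S / A_L.

    ``area`` is an :class:`AreaEstimate` or a float in cm^2.  The leaf
    cannot exceed the gasket, so A_L > S is refused.
    """
    al = area.value if isinstance(area, AreaEstimate) else float(area)
    if not al > 0:
        raise InvalidAreaError(f"measured leaf area must be positive, got {al!r}")
    s = record.assumed_area_S
    if al > s * (1.0 + 1e-6):
        raise OversizedAreaError(
            f"measured area {al!r} cm^2 exceeds the assumed (gasket) area {s!r} cm^2"
        )
    factor = s / al
    gs_corr = record.cond_gs * factor
    return CorrectedRecord(
        original=record,
        measured_area_AL=al,
        correction_factor=factor,
        photo_PN=record.photo_PN * factor,
        cond_gs=gs_corr,
        trans_E=None if record.trans_E is None else record.trans_E * factor,
        Ci=record.Ci,
        PhiPSII=record.PhiPSII,
        iWUE=(record.photo_PN * factor) / gs_corr if gs_corr > 0 else None,
    )


def _find_header(lines: Sequence[str], colmap: Mapping[str, str]):
    """Locate the header row: the first line containing every mandatory
    mapped column name after splitting on tab or comma."""
    needed = {colmap[f] for f in MANDATORY_FIELDS}
    for i, line in enumerate(lines):
        for sep in ("\t", ","):
            fields = [f.strip().strip('"') for f in line.rstrip("\n").split(sep)]
            if needed <= set(fields):
                return i, sep, fields
    return None


def parse_log(path, column_map: Mapping[str, str] | None = None) -> list[GasExchangeRecord]:
    """Read a tab/comma-delimited instrument log into records.

    Banner lines before the header are tolerated; the header is the first
    line containing the mapped mandatory columns (area, P_N, g_s).
    Optional columns not present in the file become absent fields.
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    text = Path(path).read_text() if not hasattr(path, "read") else path.read()
    lines = text.splitlines()
    found = _find_header(lines, colmap)
    if found is None:
        raise SchemaError(
            f"no header row with mandatory columns "
            f"{[colmap[f] for f in MANDATORY_FIELDS]} found; "
            f"first lines were {lines[:3]!r}"
        )
    header_idx, sep, _ = found
    df = pd.read_csv(io.StringIO("\n".join(lines[header_idx:])), sep=sep)
    df.columns = [str(c).strip().strip('"') for c in df.columns]
    missing = [colmap[f] for f in MANDATORY_FIELDS if colmap[f] not in df.columns]
    if missing:
        raise SchemaError(
            f"log is missing mandatory columns {missing}; found {list(df.columns)}"
        )

    def opt(row, fld):
        name = colmap.get(fld)
        if name is None or name not in df.columns:
            return None
        val = row[name]
        return None if pd.isna(val) else val

    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        records.append(
            GasExchangeRecord(
                assumed_area_S=float(row[colmap["area"]]),
                photo_PN=float(row[colmap["photo"]]),
                cond_gs=float(row[colmap["cond"]]),
                trans_E=None if opt(row, "trans") is None else float(opt(row, "trans")),
                Ci=None if opt(row, "ci") is None else float(opt(row, "ci")),
                PhiPSII=None if opt(row, "phipsii") is None else float(opt(row, "phipsii")),
                label=None if opt(row, "label") is None else str(opt(row, "label")),
                row_number=header_idx + 2 + i,  # 1-based line number in the file
            )
        )
    return records


def _resolve_areas(
    records: Sequence[GasExchangeRecord],
    areas,
    gasket: GasketSpec | None,
) -> list[float]:
    """Resolve ``areas`` (constant, sequence, mapping, or annotation CSV path)
    to one A_L per record, joining by label when labels are given."""
    if isinstance(areas, (int, float)):
        return [float(areas)] * len(records)
    if isinstance(areas, (str, Path)):
        ann = pd.read_csv(areas)
        ann.columns = [c.strip() for c in ann.columns]
        if "AL_cm2" in ann.columns:
            values = ann["AL_cm2"].astype(float)
        elif "width_cm" in ann.columns:
            if gasket is None:
                raise JoinError(
                    "width annotations need a gasket to convert width to area"
                )
            values = ann["width_cm"].astype(float).map(
                lambda w: width_based_area(w, gasket).enclosed_area_wAL
            )
        else:
            raise SchemaError(
                f"annotation file must have an 'AL_cm2' or 'width_cm' column; "
                f"found {list(ann.columns)}"
            )
        if "label" in ann.columns:
            areas = dict(zip(ann["label"].astype(str), values))
        else:
            areas = list(values)
    if isinstance(areas, Mapping):
        missing = [r.label for r in records if r.label not in areas]
        extra = [k for k in areas if k not in {r.label for r in records}]
        if missing or extra:
            raise JoinError(
                f"labels without an area: {missing!r}; areas without a log row: {extra!r}"
            )
        return [float(areas[r.label]) for r in records]
    areas = list(areas)
    if len(areas) != len(records):
        raise JoinError(
            f"{len(areas)} areas supplied for {len(records)} log rows"
        )
    return [float(a) for a in areas]


def correct_log(
    path,
    areas,
    gasket: GasketSpec | None = None,
    column_map: Mapping[str, str] | None = None,
    out_path=None,
    report_path=None,
):
    """Batch-correct an instrument log; returns ``(table, report)``.

    ``areas`` may be a constant (cm^2), a per-row sequence, a label -> A_L
    mapping, or the path of an annotation CSV with ``label`` plus either
    ``AL_cm2`` or ``width_cm`` columns (widths are converted through the
    circular-segment geometry, which needs ``gasket``).

    The output table preserves the original columns and order and appends
    ``AL_cm2``, ``corr_factor`` and one ``*_corr`` column per rate; the
    report summarizes the correction factors and the per-area error each
    row would have carried uncorrected.  The source file is never
    overwritten.
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    records = parse_log(path, column_map=colmap)
    al = _resolve_areas(records, areas, gasket)
    corrected = [correct_record(r, a) for r, a in zip(records, al)]

    text = Path(path).read_text()
    lines = text.splitlines()
    header_idx, sep, _ = _find_header(lines, colmap)
    df = pd.read_csv(io.StringIO("\n".join(lines[header_idx:])), sep=sep)
    df.columns = [str(c).strip().strip('"') for c in df.columns]
    df["AL_cm2"] = [c.measured_area_AL for c in corrected]
    df["corr_factor"] = [c.correction_factor for c in corrected]
    df[colmap["photo"] + "_corr"] = [c.photo_PN for c in corrected]
    df[colmap["cond"] + "_corr"] = [c.cond_gs for c in corrected]
    if colmap["trans"] in df.columns:
        df[colmap["trans"] + "_corr"] = [c.trans_E for c in corrected]
    df["iWUE_corr"] = [c.iWUE for c in corrected]

    factors = np.array([c.correction_factor for c in corrected])
    errors = np.array(
        [100.0 * (c.correction_factor - 1.0) for c in corrected]
    )  # error P_N would carry if left uncorrected
    report = {
        "n_rows": len(corrected),
        "correction_factor": {
            "min": float(factors.min()),
            "median": float(np.median(factors)),
            "max": float(factors.max()),
        },
        "uncorrected_error_percent": {
            "min": float(errors.min()),
            "median": float(np.median(errors)),
            "max": float(errors.max()),
        },
    }

    if out_path is not None:
        out_path = Path(out_path)
        if out_path.resolve() == Path(path).resolve():
            raise InvalidAreaError("refusing to overwrite the source log file")
        tmp = out_path.with_suffix(out_path.suffix + ".tmp")
        df.to_csv(tmp, sep="\t", index=False)
        os.replace(tmp, out_path)
    if report_path is not None:
        import json

        report_path = Path(report_path)
        tmp = report_path.with_suffix(report_path.suffix + ".tmp")
        tmp.write_text(json.dumps(report, indent=2) + "\n")
        os.replace(tmp, report_path)
    return df, report
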