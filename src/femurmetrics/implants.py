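"""Cephalomedullary-nail catalog and anatomy-implant compatibility scoring.

The bundled catalog transcribes published design parameters of two
commercial nails.  A femur's record is scored against an implant for:
nearest NSA option, curvature mismatch (femur radius smaller than every
nail radius), anteversion excess over the built-in value, lag-screw length
coverage of the neck axis, and the proximal insertion-depth options.  No
implant exposes a neck-shaft axis offset parameter, so every report
carries an unconditional ``FNSAO_UNCOMPENSATED`` design-gap flag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import NSA_MISMATCH_THRESHOLD_DEG
from .errors import SchemaError
from .model import MeasurementRecord

FLAG_NSA = "NSA_OUT_OF_RANGE"
FLAG_CURVATURE = "CURVATURE"
FLAG_ANTEVERSION = "ANTEVERSION_EXCESS"
FLAG_LAG_LENGTH = "LAG_LENGTH"
FLAG_FNSAO = "FNSAO_UNCOMPENSATED"
ALL_FLAGS = (FLAG_NSA, FLAG_CURVATURE, FLAG_ANTEVERSION, FLAG_LAG_LENGTH, FLAG_FNSAO)


@dataclass
class ImplantSpec:
    name: str
    nsa_options_deg: list[float]
    curvature_radii_m: list[float]
    lag_screw_min_mm: float
    lag_screw_max_mm: float
    builtin_anteversion_deg: float
    gt_to_slsni_options_mm: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not self.name:
            raise SchemaError("implant name must be non-empty")
        if not self.nsa_options_deg:
            raise SchemaError(f"{self.name}: nsa_options_deg must be non-empty")
        if not self.curvature_radii_m:
            raise SchemaError(f"{self.name}: curvature_radii_m must be non-empty")
        if self.lag_screw_min_mm > self.lag_screw_max_mm:
            raise SchemaError(f"{self.name}: lag screw min must be <= max")


@dataclass
class CompatibilityReport:
    specimen_id: str
    implant: str
    nearest_nsa_option_deg: float | None
    nsa_deviation_deg: float | None
    curvature_mismatch: bool | None
    curvature_gap_m: float | None
    anteversion_excess_deg: float | None
    lag_length_covered: bool | None
    gt_slsni_deviation_mm: float | None
    overall_flags: list[str]


def _implant_from_dict(data: dict) -> ImplantSpec:
    required = {
        "name",
        "nsa_options_deg",
        "curvature_radii_m",
        "lag_screw_min_mm",
        "lag_screw_max_mm",
        "builtin_anteversion_deg",
    }
    if not isinstance(data, dict):
        raise SchemaError("implant entry must be an object")
    missing = required - set(data)
    if missing:
        raise SchemaError(f"implant entry missing keys: {sorted(missing)}")
    return ImplantSpec(
        name=data["name"],
        nsa_options_deg=[float(v) for v in data["nsa_options_deg"]],
        curvature_radii_m=[float(v) for v in data["curvature_radii_m"]],
        lag_screw_min_mm=float(data["lag_screw_min_mm"]),
        lag_screw_max_mm=float(data["lag_screw_max_mm"]),
        builtin_anteversion_deg=float(data["builtin_anteversion_deg"]),
        gt_to_slsni_options_mm=[float(v) for v in data.get("gt_to_slsni_options_mm", [])],
    )


def load_catalog(path=None) -> list[ImplantSpec]:
    """Load an implant catalog JSON; with no path, the bundled default."""
    if path is None:
        text = resources.files("femurmetrics.data").joinpath("catalog.json").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"catalog is not valid JSON: {exc}") from exc
    if not isinstance(data, dict) or "implants" not in data:
        raise SchemaError('catalog must be an object with an "implants" array')
    implants = data["implants"]
    if not isinstance(implants, list) or not implants:
        raise SchemaError("catalog must list at least one implant")
    return [_implant_from_dict(entry) for entry in implants]


def assess(
    record: MeasurementRecord,
    implant: ImplantSpec,
    specimen_id: str = "",
    nsa_threshold_deg: float = NSA_MISMATCH_THRESHOLD_DEG,
) -> CompatibilityReport:
    """Score one femur record against one implant.

    Missing (NaN) record fields skip only their own criterion, adding a
    ``MISSING:<field>`` flag.  ``FNSAO_UNCOMPENSATED`` is always present:
    no implant parameter exists to match the neck-shaft axis offset.
    """
    flags: list[str] = []

    nearest_nsa = nsa_dev = None
    if math.isfinite(record.nsa_proximal_deg):
        # tie -> smaller option (options scanned ascending, strict improvement)
        nearest_nsa = min(sorted(implant.nsa_options_deg), key=lambda o: abs(record.nsa_proximal_deg - o))
        nsa_dev = abs(record.nsa_proximal_deg - nearest_nsa)
        if nsa_dev > nsa_threshold_deg:
            flags.append(FLAG_NSA)
    else:
        flags.append("MISSING:nsa_proximal_deg")

    curvature_mismatch = curvature_gap = None
    if math.isfinite(record.radius_of_curvature_m):
        min_radius = min(implant.curvature_radii_m)
        curvature_mismatch = record.radius_of_curvature_m < min_radius
        curvature_gap = min_radius - record.radius_of_curvature_m if curvature_mismatch else 0.0
        if curvature_mismatch:
            flags.append(FLAG_CURVATURE)
    else:
        flags.append("MISSING:radius_of_curvature_m")

    anteversion_excess = None
    if math.isfinite(record.anteversion_deg):
        anteversion_excess = record.anteversion_deg - implant.builtin_anteversion_deg
        if anteversion_excess > 0:
            flags.append(FLAG_ANTEVERSION)
    else:
        flags.append("MISSING:anteversion_deg")

    lag_covered = None
    if math.isfinite(record.neck_axis_length_mm):
        lag_covered = implant.lag_screw_min_mm <= record.neck_axis_length_mm <= implant.lag_screw_max_mm
        if not lag_covered:
            flags.append(FLAG_LAG_LENGTH)
    else:
        flags.append("MISSING:neck_axis_length_mm")

    gt_dev = None
    if implant.gt_to_slsni_options_mm and math.isfinite(record.gt_to_slsni_mm):
        gt_dev = min(abs(record.gt_to_slsni_mm - o) for o in implant.gt_to_slsni_options_mm)
    elif implant.gt_to_slsni_options_mm:
        flags.append("MISSING:gt_to_slsni_mm")

    flags.append(FLAG_FNSAO)
    return CompatibilityReport(
        specimen_id=specimen_id,
        implant=implant.name,
        nearest_nsa_option_deg=nearest_nsa,
        nsa_deviation_deg=nsa_dev,
        curvature_mismatch=curvature_mismatch,
        curvature_gap_m=curvature_gap,
        anteversion_excess_deg=anteversion_excess,
        lag_length_covered=lag_covered,
        gt_slsni_deviation_mm=gt_dev,
        overall_flags=flags,
    )


def cohort_compat_summary(
    records: Sequence[MeasurementRecord] | Iterable[MeasurementRecord],
    implant: ImplantSpec,
) -> dict:
    """Flag prevalences (in [0, 1]) and mean deviations over a cohort."""
    records = list(records)
    if not records:
        raise ValueError("cohort_compat_summary requires at least one record")
    reports = [assess(rec, implant) for rec in records]
    n = len(reports)
    summary: dict = {"implant": implant.name, "n": n}
    for flag in ALL_FLAGS:
        summary[f"prevalence_{flag}"] = sum(flag in r.overall_flags for r in reports) / n
    for attr in ("nsa_deviation_deg", "curvature_gap_m", "anteversion_excess_deg", "gt_slsni_deviation_mm"):
        values = [getattr(r, attr) for r in reports if getattr(r, attr) is not None]
        summary[f"mean_{attr}"] = float(np.mean(values)) if values else None
    return summary
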