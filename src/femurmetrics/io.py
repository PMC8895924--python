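"""Specimen JSON and measurement CSV input/output.

Specimen files are JSON with top-level keys
``{"schema_version", "specimen_id", "side", "sex", "age", "landmarks"}``;
``landmarks`` maps each group name to an array of ``[x, y, z]`` triples
(single-point groups are 1-element arrays).  Measurement tables are CSV
with a '.' decimal separator and no locale formatting; columns are
``specimen_id, side, sex, age`` followed by the eight measure fields.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .constants import SCHEMA_VERSION
from .errors import SchemaError, ValidationError
from .model import LANDMARK_GROUPS, MEASURE_FIELDS, FemurSpecimen, MeasurementRecord

MEASUREMENT_COLUMNS = ("specimen_id", "side", "sex", "age") + MEASURE_FIELDS


def specimen_to_dict(s: FemurSpecimen) -> dict:
    landmarks = {name: arr.tolist() for name, arr in s.landmark_groups().items()}
    return {
        "schema_version": SCHEMA_VERSION,
        "specimen_id": s.specimen_id,
        "side": s.side,
        "sex": s.sex,
        "age": s.age,
        "landmarks": landmarks,
    }


def specimen_from_dict(data: Mapping) -> FemurSpecimen:
    if not isinstance(data, Mapping):
        raise SchemaError("specimen document must be a JSON object")
    for key in ("specimen_id", "side", "sex", "landmarks"):
        if key not in data:
            raise SchemaError(f"specimen document missing required key {key!r}")
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {version!r}")
    landmarks = data["landmarks"]
    if not isinstance(landmarks, Mapping):
        raise SchemaError('"landmarks" must be an object mapping group name to points')
    for name in LANDMARK_GROUPS:
        if name not in landmarks:
            raise SchemaError(f"missing landmark group {name!r}")
    unknown = set(landmarks) - set(LANDMARK_GROUPS)
    if unknown:
        raise SchemaError(f"unknown landmark groups: {sorted(unknown)}")
    kwargs = {}
    for name in LANDMARK_GROUPS:
        pts = landmarks[name]
        try:
            kwargs[name] = [[float(c) for c in p] for p in pts]
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"landmark group {name!r} is not an array of [x,y,z] triples") from exc
        for p in kwargs[name]:
            if len(p) != 3:
                raise SchemaError(f"landmark group {name!r} contains a non-3D point")
            if any(not math.isfinite(c) for c in p):
                raise ValidationError(f"landmark group {name!r} contains non-finite coordinates")
    return FemurSpecimen(
        specimen_id=data["specimen_id"],
        side=data["side"],
        sex=data["sex"],
        age=data.get("age"),
        **kwargs,
    )


def read_specimen(path) -> FemurSpecimen:
    """Read and validate one specimen JSON file."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path} is not valid JSON: {exc}") from exc
    return specimen_from_dict(data)


def write_specimen(s: FemurSpecimen, path) -> None:
    """Write a specimen JSON file; round-trips coordinates exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(specimen_to_dict(s), fh, indent=1)
        fh.write("\n")


def measurement_row(
    record: MeasurementRecord,
    specimen_id: str,
    side: str = "",
    sex: str = "",
    age: float | None = None,
) -> dict:
    """Flatten one record plus metadata into a measurement-CSV row dict."""
    row = {"specimen_id": specimen_id, "side": side, "sex": sex, "age": age}
    row.update(record.as_dict())
    return row


def write_measurements(rows: Iterable[Mapping], path) -> None:
    """Write measurement rows (dicts keyed by MEASUREMENT_COLUMNS) as CSV.

    An empty iterable produces a header-only CSV.
    """
    frame = pd.DataFrame(list(rows), columns=list(MEASUREMENT_COLUMNS))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement CSV, checking the expected columns are present."""
    frame = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"measurement CSV missing columns: {missing}")
    return frame
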