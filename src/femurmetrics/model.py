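"""Domain types: femur specimens, measurement records, and axes.

Coordinate convention (canonical patient frame, right-handed):

* for a RIGHT femur ``+X`` = medial, ``+Y`` = anterior, ``+Z`` = proximal;
* a LEFT femur is stored in its own x-mirrored frame, which makes every
  scalar measure side-invariant by construction.

All stored lengths are millimeters; ``radius_of_curvature_m`` alone is
reported in meters.  Angles are stored and reported in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from .constants import UNIT_NORM_TOL
from .errors import ValidationError

SIDES = ("L", "R")
SEXES = ("M", "F", "unknown")

#: landmark group name -> (min cardinality, max cardinality or None)
LANDMARK_GROUPS: dict[str, tuple[int, int | None]] = {
    "head_surface": (5, None),
    "neck_station_centroids": (3, None),
    "canal_centroids": (10, None),
    "gt_tip": (1, 1),
    "neck_lateral_entry": (1, 1),
    "dicn": (1, 1),
    "condyle_post_medial": (1, 1),
    "condyle_post_lateral": (1, 1),
}

#: the eight scalar measures, in canonical column order
MEASURE_FIELDS = (
    "fnsao_mm",
    "gt_to_slsni_mm",
    "neck_axis_length_mm",
    "nsa_proximal_deg",
    "nsa_bow_apex_deg",
    "nsa_dicn_deg",
    "radius_of_curvature_m",
    "anteversion_deg",
)


def _as_points(name: str, value, n_min: int, n_max: int | None) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 1 and arr.shape == (3,):
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValidationError(f"landmark group {name!r} must be an (n, 3) array")
    if arr.shape[0] < n_min:
        raise ValidationError(
            f"landmark group {name!r} needs at least {n_min} points, got {arr.shape[0]}"
        )
    if n_max is not None and arr.shape[0] > n_max:
        raise ValidationError(
            f"landmark group {name!r} allows at most {n_max} points, got {arr.shape[0]}"
        )
    if not np.isfinite(arr).all():
        raise ValidationError(f"landmark group {name!r} contains non-finite coordinates")
    return arr


@dataclass
class Axis:
    """A 3D line through ``point`` with unit ``direction``."""

    point: np.ndarray
    direction: np.ndarray
    orientation_note: str = ""

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.point.shape != (3,) or self.direction.shape != (3,):
            raise ValidationError("Axis point and direction must be 3-vectors")
        if not (np.isfinite(self.point).all() and np.isfinite(self.direction).all()):
            raise ValidationError("Axis coordinates must be finite")
        if abs(float(np.linalg.norm(self.direction)) - 1.0) > UNIT_NORM_TOL:
            raise ValidationError("Axis direction must be a unit vector")


@dataclass
class FemurSpecimen:
    """Named 3D landmark groups plus metadata for a single femur."""

    specimen_id: str
    side: str
    sex: str = "unknown"
    age: float | None = None
    head_surface: np.ndarray = field(default=None)
    neck_station_centroids: np.ndarray = field(default=None)
    canal_centroids: np.ndarray = field(default=None)
    gt_tip: np.ndarray = field(default=None)
    neck_lateral_entry: np.ndarray = field(default=None)
    dicn: np.ndarray = field(default=None)
    condyle_post_medial: np.ndarray = field(default=None)
    condyle_post_lateral: np.ndarray = field(default=None)

    def __post_init__(self):
        if not isinstance(self.specimen_id, str) or not self.specimen_id:
            raise ValidationError("specimen_id must be a non-empty string")
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age is not None:
            self.age = float(self.age)
            if not math.isfinite(self.age) or self.age < 0:
                raise ValidationError("age must be a finite non-negative number")
        for name, (n_min, n_max) in LANDMARK_GROUPS.items():
            value = getattr(self, name)
            if value is None:
                raise ValidationError(f"missing landmark group {name!r}")
            arr = _as_points(name, value, n_min, n_max)
            if n_max == 1:
                arr = arr[0]
            setattr(self, name, arr)
        # canal centroids must be strictly ordered along the shaft
        steps = np.linalg.norm(np.diff(self.canal_centroids, axis=0), axis=1)
        if not (steps > 0).all():
            raise ValidationError(
                "canal_centroids must be strictly ordered (consecutive spacing > 0)"
            )

    def landmark_groups(self) -> dict[str, np.ndarray]:
        """Landmark group name -> (n, 3) array (single points as 1-row arrays)."""
        out = {}
        for name, (_, n_max) in LANDMARK_GROUPS.items():
            arr = getattr(self, name)
            out[name] = arr[None, :] if n_max == 1 else arr
        return out


def _check_measure(name: str, value: float) -> float:
    value = float(value)
    if math.isnan(value):  # missing measure (poisoned field) is representable
        return value
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite")
    if name == "fnsao_mm" and value < 0:
        raise ValidationError("fnsao_mm must be >= 0")
    if name == "radius_of_curvature_m" and value <= 0:
        raise ValidationError("radius_of_curvature_m must be > 0")
    if name.startswith("nsa_") and not (0.0 < value < 180.0):
        raise ValidationError(f"{name} must lie in (0, 180) degrees")
    if name == "anteversion_deg" and not (-90.0 < value < 90.0):
        raise ValidationError("anteversion_deg must lie in (-90, 90) degrees")
    return value


@dataclass
class MeasurementRecord:
    """The eight femur measures for one specimen.

    A field may be NaN when the corresponding measurement failed; complete
    records contain only finite values satisfying the range invariants.
    """

    fnsao_mm: float
    gt_to_slsni_mm: float
    neck_axis_length_mm: float
    nsa_proximal_deg: float
    nsa_bow_apex_deg: float
    nsa_dicn_deg: float
    radius_of_curvature_m: float
    anteversion_deg: float

    def __post_init__(self):
        for f in fields(self):
            setattr(self, f.name, _check_measure(f.name, getattr(self, f.name)))

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MEASURE_FIELDS}

    def is_complete(self) -> bool:
        return all(math.isfinite(getattr(self, name)) for name in MEASURE_FIELDS)
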