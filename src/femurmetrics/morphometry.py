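"""The eight femur measures, computed from landmarks only.

Measurement conventions:

* the proximal shaft axis is a total-least-squares fit of the canal
  centroids within the first ``PROXIMAL_WINDOW_MM`` of cumulative chord
  length, oriented proximally;
* the neck axis is a TLS fit of the neck station centroids plus the
  sphere-fit head center, oriented from the lateral entry toward the head;
* NSA is the full 3D obtuse angle (inherently anteversion-corrected);
* anteversion is signed in the plane perpendicular to the proximal shaft
  axis, positive anterior, with the anterior side derived from the
  condyle landmarks so the sign survives left/right mirroring;
* the greater-trochanter-to-closest-approach distance is measured along
  the proximal shaft axis (projection distance), matching the clinical
  meaning of nail insertion depth to the lag-screw interface;
* a straight shaft reports the capped radius ``RADIUS_CAP_M`` instead of
  an infinite value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .constants import PROXIMAL_WINDOW_MM, RADIUS_CAP_M
from .errors import CollinearityError, DegeneracyError, MeasurementError
from .geometry import (
    MaxDeviation,
    SphereFit,
    angle_between,
    circumradius,
    fit_line,
    fit_sphere,
    max_deviation_point,
    projected_angle,
    skew_distance,
)
from .model import Axis, FemurSpecimen, MeasurementRecord, MEASURE_FIELDS

logger = logging.getLogger(__name__)

SHAFT_VARIANTS = ("proximal", "bow_apex", "dicn")


@dataclass
class FnsaoResult:
    fnsao_mm: float
    closest_point_on_shaft: np.ndarray


def proximal_canal_points(canal: np.ndarray, window_mm: float = PROXIMAL_WINDOW_MM) -> np.ndarray:
    """Canal centroids spanning the first ``window_mm`` of the canal.

    The station count is derived from the window and the median
    inter-station spacing rather than by thresholding the noisy cumulative
    chord length: landmark noise inflates chord lengths (by ~var/len per
    step), and a literal <= window_mm cut would systematically drop the
    boundary station and tilt the fitted axis.  In the noise-free limit the
    two rules select the same stations.

    Shared by the synthetic generator and the measurement so the operational
    proximal-axis definition is identical on both sides of the round trip.
    """
    canal = np.asarray(canal, dtype=float)
    steps = np.linalg.norm(np.diff(canal, axis=0), axis=1)
    median_step = float(np.median(steps))
    if median_step <= 0:
        raise MeasurementError("canal centroids are not strictly ordered")
    k = int(round(window_mm / median_step)) + 1
    k = max(3, min(canal.shape[0], k))
    if canal.shape[0] < 3:
        raise MeasurementError(
            f"fewer than 3 canal centroids within the proximal {window_mm} mm window"
        )
    return canal[:k]


def apex_station(canal: np.ndarray, chord_start, chord_end):
    """Noise-aware estimate of the canal's maximal-deviation station.

    The literal argmax of per-station deviations is biased upward under
    landmark noise (it selects the most inflated station), which biases the
    three-point radius of curvature downward by far more than the recovery
    tolerance.  Instead the deviation profile is fit with a quadratic in
    cumulative chord length and the station nearest the vertex is returned
    (its original, unsmoothed coordinates).  Noise-free this picks the same
    station as the literal argmax, so round-trip exactness is untouched;
    degenerate fits fall back to the literal rule.
    """
    canal = np.asarray(canal, dtype=float)
    literal = max_deviation_point(canal, chord_start, chord_end)
    start = np.asarray(chord_start, dtype=float)
    chord = np.asarray(chord_end, dtype=float) - start
    norm = float(np.linalg.norm(chord))
    if norm <= 0 or canal.shape[0] < 5:
        return literal
    d = chord / norm
    rel = canal - start
    dev = np.linalg.norm(np.cross(rel, d), axis=1)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(canal, axis=0), axis=1))])
    a2, a1, _ = np.polyfit(s, dev, 2)
    if a2 >= 0:
        return literal
    vertex = -a1 / (2.0 * a2)
    idx = int(np.argmin(np.abs(s - vertex)))
    if idx <= 0 or idx >= canal.shape[0] - 1:
        return literal
    return MaxDeviation(index=idx, point=canal[idx].copy(), deviation=float(dev[idx]))


def neck_axis_and_head(s: FemurSpecimen) -> tuple[Axis, SphereFit]:
    """Neck axis (oriented lateral entry -> head center) plus the head sphere fit."""
    sphere = fit_sphere(s.head_surface)
    pts = np.vstack([s.neck_station_centroids, sphere.center])
    axis = fit_line(pts)
    toward_head = sphere.center - s.neck_station_centroids[0]
    if float(axis.direction @ toward_head) < 0:
        axis = Axis(point=axis.point, direction=-axis.direction)
    axis.orientation_note = "points toward head center (medial)"
    return axis, sphere


def estimate_neck_axis(s: FemurSpecimen) -> Axis:
    return neck_axis_and_head(s)[0]


def estimate_shaft_axis(s: FemurSpecimen, variant: str = "proximal") -> Axis:
    """Shaft axis under one of the three definitions, oriented proximally."""
    if variant not in SHAFT_VARIANTS:
        raise ValueError(f"variant must be one of {SHAFT_VARIANTS}, got {variant!r}")
    canal = s.canal_centroids
    entry = canal[0]
    if variant == "proximal":
        axis = fit_line(proximal_canal_points(canal))
        if float(axis.direction @ (entry - canal[-1])) < 0:
            axis = Axis(point=axis.point, direction=-axis.direction)
        axis.orientation_note = "points proximal"
        return axis
    if variant == "bow_apex":
        apex = apex_station(canal, entry, s.dicn)
        chord = entry - apex.point
        norm = float(np.linalg.norm(chord))
        if apex.deviation <= 0 or norm <= 0:
            raise MeasurementError("degenerate chord: no bow apex distinct from the entry point")
        return Axis(point=entry, direction=chord / norm, orientation_note="points proximal")
    chord = entry - s.dicn
    norm = float(np.linalg.norm(chord))
    if norm <= 0:
        raise MeasurementError("degenerate chord: entry coincides with dicn")
    return Axis(point=entry, direction=chord / norm, orientation_note="points proximal")


def measure_fnsao(s: FemurSpecimen) -> FnsaoResult:
    """Common-perpendicular offset between the neck and proximal shaft axes."""
    neck = estimate_neck_axis(s)
    shaft = estimate_shaft_axis(s, "proximal")
    res = skew_distance(neck, shaft)
    if res.parallel_flag:
        # anatomically impossible; signals corrupt input rather than a measure
        raise MeasurementError("neck and shaft axes are parallel; corrupt specimen")
    return FnsaoResult(fnsao_mm=res.distance, closest_point_on_shaft=res.point_on_line2)


def measure_gt_to_slsni(s: FemurSpecimen) -> float:
    """Distance along the proximal shaft axis from the projected greater-trochanter
    tip to the neck/shaft closest-approach point."""
    shaft = estimate_shaft_axis(s, "proximal")
    closest = measure_fnsao(s).closest_point_on_shaft
    return abs(float((s.gt_tip - closest) @ shaft.direction))


def measure_nsa(s: FemurSpecimen, variant: str = "proximal") -> float:
    """Obtuse 3D neck-shaft angle: 180 deg minus the angle between the neck
    direction (toward the head) and the shaft direction (toward proximal)."""
    neck = estimate_neck_axis(s)
    shaft = estimate_shaft_axis(s, variant)
    return 180.0 - angle_between(neck.direction, shaft.direction)


def measure_anteversion(s: FemurSpecimen) -> float:
    """Signed neck anteversion versus the posterior condylar axis, measured in
    the plane perpendicular to the proximal shaft axis; anterior positive.

    The anterior half-plane is identified from the condyle landmarks (the
    condyles sit posterior to the canal), which keeps the sign convention
    invariant under left/right mirroring.
    """
    neck = estimate_neck_axis(s)
    shaft = estimate_shaft_axis(s, "proximal")
    n = shaft.direction
    condylar = s.condyle_post_medial - s.condyle_post_lateral
    raw = projected_angle(neck.direction, condylar, n, n)
    anterior_ref = s.dicn - 0.5 * (s.condyle_post_medial + s.condyle_post_lateral)
    ref_sign = projected_angle(anterior_ref, condylar, n, n)
    return -raw if ref_sign < 0 else raw


def measure_neck_axis_length(s: FemurSpecimen) -> float:
    """Lateral cortical entry landmark to the head apex along the neck axis."""
    neck, sphere = neck_axis_and_head(s)
    apex = sphere.center + sphere.radius * neck.direction
    return float(np.linalg.norm(apex - s.neck_lateral_entry))


def measure_radius_of_curvature(s: FemurSpecimen) -> float:
    """Radius (meters) of the circle through the proximal-most canal centroid,
    the canal's maximal-deviation point from the entry->DICN chord, and the
    distal-most canal centroid.  Straight shafts report ``RADIUS_CAP_M``."""
    canal = s.canal_centroids
    entry = canal[0]
    apex = apex_station(canal, entry, s.dicn)
    try:
        circle = circumradius(entry, apex.point, canal[-1])
    except CollinearityError:
        return RADIUS_CAP_M
    return min(circle.radius / 1000.0, RADIUS_CAP_M)


_MEASURES = {
    "fnsao_mm": lambda s: measure_fnsao(s).fnsao_mm,
    "gt_to_slsni_mm": measure_gt_to_slsni,
    "neck_axis_length_mm": measure_neck_axis_length,
    "nsa_proximal_deg": lambda s: measure_nsa(s, "proximal"),
    "nsa_bow_apex_deg": lambda s: measure_nsa(s, "bow_apex"),
    "nsa_dicn_deg": lambda s: measure_nsa(s, "dicn"),
    "radius_of_curvature_m": measure_radius_of_curvature,
    "anteversion_deg": measure_anteversion,
}


def measure_all(s: FemurSpecimen) -> MeasurementRecord:
    """Compute all eight measures; a failing measure poisons only its own
    field (reported as NaN) and is logged."""
    values = {}
    for name in MEASURE_FIELDS:
        try:
            values[name] = float(_MEASURES[name](s))
        except (MeasurementError, DegeneracyError) as exc:
            logger.warning("specimen %s: %s failed: %s", s.specimen_id, name, exc)
            values[name] = math.nan
    return MeasurementRecord(**values)
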