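"""Parametric forward model of a femur landmark set, and cohort sampling.

A specimen is built in the canonical right-femur frame (+X medial,
+Y anterior, +Z proximal): a circular-arc intramedullary centerline bows
anteriorly in the sagittal plane; the neck axis passes anterior to — and
skew with — the operational proximal shaft axis by a prescribed offset;
the head is a sphere on the neck axis.  Left femurs are mirrored before
landmark noise is added.

The proximal reference axis is defined OPERATIONALLY (the same
total-least-squares fit over the proximal canal window that the
measurement uses), so every encoded parameter is recovered exactly by the
measurement pipeline in the noise-free limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .constants import RADIUS_CAP_M
from .errors import DegeneracyError, ValidationError
from .geometry import angle_between, fit_line, mirror_x, rotate_about
from .model import FemurSpecimen, MeasurementRecord, SEXES, SIDES
from .morphometry import apex_station, proximal_canal_points

__all__ = [
    "FemurParameters",
    "TruthDistribution",
    "CohortConfig",
    "GeneratedFemur",
    "generate_centerline",
    "generate_specimen",
    "generate_cohort",
    "COHORT_REFERENCE_DISTRIBUTIONS",
    "SEX_REFERENCE_STRATA",
    "AGE_REFERENCE",
]

_X = np.array([1.0, 0.0, 0.0])


@dataclass
class FemurParameters:
    """Ground-truth generator parameters for one femur."""

    nsa_deg: float
    anteversion_deg: float
    fnsao_mm: float
    gt_to_slsni_mm: float
    neck_axis_length_mm: float
    bow_radius_mm: float
    shaft_length_mm: float = 400.0
    head_radius_mm: float = 23.0
    gt_lateral_offset_mm: float = 10.0
    gt_proximal_offset_mm: float = 8.0
    head_center_from_n1_mm: float = 55.0
    n_canal_stations: int = 41
    n_head_points: int = 20
    n_neck_stations: int = 5
    noise_sd_mm: float = 0.5
    bow_plane_rotation_deg: float = 0.0
    side: str = "R"
    sex: str = "unknown"
    age: float | None = None
    specimen_id: str = "synthetic"
    seed: object = None

    def __post_init__(self):
        if not 90.0 < self.nsa_deg < 180.0:
            raise ValidationError("nsa_deg must lie in (90, 180)")
        if not -90.0 < self.anteversion_deg < 90.0:
            raise ValidationError("anteversion_deg must lie in (-90, 90)")
        if self.fnsao_mm < 0:
            raise ValidationError("fnsao_mm must be >= 0")
        for name in (
            "gt_to_slsni_mm",
            "neck_axis_length_mm",
            "bow_radius_mm",
            "shaft_length_mm",
            "head_radius_mm",
            "head_center_from_n1_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.bow_radius_mm <= self.shaft_length_mm / math.pi:
            raise ValidationError("bow_radius_mm must exceed shaft_length_mm/pi (arc < semicircle)")
        if self.neck_axis_length_mm <= self.head_center_from_n1_mm + self.head_radius_mm:
            raise ValidationError(
                "neck_axis_length_mm must exceed head_center_from_n1_mm + head_radius_mm"
            )
        if self.n_canal_stations < 10 or self.n_head_points < 5 or self.n_neck_stations < 3:
            raise ValidationError("too few stations/points for a valid specimen")
        if self.noise_sd_mm < 0:
            raise ValidationError("noise_sd_mm must be >= 0")
        if self.side not in SIDES or self.sex not in SEXES:
            raise ValidationError("invalid side or sex")


#: Population reference distributions (mean, sd) used as cohort defaults.
COHORT_REFERENCE_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "fnsao_mm": (6.1, 1.7),
    "gt_to_slsni_mm": (40.3, 5.1),
    "neck_axis_length_mm": (94.1, 7.4),
    "nsa_deg": (126.3, 5.4),
    "anteversion_deg": (18.8, 9.2),
    "bow_radius_mm": (1200.0, 300.0),
}

#: Sex-stratified reference values (mean, sd) for the same six parameters.
SEX_REFERENCE_STRATA: dict[str, dict[str, tuple[float, float]]] = {
    "M": {
        "fnsao_mm": (6.2, 1.6),
        "gt_to_slsni_mm": (41.0, 5.9),
        "neck_axis_length_mm": (98.0, 6.6),
        "nsa_deg": (126.2, 5.5),
        "anteversion_deg": (19.1, 9.6),
        "bow_radius_mm": (1200.0, 300.0),
    },
    "F": {
        "fnsao_mm": (5.9, 1.8),
        "gt_to_slsni_mm": (39.5, 3.8),
        "neck_axis_length_mm": (89.1, 5.0),
        "nsa_deg": (126.5, 5.4),
        "anteversion_deg": (18.4, 8.8),
        "bow_radius_mm": (1100.0, 300.0),
    },
}

#: Cohort age model: mean, sd, lower bound, upper bound (years).
AGE_REFERENCE = (35.2, 13.5, 18.0, 75.0)

# Hard physiologic bounds per drawn parameter (with the default geometry);
# truncation never crosses these.
_PHYSIOLOGIC_BOUNDS: dict[str, tuple[float, float]] = {
    "fnsao_mm": (0.0, math.inf),
    "gt_to_slsni_mm": (1.0, math.inf),
    "neck_axis_length_mm": (78.5, math.inf),  # > head_center_from_n1 + head_radius
    "nsa_deg": (91.0, 179.0),
    "anteversion_deg": (-89.0, 89.0),
    "bow_radius_mm": (130.0, math.inf),  # > shaft_length/pi for the 400 mm shaft
}


@dataclass
class TruthDistribution:
    """Truncated normal for one ground-truth parameter.

    When explicit bounds are not given, the distribution is truncated
    SYMMETRICALLY about the mean at ``min(4*sd, distance to the nearest
    physiologic bound)``; symmetric truncation preserves the mean, which is
    what the parameter-recovery contract needs.
    """

    mean: float
    sd: float
    low: float | None = None
    high: float | None = None

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.low is not None and self.high is not None:
            if not (self.low <= self.mean <= self.high):
                raise ValidationError("truncation bounds must bracket the mean")

    def bounds_for(self, name: str) -> tuple[float, float]:
        if self.low is not None and self.high is not None:
            return self.low, self.high
        floor, ceil = _PHYSIOLOGIC_BOUNDS.get(name, (-math.inf, math.inf))
        half = min(4.0 * self.sd, self.mean - floor, ceil - self.mean)
        if half <= 0:
            raise ValidationError(f"mean of {name} lies outside its physiologic bounds")
        low = self.mean - half if self.low is None else self.low
        high = self.mean + half if self.high is None else self.high
        return low, high

    def sample(self, name: str, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        low, high = self.bounds_for(name)
        a = (low - self.mean) / self.sd
        b = (high - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)


def _distributions(spec: dict | None) -> dict[str, TruthDistribution]:
    """Build per-parameter distributions from defaults plus overrides."""
    dists = {
        name: TruthDistribution(mean, sd)
        for name, (mean, sd) in COHORT_REFERENCE_DISTRIBUTIONS.items()
    }
    for name, override in (spec or {}).items():
        if name not in dists:
            raise ValidationError(f"unknown truth distribution {name!r}")
        if isinstance(override, TruthDistribution):
            dists[name] = override
        elif isinstance(override, dict):
            dists[name] = TruthDistribution(**override)
        else:
            mean, sd = override
            dists[name] = TruthDistribution(float(mean), float(sd))
    return dists


@dataclass
class CohortConfig:
    """Sampling configuration for a synthetic cohort."""

    n: int = 100
    distributions: dict = field(default_factory=dict)
    sex_counts: dict = field(default_factory=lambda: {"M": 56, "F": 44})
    side_counts: dict = field(default_factory=lambda: {"L": 49, "R": 51})
    stratify_by_sex: bool = False
    sex_strata: dict = field(default_factory=dict)
    age: tuple = AGE_REFERENCE
    noise_sd_mm: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.n < 0:
            raise ValidationError("n must be >= 0")
        if sum(self.sex_counts.values()) != self.n:
            raise ValidationError("sex_counts must sum to n")
        if sum(self.side_counts.values()) != self.n:
            raise ValidationError("side_counts must sum to n")
        if any(k not in SEXES for k in self.sex_counts):
            raise ValidationError("sex_counts keys must be valid sexes")
        if any(k not in SIDES for k in self.side_counts):
            raise ValidationError("side_counts keys must be valid sides")
        if self.noise_sd_mm < 0:
            raise ValidationError("noise_sd_mm must be >= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown cohort config keys: {sorted(unknown)}")
        return cls(**data)

    def resolved_distributions(self, sex: str) -> dict[str, TruthDistribution]:
        base = _distributions(self.distributions)
        if self.stratify_by_sex and sex in ("M", "F"):
            strata = self.sex_strata.get(sex) if self.sex_strata else None
            if strata is None:
                strata = SEX_REFERENCE_STRATA[sex]
            for name, value in strata.items():
                if isinstance(value, TruthDistribution):
                    base[name] = value
                elif isinstance(value, dict):
                    base[name] = TruthDistribution(**value)
                else:
                    base[name] = TruthDistribution(float(value[0]), float(value[1]))
        return base


@dataclass
class GeneratedFemur:
    specimen: FemurSpecimen
    truth: MeasurementRecord
    parameters: FemurParameters


def generate_centerline(bow_radius_mm: float, shaft_length_mm: float, n_stations: int) -> np.ndarray:
    """Circular-arc intramedullary centerline in the Y-Z (sagittal) plane.

    Starts at the origin with initial tangent (0, 0, -1) (distal); the arc
    center sits at (0, -R, 0) so the mid-arc deviates anterior (+Y) of the
    entry->end chord.  Stations are equally spaced in arc length and ordered
    proximal -> distal.
    """
    if bow_radius_mm <= 0 or shaft_length_mm <= 0:
        raise ValidationError("bow radius and shaft length must be > 0")
    if bow_radius_mm <= shaft_length_mm / math.pi:
        raise ValidationError("bow_radius_mm must exceed shaft_length_mm/pi")
    if n_stations < 2:
        raise ValidationError("need at least 2 stations")
    theta = np.linspace(0.0, shaft_length_mm / bow_radius_mm, n_stations)
    y = bow_radius_mm * np.cos(theta) - bow_radius_mm
    z = -bow_radius_mm * np.sin(theta)
    return np.column_stack([np.zeros_like(theta), y, z])


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere sampling (spherical spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def generate_specimen(p: FemurParameters) -> GeneratedFemur:
    """Forward-model one femur and echo its ground truth as a record.

    Noise-free output satisfies: every measured quantity equals the encoded
    truth (the module's self-consistency contract).
    """
    canal = generate_centerline(p.bow_radius_mm, p.shaft_length_mm, p.n_canal_stations)
    if p.bow_plane_rotation_deg:
        ang = math.radians(p.bow_plane_rotation_deg)
        rot = np.array(
            [[math.cos(ang), -math.sin(ang), 0.0], [math.sin(ang), math.cos(ang), 0.0], [0.0, 0.0, 1.0]]
        )
        canal = canal @ rot.T
    dicn = canal[-1].copy()
    condyle_med = dicn + np.array([22.0, -15.0, 0.0])
    condyle_lat = dicn + np.array([-22.0, -15.0, 0.0])

    # operational proximal axis: the same fit the measurement uses
    shaft_axis = fit_line(proximal_canal_points(canal))
    a = shaft_axis.direction  # proximal
    if float(a @ (canal[0] - canal[-1])) < 0:  # enforce proximal orientation
        a = -a

    gt = np.array([-p.gt_lateral_offset_mm, 0.0, p.gt_proximal_offset_mm])
    proj_gt = shaft_axis.point + float((gt - shaft_axis.point) @ a) * a
    closest = proj_gt - p.gt_to_slsni_mm * a  # displaced distally along the axis

    m = _X - float(_X @ a) * a
    m_norm = float(np.linalg.norm(m))
    if m_norm < 1e-12:
        raise DegeneracyError("proximal axis parallel to the medial direction")
    m /= m_norm  # in-plane unit vector nearest +X (medial)
    f = np.cross(a, m)  # anterior-ish

    beta = math.radians(180.0 - p.nsa_deg)
    d0 = math.sin(beta) * m + math.cos(beta) * a
    d_neck = rotate_about(d0, a, math.radians(p.anteversion_deg))

    u = np.cross(a, d_neck)
    u_norm = float(np.linalg.norm(u))
    if u_norm < 1e-12:
        raise DegeneracyError("neck axis parallel to shaft axis (nsa_deg too close to 180)")
    u /= u_norm
    if float(u @ f) < 0:
        u = -u  # offset is anterior
    n1 = closest + p.fnsao_mm * u

    head_center = n1 + p.head_center_from_n1_mm * d_neck
    head_surface = head_center + p.head_radius_mm * _fibonacci_sphere(p.n_head_points)
    entry = n1 - (p.neck_axis_length_mm - p.head_center_from_n1_mm - p.head_radius_mm) * d_neck
    t = np.linspace(0.0, 1.0, p.n_neck_stations)
    neck_stations = entry[None, :] + t[:, None] * (head_center - entry)[None, :]

    # ground-truth record: the axis-chord NSA variants follow from geometry
    # (same apex estimator as the measurement, for exact noise-free round trip)
    apex = apex_station(canal, canal[0], dicn)
    if apex.deviation > 0:
        dir_apex = canal[0] - apex.point
        nsa_apex = 180.0 - angle_between(d_neck, dir_apex)
    else:  # perfectly straight limit
        nsa_apex = p.nsa_deg
    nsa_dicn = 180.0 - angle_between(d_neck, canal[0] - dicn)
    truth = MeasurementRecord(
        fnsao_mm=p.fnsao_mm,
        gt_to_slsni_mm=p.gt_to_slsni_mm,
        neck_axis_length_mm=p.neck_axis_length_mm,
        nsa_proximal_deg=p.nsa_deg,
        nsa_bow_apex_deg=nsa_apex,
        nsa_dicn_deg=nsa_dicn,
        radius_of_curvature_m=min(p.bow_radius_mm / 1000.0, RADIUS_CAP_M),
        anteversion_deg=p.anteversion_deg,
    )

    groups = {
        "head_surface": head_surface,
        "neck_station_centroids": neck_stations,
        "canal_centroids": canal,
        "gt_tip": gt,
        "neck_lateral_entry": entry,
        "dicn": dicn,
        "condyle_post_medial": condyle_med,
        "condyle_post_lateral": condyle_lat,
    }
    specimen = FemurSpecimen(
        specimen_id=p.specimen_id, side="R", sex=p.sex, age=p.age, **groups
    )
    if p.side == "L":
        specimen = mirror_x(specimen)

    if p.noise_sd_mm > 0:
        rng = np.random.default_rng(p.seed)
        noisy = {}
        for name, arr in (
            (g, getattr(specimen, g))
            for g in (
                "head_surface",
                "neck_station_centroids",
                "canal_centroids",
                "gt_tip",
                "neck_lateral_entry",
                "dicn",
                "condyle_post_medial",
                "condyle_post_lateral",
            )
        ):
            noisy[name] = arr + rng.normal(0.0, p.noise_sd_mm, size=np.shape(arr))
        specimen = replace(specimen, **noisy)

    return GeneratedFemur(specimen=specimen, truth=truth, parameters=p)


def _assign_labels(counts: dict, rng: np.random.Generator) -> list[str]:
    labels = [label for label, k in sorted(counts.items()) for _ in range(k)]
    rng.shuffle(labels)
    return labels


def generate_cohort(config: CohortConfig) -> list[GeneratedFemur]:
    """Sample a reproducible cohort of synthetic femurs.

    Per-femur truths are independent truncated-normal draws; sexes and sides
    follow the configured counts; seeds propagate hierarchically (cohort
    seed -> per-specimen noise seeds) so subsets are reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)
    child_seeds = ss.spawn(config.n)
    sexes = _assign_labels(config.sex_counts, rng)
    sides = _assign_labels(config.side_counts, rng)
    age_mean, age_sd, age_lo, age_hi = config.age
    if age_sd > 0:
        ages = stats.truncnorm.rvs(
            (age_lo - age_mean) / age_sd,
            (age_hi - age_mean) / age_sd,
            loc=age_mean,
            scale=age_sd,
            size=config.n,
            random_state=rng,
        )
    else:
        ages = np.full(config.n, age_mean)

    # draw all truths up front (vectorized per stratum would complicate the
    # seed contract; per-measure batch draws keep it simple and fast)
    dists_by_sex = {sex: config.resolved_distributions(sex) for sex in set(sexes) or {"unknown"}}
    cohort = []
    for i in range(config.n):
        dists = dists_by_sex[sexes[i]]
        draws = {name: float(dist.sample(name, 1, rng)[0]) for name, dist in dists.items()}
        params = FemurParameters(
            nsa_deg=draws["nsa_deg"],
            anteversion_deg=draws["anteversion_deg"],
            fnsao_mm=draws["fnsao_mm"],
            gt_to_slsni_mm=draws["gt_to_slsni_mm"],
            neck_axis_length_mm=draws["neck_axis_length_mm"],
            bow_radius_mm=draws["bow_radius_mm"],
            noise_sd_mm=config.noise_sd_mm,
            side=sides[i],
            sex=sexes[i],
            age=float(ages[i]),
            specimen_id=f"SYN-{i:04d}",
            seed=child_seeds[i],
        )
        cohort.append(generate_specimen(params))
    return cohort
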