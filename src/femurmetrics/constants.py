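"""Centralized numeric tolerances and measurement conventions.

All lengths are millimeters unless a name says otherwise; angles are degrees
at API boundaries and radians internally.
"""

#: Schema version written into specimen JSON files.
SCHEMA_VERSION = 1

#: Two axes whose directions differ by less than this angle (radians) are
#: treated as parallel by the skew-distance primitive.
PARALLEL_TOL_RAD = 1e-9

#: Unit-vector norm tolerance for Axis validation.
UNIT_NORM_TOL = 1e-9

#: Triangle area (mm^2) below which three points are treated as collinear.
COLLINEARITY_AREA_TOL_MM2 = 1e-9

#: Minimum length (mm) of a projected vector for a planar angle to be defined.
PROJECTION_EPS_MM = 1e-9

#: Cumulative chord length (mm) of the canal polyline used to fit the
#: proximal shaft axis.  Both the generator and the measurement use the same
#: window so that the noise-free round trip is exact.
PROXIMAL_WINDOW_MM = 100.0

#: Straight shafts get this reported radius of curvature (meters) instead of
#: an infinite value, so that cohort statistics stay finite.
RADIUS_CAP_M = 100.0

#: Neck-shaft-angle deviation (degrees) beyond which an implant's nearest
#: NSA option is flagged as out of range (half the typical 10-degree option
#: spacing of commercial nails).
NSA_MISMATCH_THRESHOLD_DEG = 5.0
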