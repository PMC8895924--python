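"""Exception hierarchy shared by all femurmetrics modules."""


class FemurMetricsError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FemurMetricsError, ValueError):
    """A file or mapping does not conform to the expected schema."""


class ValidationError(FemurMetricsError, ValueError):
    """A domain object violates one of its invariants."""


class DegeneracyError(FemurMetricsError, ValueError):
    """Geometric input is degenerate (coplanar, coincident, zero-length...)."""


class CollinearityError(DegeneracyError):
    """Three points are collinear: curvature unresolvable / radius effectively infinite."""


class MeasurementError(FemurMetricsError, RuntimeError):
    """A measurement could not be computed from the given specimen."""
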