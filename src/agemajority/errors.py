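"""Exception hierarchy shared across the package."""


class AgeMajorityError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(AgeMajorityError):
    """A polygon is degenerate, self-intersecting, or otherwise unusable."""


class InvalidMeasurementError(AgeMajorityError):
    """A length, gap, or index value violates its physical constraints."""


class MissingMeasurementError(AgeMajorityError):
    """A measurement required for the requested computation is absent."""


class SchemaError(AgeMajorityError):
    """An input file does not conform to the subject-record schema."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class FixtureIntegrityError(AgeMajorityError):
    """A packaged data resource failed its checksum verification."""


class UndefinedIntervalError(AgeMajorityError):
    """A confidence interval was requested for an empty sample."""


class CalibrationError(AgeMajorityError):
    """Simulator calibration could not reach its targets; carries the report."""

    def __init__(self, message: str, achieved: dict[str, float] | None = None):
        self.achieved = achieved or {}
        super().__init__(message)
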