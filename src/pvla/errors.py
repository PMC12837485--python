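"""Exception hierarchy shared across the package."""


class PVLAError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PVLAError, ValueError):
    """Input violates a documented contract (bad label, bad range, duplicate row)."""


class SchemaError(ValidationError):
    """A tabular input is missing required columns."""


class FormatError(PVLAError, ValueError):
    """A file is structurally malformed (e.g. inconsistent slice sizes)."""


class ConfigurationError(ValidationError):
    """A phantom or run configuration cannot be realized."""


class NoSharedSliceError(PVLAError):
    """No slice contains both PV and LA pixels, so PLD/PLA are undefined.

    Carries the per-structure slice index ranges so the caller can see why
    the supports are disjoint (or empty).
    """

    def __init__(self, case_id: str, pv_slices: tuple, la_slices: tuple):
        self.case_id = case_id
        self.pv_slices = pv_slices  # (first, last) 1-based, or None if absent
        self.la_slices = la_slices
        super().__init__(
            f"case {case_id!r}: no slice contains both PV and LA pixels "
            f"(PV slices: {pv_slices}, LA slices: {la_slices})"
        )


class NoMeasurableAngleError(PVLAError):
    """Every shared slice is angle-degenerate (isotropic PV or coincident centroids)."""


class UndefinedMetricError(PVLAError):
    """A segmentation metric is undefined for this input (e.g. empty masks)."""
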