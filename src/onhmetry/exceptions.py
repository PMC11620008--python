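"""Exception hierarchy for onhmetry.

Errors are split by who can fix them: configuration errors (bad sidecars,
missing metadata), format errors (corrupt or inconsistent voxel data),
geometric/algorithmic failures (no BMO found, degenerate fits) and quality
errors (too much of a measurement is missing to report a summary).
"""


class OnhmetryError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OnhmetryError):
    """A required metadata field or parameter is missing or invalid."""


class FormatError(OnhmetryError):
    """Voxel data violates the declared label scheme or array contract."""


class OutOfBoundsError(OnhmetryError):
    """A requested sampling geometry leaves the scanned area."""


class NoBMOError(OnhmetryError):
    """No interior hole in the Bruch's membrane projection was found."""


class EllipseFitError(OnhmetryError):
    """Ellipse fitting failed (too few points or degenerate configuration)."""


class QualityError(OnhmetryError):
    """Too many meridians/sectors missing to report a reliable summary."""


class UndefinedStatisticError(OnhmetryError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
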