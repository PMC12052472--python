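"""Exception hierarchy shared across the package."""


class EggscoreError(Exception):
    """Base class for all package errors."""


class FormatError(EggscoreError):
    """A mesh file could not be parsed; the message names the offending element."""


class EmptyInputError(EggscoreError):
    """An operation received an empty mesh or sample."""


class GeometryError(EggscoreError):
    """Degenerate geometry (collinear vertices, all-degenerate faces, ...)."""


class ParameterError(EggscoreError):
    """An argument is outside its documented domain."""


class MetricError(EggscoreError):
    """A metric could not be computed for a mesh/section."""


class UndefinedOrientationError(MetricError):
    """No non-vertical surface area: the orientation score is undefined."""
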