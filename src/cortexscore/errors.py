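"""Exception hierarchy.

``ValidationError`` covers bad parameters, malformed configuration and
inputs that violate declared preconditions (CLI exit code 2);
``DataError`` covers data that is structurally valid but unusable for the
requested computation (CLI exit code 3).
"""


class CortexScoreError(Exception):
    """Base class for all package errors."""


class ValidationError(CortexScoreError):
    """Invalid parameter, configuration or input contract violation."""


class DataError(CortexScoreError):
    """Data cannot support the requested computation."""


class ThicknessRangeError(ValidationError):
    """Thickness value outside the representable [0, 6) mm range."""
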