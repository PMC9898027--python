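"""Exception hierarchy for the CIF pipeline.

``InvalidArgumentError`` covers contract violations on operation inputs,
``DataError`` covers well-formed calls on unusable data (empty cohorts,
degenerate training sets), and ``CalibrationError`` covers score
normalization failures. The CLI maps these to distinct exit codes.
"""


class CIFError(Exception):
    """Base class for all pipeline errors."""


class InvalidArgumentError(CIFError, ValueError):
    """An argument violates an operation's preconditions."""


class DataError(CIFError):
    """Input data is structurally valid but unusable (empty, degenerate)."""


class OutOfBoundsError(InvalidArgumentError):
    """A tile or coordinate lies outside the image extent."""


class CalibrationError(DataError):
    """Score normalization anchors cannot be fitted (degenerate raw scores)."""
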