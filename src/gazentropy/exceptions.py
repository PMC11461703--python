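"""Exception hierarchy for the gaze-entropy pipeline.

All pipeline errors derive from :class:`GazeError` so callers (and the CLI)
can distinguish data problems from programming errors.
"""


class GazeError(Exception):
    """Base class for all gazentropy errors."""


class FormatError(GazeError):
    """A required column or field is missing from an input file."""


class ValidationError(GazeError, ValueError):
    """A value violates a domain invariant (negative duration, bad label...)."""


class LayoutError(GazeError, ValueError):
    """An AOI layout is malformed: overlapping rectangles, duplicate ids."""


class InsufficientDataError(GazeError):
    """Too little data to estimate the requested quantity (e.g. < 2 symbols)."""


class EmptySequenceError(GazeError):
    """A trial produced no usable AOI symbols (all fixations off-AOI)."""


class ScheduleError(GazeError):
    """Requested event schedule cannot satisfy its separation constraints."""


class DesignError(GazeError, ValueError):
    """A statistical design is unbalanced or incomplete for the requested test."""
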