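"""Exception hierarchy.

Every error raised by this package derives from :class:`PulseTraceError`
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class PulseTraceError(Exception):
    """Base class for all pulsetrace errors."""


class ParseError(PulseTraceError):
    """Input file contains a cell that is neither numeric nor a missing token."""


class DimensionError(PulseTraceError):
    """Matrix too small to analyze (fewer than 3 time points, or empty)."""


class DegenerateInputError(PulseTraceError):
    """Input carries too little information (all-missing, <2 observed points)."""


class EmptyResultError(PulseTraceError):
    """A filtering step removed every trace."""


class NormalizationError(PulseTraceError):
    """Requested normalization divides by zero for a named trace."""


class ParameterError(PulseTraceError):
    """Invalid analysis parameter combination."""


class ValidationError(PulseTraceError):
    """Configuration failed validation (unknown keys, violated invariants)."""


class ReplayError(PulseTraceError):
    """A provenance record could not be replayed (missing inputs, bad record)."""
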