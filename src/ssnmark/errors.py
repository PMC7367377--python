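"""Exception hierarchy shared across the pipeline."""


class SsnmarkError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SsnmarkError, ValueError):
    """A file violates its declared dialect (bad field, duplicate id, ...)."""


class ValidationError(SsnmarkError, ValueError):
    """Parsed data violates a domain invariant (negative time, bad label, ...)."""


class GenerationError(SsnmarkError, RuntimeError):
    """The synthetic-data generator was asked for an infeasible structure."""


class AnalysisError(SsnmarkError, RuntimeError):
    """An analysis step cannot proceed (degenerate input, empty result, ...)."""
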