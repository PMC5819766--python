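"""Exception hierarchy for the sentinel-panel pipeline.

Every error raised on purpose by this package derives from
:class:`SentinelPanelError`, so callers (and the CLI) can distinguish
anticipated input/parameter problems from genuine bugs.
"""


class SentinelPanelError(Exception):
    """Base class for all anticipated errors."""


class FormatError(SentinelPanelError):
    """A file violates its format contract (duplicate ids, short lines...)."""


class ParseError(FormatError):
    """A cell could not be parsed; carries row/column coordinates."""

    def __init__(self, message: str, row: object = None, column: object = None):
        super().__init__(message)
        self.row = row
        self.column = column


class SampleLookupError(SentinelPanelError):
    """A design table references a sample id absent from the signal matrix."""


class ParameterError(SentinelPanelError):
    """A parameter is outside its documented range or inconsistent with data."""


class DegenerateInputError(SentinelPanelError):
    """Input is structurally valid but degenerate (e.g. zero total variance)."""


class InputError(SentinelPanelError):
    """Mismatched shapes, gene universes, or row orderings between inputs."""


class ConfigError(SentinelPanelError):
    """Unknown configuration key or out-of-range value."""


class CoverageInfeasibleError(SentinelPanelError):
    """No eligible inclusion/exclusion candidate exists for refinement."""


class UndefinedEnrichmentError(SentinelPanelError):
    """An enrichment score is undefined (empty hit set or empty complement)."""
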