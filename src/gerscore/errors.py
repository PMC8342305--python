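"""Exception hierarchy shared across the package.

All domain errors derive from :class:`GerScoreError` so the CLI can map
them uniformly to exit code 2 (validation failure) while programming
errors propagate normally.
"""


class GerScoreError(Exception):
    """Base class for all domain-level errors."""


class ParseError(GerScoreError):
    """A file could not be parsed; the message names the line/offset."""


class SamplingError(GerScoreError):
    """Timestamps are non-uniform beyond tolerance, or rates are inconsistent."""


class EmptyInputError(GerScoreError):
    """A recording or table is empty where data is required."""


class ValidationError(GerScoreError):
    """A value violates a physical or contractual range (e.g. pH outside 0-14)."""


class ConfigurationError(GerScoreError):
    """A configuration value is invalid or missing."""


class TooShortError(GerScoreError):
    """A recording is shorter than one analysis segment."""


class AllSegmentsExcisedError(GerScoreError):
    """Every FFT segment was excised as artifact; nothing left to score."""


class GenerationError(GerScoreError):
    """The synthetic generator cannot satisfy the requested configuration."""
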