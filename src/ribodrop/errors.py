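"""Exception types shared across the toolkit."""


class RibodropError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(RibodropError, ValueError):
    """A configuration field is missing, unknown, or out of range."""


class GenerationError(RibodropError, RuntimeError):
    """A synthetic-data generator could not satisfy its constraints."""


class ParseError(RibodropError, ValueError):
    """An input file is malformed; the message carries the offending row."""


class NormalizationError(RibodropError, ValueError):
    """Size-factor or control normalization is impossible on this input."""


class AnalysisError(RibodropError, ValueError):
    """A statistical operation received an input it cannot analyse."""


class FittingError(RibodropError, ValueError):
    """Too few points (or a degenerate configuration) for a model fit."""


class SegmentationError(RibodropError, ValueError):
    """Image thresholding or background estimation failed."""
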