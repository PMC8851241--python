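"""Exception hierarchy for feature-table and GA experiment errors."""


class GafsError(Exception):
    """Base class for all package errors."""


class FormatError(GafsError):
    """Structural problem in a feature-table file (duplicate columns/ids, bad header)."""


class TableParseError(GafsError):
    """A cell could not be parsed; the message names the offending row and column."""


class FoldError(GafsError):
    """Cross-validation folds cannot be formed (class smaller than k)."""


class ConfigError(GafsError):
    """Invalid evolutionary or experiment configuration."""


class SchemaError(GafsError):
    """A table lacks columns required by a trained model."""


class DegenerateInputError(GafsError):
    """Input carries no usable signal (e.g. a constant table for PCA)."""
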