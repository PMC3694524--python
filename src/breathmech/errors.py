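"""Exception hierarchy.

Config errors exit a CLI run with code 2, data errors with code 1.
"""


class BreathmechError(Exception):
    """Base class for all package errors."""


class ConfigError(BreathmechError):
    """Invalid run configuration or simulation scenario."""


class FormatError(BreathmechError):
    """Input file does not have the expected columns/layout."""


class SamplingError(BreathmechError):
    """Time axis is not uniformly sampled within tolerance."""


class DataError(BreathmechError):
    """Non-finite or physically impossible values in the data."""


class SegmentationError(BreathmechError):
    """No complete breathing cycle could be found."""


class EstimatorError(BreathmechError):
    """A per-breath estimator cannot be computed (e.g. rank-deficient design)."""
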