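"""Exception types shared across the pipeline."""


class InvalidParameterError(ValueError):
    """A configuration or function parameter is outside its valid domain."""


class OrderingError(ValueError):
    """Timestamps are not sorted within an animal."""


class InsufficientDataError(ValueError):
    """Too few fixes to estimate the requested quantity."""


class DegenerateBandwidthError(ValueError):
    """Kernel bandwidth is zero (all fixes coincide)."""


class GridExtentError(ValueError):
    """Evaluation grid truncates more probability mass than allowed."""


class AlignmentError(ValueError):
    """Two utilization distributions are not on a common grid."""
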