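"""Exception types raised across the package."""


class HistobenchError(Exception):
    """Base class for all package-specific errors."""


class OrderingError(HistobenchError):
    """Section files cannot be put into a unique, gap-free order."""


class DegenerateInputError(HistobenchError):
    """Input is geometrically or numerically degenerate for the operation."""


class EncodingError(HistobenchError):
    """Landmarks cannot be encoded as disk images without ambiguity."""


class MatchFailureError(HistobenchError):
    """Feature matching produced too few inliers for a reliable transform."""


class CanvasError(HistobenchError):
    """Images or masks do not share the common canvas required."""


class PhantomSpecError(HistobenchError):
    """A synthetic phantom specification is infeasible."""
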