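"""Exception hierarchy for rmtnet.

All package-specific failures derive from :class:`RMTNetError` so callers can
catch one base class at pipeline boundaries.
"""

from __future__ import annotations


class RMTNetError(Exception):
    """Base class for all rmtnet errors."""


class DuplicateIdentifier(RMTNetError):
    """A probe-set or sample identifier occurs more than once."""


class MalformedInput(RMTNetError):
    """Ragged rows, non-numeric cells, or otherwise unparsable input."""


class UnknownIdentifier(RMTNetError):
    """A requested identifier is not present in the matrix."""


class DimensionMismatch(RMTNetError):
    """Two vectors that must align have different lengths."""


class InsufficientData(RMTNetError):
    """Too few probes or samples to run the requested computation."""


class FormatError(RMTNetError):
    """Corrupt or truncated binary similarity file."""


class AsymmetricMatrix(RMTNetError):
    """A matrix that must be symmetric is not (beyond tolerance)."""


class InsufficientEigenvalues(RMTNetError):
    """Too few unique eigenvalues to unfold a spectrum."""


class InvalidParameter(RMTNetError):
    """A parameter is outside its documented domain."""


class ThresholdNotFound(RMTNetError):
    """The threshold scan exhausted its range without a confirmed transition.

    Attributes
    ----------
    trace : list of ScanRecord
        The full scan trace accumulated before giving up.
    homogeneous : bool
        True when every computable chi-square already exceeded the
        significance level, which indicates near-uniformly high correlation
        across the similarity matrix (no Poisson regime exists to depart
        from); lowering the start threshold will not help in that case.
    """

    def __init__(self, message: str, trace=None, homogeneous: bool = False):
        super().__init__(message)
        self.trace = trace if trace is not None else []
        self.homogeneous = homogeneous


class EmptyNetwork(RMTNetError):
    """An operation that needs at least one node got an empty network."""


class DegenerateDegrees(RMTNetError):
    """All degrees equal the cutoff; the power-law exponent is unidentifiable."""


class NotComparable(RMTNetError):
    """Edge pair shares zero or two endpoints; Jaccard similarity undefined."""


class TooSmall(RMTNetError):
    """Network has fewer than two edges; no link communities exist."""


class InvalidBackground(RMTNetError):
    """Enrichment requested against an empty gene background."""


class NoComparableModules(RMTNetError):
    """Neither network has a module with at least one enriched term."""


class GlobalNetworkError(RMTNetError):
    """The unperturbed (global) network could not be constructed."""
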