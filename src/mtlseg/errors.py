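"""Exception hierarchy for the mtlseg pipeline."""


class MtlsegError(Exception):
    """Base class for all mtlseg errors."""


class MalformedContourError(MtlsegError):
    """Contour violates a structural invariant (too few vertices, duplicate
    consecutive vertices, key-vertex ordering, ...)."""


class MalformedSulcusError(MalformedContourError):
    """Collateral-sulcus geometry is inconsistent (fundus above its mouths)."""


class MissingLandmarkError(MtlsegError):
    """A required key vertex or landmark is absent; the message names it."""


class OutOfDomainError(MtlsegError):
    """An arc-length position or depth lies outside its valid domain."""


class PairingError(MtlsegError):
    """Two objects that must share a domain (slice, grid, case) do not."""


class CohortConfigError(MtlsegError):
    """Invalid synthetic-cohort configuration, or sampling could not produce
    an admissible value within the retry budget."""


class RuleDerivationError(MtlsegError):
    """A statistics cell required by the rule-table template is missing."""


class SegmentationRangeError(MtlsegError):
    """A slice lies outside the protocol range covered by the rule table."""


class DegenerateSliceError(MtlsegError):
    """Resolved borders produce an inverted (zero/negative length) interval."""


class StackGapError(MtlsegError):
    """A slice stack is missing slices inside the protocol range."""
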