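"""Exception types raised across the package."""


class SSEAlignError(Exception):
    """Base class for all package-specific errors."""


class ChainNotFoundError(SSEAlignError):
    """Requested chain id is absent from the structure file."""


class EmptyChainError(SSEAlignError):
    """Chain contains no C-alpha atoms."""


class AssignmentLengthError(SSEAlignError):
    """Secondary-structure assignment length does not match the chain."""


class DegenerateAxisError(SSEAlignError):
    """Axis fit requested on coincident points."""


class TooFewSSEsError(SSEAlignError):
    """Fewer than two secondary-structure elements survive filtering."""


class NoAlignedSSEsError(SSEAlignError):
    """Delta sub-matrix requested for an empty alignment."""


class UnscorablePairError(SSEAlignError):
    """Neither structure has any SSE pair in contact; scores undefined."""


class MatrixRecordError(SSEAlignError):
    """Database matrix record is corrupted or unreadable."""
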