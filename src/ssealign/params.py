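"""Scoring parameters shared by the alignment stages.

The four numbers that matter most are the angular constant ``C`` (caps the
per-pair score and sets the mismatch penalty), the contact cutoff ``D``
(midpoint distance, in Angstroms, beyond which an SSE pair contributes
nothing), and the gap-opening penalties ``g1``/``g2`` of the two dynamic
programming stages.  Defaults follow the calibrated values C=45, D=20 A,
g1=g2=-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of the nested dynamic-programming comparison.

    Attributes
    ----------
    C : float
        Angular constant in degrees; pair scores live in {0} U [-C, C].
    D : float
        Contact cutoff in Angstroms between SSE axis midpoints.
    g1 : float
        Gap-opening penalty of the first (global/semi-global) stage.
        Charged once per contiguous gap; extensions are free.
    g2 : float
        Gap-opening penalty of the second (local Smith-Waterman) stage.
    sigma : float
        Gaussian scale (degrees) of the raw similarity score.
    delta_d : float or None
        Reporting cutoff (Angstroms) for distance differences in the delta
        sub-matrix; ``None`` means "equal to D".
    mode_ratio : float
        Semi-global alignment is used when max(M, N)/min(M, N) exceeds
        this ratio (strictly); fixed at 2.
    block_angle_max : float
        Delta-angle ceiling (degrees) of the rigid-block walk.
    block_min_size : int
        Minimum number of aligned SSE pairs per rigid block.
    """

    C: float = 45.0
    D: float = 20.0
    g1: float = -4.0
    g2: float = -4.0
    sigma: float = 45.0
    delta_d: float | None = None
    mode_ratio: float = 2.0
    block_angle_max: float = 90.0
    block_min_size: int = 3

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.g1 > 0 or self.g2 > 0:
            raise ValueError("gap-opening penalties must be <= 0")

    @property
    def effective_delta_d(self) -> float:
        return self.D if self.delta_d is None else self.delta_d


DEFAULT_PARAMS = ScoringParams()
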