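"""Delta sub-matrix and similarity measures.

After stage 2 has matched SSEs, rows and columns of unaligned elements
are removed from both fold matrices, leaving two equal-shape matrices
compared cell to cell.  Their difference -- angular differences in one
half, distance differences in the other -- is the delta sub-matrix, from
which three measures are computed:

* raw score  S  = sum over reported entries of exp(-dOmega^2 / sigma^2);
  equals the number of reported entries N for identical structures;
* relative similarity  S_r = 100 * 2S / (n_q + n_t)  -- the default
  database ranking score;
* relative cover       C_r = 100 * S / min(n_q, n_t),

where n_q and n_t are the unordered contact-pair counts of the full query
and target matrices.  A Sorensen-Dice index (QS) compares one SSE
alignment against a gold-standard alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .dp import SSEAlignment, delta_omega
from .errors import NoAlignedSSEsError, UnscorablePairError
from .foldmatrix import FoldMatrix


@dataclass
class DeltaSubMatrix:
    """Difference matrix over aligned SSEs only.

    ``dw`` holds angular differences in [0, 180] degrees, ``dd`` absolute
    distance differences in Angstroms; ``valid[a, b]`` marks entries that
    are reported: both source pairs in contact under D and the distance
    difference within the reporting cutoff delta_d.
    """

    aligned_labels: list[str]
    query_indices: list[int]
    target_indices: list[int]
    dw: np.ndarray
    dd: np.ndarray
    valid: np.ndarray
    delta_d: float

    @property
    def size(self) -> int:
        return len(self.aligned_labels)

    @property
    def n_entries(self) -> int:
        """Number of reported (unordered) SSE-pair entries, the N of the raw score."""
        return int(np.triu(self.valid, k=1).sum())

    def subdiagonal(self) -> list[float | None]:
        """First-subdiagonal delta-angle walk consumed by block inference."""
        return [
            float(self.dw[k, k - 1]) if self.valid[k, k - 1] else None
            for k in range(1, self.size)
        ]

    def render_text(self) -> str:
        """Delta tableau: labels diagonal, dOmega upper half, dDist lower."""
        width = 8
        lines = [" " * 4 + "".join(
            f"{self.aligned_labels[j]}".rjust(width) for j in range(self.size)
        )]
        for i in range(self.size):
            cells = []
            for j in range(self.size):
                if i == j:
                    cells.append(self.aligned_labels[i].rjust(width))
                elif not self.valid[i, j]:
                    cells.append(" " * width)
                elif i < j:
                    cells.append(f"{self.dw[i, j]:7.1f} ".rjust(width))
                else:
                    cells.append(f"{self.dd[i, j]:7.1f} ".rjust(width))
            lines.append(self.aligned_labels[i].ljust(4) + "".join(cells))
        return "\n".join(lines)


def build_delta_submatrix(
    fm_q: FoldMatrix,
    fm_t: FoldMatrix,
    aln: SSEAlignment,
    delta_d: float | None = None,
) -> DeltaSubMatrix:
    """Reduce both matrices to the aligned SSEs and take their difference.

    An off-diagonal entry is reported only when both source pairs are in
    contact (d <= D in their own matrix) and the distance difference does
    not exceed ``delta_d`` (defaults to the contact cutoff D of the query).
    """
    if len(aln) == 0:
        raise NoAlignedSSEsError("no aligned SSEs")
    if delta_d is None:
        delta_d = fm_q.D
    qi = np.array(aln.query_indices) - 1
    ti = np.array(aln.target_indices) - 1
    wq = fm_q.angle[np.ix_(qi, qi)]
    wt = fm_t.angle[np.ix_(ti, ti)]
    dq = fm_q.dist[np.ix_(qi, qi)]
    dt = fm_t.dist[np.ix_(ti, ti)]
    diff = np.abs(wq - wt) % 360.0
    dw = np.minimum(diff, 360.0 - diff)
    dd = np.abs(dq - dt)
    with np.errstate(invalid="ignore"):
        valid = (dq <= fm_q.D) & (dt <= fm_t.D) & (dd <= delta_d)
    np.fill_diagonal(valid, False)
    np.fill_diagonal(dw, 0.0)
    np.fill_diagonal(dd, 0.0)
    labels = [fm_q.labels[i] for i in qi]
    return DeltaSubMatrix(
        aligned_labels=labels,
        query_indices=list(aln.query_indices),
        target_indices=list(aln.target_indices),
        dw=dw,
        dd=dd,
        valid=valid,
        delta_d=float(delta_d),
    )


def raw_score(
    dsm: DeltaSubMatrix, sigma: float = 45.0, form: str = "gaussian"
) -> float:
    """Gaussian-weighted sum over the reported delta-matrix entries.

    ``form="gaussian"`` (default): S = sum_i exp(-dOmega_i^2 / sigma^2),
    so S = N when every angular difference vanishes.  ``form="scaled_sum"``
    instead divides the plain Gaussian sum by sigma^2 (an alternative
    normalization kept for auditability; it does not satisfy S = N).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    mask = np.triu(dsm.valid, k=1)
    r2 = dsm.dw[mask] ** 2
    if form == "gaussian":
        return float(np.exp(-r2 / sigma**2).sum())
    if form == "scaled_sum":
        return float(np.exp(-r2).sum() / sigma**2)
    raise ValueError(f"unknown form {form!r}")


def relative_similarity(S: float, n_q: int, n_t: int) -> float:
    """S_r = 100 * 2S / (n_q + n_t), a global similarity in [0, 100]."""
    if n_q <= 0 and n_t <= 0:
        raise UnscorablePairError("unscorable pair of structures: no contact pairs")
    return 100.0 * 2.0 * S / (n_q + n_t)


def relative_cover(S: float, n_q: int, n_t: int) -> float:
    """C_r = 100 * S / min(n_q, n_t): match cover of the smaller structure."""
    if min(n_q, n_t) <= 0:
        raise UnscorablePairError("unscorable pair of structures: no contact pairs")
    return 100.0 * S / min(n_q, n_t)


@dataclass
class SimilarityScores:
    S: float
    S_r: float
    C_r: float
    N: int
    n_q: int
    n_t: int
    sigma: float


def compute_scores(
    dsm: DeltaSubMatrix,
    fm_q: FoldMatrix,
    fm_t: FoldMatrix,
    sigma: float = 45.0,
) -> SimilarityScores:
    """Raw score plus both normalizations for one aligned structure pair."""
    n_q = fm_q.n_contact_pairs()
    n_t = fm_t.n_contact_pairs()
    S = raw_score(dsm, sigma=sigma)
    return SimilarityScores(
        S=S,
        S_r=relative_similarity(S, n_q, n_t),
        C_r=relative_cover(S, n_q, n_t),
        N=dsm.n_entries,
        n_q=n_q,
        n_t=n_t,
        sigma=sigma,
    )


def qs_index(
    A: Iterable[tuple[int, int]], B: Iterable[tuple[int, int]]
) -> float:
    """Sorensen-Dice agreement between two SSE alignments.

    QS = 2M / (|A| + |B|) with M the matched pairs in common; 1 for
    identical non-empty alignments, 0 for disjoint ones.  Two empty
    alignments give 0 (with a warning): there is no agreement to measure.
    """
    sa, sb = set(A), set(B)
    if not sa and not sb:
        warnings.warn("QS of two empty alignments defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))
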