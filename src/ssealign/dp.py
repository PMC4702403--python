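"""Nested two-stage dynamic programming over fold-matrix rows.

Stage 1 treats each row of the two fold matrices as a linear sequence of
SSE pairs and aligns every query row against every target row with a
global (or, for very unequal SSE counts, semi-global) Needleman-Wunsch
variant under a constant gap-opening penalty model: a contiguous gap costs
its opening penalty once, extensions are free.  The optimum of each of the
M x N row alignments fills a second score matrix, which stage 2 aligns
with local Smith-Waterman; backtracking from the maximum cell yields the
matched SSE pairs.

The pair substitution score caps at the angular constant C, decreases
linearly with the (wraparound) angular difference, charges -C for
type-pair mismatches or angular differences beyond 2C, and is 0 whenever
either pair is out of contact (midpoint distance above D).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .foldmatrix import PairEntry, PairRow
from .params import ScoringParams

NEG_INF = float("-inf")

Mode = Literal["global", "semiglobal"]


@dataclass
class SSEAlignment:
    """Matched SSE index pairs (1-based, strictly increasing) plus score."""

    pairs: list[tuple[int, int]]
    score: float
    stage1_mode: Mode = "global"

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def query_indices(self) -> list[int]:
        return [p[0] for p in self.pairs]

    @property
    def target_indices(self) -> list[int]:
        return [p[1] for p in self.pairs]


def delta_omega(w1: float, w2: float) -> float:
    """Minimal angular difference on the circle, in [0, 180]."""
    a = abs(w1 - w2) % 360.0
    return min(a, 360.0 - a)


def pair_score(
    omega_q: float,
    omega_t: float,
    d_q: float,
    d_t: float,
    types_q: str,
    types_t: str,
    params: ScoringParams,
) -> float:
    """Substitution score of one query SSE pair against one target pair."""
    if d_q > params.D or d_t > params.D:
        return 0.0
    if types_q != types_t:
        return -params.C
    dw = delta_omega(omega_q, omega_t)
    if dw > 2.0 * params.C:
        return -params.C
    return params.C - dw


def _entry_score(a: PairEntry, b: PairEntry, params: ScoringParams) -> float:
    return pair_score(a.omega, b.omega, a.dist, b.dist, a.type_pair, b.type_pair, params)


def choose_stage1_mode(M: int, N: int, params: ScoringParams | None = None) -> Mode:
    """Semi-global iff the SSE-count ratio strictly exceeds the threshold."""
    ratio = (params.mode_ratio if params is not None else 2.0)
    if min(M, N) <= 0:
        raise ValueError("SSE counts must be positive")
    return "semiglobal" if max(M, N) / min(M, N) > ratio else "global"


def _gotoh_matrices(
    sub: np.ndarray, g: float, semiglobal: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill Gotoh H/E/F matrices for a constant gap-opening penalty model.

    E holds alignments ending in a gap consuming the second sequence
    (horizontal moves), F in a gap consuming the first (vertical moves).
    """
    m, n = sub.shape
    H = np.full((m + 1, n + 1), NEG_INF)
    E = np.full((m + 1, n + 1), NEG_INF)
    F = np.full((m + 1, n + 1), NEG_INF)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = 0.0 if semiglobal else g
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = 0.0 if semiglobal else g
        H[i, 0] = F[i, 0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] + g, E[i, j - 1])
            F[i, j] = max(H[i - 1, j] + g, F[i - 1, j])
            H[i, j] = max(H[i - 1, j - 1] + sub[i - 1, j - 1], E[i, j], F[i, j])
    return H, E, F


def stage1_row_alignment(
    row_q: PairRow | Sequence[PairEntry],
    row_t: PairRow | Sequence[PairEntry],
    params: ScoringParams,
    mode: Mode = "global",
) -> float:
    """Optimal stage-1 score for one query row against one target row.

    Global mode returns the bottom-right Gotoh cell; semi-global mode frees
    leading and trailing gaps on both rows and returns the maximum over the
    last row and last column.
    """
    ea = row_q.entries if isinstance(row_q, PairRow) else list(row_q)
    eb = row_t.entries if isinstance(row_t, PairRow) else list(row_t)
    if not ea or not eb:
        raise ValueError("rows must be non-empty")
    sub = np.array([[_entry_score(a, b, params) for b in eb] for a in ea])
    semiglobal = mode == "semiglobal"
    H, _E, _F = _gotoh_matrices(sub, params.g1, semiglobal)
    if semiglobal:
        return float(max(H[-1, :].max(), H[:, -1].max()))
    return float(H[-1, -1])


def build_stage2_score_matrix(
    query_rows: Sequence[PairRow],
    target_rows: Sequence[PairRow],
    params: ScoringParams,
    mode: Mode | None = None,
) -> np.ndarray:
    """Stage-1 optimum of every query row vs every target row (M x N)."""
    if mode is None:
        mode = choose_stage1_mode(len(query_rows), len(target_rows), params)
    M, N = len(query_rows), len(target_rows)
    S = np.empty((M, N))
    for i in range(M):
        for k in range(N):
            S[i, k] = stage1_row_alignment(query_rows[i], target_rows[k], params, mode)
    return S


def stage2_local_alignment(
    score_matrix: np.ndarray,
    params: ScoringParams,
    stage1_mode: Mode = "global",
) -> SSEAlignment:
    """Smith-Waterman over the stage-2 score matrix, cell floor at zero.

    Backtracks from the maximum cell (ties: smallest (i, k)
    lexicographically); at each step the move preference is diagonal, then
    up, then left, so output is deterministic.  An all-nonpositive matrix
    yields an empty alignment (no detectable similarity).
    """
    sub = np.asarray(score_matrix, dtype=float)
    m, n = sub.shape
    g = params.g2
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG_INF)
    F = np.full((m + 1, n + 1), NEG_INF)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] + g, E[i, j - 1])
            F[i, j] = max(H[i - 1, j] + g, F[i - 1, j])
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub[i - 1, j - 1], E[i, j], F[i, j])

    best = H[1:, 1:].max(initial=0.0)
    if best <= 0.0:
        return SSEAlignment(pairs=[], score=0.0, stage1_mode=stage1_mode)
    where = np.argwhere(H[1:, 1:] == best)
    i, j = (int(where[0][0]) + 1, int(where[0][1]) + 1)  # argwhere is row-major

    pairs: list[tuple[int, int]] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0.0:
                break
            if H[i, j] == H[i - 1, j - 1] + sub[i - 1, j - 1]:
                pairs.append((i, j))
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            if F[i, j] == H[i - 1, j] + g:
                state = "H"
            i -= 1
        else:  # E
            if E[i, j] == H[i, j - 1] + g:
                state = "H"
            j -= 1
    pairs.reverse()
    return SSEAlignment(pairs=pairs, score=float(best), stage1_mode=stage1_mode)


def align_rows(
    query_rows: Sequence[PairRow],
    target_rows: Sequence[PairRow],
    params: ScoringParams,
) -> SSEAlignment:
    """Full nested DP: mode choice, stage-1 matrix assembly, stage-2 local."""
    mode = choose_stage1_mode(len(query_rows), len(target_rows), params)
    S = build_stage2_score_matrix(query_rows, target_rows, params, mode)
    return stage2_local_alignment(S, params, stage1_mode=mode)
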