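"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: alignment optima come
from exhaustive enumeration of all monotone match sets, and superposition
from a plain SVD Kabsch solver.
"""

from __future__ import annotations

import itertools

import numpy as np


def _gap_runs(matched_positions: tuple[int, ...], length: int) -> list[tuple[bool, bool]]:
    """Maximal unmatched runs of one sequence as (is_leading, is_trailing)."""
    runs: list[tuple[bool, bool]] = []
    prev = 0
    for pos in matched_positions:
        if pos - prev > 1:
            runs.append((prev == 0, False))
        prev = pos
    if length - prev >= 1:
        runs.append((prev == 0, True))
    return runs


def _end_gap_cost(
    runs_a: list[tuple[bool, bool]],
    runs_b: list[tuple[bool, bool]],
    g: float,
    free_ends: bool,
) -> float:
    """Total gap-opening cost; one run opens one gap, extension is free.

    With free ends, an alignment path may skip the leading run of exactly
    one sequence for free and the trailing run of exactly one sequence for
    free; the cost is minimized over those two independent choices.
    """
    if not free_ends:
        return g * (len(runs_a) + len(runs_b))
    best = float("-inf")  # g <= 0: the least penalty is the largest value
    for lead_free in (0, 1):
        for trail_free in (0, 1):
            cost = 0.0
            for which, runs in enumerate((runs_a, runs_b)):
                for leading, trailing in runs:
                    if (leading and lead_free == which) or (
                        trailing and trail_free == which
                    ):
                        continue
                    cost += g
            best = max(best, cost)
    return best


def enumerate_stage1(sub: np.ndarray, g: float, mode: str) -> float:
    """Optimal global/semi-global score by exhaustive enumeration.

    ``sub[i, j]`` is the substitution score; every maximal unmatched run
    in either sequence opens one gap of cost ``g``; semi-global mode frees
    end gaps as described in ``_end_gap_cost``.
    """
    m, n = sub.shape
    free = mode == "semiglobal"
    best = float("-inf")
    for k in range(0, min(m, n) + 1):
        for rows in itertools.combinations(range(1, m + 1), k):
            for cols in itertools.combinations(range(1, n + 1), k):
                score = sum(sub[i - 1, j - 1] for i, j in zip(rows, cols))
                score += _end_gap_cost(
                    _gap_runs(rows, m), _gap_runs(cols, n), g, free
                )
                best = max(best, score)
    return float(best)


def enumerate_stage2(sub: np.ndarray, g: float) -> tuple[float, list[tuple[int, int]]]:
    """Optimal local score (floor 0) by exhaustive enumeration.

    Only interior gap runs (between consecutive matched pairs) cost ``g``;
    unmatched ends are free, as in Smith-Waterman.  Returns the best score
    and one optimal match set (smallest end cell, diagonal-preferring ties
    are not reproduced -- use the score for equality checks).
    """
    m, n = sub.shape
    best = 0.0
    best_pairs: list[tuple[int, int]] = []
    for k in range(1, min(m, n) + 1):
        for rows in itertools.combinations(range(1, m + 1), k):
            for cols in itertools.combinations(range(1, n + 1), k):
                score = sum(sub[i - 1, j - 1] for i, j in zip(rows, cols))
                for a in range(1, k):
                    if rows[a] - rows[a - 1] > 1:
                        score += g
                    if cols[a] - cols[a - 1] > 1:
                        score += g
                if score > best:
                    best = score
                    best_pairs = list(zip(rows, cols))
    return float(best), best_pairs


def svd_superpose(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, float]:
    """SVD-based Kabsch: rotation R (and RMSD) minimizing |X - (R Y + t)|."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    xm = X - X.mean(axis=0)
    ym = Y - Y.mean(axis=0)
    H = ym.T @ xm
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    resid = xm - ym @ R.T
    rmsd = float(np.sqrt((resid**2).sum() / len(X)))
    return R, rmsd


def random_fold_matrix(rng: np.random.Generator, m: int, helix_prob: float = 0.6):
    """Random symmetric tableau payload (labels, angles, distances)."""
    labels = ["A" if rng.random() < helix_prob else "B" for _ in range(m)]
    angle = np.full((m, m), np.nan)
    dist = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            w = float(rng.uniform(-180.0, 180.0))
            d = float(rng.uniform(2.0, 30.0))
            angle[i, j] = angle[j, i] = w
            dist[i, j] = dist[j, i] = d
    return labels, angle, dist
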