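"""High-level alignment pipeline: structures in, flexible alignment out."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .blocks import (
    FlexibleSuperposition,
    assemble_flexible_superposition,
    single_rigid_rmsd,
)
from .dp import SSEAlignment, align_rows, choose_stage1_mode
from .errors import TooFewSSEsError
from .foldmatrix import FoldMatrix, build_fold_matrix, build_pair_rows
from .params import ScoringParams
from .similarity import (
    DeltaSubMatrix,
    SimilarityScores,
    build_delta_submatrix,
    compute_scores,
)
from .structure import ChainModel, SSEVector, chain_to_sses, parse_chain


@dataclass
class AlignmentResult:
    """Everything the pipeline produces for one structure pair."""

    fm_q: FoldMatrix
    fm_t: FoldMatrix
    alignment: SSEAlignment
    dsm: DeltaSubMatrix | None
    scores: SimilarityScores | None
    superposition: FlexibleSuperposition | None
    sses_q: list[SSEVector]
    sses_t: list[SSEVector]
    params: ScoringParams

    @property
    def n_blocks(self) -> int:
        return 0 if self.superposition is None else len(self.superposition.blocks)

    def single_rigid_rmsd(self) -> float:
        """RMSD of forcing the whole alignment into one rigid superposition."""
        if not self.alignment.pairs:
            return float("nan")
        return single_rigid_rmsd(self.alignment.pairs, self.sses_q, self.sses_t)


def align_sses(
    sses_q: Sequence[SSEVector],
    sses_t: Sequence[SSEVector],
    params: ScoringParams | None = None,
) -> AlignmentResult:
    """Align two SSE vector sets through the full nested-DP pipeline."""
    params = params or ScoringParams()
    if len(sses_q) < 2 or len(sses_t) < 2:
        raise TooFewSSEsError(
            f"too few SSEs: query has {len(sses_q)}, target has {len(sses_t)}"
        )
    fm_q = build_fold_matrix(sses_q, D=params.D)
    fm_t = build_fold_matrix(sses_t, D=params.D)
    aln = align_rows(build_pair_rows(fm_q), build_pair_rows(fm_t), params)
    if not aln.pairs:
        return AlignmentResult(
            fm_q, fm_t, aln, None, None, None, list(sses_q), list(sses_t), params
        )
    dsm = build_delta_submatrix(fm_q, fm_t, aln, delta_d=params.effective_delta_d)
    scores = compute_scores(dsm, fm_q, fm_t, sigma=params.sigma)
    sup = assemble_flexible_superposition(
        dsm,
        aln.pairs,
        sses_q,
        sses_t,
        angle_max=params.block_angle_max,
        min_size=params.block_min_size,
    )
    return AlignmentResult(
        fm_q, fm_t, aln, dsm, scores, sup, list(sses_q), list(sses_t), params
    )


def align_chains(
    chain_q: ChainModel,
    labels_q: str,
    chain_t: ChainModel,
    labels_t: str,
    params: ScoringParams | None = None,
) -> AlignmentResult:
    """Align two chains given their per-residue secondary structure."""
    return align_sses(
        chain_to_sses(chain_q, labels_q), chain_to_sses(chain_t, labels_t), params
    )


def align_files(
    query_file: str | Path,
    query_chain: str,
    target_file: str | Path,
    target_chain: str,
    labels_q: str,
    labels_t: str,
    params: ScoringParams | None = None,
) -> AlignmentResult:
    """Parse two structure files and align the selected chains."""
    cq = parse_chain(query_file, query_chain)
    ct = parse_chain(target_file, target_chain)
    return align_chains(cq, labels_q, ct, labels_t, params)


def score_report(result: AlignmentResult, query_id: str = "query", target_id: str = "target") -> dict:
    """JSON-ready score report for one aligned pair."""
    s = result.scores
    return {
        "query": query_id,
        "target": target_id,
        "M": result.fm_q.size,
        "N": result.fm_t.size,
        "n_aligned": len(result.alignment),
        "aligned_pairs": list(map(list, result.alignment.pairs)),
        "stage1_mode": result.alignment.stage1_mode,
        "stage2_score": result.alignment.score,
        "S": None if s is None else round(s.S, 6),
        "S_r": 0.0 if s is None else round(s.S_r, 6),
        "C_r": 0.0 if s is None else round(s.C_r, 6),
        "n_blocks": result.n_blocks,
        "params": {
            "C": result.params.C,
            "D": result.params.D,
            "g1": result.params.g1,
            "g2": result.params.g2,
            "sigma": result.params.sigma,
            "delta_d": result.params.effective_delta_d,
        },
    }
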