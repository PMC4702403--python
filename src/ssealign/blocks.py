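"""Rigid-block inference and per-block quaternion superposition.

A flexible alignment is a set of rigid local matches ("blocks"): maximal
contiguous runs of aligned SSE pairs whose geometry is consistent with a
single rotation + translation.  Blocks are read off the first subdiagonal
of the delta sub-matrix: a run starts at a reported delta-angle <= 90 deg
and extends while entries stay <= 90 deg; a suppressed (null) entry closes
the run; an entry above 90 deg may be rescued by the adjacent left-row or
bottom-column cell if one of those is reported and <= 90 deg.  Runs of
fewer than three SSE pairs are discarded.

Each block is then superposed independently with the quaternion
(Kearsley) closed-form solution of the Kabsch problem, using the two axis
endpoints of every member SSE as the coordinate set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .similarity import DeltaSubMatrix
from .structure import ChainModel, SSEVector


@dataclass
class RigidBlock:
    """Contiguous run of aligned SSE pairs sharing one transformation.

    ``member_pairs`` are 0-based indices into the alignment's pair list;
    applying ``rotation @ x + translation`` to target coordinates
    superposes them onto the query.
    """

    member_pairs: list[int]
    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float

    @property
    def size(self) -> int:
        return len(self.member_pairs)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class FlexibleSuperposition:
    blocks: list[RigidBlock]
    unassigned_pairs: list[int]
    query_indices: list[int]  # 1-based SSE indices per aligned pair
    target_indices: list[int]


def infer_blocks(dsm: DeltaSubMatrix, angle_max: float = 90.0, min_size: int = 3) -> list[tuple[int, int]]:
    """Contiguous rigid runs as inclusive (start, end) aligned-pair indices.

    Walks the first subdiagonal of the delta sub-matrix (cell (k, k-1)
    couples aligned pairs k-1 and k).  See the module docstring for the
    extend/trim/rescue rules.
    """
    L = dsm.size
    runs: list[tuple[int, int]] = []
    cur_start: int | None = None
    for k in range(1, L):
        if dsm.valid[k, k - 1]:
            v = float(dsm.dw[k, k - 1])
            if v <= angle_max:
                accept = True
            else:
                accept = _rescued(dsm, k, angle_max)
        else:
            accept = False
        if accept:
            if cur_start is None:
                cur_start = k - 1
        else:
            if cur_start is not None:
                runs.append((cur_start, k - 1))
                cur_start = None
    if cur_start is not None:
        runs.append((cur_start, L - 1))
    return [(a, b) for a, b in runs if b - a + 1 >= min_size]


def _rescued(dsm: DeltaSubMatrix, k: int, angle_max: float) -> bool:
    """Check the adjacent left-row cell (k, k-2) and bottom-column cell
    (k+1, k-1) for a reported delta-angle within the ceiling."""
    for i, j in ((k, k - 2), (k + 1, k - 1)):
        if 0 <= j < dsm.size and 0 <= i < dsm.size and dsm.valid[i, j]:
            if float(dsm.dw[i, j]) <= angle_max:
                return True
    return False


# ---------------------------------------------------------------------------
# quaternion (Kearsley) superposition


def kearsley_superpose(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of Y onto X via quaternions.

    Solves the Kabsch problem analytically: the smallest eigenvalue of
    Kearsley's symmetric 4x4 matrix (built from coordinate sums and
    differences) equals the residual sum of squares, and its eigenvector
    is the optimal rotation quaternion.  Returns (R, t, rmsd) with
    ``R @ y + t`` minimizing the RMSD to X; R is always a proper rotation.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("need matching (n, 3) coordinate sets")
    n = X.shape[0]
    cx = X.mean(axis=0)
    cy = Y.mean(axis=0)
    xm = X - cx
    ym = Y - cy
    d = ym - xm  # differences
    s = ym + xm  # sums
    K = np.empty((4, 4))
    K[0, 0] = (d**2).sum()
    K[1, 1] = (s[:, 1] ** 2 + s[:, 2] ** 2 + d[:, 0] ** 2).sum()
    K[2, 2] = (s[:, 0] ** 2 + s[:, 2] ** 2 + d[:, 1] ** 2).sum()
    K[3, 3] = (s[:, 0] ** 2 + s[:, 1] ** 2 + d[:, 2] ** 2).sum()
    K[0, 1] = K[1, 0] = (s[:, 1] * d[:, 2] - d[:, 1] * s[:, 2]).sum()
    K[0, 2] = K[2, 0] = (d[:, 0] * s[:, 2] - s[:, 0] * d[:, 2]).sum()
    K[0, 3] = K[3, 0] = (s[:, 0] * d[:, 1] - d[:, 0] * s[:, 1]).sum()
    K[1, 2] = K[2, 1] = (d[:, 0] * d[:, 1] - s[:, 0] * s[:, 1]).sum()
    K[1, 3] = K[3, 1] = (d[:, 0] * d[:, 2] - s[:, 0] * s[:, 2]).sum()
    K[2, 3] = K[3, 2] = (d[:, 1] * d[:, 2] - s[:, 1] * s[:, 2]).sum()
    evals, evecs = np.linalg.eigh(K)
    q = evecs[:, 0]  # eigenvector of the smallest eigenvalue, (w, x, y, z)
    R = _quat_to_matrix(q)
    t = cx - R @ cy
    # the smallest eigenvalue equals the residual sum of squares, but the
    # explicit residual is numerically cleaner near a perfect match
    resid = xm - ym @ R.T
    rmsd = float(np.sqrt((resid**2).sum() / n))
    return R, t, rmsd


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q / np.linalg.norm(q)
    return np.array(
        [
            [w * w + x * x - y * y - z * z, 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), w * w - x * x + y * y - z * z, 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), w * w - x * x - y * y + z * z],
        ]
    )


def _endpoint_coords(sses: Sequence[SSEVector], indices: Sequence[int]) -> np.ndarray:
    """Stack axis start/end points (2 per SSE) for the given 1-based indices."""
    pts = []
    for idx in indices:
        v = sses[idx - 1]
        pts.append(v.axis_start)
        pts.append(v.axis_end)
    return np.array(pts)


def superpose_block(
    block_pairs: Sequence[int],
    query_pairs: Sequence[tuple[int, int]],
    sses_q: Sequence[SSEVector],
    sses_t: Sequence[SSEVector],
) -> RigidBlock:
    """Superpose one block's target SSE axes onto the query's.

    ``block_pairs`` indexes into ``query_pairs`` (the stage-2 alignment);
    coordinates are the axis endpoints of the member SSEs.
    """
    qi = [query_pairs[p][0] for p in block_pairs]
    ti = [query_pairs[p][1] for p in block_pairs]
    X = _endpoint_coords(sses_q, qi)
    Y = _endpoint_coords(sses_t, ti)
    R, t, rmsd = kearsley_superpose(X, Y)
    return RigidBlock(member_pairs=list(block_pairs), rotation=R, translation=t, rmsd=rmsd)


def single_rigid_rmsd(
    pairs: Sequence[tuple[int, int]],
    sses_q: Sequence[SSEVector],
    sses_t: Sequence[SSEVector],
) -> float:
    """RMSD of one whole-alignment rigid superposition (hinge diagnostic)."""
    X = _endpoint_coords(sses_q, [p[0] for p in pairs])
    Y = _endpoint_coords(sses_t, [p[1] for p in pairs])
    return kearsley_superpose(X, Y)[2]


def assemble_flexible_superposition(
    dsm: DeltaSubMatrix,
    pairs: Sequence[tuple[int, int]],
    sses_q: Sequence[SSEVector],
    sses_t: Sequence[SSEVector],
    angle_max: float = 90.0,
    min_size: int = 3,
) -> FlexibleSuperposition:
    """Infer blocks and fit each block's independent transformation."""
    runs = infer_blocks(dsm, angle_max=angle_max, min_size=min_size)
    blocks = [
        superpose_block(list(range(a, b + 1)), pairs, sses_q, sses_t)
        for a, b in runs
    ]
    assigned = {p for blk in blocks for p in blk.member_pairs}
    unassigned = [p for p in range(len(pairs)) if p not in assigned]
    return FlexibleSuperposition(
        blocks=blocks,
        unassigned_pairs=unassigned,
        query_indices=[p[0] for p in pairs],
        target_indices=[p[1] for p in pairs],
    )


# ---------------------------------------------------------------------------
# coordinate output


def write_superposition_pdb(
    path: str | Path,
    chain_t: ChainModel,
    sup: FlexibleSuperposition,
) -> None:
    """Write the transformed target trace, one model per rigid block.

    Each model holds the full target C-alpha trace under that block's
    transformation, so any viewer can overlay the models on the query.
    """
    import gemmi

    st = gemmi.Structure()
    st.name = "flexible_superposition"
    for bi, blk in enumerate(sup.blocks, start=1):
        model = gemmi.Model(bi)
        chain = gemmi.Chain(chain_t.chain_id or "T")
        coords = blk.transform(chain_t.ca_coords)
        for res, xyz in zip(chain_t.residues, coords):
            r = gemmi.Residue()
            r.name = "ALA"
            r.seqid = gemmi.SeqId(res.number, res.icode or " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            r.add_atom(atom)
            chain.add_residue(r)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


def block_summary(sup: FlexibleSuperposition) -> str:
    """Plain-text membership + RMSD table of the flexible superposition."""
    lines = ["block\tsize\tquery_sses\ttarget_sses\trmsd_A"]
    for bi, blk in enumerate(sup.blocks, start=1):
        qs = ",".join(str(sup.query_indices[p]) for p in blk.member_pairs)
        ts = ",".join(str(sup.target_indices[p]) for p in blk.member_pairs)
        lines.append(f"{bi}\t{blk.size}\t{qs}\t{ts}\t{blk.rmsd:.4f}")
    if sup.unassigned_pairs:
        qs = ",".join(str(sup.query_indices[p]) for p in sup.unassigned_pairs)
        lines.append(f"unassigned\t{len(sup.unassigned_pairs)}\t{qs}\t-\t-")
    return "\n".join(lines)
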