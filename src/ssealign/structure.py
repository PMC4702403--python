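"""Chain parsing, secondary-structure handling and SSE vectorization.

A protein chain is reduced to its C-alpha trace, per-residue secondary
structure is attached (from a DSSP output file, an external DSSP run, or a
user-supplied assignment string), and maximal helix/strand runs are turned
into directed axis vectors by a least-squares line fit.  Those vectors --
one per secondary-structure element (SSE) -- are the atomic unit of every
downstream comparison.

Helix subtypes (alpha, 3-10, pi; DSSP classes H, G, I) are treated as one
helix class and merged before length filtering.  Helices shorter than five
residues and strands shorter than four are discarded.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np

from .errors import (
    AssignmentLengthError,
    ChainNotFoundError,
    DegenerateAxisError,
    EmptyChainError,
)

# canonical internal labels
HELIX, STRAND, COIL = "H", "E", "C"
# SSE type labels used on the matrix diagonal
TYPE_HELIX, TYPE_STRAND = "A", "B"

#: minimum residue counts for an element to survive filtering
MIN_HELIX_LEN = 5
MIN_STRAND_LEN = 4

_DSSP_TO_INTERNAL = {"H": HELIX, "G": HELIX, "I": HELIX, "E": STRAND}


@dataclass(frozen=True)
class Residue:
    number: int
    icode: str
    ca: np.ndarray  # shape (3,), Angstroms

    @property
    def ident(self) -> str:
        return f"{self.number}{self.icode}".strip()


@dataclass
class ChainModel:
    """C-alpha trace of a single protein chain, in file order."""

    chain_id: str
    residues: list[Residue]

    @property
    def sequence_length(self) -> int:
        return len(self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SSEVector:
    """A secondary-structure element as a typed, directed axis segment.

    ``axis_start``/``axis_end`` run from the amino- to the carboxyl-terminal
    end of the element; ``midpoint`` is the midpoint of that segment.
    """

    index: int  # 1-based, order of appearance N->C
    sse_type: str  # TYPE_HELIX ("A") or TYPE_STRAND ("B")
    start_residue: str
    end_residue: str
    axis_start: np.ndarray
    axis_end: np.ndarray
    midpoint: np.ndarray
    n_residues: int

    @property
    def direction(self) -> np.ndarray:
        d = self.axis_end - self.axis_start
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise DegenerateAxisError(f"SSE {self.index} has a zero-length axis")
        return d / n


# ---------------------------------------------------------------------------
# structure file parsing


def parse_chain(structure_file: str | Path, chain_id: str) -> ChainModel:
    """Read the C-alpha trace of one chain from a PDB or mmCIF file.

    Altloc duplicates collapse to the highest-occupancy conformer (first
    listed wins ties); insertion codes are preserved in residue identifiers.
    """
    st = gemmi.read_structure(str(structure_file))
    st.setup_entities()
    if len(st) == 0:
        raise EmptyChainError(f"{structure_file}: no models")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainNotFoundError(
            f"chain not found: {chain_id!r} in {structure_file}"
        )
    residues: list[Residue] = []
    for res in chain:
        best = None
        for atom in res:
            if atom.name != "CA" or atom.element == gemmi.Element("Ca"):
                continue
            if best is None or atom.occ > best.occ:
                best = atom
        if best is not None:
            pos = np.array([best.pos.x, best.pos.y, best.pos.z])
            icode = res.seqid.icode.strip()
            residues.append(Residue(res.seqid.num, icode, pos))
    if not residues:
        raise EmptyChainError(f"empty chain: {chain_id!r} has no C-alpha atoms")
    return ChainModel(chain_id=chain_id, residues=residues)


# ---------------------------------------------------------------------------
# secondary structure assignment


def labels_from_user_string(assignment: str, chain: ChainModel) -> str:
    """Map a one-char-per-residue DSSP-alphabet string to internal labels."""
    if len(assignment) != len(chain):
        raise AssignmentLengthError(
            f"assignment length mismatch: {len(assignment)} labels for "
            f"{len(chain)} residues"
        )
    return "".join(_DSSP_TO_INTERNAL.get(c.upper(), COIL) for c in assignment)


def labels_from_dssp_file(dssp_file: str | Path, chain: ChainModel) -> str:
    """Read per-residue labels for ``chain`` from a DSSP output file.

    Both the classic fixed-column dialect and the mmCIF dialect produced by
    recent mkdssp versions are accepted.
    """
    path = Path(dssp_file)
    head = path.read_text(errors="replace")[:2048]
    if head.lstrip().startswith("data_") or "_dssp_struct_summary" in head:
        raw = _read_dssp_mmcif(path, chain.chain_id)
    else:
        raw = _read_dssp_classic(path, chain.chain_id)
    labels = []
    for res in chain.residues:
        labels.append(_DSSP_TO_INTERNAL.get(raw.get((res.number, res.icode), " "), COIL))
    return "".join(labels)


def _read_dssp_classic(path: Path, chain_id: str) -> dict[tuple[int, str], str]:
    from Bio.PDB.DSSP import make_dssp_dict

    dssp_dict, _keys = make_dssp_dict(str(path))
    out: dict[tuple[int, str], str] = {}
    for (cid, res_id), values in dssp_dict.items():
        if cid != chain_id:
            continue
        _het, num, icode = res_id
        out[(num, icode.strip())] = values[1]  # secondary structure class
    return out


def _read_dssp_mmcif(path: Path, chain_id: str) -> dict[tuple[int, str], str]:
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    table = block.find(
        "_dssp_struct_summary.",
        ["label_asym_id", "label_seq_id", "secondary_structure"],
    )
    out: dict[tuple[int, str], str] = {}
    for row in table:
        if row[0] != chain_id:
            continue
        try:
            num = int(row[1])
        except ValueError:
            continue
        ss = gemmi.cif.as_string(row[2]).strip() or "-"
        out[(num, "")] = ss if ss != "-" else " "
    return out


def run_dssp(structure_file: str | Path, executable: str = "mkdssp") -> Path:
    """Run an external DSSP binary and return the path of its output file."""
    exe = shutil.which(executable)
    if exe is None:
        raise FileNotFoundError(
            f"DSSP executable {executable!r} not found on PATH; supply a DSSP "
            "output file or a per-residue assignment string instead"
        )
    out = Path(tempfile.mkstemp(suffix=".dssp")[1])
    subprocess.run([exe, str(structure_file), str(out)], check=True)
    return out


def assign_secondary_structure(
    chain: ChainModel,
    *,
    user_string: str | None = None,
    dssp_file: str | Path | None = None,
    structure_file: str | Path | None = None,
    source: Literal["user-string", "dssp-file", "external-dssp"] | None = None,
) -> str:
    """Obtain internal per-residue labels (H/E/C) from one of three sources."""
    if source is None:
        if user_string is not None:
            source = "user-string"
        elif dssp_file is not None:
            source = "dssp-file"
        else:
            source = "external-dssp"
    if source == "user-string":
        if user_string is None:
            raise ValueError("user_string required")
        return labels_from_user_string(user_string, chain)
    if source == "dssp-file":
        if dssp_file is None:
            raise ValueError("dssp_file required")
        return labels_from_dssp_file(dssp_file, chain)
    if structure_file is None:
        raise ValueError("structure_file required to invoke external DSSP")
    return labels_from_dssp_file(run_dssp(structure_file), chain)


# ---------------------------------------------------------------------------
# segmentation and filtering


def segment_and_filter(
    labels: str, chain: ChainModel
) -> list[tuple[str, int, int]]:
    """Extract surviving SSEs as (type, start_pos, end_pos) position ranges.

    Maximal runs of helix/strand labels become candidate elements (helix
    subtypes were already merged during label mapping); helices need at
    least MIN_HELIX_LEN residues and strands MIN_STRAND_LEN to survive.
    Positions are 0-based indices into ``chain.residues``, inclusive.
    Gaps in residue *numbering* never split a run; only label changes do.
    """
    if len(labels) != len(chain):
        raise AssignmentLengthError(
            f"assignment length mismatch: {len(labels)} labels for "
            f"{len(chain)} residues"
        )
    segments: list[tuple[str, int, int]] = []
    i = 0
    n = len(labels)
    while i < n:
        lab = labels[i]
        j = i
        while j + 1 < n and labels[j + 1] == lab:
            j += 1
        if lab == HELIX and (j - i + 1) >= MIN_HELIX_LEN:
            segments.append((TYPE_HELIX, i, j))
        elif lab == STRAND and (j - i + 1) >= MIN_STRAND_LEN:
            segments.append((TYPE_STRAND, i, j))
        i = j + 1
    return segments


# ---------------------------------------------------------------------------
# axis geometry


def fit_axis(ca_coords: Sequence[np.ndarray] | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares line fit through C-alpha coordinates.

    Returns (axis_start, axis_end, midpoint).  The axis is the first
    principal direction of the mean-centered coordinates (via SVD); the
    endpoints are the projections of the first and last residue onto that
    line, and the direction is fixed amino->carboxyl: the principal vector
    is flipped if it opposes (last - first).
    """
    pts = np.asarray(ca_coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("need an (n, 3) array with n >= 2")
    center = pts.mean(axis=0)
    centered = pts - center
    if np.max(np.linalg.norm(centered, axis=1)) < 1e-9:
        raise DegenerateAxisError("degenerate axis: all points coincident")
    _u, _s, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if np.dot(direction, pts[-1] - pts[0]) < 0:
        direction = -direction
    t = centered @ direction
    axis_start = center + t[0] * direction
    axis_end = center + t[-1] * direction
    midpoint = 0.5 * (axis_start + axis_end)
    return axis_start, axis_end, midpoint


def build_sse_vectors(
    chain: ChainModel, segments: Iterable[tuple[str, int, int]]
) -> list[SSEVector]:
    """Fit an axis to each surviving segment, numbering elements 1..M."""
    coords = chain.ca_coords
    sses: list[SSEVector] = []
    for idx, (sse_type, a, b) in enumerate(segments, start=1):
        start, end, mid = fit_axis(coords[a : b + 1])
        sses.append(
            SSEVector(
                index=idx,
                sse_type=sse_type,
                start_residue=chain.residues[a].ident,
                end_residue=chain.residues[b].ident,
                axis_start=start,
                axis_end=end,
                midpoint=mid,
                n_residues=b - a + 1,
            )
        )
    return sses


def chain_to_sses(chain: ChainModel, labels: str) -> list[SSEVector]:
    """Convenience: segmentation + filtering + axis fitting in one call."""
    return build_sse_vectors(chain, segment_and_filter(labels, chain))


def interaxial_angle(v1: SSEVector, v2: SSEVector) -> float:
    """Signed interaxial angle omega between two SSE axes, in (-180, 180].

    Implemented as the torsion (dihedral) angle of the triple
    (axis-1 direction, midpoint-connection vector, axis-2 direction): the
    signed rotation about the line joining the two midpoints that brings
    one axis into eclipse with the other.  Falls back to the unsigned angle
    between the directions when the midpoints coincide or an axis is
    parallel to the connection line (torsion undefined there).
    """
    u1 = v1.direction
    u2 = v2.direction
    conn = v2.midpoint - v1.midpoint
    nc = np.linalg.norm(conn)
    if nc < 1e-9:
        return _unsigned_angle(u1, u2)
    c = conn / nc
    p1 = u1 - np.dot(u1, c) * c
    p2 = u2 - np.dot(u2, c) * c
    if np.linalg.norm(p1) < 1e-9 or np.linalg.norm(p2) < 1e-9:
        return _unsigned_angle(u1, u2)
    omega = np.degrees(np.arctan2(np.dot(np.cross(p1, p2), c), np.dot(p1, p2)))
    if omega <= -180.0 + 1e-12:
        omega = 180.0
    return float(omega)


def _unsigned_angle(u1: np.ndarray, u2: np.ndarray) -> float:
    cosang = float(np.clip(np.dot(u1, u2), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def midpoint_distance(v1: SSEVector, v2: SSEVector) -> float:
    """Euclidean distance between the axis midpoints, in Angstroms."""
    return float(np.linalg.norm(v1.midpoint - v2.midpoint))
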