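"""Fold matrices (SSE tableaux), pair rows and the matrix database.

The fold matrix of a chain with M secondary-structure elements is an M x M
table: element type labels on the diagonal, the interaxial angle of each
pair in one half, their midpoint distance in the other.  Angles and
distances are computed and stored for *all* pairs; the contact cutoff D is
applied at scoring time, so a precomputed database can be queried with any
D without rebuilding.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import MatrixRecordError, TooFewSSEsError
from .structure import SSEVector, interaxial_angle, midpoint_distance

logger = logging.getLogger(__name__)


@dataclass
class FoldMatrix:
    """Square matrix over a chain's SSEs: labels, angles, distances.

    ``angle`` and ``dist`` are symmetric (M, M) arrays with NaN on the
    diagonal; ``labels[i]`` is "A" (helix) or "B" (strand).
    """

    labels: list[str]
    angle: np.ndarray
    dist: np.ndarray
    D: float = 20.0

    @property
    def size(self) -> int:
        return len(self.labels)

    def contact(self, D: float | None = None) -> np.ndarray:
        """Boolean contact mask: midpoint distance <= D, diagonal False."""
        cutoff = self.D if D is None else D
        with np.errstate(invalid="ignore"):
            mask = self.dist <= cutoff
        np.fill_diagonal(mask, False)
        return mask

    def n_contact_pairs(self, D: float | None = None) -> int:
        """Number of unordered SSE pairs in contact."""
        return int(np.triu(self.contact(D), k=1).sum())

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "angle": np.round(self.angle, 9).tolist(),
            "dist": np.round(self.dist, 9).tolist(),
            "D": self.D,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FoldMatrix":
        try:
            labels = list(data["labels"])
            angle = np.array(data["angle"], dtype=float)
            dist = np.array(data["dist"], dtype=float)
            D = float(data["D"])
        except (KeyError, TypeError, ValueError) as exc:
            raise MatrixRecordError(f"unreadable matrix record: {exc}") from exc
        m = len(labels)
        if angle.shape != (m, m) or dist.shape != (m, m):
            raise MatrixRecordError("unreadable matrix record: shape mismatch")
        return cls(labels=labels, angle=angle, dist=dist, D=D)

    def render_text(self, D: float | None = None) -> str:
        """Plain-text tableau: labels on the diagonal, angles in the upper
        half, distances in the lower half; non-contact cells blank."""
        cutoff = self.D if D is None else D
        m = self.size
        contact = self.contact(cutoff)
        width = 8
        lines = []
        header = " " * 4 + "".join(f"{self.labels[j]}{j + 1}".rjust(width) for j in range(m))
        lines.append(header)
        for i in range(m):
            cells = []
            for j in range(m):
                if i == j:
                    cells.append(f"{self.labels[i]}{i + 1}".rjust(width))
                elif not contact[i, j]:
                    cells.append(" " * width)
                elif i < j:  # angle half
                    cells.append(f"{self.angle[i, j]:7.1f} ".rjust(width))
                else:  # distance half
                    cells.append(f"{self.dist[i, j]:7.1f} ".rjust(width))
            lines.append(f"{self.labels[i]}{i + 1}".ljust(4) + "".join(cells))
        return "\n".join(lines)


@dataclass(frozen=True)
class PairEntry:
    partner: int  # 1-based partner SSE index j
    type_pair: str  # two-label code E_i E_j, e.g. "AB"
    omega: float
    dist: float


@dataclass
class PairRow:
    """Row i of the fold matrix as an ordered sequence of SSE pairs."""

    owner_index: int  # 1-based i
    entries: list[PairEntry]  # partners j != i, ascending j


def build_fold_matrix(sses: Sequence[SSEVector], D: float = 20.0) -> FoldMatrix:
    """Compute all pairwise interaxial angles and midpoint distances."""
    if len(sses) < 1:
        raise TooFewSSEsError("no SSEs to build a matrix from")
    order = [s.index for s in sses]
    if order != sorted(order):
        raise ValueError("SSEs must be given in sequence order")
    m = len(sses)
    angle = np.full((m, m), np.nan)
    dist = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            w = interaxial_angle(sses[i], sses[j])
            d = midpoint_distance(sses[i], sses[j])
            angle[i, j] = angle[j, i] = w
            dist[i, j] = dist[j, i] = d
    return FoldMatrix(labels=[s.sse_type for s in sses], angle=angle, dist=dist, D=D)


def build_pair_rows(fm: FoldMatrix) -> list[PairRow]:
    """One row per SSE: its pairs with every other element, ascending j."""
    m = fm.size
    if m < 2:
        raise TooFewSSEsError("too few SSEs to align (need at least 2)")
    rows = []
    for i in range(m):
        entries = [
            PairEntry(
                partner=j + 1,
                type_pair=fm.labels[i] + fm.labels[j],
                omega=float(fm.angle[i, j]),
                dist=float(fm.dist[i, j]),
            )
            for j in range(m)
            if j != i
        ]
        rows.append(PairRow(owner_index=i + 1, entries=entries))
    return rows


# ---------------------------------------------------------------------------
# directory-backed matrix database


class MatrixDB:
    """Directory of per-chain fold-matrix records plus a manifest.

    Records are plain-text JSON, one file per (structure file, chain) key;
    the angle/distance payload is independent of D, so searches may use any
    contact cutoff.
    """

    MANIFEST = "manifest.json"

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)

    def _manifest_path(self) -> Path:
        return self.directory / self.MANIFEST

    def _load_manifest(self) -> dict:
        path = self._manifest_path()
        if not path.exists():
            return {"records": {}}
        return json.loads(path.read_text())

    def add(self, key: str, fm: FoldMatrix, source: str = "", chain_id: str = "") -> None:
        self.directory.mkdir(parents=True, exist_ok=True)
        record_name = f"{_safe_name(key)}.json"
        (self.directory / record_name).write_text(json.dumps(fm.to_dict()))
        manifest = self._load_manifest()
        manifest["records"][key] = {
            "file": record_name,
            "source": source,
            "chain": chain_id,
            "n_sses": fm.size,
        }
        self._manifest_path().write_text(json.dumps(manifest, indent=1, sort_keys=True))

    def get(self, key: str) -> FoldMatrix:
        manifest = self._load_manifest()
        if key not in manifest["records"]:
            raise MatrixRecordError(f"unreadable matrix record: no record {key!r}")
        path = self.directory / manifest["records"][key]["file"]
        try:
            data = json.loads(path.read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise MatrixRecordError(f"unreadable matrix record: {exc}") from exc
        return FoldMatrix.from_dict(data)

    def keys(self) -> list[str]:
        return sorted(self._load_manifest()["records"])

    def __iter__(self) -> Iterator[tuple[str, FoldMatrix]]:
        keys = self.keys()
        if not keys:
            warnings.warn("matrix database is empty", stacklevel=2)
        for key in keys:
            yield key, self.get(key)

    def __len__(self) -> int:
        return len(self._load_manifest()["records"])


def _safe_name(key: str) -> str:
    return "".join(c if (c.isalnum() or c in "._-") else "_" for c in key)
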