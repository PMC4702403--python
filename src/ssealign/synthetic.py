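"""Idealized C-alpha trace generator for testing and demonstration.

Builds chains of ideal secondary-structure elements -- alpha helices
(1.5 A rise/residue, ~100 deg twist, 2.3 A radius) and near-linear
beta strands (~3.4 A rise, alternating 0.5 A pleat) -- joined by straight
coil linkers, together with the matching one-character assignment string.
Multi-domain "hinge" constructs pair such a chain with a copy whose second
(or later) segment is moved by a known rigid transformation, exporting the
ground-truth block partition and transforms for recovery tests.

These traces are geometric idealizations: no side chains, no sterics, no
realistic loop conformations.  They exercise the full pipeline (including
PDB file round-trips) with exactly known geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure import ChainModel, Residue

HELIX_RISE = 1.5  # A per residue along the axis
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # A
STRAND_RISE = 3.4  # A per residue
STRAND_PLEAT = 0.5  # A lateral alternation


def _frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic orthonormal frame with e3 = direction."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2, d


def _detrend_lateral(pts: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Remove the linear drift of the lateral offsets along the axis.

    An incomplete helical turn makes the circular offsets correlate with
    the axial coordinate, tilting a least-squares line fit away from the
    nominal axis (by many degrees for short elements).  Subtracting the
    regression of the lateral component on the axial coordinate makes the
    principal direction of the trace exactly the requested axis, at the
    price of a tiny shear of the ideal geometry.
    """
    z = pts @ d
    zc = z - z.mean()
    lateral = pts - np.outer(z, d)
    slope = (zc @ (lateral - lateral.mean(axis=0))) / (zc @ zc)
    return pts - np.outer(zc, slope)


def make_helix(
    n_residues: int,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    direction: Sequence[float] = (0.0, 0.0, 1.0),
    phase: float = 0.0,
) -> np.ndarray:
    """Idealized alpha-helix C-alpha trace whose axis runs along ``direction``."""
    if n_residues < 5:
        raise ValueError("a helix needs at least 5 residues")
    e1, e2, d = _frame(direction)
    origin = np.asarray(origin, dtype=float)
    pts = []
    for i in range(n_residues):
        ang = np.radians(phase + HELIX_TWIST * i)
        pts.append(
            origin
            + HELIX_RISE * i * d
            + HELIX_RADIUS * (np.cos(ang) * e1 + np.sin(ang) * e2)
        )
    return _detrend_lateral(np.array(pts), d)


def make_strand(
    n_residues: int,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    direction: Sequence[float] = (0.0, 0.0, 1.0),
) -> np.ndarray:
    """Near-linear pleated strand trace along ``direction``."""
    if n_residues < 4:
        raise ValueError("a strand needs at least 4 residues")
    e1, _e2, d = _frame(direction)
    origin = np.asarray(origin, dtype=float)
    pts = [
        origin + STRAND_RISE * i * d + STRAND_PLEAT * ((-1) ** i) * e1
        for i in range(n_residues)
    ]
    return _detrend_lateral(np.array(pts), d)


@dataclass(frozen=True)
class ElementSpec:
    """One secondary-structure element of a synthetic chain."""

    kind: str  # "H" (helix) or "E" (strand)
    length: int
    origin: tuple[float, float, float]
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)


@dataclass
class SyntheticChain:
    coords: np.ndarray
    labels: str  # internal alphabet H/E/C, one char per residue
    elements: list[ElementSpec]

    def to_chain_model(self, chain_id: str = "A") -> ChainModel:
        residues = [
            Residue(number=i + 1, icode="", ca=np.array(xyz))
            for i, xyz in enumerate(self.coords)
        ]
        return ChainModel(chain_id=chain_id, residues=residues)


def _element_points(spec: ElementSpec) -> np.ndarray:
    if spec.kind == "H":
        return make_helix(spec.length, spec.origin, spec.direction)
    if spec.kind == "E":
        return make_strand(spec.length, spec.origin, spec.direction)
    raise ValueError(f"unknown element kind {spec.kind!r}")


def _assemble(
    element_points: Sequence[tuple[str, np.ndarray]],
    elements: Sequence[ElementSpec],
    loop_length: int,
    noise_sigma: float,
    rng: np.random.Generator,
) -> SyntheticChain:
    """Join element traces N->C with straight coil linkers in between."""
    coords: list[np.ndarray] = []
    labels: list[str] = []
    prev_end: np.ndarray | None = None
    for kind, pts in element_points:
        if prev_end is not None and loop_length > 0:
            for k in range(1, loop_length + 1):
                frac = k / (loop_length + 1)
                coords.append(prev_end + frac * (pts[0] - prev_end))
                labels.append("C")
        coords.extend(pts)
        labels.extend(kind * len(pts))
        prev_end = pts[-1]
    arr = np.array(coords)
    if noise_sigma > 0:
        arr = arr + rng.normal(0.0, noise_sigma, size=arr.shape)
    return SyntheticChain(coords=arr, labels="".join(labels), elements=list(elements))


def build_chain(
    elements: Sequence[ElementSpec],
    loop_length: int = 3,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SyntheticChain:
    """Assemble elements N->C with straight coil linkers in between."""
    rng = np.random.default_rng(seed)
    pts = [(spec.kind, _element_points(spec)) for spec in elements]
    return _assemble(pts, elements, loop_length, noise_sigma, rng)


# ---------------------------------------------------------------------------
# multi-domain hinge constructs


def _rotation_z(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass
class HingeTruth:
    """Ground truth of a multi-segment construct: per-segment SSE index
    partition (1-based) and the rigid transform applied to each segment."""

    partition: list[list[int]]
    rotations: list[np.ndarray]
    translations: list[np.ndarray]


def _domain_specs(
    n_helices: int, x0: float, helix_len: int, spacing: float, tilt_step: float, tilt0: float
) -> list[ElementSpec]:
    specs = []
    for k in range(n_helices):
        tilt = np.radians(tilt0 + tilt_step * k)
        direction = (np.sin(tilt), 0.0, np.cos(tilt))
        specs.append(
            ElementSpec("H", helix_len + (k % 3), (x0 + spacing * k, 0.0, 0.0), direction)
        )
    return specs


def make_hinge_protein(
    hinge_rotation: float,
    n_helices_per_domain: int = 3,
    helix_len: int = 12,
    spacing: float = 6.0,
    pivot_offset: float = 34.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[SyntheticChain, SyntheticChain, HingeTruth]:
    """Two-domain construct and a copy with domain 2 rotated about a pivot.

    Both chains share domain 1; in the second chain, domain 2 is rotated by
    ``hinge_rotation`` degrees about a z-axis pivot offset beyond the
    domain (a rigid-body shift, as seen in hinge motions of two-lobed
    proteins).  Slightly distinct helix tilts break row-score ties so the
    identity-like alignment is unique.  Returns (query, target, truth).
    """
    nd = n_helices_per_domain
    dom1 = _domain_specs(nd, 0.0, helix_len, spacing, 4.0, 0.0)
    dom2_x0 = spacing * nd  # domain 2 starts one spacing beyond domain 1
    dom2 = _domain_specs(nd, dom2_x0, helix_len, spacing, 4.0, 4.0 * nd)
    specs = dom1 + dom2
    pts = [(s.kind, _element_points(s)) for s in specs]
    rng = np.random.default_rng(seed)
    query = _assemble(pts, specs, 3, noise_sigma, rng)

    pivot = np.array([dom2_x0 + spacing * (nd - 1) + pivot_offset, 0.0, 0.0])
    R = _rotation_z(hinge_rotation)
    t = pivot - R @ pivot
    moved = [
        (kind, p if k < nd else p @ R.T + t)
        for k, (kind, p) in enumerate(pts)
    ]
    target = _assemble(moved, specs, 3, noise_sigma, rng)

    truth = HingeTruth(
        partition=[list(range(1, nd + 1)), list(range(nd + 1, 2 * nd + 1))],
        rotations=[np.eye(3), R],
        translations=[np.zeros(3), t],
    )
    return query, target, truth


def make_multi_segment_protein(
    rotations: Sequence[float] = (0.0, 60.0, -60.0),
    translations: Sequence[Sequence[float]] = ((0, 0, 0), (0, 35, 0), (0, -35, 0)),
    n_helices_per_segment: int = 3,
    helix_len: int = 12,
    spacing: float = 6.0,
    seed: int = 0,
) -> tuple[SyntheticChain, SyntheticChain, HingeTruth]:
    """Chain of several segments, each given its own rigid transform.

    Segment k of the target copy is rotated by ``rotations[k]`` degrees
    about the z-axis through its own centroid and then shifted by
    ``translations[k]``; segment boundaries become hinge points.
    """
    n_seg = len(rotations)
    nd = n_helices_per_segment
    segments = [
        _domain_specs(nd, spacing * nd * s, helix_len, spacing, 4.0, 4.0 * nd * s)
        for s in range(n_seg)
    ]
    specs = [e for seg in segments for e in seg]
    pts = [(spec.kind, _element_points(spec)) for spec in specs]
    rng = np.random.default_rng(seed)
    query = _assemble(pts, specs, 3, 0.0, rng)

    moved: list[tuple[str, np.ndarray]] = []
    rots, trans = [], []
    partition = []
    for s, seg in enumerate(segments):
        centroid = np.mean([np.array(e.origin) for e in seg], axis=0)
        R = _rotation_z(float(rotations[s]))
        t_full = centroid - R @ centroid + np.asarray(translations[s], dtype=float)
        for kind, p in pts[nd * s : nd * (s + 1)]:
            moved.append((kind, p @ R.T + t_full))
        rots.append(R)
        trans.append(t_full)
        partition.append(list(range(nd * s + 1, nd * (s + 1) + 1)))
    target = _assemble(moved, specs, 3, 0.0, rng)
    truth = HingeTruth(partition=partition, rotations=rots, translations=trans)
    return query, target, truth


# ---------------------------------------------------------------------------
# standard single-domain fixtures and PDB export


def helix_bundle(n: int = 4, seed: int = 0) -> SyntheticChain:
    """Bundle of ``n`` slightly tilted parallel helices, 6 A apart."""
    return build_chain(_domain_specs(n, 0.0, 12, 6.0, 4.0, 0.0), seed=seed)


def strand_sheet(n: int = 4, seed: int = 0) -> SyntheticChain:
    """Flat sheet of ``n`` parallel strands, 4.8 A apart."""
    specs = [ElementSpec("E", 6 + (k % 2), (4.8 * k, 0.0, 0.0)) for k in range(n)]
    return build_chain(specs, seed=seed)


def mixed_fold(seed: int = 0) -> SyntheticChain:
    """Small alpha/beta fold: strand-helix-strand-helix."""
    specs = [
        ElementSpec("E", 6, (0.0, 0.0, 0.0)),
        ElementSpec("H", 12, (6.0, 0.0, 0.0), (0.10, 0.0, 0.995)),
        ElementSpec("E", 7, (12.0, 0.0, 0.0)),
        ElementSpec("H", 13, (18.0, 0.0, 0.0), (-0.10, 0.0, 0.995)),
    ]
    return build_chain(specs, seed=seed)


def write_pdb(chain: SyntheticChain | ChainModel, path: str | Path, chain_id: str = "A") -> Path:
    """Write a minimal CA-only PDB file for the given trace."""
    if isinstance(chain, SyntheticChain):
        model = chain.to_chain_model(chain_id)
    else:
        model = chain
    lines = []
    for serial, res in enumerate(model.residues, start=1):
        x, y, z = res.ca
        lines.append(
            f"ATOM  {serial:5d}  CA  ALA {model.chain_id:1s}{res.number:4d}"
            f"{(res.icode or ' '):1s}   {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"           C  "
        )
    lines.append("END")
    p = Path(path)
    p.write_text("\n".join(lines) + "\n")
    return p
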