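"""Aromatic-ring extraction and the (α, β, d) pair descriptors.

For a pair of aromatic side chains the package characterises the mutual
arrangement with three numbers:

α
    The interplanar dihedral, measured with a *position-dependent* half-plane
    convention.  Let L be the intersection line of the two ring planes and
    w_k the in-plane unit vector pointing from L toward ring k's center.  Then
    α = angle(w1, w2) ∈ [0°, 180°].  Unlike the plain angle between normals
    θ = arccos|n1·n2| ∈ [0°, 90°], α distinguishes acute from obtuse
    arrangements: it always equals θ or 180° − θ, depending on which side of L
    the centers lie.
β
    The angle between the two guiding vectors (ring center → Cγ, i.e. toward
    the stem connecting ring and backbone) after orthogonal projection onto
    the central plane.  β ≈ 0° is a cis arrangement, β ≈ 180° trans.
d
    The shift: the distance between the projections of the two ring centers
    onto the central plane.  For parallel rings this is the lateral offset
    (0 for a perfectly stacked pair).

The *central plane* is the plane through L and the midpoint of the two ring
centers; for (near-)parallel rings it degenerates to the mid-plane.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .pdb_io import Structure

__all__ = [
    "RING_ATOMS",
    "AromaticRing",
    "PairGeometry",
    "extract_rings",
    "fit_plane",
    "dihedral_alpha",
    "central_plane",
    "beta_angle",
    "shift_d",
    "pair_geometry",
]

log = logging.getLogger(__name__)

#: Heavy atoms defining the aromatic ring plane per residue type.  For Trp the
#: whole (planar) indole system is fitted.
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

#: RMS out-of-plane deviation (Å) above which a ring is rejected as distorted.
MAX_RING_RMS = 0.25

_PARALLEL_SIN = 1e-6  # sin θ below which planes are treated as parallel
_PROJ_EPS = 1e-9  # squared-norm floor for projected guide vectors


@dataclass(frozen=True)
class AromaticRing:
    """One aromatic side group: fitted plane, guiding vector and stem atoms."""

    residue_ref: tuple[str, int, str]  # (chain_id, seq_index, residue_name)
    ring_atoms: dict[str, np.ndarray]
    center: np.ndarray
    normal: np.ndarray  # unit; sign arbitrary
    guide: np.ndarray  # unit, center -> CG
    cbeta: np.ndarray
    cgamma: np.ndarray
    auth_seqid: str = ""

    @property
    def chain_id(self) -> str:
        return self.residue_ref[0]

    @property
    def seq_index(self) -> int:
        return self.residue_ref[1]

    @property
    def residue_name(self) -> str:
        return self.residue_ref[2]


@dataclass(frozen=True)
class PairGeometry:
    """The descriptor triple (α, β, d) plus center distance and class label."""

    alpha: float  # degrees in [0, 180]
    beta: float  # degrees in [0, 180]; NaN when undefined
    d: float  # Å
    center_distance: float  # Å
    orientation_class: str


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def fit_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through ≥3 non-collinear points.

    Returns (centroid, unit normal); the normal minimises the sum of squared
    out-of-plane distances (smallest principal axis of the point cloud).  Its
    sign is unspecified — all downstream constructions are sign-independent.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3 or coords.shape[1] != 3:
        raise ValueError("need >= 3 points in 3-D")
    center = coords.mean(axis=0)
    _, s, vt = np.linalg.svd(coords - center)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("points are collinear or coincident; plane undefined")
    return center, vt[2]


def _make_ring(
    chain_id: str, seq_index: int, name: str, auth_seqid: str, atoms: dict[str, np.ndarray]
) -> AromaticRing | None:
    required = RING_ATOMS[name]
    missing = [a for a in (*required, "CB", "CG") if a not in atoms]
    if missing:
        log.warning(
            "skipping %s %s%s: missing atoms %s", name, chain_id, auth_seqid, missing
        )
        return None
    coords = np.array([atoms[a] for a in required])
    center, normal = fit_plane(coords)
    resid = coords - center
    rms = math.sqrt(float(np.mean((resid @ normal) ** 2)))
    if rms > MAX_RING_RMS:
        log.warning(
            "skipping %s %s%s: ring RMS out-of-plane %.3f Å > %.2f Å",
            name, chain_id, auth_seqid, rms, MAX_RING_RMS,
        )
        return None
    guide = _unit(atoms["CG"] - center)
    tilt = math.degrees(math.acos(min(1.0, abs(float(guide @ normal)))))
    if tilt < 65.0:  # guide should be near-orthogonal to the normal
        log.warning(
            "%s %s%s: guiding vector only %.0f deg from ring plane normal",
            name, chain_id, auth_seqid, 90.0 - tilt,
        )
    return AromaticRing(
        residue_ref=(chain_id, seq_index, name),
        ring_atoms={a: atoms[a].copy() for a in required},
        center=center,
        normal=normal,
        guide=guide,
        cbeta=atoms["CB"].copy(),
        cgamma=atoms["CG"].copy(),
        auth_seqid=auth_seqid,
    )


def extract_rings(structure: Structure) -> list[AromaticRing]:
    """One ring per Phe/Tyr/Trp/His residue with a complete atom set.

    Residues missing any required ring atom or CB/CG, or with a distorted
    (non-planar) ring, are skipped with a logged warning.
    """
    rings: list[AromaticRing] = []
    for chain in structure.chains:
        for res in chain.residues:
            if res.name not in RING_ATOMS:
                continue
            ring = _make_ring(
                chain.chain_id, res.seq_index, res.name, res.auth_seqid, res.atoms
            )
            if ring is not None:
                rings.append(ring)
    return rings


def _plane_intersection(
    n1: np.ndarray, c1: np.ndarray, n2: np.ndarray, c2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Line of intersection of the planes (n1, c1) and (n2, c2): (point, unit dir)."""
    u = _unit(np.cross(n1, n2))
    d1 = float(n1 @ c1)
    d2 = float(n2 @ c2)
    c = float(n1 @ n2)
    denom = 1.0 - c * c
    p0 = ((d1 - d2 * c) * n1 + (d2 - d1 * c) * n2) / denom
    return p0, u


def _foot_offset(p0: np.ndarray, u: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Vector from the point of the line (p0, u) nearest to x, toward x."""
    return x - (p0 + float((x - p0) @ u) * u)


def dihedral_alpha(ring1: AromaticRing, ring2: AromaticRing) -> float:
    """Position-dependent interplanar dihedral α in degrees, [0, 180].

    Symmetric in its arguments; always equals θ or 180° − θ where
    θ = arccos|n1·n2|.  Near-parallel planes (sin θ < 1e-6) and the degenerate
    case of a center lying on the intersection line fall back to θ.
    """
    n1, n2 = ring1.normal, ring2.normal
    cos_t = min(1.0, abs(float(n1 @ n2)))
    theta = math.degrees(math.acos(cos_t))
    if math.sqrt(max(0.0, 1.0 - cos_t * cos_t)) < _PARALLEL_SIN:
        return theta
    p0, u = _plane_intersection(n1, ring1.center, n2, ring2.center)
    w1 = _foot_offset(p0, u, ring1.center)
    w2 = _foot_offset(p0, u, ring2.center)
    nrm1, nrm2 = np.linalg.norm(w1), np.linalg.norm(w2)
    if nrm1 < 1e-6 or nrm2 < 1e-6:
        log.debug("ring center on the intersection line; falling back to plane angle")
        return theta
    cos_a = float(np.clip(w1 @ w2 / (nrm1 * nrm2), -1.0, 1.0))
    return math.degrees(math.acos(cos_a))


def central_plane(
    ring1: AromaticRing, ring2: AromaticRing
) -> tuple[np.ndarray, np.ndarray]:
    """The central plane (point, unit normal).

    Non-parallel case: the plane containing the intersection line L of the two
    ring planes and the midpoint M of the centers.  Parallel case: the plane
    through M with normal n1.  If M lies on L, the plane spanned by L and the
    dihedral bisector direction is used (logged fallback).
    """
    n1, n2 = ring1.normal, ring2.normal
    c1, c2 = ring1.center, ring2.center
    M = 0.5 * (c1 + c2)
    cos_t = abs(float(n1 @ n2))
    if math.sqrt(max(0.0, 1.0 - cos_t * cos_t)) < _PARALLEL_SIN:
        return M, n1.copy()
    p0, u = _plane_intersection(n1, c1, n2, c2)
    t = _foot_offset(p0, u, M)
    nt = np.linalg.norm(t)
    if nt < 1e-6:
        log.debug("midpoint on the intersection line; using dihedral bisector")
        w1 = _foot_offset(p0, u, c1)
        w2 = _foot_offset(p0, u, c2)
        b = _unit(w1) + _unit(w2)
        if np.linalg.norm(b) < 1e-9:
            b = _unit(w1) - _unit(w2)
        t = b
        nt = np.linalg.norm(t)
    normal = _unit(np.cross(u, t / nt))
    return M, normal


def beta_angle(ring1: AromaticRing, ring2: AromaticRing) -> float:
    """Angle (degrees, [0, 180]) between the guiding vectors projected onto the
    central plane; 0 ↔ cis, 180 ↔ trans.  NaN if a guide is parallel to the
    central-plane normal (projection vanishes)."""
    _, N = central_plane(ring1, ring2)
    p1 = ring1.guide - float(ring1.guide @ N) * N
    p2 = ring2.guide - float(ring2.guide @ N) * N
    n1, n2 = np.linalg.norm(p1), np.linalg.norm(p2)
    if n1 < _PROJ_EPS or n2 < _PROJ_EPS:
        return float("nan")
    cos_b = float(np.clip(p1 @ p2 / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(cos_b))


def shift_d(ring1: AromaticRing, ring2: AromaticRing) -> float:
    """Shift d (Å): distance between the centers' orthogonal projections onto
    the central plane.  Never exceeds the center–center distance."""
    _, N = central_plane(ring1, ring2)
    delta = ring2.center - ring1.center
    proj = delta - float(delta @ N) * N
    return float(np.linalg.norm(proj))


def pair_geometry(ring1: AromaticRing, ring2: AromaticRing) -> PairGeometry:
    """Bundle (α, β, d), the center distance and the orientation class."""
    from .contact_analysis import classify_alpha  # avoid a module cycle

    alpha = dihedral_alpha(ring1, ring2)
    return PairGeometry(
        alpha=alpha,
        beta=beta_angle(ring1, ring2),
        d=shift_d(ring1, ring2),
        center_distance=float(np.linalg.norm(ring2.center - ring1.center)),
        orientation_class=classify_alpha(alpha),
    )


def transform_ring(ring: AromaticRing, R: np.ndarray, t: np.ndarray) -> AromaticRing:
    """Apply the rigid motion x ↦ R·x + t to every coordinate of the ring."""
    R = np.asarray(R, dtype=float)
    t = np.asarray(t, dtype=float)
    return AromaticRing(
        residue_ref=ring.residue_ref,
        ring_atoms={k: R @ v + t for k, v in ring.ring_atoms.items()},
        center=R @ ring.center + t,
        normal=R @ ring.normal,
        guide=R @ ring.guide,
        cbeta=R @ ring.cbeta + t,
        cgamma=R @ ring.cgamma + t,
        auth_seqid=ring.auth_seqid,
    )
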