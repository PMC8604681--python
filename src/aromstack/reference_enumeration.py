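"""Featureless reference distribution for aromatic ring pairs.

The reference (null) distribution answers: if two phenylalanine side groups
are placed in contact with *no* interaction beyond hard-sphere sterics, how
often does each mutual orientation occur?  It is built by exhaustive
enumeration: ring 1 is an ideal Phe side group centered at the origin in the
z = 0 plane; ring 2 is the same template rotated by a matrix ``m`` and shifted
by a vector ``v``.  Rotations come either from a sifted Euler-angle grid
(quasi-uniform over SO(3)) or from exactly-uniform random sampling; shifts run
over a cubic lattice strictly inside the 7 Å contact sphere.  A steric ball
model (side-chain atoms 1.75 Å, a single 3 Å backbone ball 3 Å beyond Cβ on
the Cγ–Cβ line) optionally rejects clashing conformations.

Under exactly-uniform rotations the plain interplanar angle θ has density
sin θ on [0°, 90°], so the parallel class has probability 1 − cos 15° ≈ 3.4%
and the perpendicular class cos 75° ≈ 25.9%; the position-dependent dihedral
α redistributes each θ between the acute (α = θ) and obtuse (α = 180° − θ)
branches according to where the ring centers fall relative to the plane
intersection line.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .ring_geometry import AromaticRing, transform_ring

__all__ = [
    "BallModel",
    "RotationSet",
    "TranslationGrid",
    "ReferenceHistogram",
    "sphere_points",
    "euler_rotation_grid",
    "sift_rotations",
    "random_rotations",
    "load_rotation_matrices",
    "translation_grid",
    "template_phe",
    "place_pair",
    "overlap_test",
    "enumerate_reference",
    "enumerate_histograms",
    "bin_fractions",
    "overlap_allowed_total",
]

ALPHA_EDGES = np.array([15.0, 45.0, 75.0, 105.0, 135.0, 165.0])
CLASS_LABELS = ("parallel", "15-45", "45-75", "perpendicular", "105-135", "135-165")

_EZ = np.array([0.0, 0.0, 1.0])
_EX = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class BallModel:
    """Steric model: every side-chain atom is a 1.75 Å ball; the whole backbone
    is one 3 Å ball centered on the Cγ–Cβ line, 3 Å beyond Cβ (away from the
    ring).  Overlap of any inter-residue ball pair forbids a conformation."""

    side_chain_radius: float = 1.75
    backbone_radius: float = 3.0
    backbone_offset: float = 3.0

    def __post_init__(self) -> None:
        if min(self.side_chain_radius, self.backbone_radius, self.backbone_offset) <= 0:
            raise ValueError("ball-model parameters must be positive")

    def balls(self, ring: AromaticRing) -> tuple[np.ndarray, np.ndarray]:
        """(centers (k,3), radii (k,)) for one residue."""
        side = list(ring.ring_atoms.values()) + [ring.cbeta]
        stem = ring.cbeta - ring.cgamma
        backbone = ring.cbeta + self.backbone_offset * stem / np.linalg.norm(stem)
        centers = np.vstack([side, backbone[None, :]])
        radii = np.full(len(centers), self.side_chain_radius)
        radii[-1] = self.backbone_radius
        return centers, radii


@dataclass
class RotationSet:
    """A collection of proper rotation matrices with provenance."""

    matrices: np.ndarray  # (n, 3, 3)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.matrices
        if m.ndim != 3 or m.shape[1:] != (3, 3):
            raise ValueError("matrices must have shape (n, 3, 3)")

    def __len__(self) -> int:
        return len(self.matrices)

    def validate(self, tol: float = 1e-9) -> None:
        m = self.matrices
        eye = np.eye(3)
        if not np.allclose(m @ m.transpose(0, 2, 1), eye, atol=tol):
            raise ValueError("non-orthonormal matrix in rotation set")
        if not np.allclose(np.linalg.det(m), 1.0, atol=tol):
            raise ValueError("rotation set contains an improper rotation")


@dataclass
class TranslationGrid:
    """Lattice of shift vectors, components integer multiples of ``step``,
    all strictly inside the ``rmax`` sphere."""

    vectors: np.ndarray  # (n, 3)
    step: float
    rmax: float

    def __len__(self) -> int:
        return len(self.vectors)


@dataclass
class ReferenceHistogram:
    """Binned α counts per orientation class over enumerated conformations."""

    class_counts: dict[str, int]
    total: int
    overlap_filtered: bool
    provenance: dict = field(default_factory=dict)
    beta_counts: np.ndarray | None = None  # 10° bins on [0, 180]
    d_counts: np.ndarray | None = None  # 0.5 Å bins on [0, 14)

    def __post_init__(self) -> None:
        if sum(self.class_counts.values()) != self.total:
            raise ValueError("class counts do not sum to total")


def sphere_points(spacing_deg: float) -> np.ndarray:
    """Quasi-uniform unit vectors (Fibonacci spiral) at a requested angular
    spacing: the point count is 4π / spacing² (in radians), so the median
    nearest-neighbour angle tracks ``spacing_deg``.

    2.5° spacing yields ≈ 6 600 points.
    """
    if not 0 < spacing_deg <= 180:
        raise ValueError("spacing must be in (0, 180] degrees")
    s = math.radians(spacing_deg)
    n = int(round(4.0 * math.pi / (s * s)))
    n = max(n, 8)  # floor keeps even the coarsest request covering all axes
    if n > 10_000_000:
        raise ValueError(f"spacing {spacing_deg} deg would allocate {n} points")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _rx(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _ry(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rz(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def euler_rotation_grid(step_deg: float) -> Iterator[np.ndarray]:
    """All products Rz(c)·Ry(b)·Rx(a), a, b, c ∈ {0, step, …, 360 − step}.

    Yields (360/step)³ matrices; deliberately *uneven* over SO(3) — the sift
    step thins it to a quasi-uniform set.
    """
    if not (360.0 / step_deg).is_integer():
        raise ValueError("step must divide 360")
    k = int(360.0 / step_deg)
    angles = [math.radians(step_deg * i) for i in range(k)]
    rxs = [_rx(a) for a in angles]
    rys = [_ry(a) for a in angles]
    rzs = [_rz(a) for a in angles]
    for c, b, a in itertools.product(range(k), range(k), range(k)):
        yield rzs[c] @ rys[b] @ rxs[a]


def sift_rotations(
    grid: Iterable[np.ndarray],
    points: np.ndarray,
    chunk: int = 8192,
    provenance: dict | None = None,
) -> RotationSet:
    """Thin a rotation stream to quasi-uniform density.

    Each matrix is keyed by the nearest sphere point to each of its three axis
    images (the matrix columns); among matrices sharing a key, the one with
    the smallest summed distance D to its key points is kept (ties: first
    encountered).
    """
    tree = cKDTree(points)
    best: dict[tuple[int, int, int], tuple[float, np.ndarray]] = {}
    buf: list[np.ndarray] = []

    def flush() -> None:
        if not buf:
            return
        mats = np.array(buf)
        axes = mats.transpose(0, 2, 1).reshape(-1, 3)  # columns x,y,z per matrix
        dists, idx = tree.query(axes)
        dists = dists.reshape(-1, 3)
        idx = idx.reshape(-1, 3)
        D = np.sqrt((dists**2).sum(axis=1))
        for m, key, dd in zip(mats, map(tuple, idx), D):
            cur = best.get(key)
            if cur is None or dd < cur[0]:
                best[key] = (float(dd), m)
        buf.clear()

    for m in grid:
        buf.append(m)
        if len(buf) >= chunk:
            flush()
    flush()
    matrices = np.array([m for _, m in best.values()])
    return RotationSet(matrices=matrices, provenance=provenance or {"sifted": True})


def random_rotations(n: int, seed: int | np.random.Generator = 0) -> RotationSet:
    """Exactly-uniform random rotations (normalized Gaussian quaternions)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return RotationSet(
        matrices=Rotation.from_quat(q).as_matrix(),
        provenance={"mode": "uniform-random", "n": n},
    )


def load_rotation_matrices(path: str) -> RotationSet:
    """Read an external rotation list: nine whitespace-separated numbers per
    line (row-major 3×3)."""
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] != 9:
        raise ValueError("expected 9 numbers per line")
    return RotationSet(
        matrices=data.reshape(-1, 3, 3), provenance={"source": str(path)}
    )


def translation_grid(step: float = 0.5, rmax: float = 7.0) -> TranslationGrid:
    """All lattice vectors step·(i, j, k) with |v| < rmax strictly."""
    if not 0 < step <= rmax:
        raise ValueError("require 0 < step <= rmax")
    m = int(math.floor(rmax / step))
    ax = step * np.arange(-m, m + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    V = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    V = V[(V**2).sum(axis=1) < rmax * rmax]
    return TranslationGrid(vectors=V, step=step, rmax=rmax)


# --- Phe template -----------------------------------------------------------

RING_BOND = 1.39  # Å, aromatic C–C; also the hexagon circumradius
CG_CB_BOND = 1.52  # Å


def template_phe() -> AromaticRing:
    """Ideal phenylalanine side group: regular hexagon (C–C 1.39 Å) in the
    z = 0 plane, centroid at the origin, CG on +x; CB 1.52 Å beyond CG on the
    same line."""
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    ang = np.radians(60.0 * np.arange(6))
    coords = RING_BOND * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])
    atoms = {n: c for n, c in zip(names, coords)}
    cg = atoms["CG"]
    cb = cg + np.array([CG_CB_BOND, 0.0, 0.0])
    return AromaticRing(
        residue_ref=("_", 0, "PHE"),
        ring_atoms=atoms,
        center=np.zeros(3),
        normal=_EZ.copy(),
        guide=_EX.copy(),
        cbeta=cb,
        cgamma=cg.copy(),
    )


def place_pair(m: np.ndarray, v: np.ndarray) -> tuple[AromaticRing, AromaticRing]:
    """Ring 1 = template at the origin; ring 2 = template rotated by ``m``
    about the origin, then shifted by ``v``.  The center distance equals |v|."""
    t = template_phe()
    return t, transform_ring(t, np.asarray(m, float), np.asarray(v, float))


def overlap_test(
    pair: tuple[AromaticRing, AromaticRing], model: BallModel | None = None
) -> bool:
    """True iff any inter-residue ball pair overlaps (distance strictly below
    the radius sum).  Intra-residue contacts are ignored."""
    model = model or BallModel()
    c1, r1 = model.balls(pair[0])
    c2, r2 = model.balls(pair[1])
    d2 = ((c1[:, None, :] - c2[None, :, :]) ** 2).sum(axis=2)
    return bool((d2 < (r1[:, None] + r2[None, :]) ** 2).any())


# --- vectorized per-rotation kernels ---------------------------------------


def _alphas_for_rotation(R: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Position-dependent dihedral α (degrees) of the template pair (R, v)
    for every translation v in V, with ring 1 fixed in z = 0 at the origin."""
    n2 = R[:, 2]
    c = float(n2[2])  # n1·n2 with n1 = e_z
    sin2 = 1.0 - c * c
    theta = math.degrees(math.acos(min(1.0, abs(c))))
    if sin2 < 1e-12:
        return np.full(len(V), theta)
    u = np.cross(_EZ, n2)
    u /= np.linalg.norm(u)
    A = (n2 - c * _EZ) / sin2
    P0 = (V @ n2)[:, None] * A  # nearest solution point of both plane equations
    w1 = -(P0 - (P0 @ u)[:, None] * u)  # from line toward c1 = 0
    Vp = V - P0
    w2 = Vp - (Vp @ u)[:, None] * u  # from line toward c2 = v
    nw1 = np.linalg.norm(w1, axis=1)
    nw2 = np.linalg.norm(w2, axis=1)
    denom = nw1 * nw2
    ok = denom > 1e-12
    cos_a = np.full(len(V), np.cos(np.radians(theta)))
    cos_a[ok] = (w1[ok] * w2[ok]).sum(axis=1) / denom[ok]
    alpha = np.degrees(np.arccos(np.clip(cos_a, -1.0, 1.0)))
    alpha[(nw1 < 1e-6) | (nw2 < 1e-6)] = theta  # center on the line: fall back
    return alpha


def _overlaps_for_rotation(
    R: np.ndarray,
    V: np.ndarray,
    balls: np.ndarray,
    radii: np.ndarray,
) -> np.ndarray:
    """Boolean overlap mask over translations for the template pair."""
    balls2 = balls @ R.T
    diff0 = balls2[None, :, :] - balls[:, None, :]  # (k, k, 3)
    rsum2 = (radii[:, None] + radii[None, :]) ** 2
    d2 = ((diff0[None, :, :, :] + V[:, None, None, :]) ** 2).sum(axis=3)
    return (d2 < rsum2[None, :, :]).any(axis=(1, 2))


def _class_counts(alpha: np.ndarray) -> np.ndarray:
    """Counts per orientation class (parallel folds the two outer α ranges)."""
    idx = np.searchsorted(ALPHA_EDGES, alpha, side="right")
    c7 = np.bincount(idx, minlength=7)
    return np.array([c7[0] + c7[6], c7[1], c7[2], c7[3], c7[4], c7[5]])


def _betas_ds_for_rotation(
    R: np.ndarray, V: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """β (degrees; NaN when undefined) and shift d (Å) for every translation."""
    n2 = R[:, 2]
    g2 = R[:, 0]
    c = float(n2[2])
    sin2 = 1.0 - c * c
    n = len(V)
    if sin2 < 1e-12:
        N = np.tile(_EZ, (n, 1))
    else:
        u = np.cross(_EZ, n2)
        u /= np.linalg.norm(u)
        A = (n2 - c * _EZ) / sin2
        P0 = (V @ n2)[:, None] * A
        M = 0.5 * V
        Mp = M - P0
        t = Mp - (Mp @ u)[:, None] * u
        nt = np.linalg.norm(t, axis=1)
        deg = nt < 1e-6
        if deg.any():  # midpoint on the line: use the dihedral bisector
            w1 = -(P0[deg] - (P0[deg] @ u)[:, None] * u)
            Vp = V[deg] - P0[deg]
            w2 = Vp - (Vp @ u)[:, None] * u
            b = w1 / np.maximum(np.linalg.norm(w1, axis=1), 1e-12)[:, None] + w2 / np.maximum(
                np.linalg.norm(w2, axis=1), 1e-12
            )[:, None]
            t[deg] = b
            nt = np.linalg.norm(t, axis=1)
        N = np.cross(np.broadcast_to(u, (n, 3)), t / np.maximum(nt, 1e-12)[:, None])
        N /= np.maximum(np.linalg.norm(N, axis=1), 1e-12)[:, None]
    p1 = _EX[None, :] - (N @ _EX)[:, None] * N
    p2 = g2[None, :] - (N @ g2)[:, None] * N
    n1n = np.linalg.norm(p1, axis=1)
    n2n = np.linalg.norm(p2, axis=1)
    beta = np.full(n, np.nan)
    ok = (n1n > 1e-9) & (n2n > 1e-9)
    cos_b = (p1[ok] * p2[ok]).sum(axis=1) / (n1n[ok] * n2n[ok])
    beta[ok] = np.degrees(np.arccos(np.clip(cos_b, -1.0, 1.0)))
    proj = V - (V * N).sum(axis=1)[:, None] * N
    d = np.linalg.norm(proj, axis=1)
    return beta, d


# --- enumeration ------------------------------------------------------------

BETA_BIN_EDGES = np.arange(0.0, 180.0 + 10.0, 10.0)
D_BIN_EDGES = np.arange(0.0, 14.0 + 0.5, 0.5)


def enumerate_histograms(
    rotations: RotationSet,
    grid: TranslationGrid,
    model: BallModel | None = None,
) -> tuple[ReferenceHistogram, ReferenceHistogram]:
    """One pass over all (m, v): returns (overlap-allowed, non-overlap)
    α histograms.  The second counts only conformations whose steric balls do
    not clash."""
    if len(rotations) == 0:
        raise ValueError("empty rotation set")
    model = model or BallModel()
    t = template_phe()
    balls, radii = model.balls(t)
    V = grid.vectors
    counts_all = np.zeros(6, dtype=np.int64)
    counts_keep = np.zeros(6, dtype=np.int64)
    n_keep = 0
    for R in rotations.matrices:
        alpha = _alphas_for_rotation(R, V)
        counts_all += _class_counts(alpha)
        ov = _overlaps_for_rotation(R, V, balls, radii)
        kept = alpha[~ov]
        counts_keep += _class_counts(kept)
        n_keep += len(kept)
    prov = {
        "n_rotations": len(rotations),
        "n_translations": len(V),
        "grid_step": grid.step,
        "rmax": grid.rmax,
        **rotations.provenance,
    }
    hist_all = ReferenceHistogram(
        class_counts=dict(zip(CLASS_LABELS, counts_all.tolist())),
        total=int(len(rotations) * len(V)),
        overlap_filtered=False,
        provenance=prov,
    )
    hist_keep = ReferenceHistogram(
        class_counts=dict(zip(CLASS_LABELS, counts_keep.tolist())),
        total=int(n_keep),
        overlap_filtered=True,
        provenance=prov,
    )
    return hist_all, hist_keep


def enumerate_reference(
    rotations: RotationSet,
    grid: TranslationGrid,
    filter_overlap: bool = False,
    model: BallModel | None = None,
    collect_beta_d: bool = False,
) -> ReferenceHistogram:
    """Enumerate every (rotation, translation) conformation of the template
    pair and bin the dihedral α into the six orientation classes; optionally
    reject steric overlaps and collect β / d histograms.

    Deterministic given its inputs.
    """
    if len(rotations) == 0:
        raise ValueError("empty rotation set")
    model = model or BallModel()
    t = template_phe()
    balls, radii = model.balls(t)
    V = grid.vectors
    counts = np.zeros(6, dtype=np.int64)
    total = 0
    beta_counts = np.zeros(len(BETA_BIN_EDGES) - 1, dtype=np.int64)
    d_counts = np.zeros(len(D_BIN_EDGES) - 1, dtype=np.int64)
    for R in rotations.matrices:
        alpha = _alphas_for_rotation(R, V)
        if filter_overlap:
            keep = ~_overlaps_for_rotation(R, V, balls, radii)
            alpha = alpha[keep]
        counts += _class_counts(alpha)
        total += len(alpha)
        if collect_beta_d:
            beta, d = _betas_ds_for_rotation(R, V)
            if filter_overlap:
                beta, d = beta[keep], d[keep]
            beta_counts += np.histogram(beta[~np.isnan(beta)], bins=BETA_BIN_EDGES)[0]
            d_counts += np.histogram(d, bins=D_BIN_EDGES)[0]
    return ReferenceHistogram(
        class_counts=dict(zip(CLASS_LABELS, counts.tolist())),
        total=int(total),
        overlap_filtered=filter_overlap,
        provenance={
            "n_rotations": len(rotations),
            "n_translations": len(V),
            "grid_step": grid.step,
            "rmax": grid.rmax,
            **rotations.provenance,
        },
        beta_counts=beta_counts if collect_beta_d else None,
        d_counts=d_counts if collect_beta_d else None,
    )


def bin_fractions(hist: ReferenceHistogram) -> dict[str, float]:
    """Per-class fractions of the histogram total (sum exactly 1)."""
    if hist.total <= 0:
        raise ValueError("histogram is empty")
    return {k: v / hist.total for k, v in hist.class_counts.items()}


def overlap_allowed_total(n_rotations: int, grid: TranslationGrid) -> int:
    """Overlap-allowed conformation count without iteration: every rotation is
    paired with every grid vector."""
    return int(n_rotations) * len(grid)
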