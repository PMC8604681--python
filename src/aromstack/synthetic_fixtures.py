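"""Synthetic inputs with known ground truth.

Three generators cover the package's input formats:

* :func:`make_pair_structure` — a two-phenylalanine PDB "structure" built by
  the rotate-then-translate construction: ring 2 is the ideal template rotated
  about the Y axis by α₀, then shifted by (Δx, Δy, h).  The closed-form rule
  :func:`expected_pair_alpha` gives the exact dihedral the analysis must
  recover: α = α₀ on one side of the switching boundary Δx = −h·cot α₀ and
  180° − α₀ on the other.
* :func:`random_structure` — aromatic residues of random type, position and
  orientation in a box (each in its own chain, so every pair is
  contact-eligible and a brute-force distance count is the oracle).
* :func:`identity_fixture` — a block-structured pairwise alignment table with
  a planted partition for the clustering module.

Fixture PDB files use a minimal legal subset of the format; backbone atoms
are placed crudely since only CB/CG and ring atoms matter downstream.  No
attempt is made to mimic realistic protein packing.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pdb_io import Chain, Residue, Structure, StructureMeta, write_structure
from .reference_enumeration import _ry, _rz, template_phe

__all__ = [
    "PairSpec",
    "expected_pair_alpha",
    "make_pair_structure",
    "random_structure",
    "identity_fixture",
]


@dataclass(frozen=True)
class PairSpec:
    """Parameters of the rotate-then-translate pair construction."""

    alpha0: float  # degrees; rotation of ring 2 about the Y axis
    h: float  # Å; offset along Z
    dx: float = 0.0  # Å
    dy: float = 0.0  # Å
    guide_az1: float = 0.0  # degrees; in-plane rotation of ring 1 (β control)
    guide_az2: float = 0.0  # degrees; in-plane rotation of ring 2 before tilting

    @property
    def center_distance(self) -> float:
        return math.sqrt(self.dx**2 + self.dy**2 + self.h**2)


def expected_pair_alpha(alpha0: float, h: float, dx: float) -> float:
    """Closed-form dihedral of the constructed pair (degrees).

    For h > 0 and sin α₀ ≠ 0:  α = arccos(sign(Δx + h·cot α₀) · cos α₀) —
    i.e. α₀ when the second center lies on the acute side of the plane
    intersection line and 180° − α₀ on the obtuse side.  Exactly on the
    boundary the dihedral degenerates (center on the line); callers should
    stay off it.
    """
    a = math.radians(alpha0 % 180.0)
    if math.sin(a) < 1e-12:
        return 0.0
    x_line = dx + h / math.tan(a)
    return math.degrees(math.acos(math.copysign(1.0, x_line) * math.cos(a)))


def _phe_residue(seq_index: int, R: np.ndarray, t: np.ndarray) -> Residue:
    """A PHE residue: transformed template ring + CB + crude backbone."""
    tpl = template_phe()
    atoms = {k: R @ v + t for k, v in tpl.ring_atoms.items()}
    cb = R @ tpl.cbeta + t
    cg = atoms["CG"]
    stem = cb - cg
    stem /= np.linalg.norm(stem)
    atoms["CB"] = cb
    atoms["CA"] = cb + 1.52 * stem
    atoms["N"] = atoms["CA"] + np.array([0.0, 1.45, 0.0])
    atoms["C"] = atoms["CA"] + np.array([0.0, -1.52, 0.0])
    return Residue(seq_index=seq_index, name="PHE", auth_seqid=str(seq_index), atoms=atoms)


def _gly_residue(seq_index: int, pos: np.ndarray) -> Residue:
    return Residue(
        seq_index=seq_index,
        name="GLY",
        auth_seqid=str(seq_index),
        atoms={"CA": np.asarray(pos, dtype=float)},
    )


def make_pair_structure(spec: PairSpec) -> str:
    """PDB text of a two-Phe fixture at prescribed relative geometry.

    Ring 1 sits in the z = 0 plane at the origin; ring 2 is rotated by
    Ry(α₀) and shifted by (Δx, Δy, h).  The two PHE residues occupy chain
    ordinals 1 and 5 (glycine spacers in between keep them contact-eligible
    under the |i−j| ≥ 2 rule)."""
    R1 = _rz(math.radians(spec.guide_az1))
    R2 = _ry(math.radians(spec.alpha0)) @ _rz(math.radians(spec.guide_az2))
    res = [
        _phe_residue(1, R1, np.zeros(3)),
        _gly_residue(2, [50.0, 0.0, 0.0]),
        _gly_residue(3, [55.0, 0.0, 0.0]),
        _gly_residue(4, [60.0, 0.0, 0.0]),
        _phe_residue(5, R2, np.array([spec.dx, spec.dy, spec.h])),
    ]
    st = Structure(
        id="fixture",
        chains=[Chain(chain_id="A", residues=res)],
        meta=StructureMeta(method="X-RAY DIFFRACTION", resolution=1.5),
    )
    return write_structure(st)


_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _his_template() -> dict[str, np.ndarray]:
    """Planar regular-pentagon imidazole, bond 1.37 Å, centroid at origin."""
    names = ("CG", "ND1", "CE1", "NE2", "CD2")
    R = 1.37 / (2.0 * math.sin(math.pi / 5.0))
    ang = np.radians(72.0 * np.arange(5))
    return {n: R * np.array([math.cos(a), math.sin(a), 0.0]) for n, a in zip(names, ang)}


def _trp_template() -> dict[str, np.ndarray]:
    """Planar idealized indole (fused hexagon + pentagon), centroid at origin."""
    hexn = {"CE2": 30.0, "CD2": 90.0, "CE3": 150.0, "CZ3": 210.0, "CH2": 270.0, "CZ2": 330.0}
    atoms = {n: 1.40 * np.array([math.cos(math.radians(a)), math.sin(math.radians(a)), 0.0])
             for n, a in hexn.items()}
    ce2, cd2 = atoms["CE2"], atoms["CD2"]
    mid = 0.5 * (ce2 + cd2)
    out = mid / np.linalg.norm(mid)
    apothem = 1.40 / (2.0 * math.tan(math.pi / 5.0))
    R5 = 1.40 / (2.0 * math.sin(math.pi / 5.0))
    pc = mid + apothem * out  # pentagon center
    # pentagon order around: CD2 -> CG -> CD1 -> NE1 -> CE2
    a0 = math.atan2(cd2[1] - pc[1], cd2[0] - pc[0])
    step = 2.0 * math.pi / 5.0
    # walk from CD2 in the rotation direction that does not land on CE2 first
    probe = pc + R5 * np.array([math.cos(a0 + step), math.sin(a0 + step), 0.0])
    direction = -1.0 if np.linalg.norm(probe - ce2) < 0.1 else 1.0
    for k, name in enumerate(("CG", "CD1", "NE1"), start=1):
        a = a0 + direction * step * k
        atoms[name] = pc + R5 * np.array([math.cos(a), math.sin(a), 0.0])
    centroid = np.mean(list(atoms.values()), axis=0)
    return {n: v - centroid for n, v in atoms.items()}


def _aromatic_residue(
    seq_index: int, resname: str, R: np.ndarray, t: np.ndarray
) -> Residue:
    if resname in ("PHE", "TYR"):
        tpl = template_phe()
        ring = dict(tpl.ring_atoms)
    elif resname == "HIS":
        ring = _his_template()
    elif resname == "TRP":
        ring = _trp_template()
    else:
        raise ValueError(resname)
    centroid = np.mean(list(ring.values()), axis=0)
    cg = ring["CG"]
    stem = cg - centroid
    stem /= np.linalg.norm(stem)
    cb = cg + 1.52 * stem
    atoms = {k: R @ v + t for k, v in ring.items()}
    atoms["CB"] = R @ cb + t
    atoms["CA"] = R @ (cb + 1.52 * stem) + t
    return Residue(
        seq_index=seq_index, name=resname, auth_seqid=str(seq_index), atoms=atoms
    )


def random_structure(n_aromatic: int, box: float = 30.0, seed: int = 0) -> str:
    """PDB text with ``n_aromatic`` randomly placed/oriented aromatic residues.

    Each residue lives in its own chain, so all pairs are inter-chain and
    contact eligibility reduces to the distance cutoff alone.  Reproducible
    by seed; n = 0 yields a valid structure with a single glycine.
    """
    if n_aromatic > len(_CHAIN_IDS):
        raise ValueError(f"at most {len(_CHAIN_IDS)} residues supported")
    rng = np.random.default_rng(seed)
    types = ("PHE", "TYR", "TRP", "HIS")
    chains = []
    for k in range(n_aromatic):
        resname = types[rng.integers(len(types))]
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        t = rng.uniform(0.0, box, size=3)
        chains.append(
            Chain(chain_id=_CHAIN_IDS[k], residues=[_aromatic_residue(1, resname, R, t)])
        )
    if not chains:
        chains = [Chain(chain_id="A", residues=[_gly_residue(1, [0.0, 0.0, 0.0])])]
    st = Structure(
        id="random",
        chains=chains,
        meta=StructureMeta(method="X-RAY DIFFRACTION", resolution=2.0),
    )
    return write_structure(st)


def identity_fixture(
    n_chains: int,
    blocks: int | list[int] = 2,
    within_id: float = 85.0,
    across_id: float = 30.0,
    noise: float = 3.0,
    seed: int = 0,
    chain_length: int = 200,
) -> pd.DataFrame:
    """Block-structured alignment table with a planted partition.

    Pairs within a block get identity ``within_id`` ± noise, across blocks
    ``across_id`` ± noise (uniform, clipped to [1, 99]).  Columns are the
    alignment-table schema (chain_a, chain_b, I, L1, L2); the block of chain
    ``c{i}`` is ``i mod n_blocks`` when sizes are split evenly.
    """
    rng = np.random.default_rng(seed)
    if isinstance(blocks, int):
        base = n_chains // blocks
        sizes = [base + (1 if i < n_chains % blocks else 0) for i in range(blocks)]
    else:
        sizes = list(blocks)
        if sum(sizes) != n_chains:
            raise ValueError("block sizes must sum to n_chains")
    labels = []
    for b, sz in enumerate(sizes):
        labels += [b] * sz
    chains = [f"c{i:03d}" for i in range(n_chains)]
    rows = []
    L = chain_length
    for i in range(n_chains):
        for j in range(i + 1, n_chains):
            target = within_id if labels[i] == labels[j] else across_id
            ident = float(np.clip(target + rng.uniform(-noise, noise), 1.0, 99.0))
            # invert Id = I/(L1+L2-I)*100 for I
            I = int(round(ident * 2 * L / (100.0 + ident)))
            rows.append(
                {"chain_a": chains[i], "chain_b": chains[j], "I": I, "L1": L, "L2": L}
            )
    return pd.DataFrame(rows, columns=["chain_a", "chain_b", "I", "L1", "L2"])
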