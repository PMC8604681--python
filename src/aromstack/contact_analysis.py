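"""Contact-pair extraction and orientation classification.

A contact exists when two aromatic ring centers are strictly closer than 7 Å
and, within one chain, the residues are separated by at least two positions
(|i − j| ≥ 2 on chain ordinals; nearest neighbours are excluded for sterics).
The interplanar dihedral α assigns each pair to one of six orientation
classes: parallel (α < 15° or α ≥ 165°), four 30° intermediate bins, and
perpendicular / T-stacking ([75°, 105°)).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .pdb_io import Structure
from .ring_geometry import AromaticRing, PairGeometry, extract_rings, pair_geometry

__all__ = [
    "ALPHA_CLASSES",
    "ContactPair",
    "classify_alpha",
    "find_pairs",
    "analyze_structure",
    "pairs_to_table",
]

DEFAULT_CUTOFF = 7.0  # Å, strict
DEFAULT_MIN_SEPARATION = 2

#: Orientation class labels in increasing-α order (parallel listed first;
#: it covers both [0, 15) and [165, 180]).
ALPHA_CLASSES = ("parallel", "15-45", "45-75", "perpendicular", "105-135", "135-165")

_EDGES = (15.0, 45.0, 75.0, 105.0, 135.0, 165.0)
_BIN_LABELS = ("15-45", "45-75", "perpendicular", "105-135", "135-165")


def classify_alpha(alpha: float) -> str:
    """Orientation class of a dihedral α ∈ [0, 180] (degrees).

    Bins are lower-closed: parallel iff α < 15 or α ≥ 165; perpendicular
    iff 75 ≤ α < 105; otherwise the enclosing 30° bin label.
    """
    if not 0.0 <= alpha <= 180.0:
        raise ValueError(f"alpha must be in [0, 180], got {alpha}")
    if alpha < _EDGES[0] or alpha >= _EDGES[-1]:
        return "parallel"
    i = int(np.searchsorted(_EDGES, alpha, side="right")) - 1
    return _BIN_LABELS[i]


@dataclass(frozen=True)
class ContactPair:
    """An unordered contacting ring pair with its geometry descriptors."""

    ring1: AromaticRing
    ring2: AromaticRing
    geometry: PairGeometry
    seq_separation: int | None  # ordinal |i−j| within a chain; None = interchain
    neighbor_flag: bool  # same chain and |i−j| == 2 (contact through one residue)

    @property
    def type_pair(self) -> tuple[str, str]:
        return tuple(sorted((self.ring1.residue_name, self.ring2.residue_name)))


def find_pairs(
    rings: list[AromaticRing],
    cutoff: float = DEFAULT_CUTOFF,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    include_interchain: bool = True,
) -> list[ContactPair]:
    """All contacting ring pairs, each listed once.

    The distance cutoff is strict (< cutoff); same-chain pairs additionally
    require ordinal separation ≥ ``min_separation``.
    """
    if not rings:
        return []
    centers = np.array([r.center for r in rings])
    tree = cKDTree(centers)
    pairs: list[ContactPair] = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        r1, r2 = rings[i], rings[j]
        dist = float(np.linalg.norm(r1.center - r2.center))
        if not dist < cutoff:  # query_pairs uses <=; enforce strictness
            continue
        same_chain = r1.chain_id == r2.chain_id
        if same_chain:
            sep = abs(r1.seq_index - r2.seq_index)
            if sep < min_separation:
                continue
        else:
            if not include_interchain:
                continue
            sep = None
        # canonical order: by (chain, ordinal)
        if (r2.chain_id, r2.seq_index) < (r1.chain_id, r1.seq_index):
            r1, r2 = r2, r1
        pairs.append(
            ContactPair(
                ring1=r1,
                ring2=r2,
                geometry=pair_geometry(r1, r2),
                seq_separation=sep,
                neighbor_flag=same_chain and sep == 2,
            )
        )
    return pairs


def analyze_structure(
    structure: Structure,
    cutoff: float = DEFAULT_CUTOFF,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    include_interchain: bool = True,
) -> tuple[list[ContactPair], dict]:
    """Full per-structure analysis: rings → contacts → descriptors → summary.

    The summary maps each orientation class and each residue-type combination
    to its pair count; a structure without aromatic residues yields an empty
    pair list, not an error.
    """
    rings = extract_rings(structure)
    pairs = find_pairs(
        rings,
        cutoff=cutoff,
        min_separation=min_separation,
        include_interchain=include_interchain,
    )
    by_class = Counter(p.geometry.orientation_class for p in pairs)
    by_type = Counter("-".join(p.type_pair) for p in pairs)
    summary = {
        "structure_id": structure.id,
        "n_rings": len(rings),
        "n_pairs": len(pairs),
        "by_class": {c: by_class.get(c, 0) for c in ALPHA_CLASSES},
        "by_type": dict(sorted(by_type.items())),
    }
    return pairs, summary


def pairs_to_table(pairs: list[ContactPair], structure_id: str) -> pd.DataFrame:
    """One TSV-ready row per pair (author residue numbering)."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "structure_id": structure_id,
                "chain1": p.ring1.chain_id,
                "resi1": p.ring1.auth_seqid or str(p.ring1.seq_index),
                "resn1": p.ring1.residue_name,
                "chain2": p.ring2.chain_id,
                "resi2": p.ring2.auth_seqid or str(p.ring2.seq_index),
                "resn2": p.ring2.residue_name,
                "center_distance": round(p.geometry.center_distance, 3),
                "alpha": round(p.geometry.alpha, 2),
                "beta": round(p.geometry.beta, 2),
                "d": round(p.geometry.d, 3),
                "class": p.geometry.orientation_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "structure_id", "chain1", "resi1", "resn1", "chain2", "resi2",
            "resn2", "center_distance", "alpha", "beta", "d", "class",
        ],
    )
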