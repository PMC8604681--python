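"""Identity-constrained chain clustering for nonredundant structure sets.

Pairwise sequence identity between two aligned chains is

    Id = I / (L1 + L2 − I) × 100%,

with I identical aligned residues and L1, L2 the chain lengths.  Chains are
grouped bottom-up: perfectly matching chains first collapse into 100%-identity
groups; then, at each threshold (75, 50, 25, 5%), the pair of clusters with
the highest *average* cross-identity is merged, subject to a complete-linkage
veto — if any cross pair falls below the threshold the merge is forbidden.
Lower-threshold clusterings are seeded from the higher-threshold partition,
so the hierarchy is nested by construction.

Alignment production (e.g. BLAST) is out of scope: the module consumes a
table of (chain_a, chain_b, I, L1, L2) records; absent pairs count as
identity 0 (they always veto).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentRecord",
    "ClusterPartition",
    "sequence_identity",
    "identity_matrix",
    "dedup_identical",
    "agglomerate",
    "cluster_hierarchy",
    "load_alignments",
    "partition_to_frame",
]


@dataclass(frozen=True)
class AlignmentRecord:
    chain_a: str
    chain_b: str
    identical: int  # I
    length_a: int  # L1
    length_b: int  # L2

    def __post_init__(self) -> None:
        if self.length_a <= 0 or self.length_b <= 0:
            raise ValueError("chain lengths must be positive")
        if not 0 <= self.identical <= min(self.length_a, self.length_b):
            raise ValueError("identical-residue count exceeds a chain length")

    @property
    def identity(self) -> float:
        return sequence_identity(self.identical, self.length_a, self.length_b)


@dataclass
class ClusterPartition:
    """Disjoint chain clusters; every within-cluster pair meets the threshold."""

    clusters: list[tuple[str, ...]]
    threshold: float
    representatives: dict[str, str] = field(default_factory=dict)

    def cluster_of(self, chain: str) -> tuple[str, ...]:
        for cl in self.clusters:
            if chain in cl:
                return cl
        raise KeyError(chain)

    def __len__(self) -> int:
        return len(self.clusters)


def sequence_identity(identical: int, length_a: int, length_b: int) -> float:
    """Id = I / (L1 + L2 − I) × 100; equals 100 iff I = L1 = L2."""
    if length_a <= 0 or length_b <= 0:
        raise ValueError("chain lengths must be positive")
    if not 0 <= identical <= min(length_a, length_b):
        raise ValueError("identical count out of range")
    return identical / (length_a + length_b - identical) * 100.0


def load_alignments(source) -> list[AlignmentRecord]:
    """Read alignment records from a TSV (path or file-like) with columns
    chain_a, chain_b, I, L1, L2."""
    df = pd.read_csv(source, sep="\t")
    cols = {"chain_a", "chain_b", "I", "L1", "L2"}
    if not cols.issubset(df.columns):
        raise ValueError(f"alignment table needs columns {sorted(cols)}")
    return [
        AlignmentRecord(str(r.chain_a), str(r.chain_b), int(r.I), int(r.L1), int(r.L2))
        for r in df.itertuples()
    ]


def identity_matrix(
    records: list[AlignmentRecord], chains: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Symmetric identity matrix (%); missing pairs are 0, the diagonal 100."""
    if chains is None:
        seen: dict[str, None] = {}
        for r in records:
            seen.setdefault(r.chain_a)
            seen.setdefault(r.chain_b)
        chains = sorted(seen)
    index = {c: i for i, c in enumerate(chains)}
    n = len(chains)
    mat = np.zeros((n, n))
    np.fill_diagonal(mat, 100.0)
    for r in records:
        if r.chain_a not in index or r.chain_b not in index:
            continue
        i, j = index[r.chain_a], index[r.chain_b]
        mat[i, j] = mat[j, i] = max(mat[i, j], r.identity)
    return mat, chains


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def dedup_identical(
    identity: np.ndarray, chains: list[str]
) -> list[tuple[str, ...]]:
    """Connected components of the Id = 100 relation (perfect matches)."""
    n = len(chains)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if identity[i, j] >= 100.0:
                uf.union(i, j)
    groups: dict[int, list[str]] = {}
    for i, c in enumerate(chains):
        groups.setdefault(uf.find(i), []).append(c)
    return [tuple(sorted(g)) for g in sorted(groups.values())]


def _cluster_key(cluster: frozenset[int], chains: list[str]) -> str:
    return min(chains[i] for i in cluster)


def agglomerate(
    identity: np.ndarray,
    chains: list[str],
    threshold: float,
    initial: list[tuple[str, ...]] | None = None,
) -> ClusterPartition:
    """Average-linkage merging with a complete-linkage veto.

    Repeatedly merge the pair of clusters with the maximal mean cross-identity
    among pairs whose *minimum* cross-identity is at least ``threshold``; stop
    when no admissible merge remains.  Equal averages break lexicographically
    on the smallest chain id of each cluster.  ``initial`` seeds the partition
    (used for hierarchy nesting); by default every chain is a singleton.
    """
    index = {c: i for i, c in enumerate(chains)}
    if initial is None:
        clusters = [frozenset([i]) for i in range(len(chains))]
    else:
        clusters = [frozenset(index[c] for c in grp) for grp in initial]
    while True:
        best = None  # (neg_avg, key_a, key_b, ia, ib)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ia = np.fromiter(clusters[a], int)
                ib = np.fromiter(clusters[b], int)
                cross = identity[np.ix_(ia, ib)]
                if cross.min() < threshold:
                    continue
                keys = tuple(
                    sorted(
                        (_cluster_key(clusters[a], chains), _cluster_key(clusters[b], chains))
                    )
                )
                cand = (-cross.mean(), keys[0], keys[1], a, b)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        _, _, _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    out = [tuple(sorted(chains[i] for i in cl)) for cl in clusters]
    out.sort()
    part = ClusterPartition(clusters=out, threshold=threshold)
    _assert_complete_linkage(identity, chains, part)
    return part


def _assert_complete_linkage(
    identity: np.ndarray, chains: list[str], part: ClusterPartition
) -> None:
    index = {c: i for i, c in enumerate(chains)}
    for cl in part.clusters:
        idx = [index[c] for c in cl]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if identity[idx[a], idx[b]] < part.threshold:
                    raise AssertionError(
                        f"within-cluster identity {identity[idx[a], idx[b]]:.1f}% "
                        f"below threshold {part.threshold}%"
                    )


def cluster_hierarchy(
    identity: np.ndarray,
    chains: list[str],
    thresholds: tuple[float, ...] = (75.0, 50.0, 25.0, 5.0),
) -> dict[float, ClusterPartition]:
    """Nested partitions at decreasing identity thresholds.

    The 100%-identity dedup seeds the first level; each subsequent level is
    seeded from the previous partition, so every higher-threshold cluster is
    wholly contained in one lower-threshold cluster.
    """
    if list(thresholds) != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be decreasing")
    current = dedup_identical(identity, chains)
    out: dict[float, ClusterPartition] = {}
    for th in thresholds:
        part = agglomerate(identity, chains, th, initial=current)
        out[th] = part
        current = part.clusters
    return out


def select_representatives(
    part: ClusterPartition, resolution: dict[str, float] | None = None
) -> dict[str, str]:
    """One representative per cluster: highest resolution (smallest Å value),
    ties broken lexicographically; without resolutions, the smallest id."""
    reps = {}
    for cl in part.clusters:
        if resolution:
            rep = min(cl, key=lambda c: (resolution.get(c, float("inf")), c))
        else:
            rep = min(cl)
        reps[min(cl)] = rep
    part.representatives.update(reps)
    return reps


def partition_to_frame(part: ClusterPartition) -> pd.DataFrame:
    """Tabular form: cluster_id, chain_id, representative flag."""
    reps = part.representatives or {min(cl): min(cl) for cl in part.clusters}
    rows = []
    for k, cl in enumerate(part.clusters):
        rep = reps.get(min(cl), min(cl))
        for c in cl:
            rows.append({"cluster_id": k, "chain_id": c, "representative": c == rep})
    return pd.DataFrame(rows, columns=["cluster_id", "chain_id", "representative"])
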