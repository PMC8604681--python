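"""Observed-vs-expected pair-type statistics and normalized angular densities.

Residue-type frequencies P_A are estimated over the members of the contact
pairs themselves (each pair contributes two members).  Under independent
pairing the expected count of a hetero pair A–B is 2·N_sum·P_A·P_B and of a
homo pair A–A is N_sum·P_A² (multinomial convention: expectations sum to
N_sum).  Angular histograms are reported as probability densities
f_i = N_i / (N·Δ_i), so that Σ f_i·Δ_i = 1 even with unequal bin widths.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AROMATIC_TYPES",
    "PairCounts",
    "DensityHistogram",
    "residue_frequencies",
    "expected_counts",
    "observed_expected_table",
    "probability_density",
    "equivalent_free_energy",
]

#: The four aromatic residue types, as one-letter codes.
AROMATIC_TYPES = ("F", "Y", "W", "H")

_THREE_TO_ONE = {"PHE": "F", "TYR": "Y", "TRP": "W", "HIS": "H"}

#: kcal/(mol·K)
GAS_CONSTANT_KCAL = 1.987204e-3


@dataclass(frozen=True)
class PairCounts:
    """Pair-type counts and member frequencies over a set of contact pairs."""

    n_sum: int
    counts: dict[tuple[str, str], int]  # key: sorted type pair
    frequencies: dict[str, float]  # P_A, over pair members; sums to 1


@dataclass(frozen=True)
class DensityHistogram:
    edges: np.ndarray
    counts: np.ndarray
    widths: np.ndarray
    densities: np.ndarray  # N_i / (N · Δ_i)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _as_type(x: str) -> str:
    x = x.upper()
    if x in _THREE_TO_ONE:
        return _THREE_TO_ONE[x]
    if x in AROMATIC_TYPES:
        return x
    raise ValueError(f"not an aromatic residue type: {x!r}")


def _member_types(pair) -> tuple[str, str]:
    if hasattr(pair, "ring1"):  # a ContactPair
        return _as_type(pair.ring1.residue_name), _as_type(pair.ring2.residue_name)
    a, b = pair
    return _as_type(a), _as_type(b)


def residue_frequencies(pairs) -> PairCounts:
    """Count pair types and estimate member frequencies.

    ``pairs`` is an iterable of ContactPair objects or of (type, type) tuples
    (one- or three-letter codes).
    """
    counts: dict[tuple[str, str], int] = {}
    members: dict[str, int] = {t: 0 for t in AROMATIC_TYPES}
    n = 0
    for pair in pairs:
        a, b = _member_types(pair)
        key = tuple(sorted((a, b)))
        counts[key] = counts.get(key, 0) + 1
        members[a] += 1
        members[b] += 1
        n += 1
    if n == 0:
        raise ValueError("no pairs given")
    freqs = {t: members[t] / (2 * n) for t in AROMATIC_TYPES}
    return PairCounts(n_sum=n, counts=counts, frequencies=freqs)


def expected_counts(
    frequencies: dict[str, float], n_sum: int
) -> dict[tuple[str, str], float]:
    """Expected pair-type counts under independent pairing.

    Hetero A≠B: 2·N_sum·P_A·P_B; homo A–A: N_sum·P_A².  The expectations sum
    to N_sum exactly when Σ P = 1.
    """
    types = sorted(frequencies)
    for t, p in frequencies.items():
        if p < 0:
            raise ValueError(f"negative frequency for {t}")
    out: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations_with_replacement(types, 2):
        key = tuple(sorted((a, b)))
        if a == b:
            out[key] = n_sum * frequencies[a] ** 2
        else:
            out[key] = 2.0 * n_sum * frequencies[a] * frequencies[b]
    return out


def observed_expected_table(pairs) -> dict:
    """Observed counts, expected counts and their ratio per pair type."""
    pc = residue_frequencies(pairs)
    exp = expected_counts(pc.frequencies, pc.n_sum)
    table = {}
    for key, e in sorted(exp.items()):
        o = pc.counts.get(key, 0)
        table["-".join(key)] = {
            "observed": o,
            "expected": e,
            "ratio": o / e if e > 0 else math.nan,
        }
    return {
        "n_sum": pc.n_sum,
        "frequencies": pc.frequencies,
        "pairs": table,
    }


def probability_density(
    counts, edges, widths=None
) -> DensityHistogram:
    """Normalized density f_i = N_i / (N·Δ_i).

    ``widths`` may be given explicitly for classes spanning disjoint ranges
    (e.g. the parallel class covering [0, 15) ∪ [165, 180] has width 30);
    otherwise widths are taken from consecutive edges.
    """
    counts = np.asarray(counts, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if widths is None:
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        widths = np.diff(edges)
    else:
        widths = np.asarray(widths, dtype=float)
    if len(widths) != len(counts):
        raise ValueError("counts and widths differ in length")
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    densities = counts / (total * widths)
    return DensityHistogram(edges=edges, counts=counts, widths=widths, densities=densities)


def equivalent_free_energy(ratio: float, temperature: float = 298.15) -> float:
    """Free-energy difference (kcal/mol) equivalent to an occurrence ratio:
    ΔE = RT·ln(ratio).  A two-fold enrichment corresponds to ≈ 0.4 kcal/mol."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(ratio)
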