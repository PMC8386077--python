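"""Absence-based phylogenetics: Jaccard matrices over species absent-word
sets, Ward dendrograms, and clade partitions."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

__all__ = [
    "SpeciesProfile",
    "JaccardMatrix",
    "AbsenceTree",
    "jaccard_index",
    "pairwise_jaccard_matrix",
    "build_tree",
    "clade_partition",
]


@dataclass
class SpeciesProfile:
    species: str
    words: set
    groups: tuple = ()

    def __post_init__(self):
        self.words = set(self.words)
        if self.words:
            lengths = {len(w) for w in self.words}
            if len(lengths) != 1:
                raise ValueError(f"{self.species}: mixed word lengths {sorted(lengths)}")


@dataclass
class JaccardMatrix:
    species: list
    J: np.ndarray

    def __post_init__(self):
        self.J = np.asarray(self.J, dtype=float)
        if self.J.shape != (len(self.species), len(self.species)):
            raise ValueError("matrix shape does not match species list")


@dataclass
class AbsenceTree:
    species: list
    linkage_matrix: np.ndarray

    def to_newick(self) -> str:
        """Newick serialization with branch lengths from merge heights."""
        root = to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.species[node.id]}:{length:.6f}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6f}"

        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


def jaccard_index(set_a: Iterable, set_b: Iterable) -> float:
    """|A intersect B| / |A union B|; two empty sets give 0 with a warning."""
    a, b = set(set_a), set(set_b)
    lengths = {len(w) for w in a} | {len(w) for w in b}
    if len(lengths) > 1:
        raise ValueError(f"word length mismatch between sets: {sorted(lengths)}")
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 0", stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


def pairwise_jaccard_matrix(profiles: Sequence[SpeciesProfile]) -> JaccardMatrix:
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    names = [p.species for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names")
    n = len(profiles)
    J = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            J[i, j] = J[j, i] = jaccard_index(profiles[i].words, profiles[j].words)
    return JaccardMatrix(species=names, J=J)


def build_tree(jaccard_matrix: JaccardMatrix) -> AbsenceTree:
    """Ward agglomeration on distance 1 - J.

    Species are ordered lexicographically before clustering so that
    equidistant merges break ties reproducibly.
    """
    J = jaccard_matrix.J
    if not np.allclose(J, J.T):
        raise ValueError("Jaccard matrix is not symmetric")
    order = np.argsort(jaccard_matrix.species)
    species = [jaccard_matrix.species[i] for i in order]
    D = 1.0 - J[np.ix_(order, order)]
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="ward")
    return AbsenceTree(species=species, linkage_matrix=Z)


def clade_partition(
    profiles: Sequence[SpeciesProfile],
    group_map: Mapping[str, str] | None = None,
) -> dict:
    """Partition the union of absent words by sharing pattern.

    Returns primes (in every profile), species-specific words (in exactly
    one), group-specific words (in all members of a group, missing from at
    least one non-member), and the per-cardinality sharing histogram.
    """
    if not profiles:
        raise ValueError("empty profile list")
    if group_map is None:
        group_map = {}
        for p in profiles:
            if p.groups:
                group_map[p.species] = p.groups[0]
    membership: dict[str, set] = {}
    for p in profiles:
        for w in p.words:
            membership.setdefault(w, set()).add(p.species)
    all_species = {p.species for p in profiles}

    primes = {w for w, sp in membership.items() if sp == all_species}
    species_specific = {p.species: set() for p in profiles}
    for w, sp in membership.items():
        if len(sp) == 1:
            species_specific[next(iter(sp))].add(w)

    groups = sorted(set(group_map.values()))
    group_specific = {}
    for g in groups:
        members = {s for s, gg in group_map.items() if gg == g}
        nonmembers = all_species - members
        group_specific[g] = {
            w
            for w, sp in membership.items()
            if members <= sp and (not nonmembers or sp & nonmembers != nonmembers)
        }

    histogram: dict[int, int] = {}
    for sp in membership.values():
        histogram[len(sp)] = histogram.get(len(sp), 0) + 1

    return {
        "primes": primes,
        "species_specific": species_specific,
        "group_specific": group_specific,
        "sharing_histogram": histogram,
    }
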