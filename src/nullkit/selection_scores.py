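"""Negative-selection scoring of absent words.

Four tiers: the substitution-neighbor occurrence mean, a Monte Carlo
shuffle score with k-let-preserving permutations, a cross-species
absence ratio, and their aggregate sum-of-ranks with an optional
common-variant exclusion filter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from ._alphabet import AA20, DNA4, Alphabet
from .kmer_core import (
    NullomerRecord,
    OccurrenceCounts,
    count_occurrences,
    hamming_neighbors,
    scan_presence,
)

__all__ = [
    "Phi1Score",
    "PermutationScore",
    "Phi2Score",
    "CompartmentEnrichment",
    "Phi3Score",
    "PhiNRanking",
    "phi1",
    "phi1_peptide",
    "shuffle_klet",
    "phi2_simulate",
    "phi3",
    "phiN_rank",
    "finalize_ranking",
]


@dataclass(frozen=True)
class Phi1Score:
    word: str
    k: int
    value: float


@dataclass(frozen=True)
class PermutationScore:
    word: str
    mean: float
    min: int
    max: int
    median: float
    n_permutations: int


@dataclass
class Phi2Score:
    word: str
    replicate_counts: list
    klet: int

    @property
    def value(self) -> float:
        return float(np.mean(self.replicate_counts))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicate_counts))


@dataclass(frozen=True)
class CompartmentEnrichment:
    label: str
    k: int
    klet: int
    observed_nullomer_count: int
    expected: float
    expected_sd: float

    @property
    def enrichment(self) -> float:
        return self.observed_nullomer_count / self.expected


@dataclass(frozen=True)
class Phi3Score:
    word: str
    M: int
    n: int

    @property
    def value(self) -> float:
        return self.M / self.n


@dataclass
class PhiNRanking:
    words: list
    rank1: np.ndarray
    rank2: np.ndarray
    rank3: np.ndarray

    @property
    def phiN(self) -> np.ndarray:
        return self.rank1 + self.rank2 + self.rank3

    def sorted_words(self) -> list:
        order = np.lexsort((self.words, self.phiN))
        return [self.words[i] for i in order]


def phi1(record: NullomerRecord | str, occurrence_counts: OccurrenceCounts) -> Phi1Score:
    """Mean occurrence count over all substitution neighbors of the word."""
    word = record.word if isinstance(record, NullomerRecord) else record
    alphabet = DNA4 if set(word) <= set(DNA4.letters) else AA20
    neighbors = hamming_neighbors(word, alphabet)
    total = 0
    for nb in neighbors:
        c = occurrence_counts.get(nb)
        if c is None:
            raise KeyError(f"occurrence count missing for neighbor {nb!r} of {word!r}")
        total += c
    return Phi1Score(word=word, k=len(word), value=total / len(neighbors))


def phi1_peptide(word: str, proteome_counts: OccurrenceCounts) -> PermutationScore:
    """Occurrence statistics over the distinct multiset permutations of a
    peptide (the identity permutation contributes its own count, 0 for a
    genuinely absent word)."""
    perms = sorted({"".join(p) for p in itertools.permutations(word)})
    counts = []
    for p in perms:
        c = proteome_counts.get(p)
        if c is None:
            raise KeyError(f"occurrence count missing for permutation {p!r} of {word!r}")
        counts.append(c)
    return PermutationScore(
        word=word,
        mean=sum(counts) / len(counts),
        min=min(counts),
        max=max(counts),
        median=float(median(counts)),
        n_permutations=len(perms),
    )


# ---------------------------------------------------------------------------
# k-let-preserving shuffling (Euler-path shuffle on the de Bruijn multigraph)
# ---------------------------------------------------------------------------


def _euler_shuffle(s: str, m: int, rng: np.random.Generator, max_tries: int = 10000) -> str:
    """Shuffle ``s`` preserving its exact m-let count vector and both
    terminal (m-1)-mers (Altschul-Erickson style)."""
    n = len(s)
    if n <= m:
        return s
    order = m - 1
    start = s[:order]
    end = s[n - order :]
    # out-edges per vertex, each edge labelled by the next character
    edges: dict[str, list] = {}
    for i in range(n - order):
        v = s[i : i + order]
        edges.setdefault(v, []).append(s[i + order])
    vertices = list(edges)
    if len(vertices) == 1 and len(set(edges[vertices[0]])) == 1:
        return s  # e.g. homopolymer: unique arrangement

    for _ in range(max_tries):
        # pick a random candidate "last edge" per non-end vertex
        last = {}
        for v in vertices:
            if v == end:
                continue
            last[v] = v[1:] + edges[v][rng.integers(len(edges[v]))]
        # the chosen last edges must form an in-tree rooted at `end`
        ok = True
        reached: dict[str, bool] = {end: True}
        for v in vertices:
            path = []
            u = v
            while u not in reached:
                path.append(u)
                u = last.get(u)
                if u is None or u in path:
                    ok = False
                    break
            good = ok and reached.get(u, False)
            for p in path:
                reached[p] = good
            if not good:
                ok = False
                break
        if not ok:
            continue
        # order each adjacency list randomly with the chosen last edge final
        walk_edges = {}
        for v in vertices:
            chars = list(edges[v])
            if v in last:
                last_char = last[v][-1]
                chars.remove(last_char)
                rng.shuffle(chars)
                chars.append(last_char)
            else:
                rng.shuffle(chars)
            walk_edges[v] = chars
        out = [start]
        ptr = {v: 0 for v in vertices}
        v = start
        for _ in range(n - order):
            ch = walk_edges[v][ptr[v]]
            ptr[v] += 1
            out.append(ch)
            v = v[1:] + ch
        return "".join(out)
    raise RuntimeError(f"Euler shuffle failed to find an arborescence in {max_tries} tries")


def _split_segments(sequence: str, alphabet: Alphabet):
    """Split on runs of out-of-alphabet symbols, keeping the runs in place."""
    segments = []
    cur = []
    cur_valid = None
    valid_set = set(alphabet.letters)
    for ch in sequence:
        v = ch in valid_set
        if cur_valid is None or v == cur_valid:
            cur.append(ch)
            cur_valid = v
        else:
            segments.append(("seq" if cur_valid else "gap", "".join(cur)))
            cur = [ch]
            cur_valid = v
    if cur:
        segments.append(("seq" if cur_valid else "gap", "".join(cur)))
    return segments


def shuffle_klet(
    sequence: str,
    klet: int,
    seed: int | np.random.Generator,
    alphabet: Alphabet = DNA4,
) -> str:
    """Permutation of ``sequence`` preserving its exact klet-count vector.

    klet=1 is a uniform permutation; klet in {2, 3} uses an Euler-path
    shuffle on the de Bruijn multigraph of (klet-1)-mers, preserving the
    terminal (klet-1)-mers of each segment.  Runs of N / nonstandard
    residues stay fixed in place and segments shuffle independently.
    Deterministic for a given seed.
    """
    if klet not in (1, 2, 3):
        raise ValueError(f"klet must be 1, 2, or 3 (got {klet})")
    if len(sequence) < klet:
        raise ValueError("sequence shorter than klet")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for kind, seg in _split_segments(sequence, alphabet):
        if kind == "gap" or len(seg) < klet:
            out.append(seg)
        elif klet == 1:
            arr = np.array(list(seg))
            out.append("".join(arr[rng.permutation(len(arr))]))
        else:
            out.append(_euler_shuffle(seg, klet, rng))
    return "".join(out)


def phi2_simulate(
    compartment_sequences: Sequence[str],
    k: int,
    klet: int = 3,
    R: int = 100,
    seed: int = 0,
    strand_mode: str = "both",
    alphabet: Alphabet = DNA4,
    words: Sequence[str] = (),
    label: str = "genome",
):
    """Monte Carlo shuffle score and compartment nullomer enrichment.

    Each replicate shuffles every sequence independently (seeds spawned
    from the master seed), then counts occurrences of the requested words
    and the replicate's nullomer total.  Returns ``(scores, enrichment)``
    where scores maps word -> :class:`Phi2Score` and the enrichment is
    observed over mean simulated nullomer count, with the simulation
    standard deviation retained.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if not alphabet.complementable:
        strand_mode = "forward"
    seqs = [getattr(s, "residues", s) for s in compartment_sequences]
    observed = scan_presence(seqs, k, alphabet, strand_mode).n_absent()

    replicate_counts = {w: [] for w in words}
    null_counts = []
    child_seeds = np.random.SeedSequence(seed).spawn(R)
    for r in range(R):
        rng = np.random.default_rng(child_seeds[r])
        shuffled = [shuffle_klet(s, klet, rng, alphabet) for s in seqs]
        pmap = scan_presence(shuffled, k, alphabet, strand_mode)
        null_counts.append(pmap.n_absent())
        if words:
            occ = count_occurrences(shuffled, list(words), strand_mode, alphabet)
            for w in words:
                replicate_counts[w].append(occ[w])

    scores = {w: Phi2Score(word=w, replicate_counts=c, klet=klet) for w, c in replicate_counts.items()}
    enrichment = CompartmentEnrichment(
        label=label,
        k=k,
        klet=klet,
        observed_nullomer_count=observed,
        expected=float(np.mean(null_counts)),
        expected_sd=float(np.std(null_counts)),
    )
    return scores, enrichment


def phi3(word: str, species_presence_flags: Sequence[bool], n: int | None = None) -> Phi3Score:
    """Fraction of non-reference species whose compartment contains the word."""
    flags = list(species_presence_flags)
    if n is None:
        n = len(flags)
    if n == 0:
        raise ValueError("n must be positive")
    return Phi3Score(word=word, M=sum(bool(f) for f in flags), n=n)


def phiN_rank(
    words: Sequence[str],
    phi1_values: Sequence[float],
    phi2_values: Sequence[float],
    phi3_values: Sequence[float],
) -> PhiNRanking:
    """Sum of per-metric ascending competition ranks (ties share the
    minimal rank); lower is a stronger negative-selection candidate."""
    n = len(words)
    for name, vals in (("phi1", phi1_values), ("phi2", phi2_values), ("phi3", phi3_values)):
        if len(vals) != n:
            raise ValueError(f"{name} has {len(vals)} values for {n} words")
    return PhiNRanking(
        words=list(words),
        rank1=rankdata(phi1_values, method="min").astype(np.int64),
        rank2=rankdata(phi2_values, method="min").astype(np.int64),
        rank3=rankdata(phi3_values, method="min").astype(np.int64),
    )


def finalize_ranking(
    ranking: PhiNRanking,
    resurfacing_probabilities: Mapping[str, float],
    probability_threshold: float = 0.05,
) -> PhiNRanking:
    """Drop words whose aggregate resurfacing probability exceeds the
    threshold (unprofiled words count as probability 0 and are kept)."""
    keep = [
        i
        for i, w in enumerate(ranking.words)
        if resurfacing_probabilities.get(w, 0.0) <= probability_threshold
    ]
    return PhiNRanking(
        words=[ranking.words[i] for i in keep],
        rank1=ranking.rank1[keep],
        rank2=ranking.rank2[keep],
        rank3=ranking.rank3[keep],
    )
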