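"""Observed-variant intersection: which absent words resurface in the
population, with what aggregate probability, and in which populations."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .kmer_core import PresenceMap
from .mutation_maps import materialized_words_variant
from .sequence_io import ContigSequence, VariantRecord

log = logging.getLogger(__name__)

__all__ = [
    "ResurfacingProfile",
    "PopulationSpecificCall",
    "variant_materialized_nullomers",
    "aggregate_resurfacing_probability",
    "population_specific_nullomers",
    "non_resurfacing_fraction",
]


@dataclass
class ResurfacingProfile:
    word: str
    supporting_variants: list  # (VariantRecord, af used)
    aggregate_probability: float


@dataclass(frozen=True)
class PopulationSpecificCall:
    word: str
    carrier_population: str
    carrier_probability: float
    max_other_probability: float
    common_threshold: float = 0.05
    rare_threshold: float = 0.01


def variant_materialized_nullomers(
    genome: Sequence[ContigSequence],
    variants: Iterable[VariantRecord],
    nullomer_presence: PresenceMap,
    k: int,
) -> dict:
    """Map word -> list of variants whose application materializes it.

    Each variant is applied independently to the reference; variants whose
    REF does not match the genome are skipped with a warning count.
    """
    if nullomer_presence.k != k:
        raise ValueError("presence map k mismatch")
    contigs = {c.id: c.residues for c in genome}
    out: dict[str, list] = {}
    n_mismatch = 0
    for v in variants:
        seq = contigs.get(v.contig)
        if seq is None:
            n_mismatch += 1
            continue
        if v.ref and seq[v.pos - 1 : v.pos - 1 + len(v.ref)] != v.ref:
            n_mismatch += 1
            continue
        for w in materialized_words_variant(seq, k, v.pos, v.ref, v.alt, nullomer_presence):
            out.setdefault(w, []).append(v)
    if n_mismatch:
        log.warning("%d variants skipped (REF mismatch or unknown contig)", n_mismatch)
    return out


def _aggregate(afs: Iterable[float], method: str) -> float:
    afs = list(afs)
    for af in afs:
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"allele frequency {af} outside [0,1]")
    if method == "complement":
        return 1.0 - math.prod(1.0 - af for af in afs)
    if method == "sum":
        return min(1.0, sum(afs))
    raise ValueError(f"unknown aggregation method {method!r}")


def aggregate_resurfacing_probability(
    word: str,
    supporting_variants: Sequence[VariantRecord],
    method: str = "complement",
) -> ResurfacingProfile:
    """P = 1 - prod(1 - AF) over supporting variants (independent-sites
    approximation); ``method='sum'`` gives the capped sum-of-AFs variant."""
    pairs = [(v, v.af_global) for v in supporting_variants]
    prob = _aggregate((af for _, af in pairs), method)
    return ResurfacingProfile(word=word, supporting_variants=pairs, aggregate_probability=prob)


def population_specific_nullomers(
    word_variants: Mapping[str, Sequence[VariantRecord]],
    populations: Sequence[str] | None = None,
    common: float = 0.05,
    rare: float = 0.01,
    method: str = "complement",
) -> list[PopulationSpecificCall]:
    """Words common (aggregate probability > ``common``) in exactly one
    population and rare (< ``rare``) in all others; a missing population
    AF counts as 0."""
    if populations is None:
        pops = set()
        for variants in word_variants.values():
            for v in variants:
                pops.update(v.af_by_population)
        populations = sorted(pops)
    if len(populations) < 2:
        raise ValueError("need at least 2 populations")
    calls = []
    for word in sorted(word_variants):
        variants = word_variants[word]
        probs = {
            p: _aggregate((v.af_by_population.get(p, 0.0) for v in variants), method)
            for p in populations
        }
        carriers = [p for p, pr in probs.items() if pr > common]
        if len(carriers) != 1:
            continue
        carrier = carriers[0]
        others = {p: pr for p, pr in probs.items() if p != carrier}
        if all(pr < rare for pr in others.values()):
            calls.append(
                PopulationSpecificCall(
                    word=word,
                    carrier_population=carrier,
                    carrier_probability=probs[carrier],
                    max_other_probability=max(others.values()),
                    common_threshold=common,
                    rare_threshold=rare,
                )
            )
    return calls


def non_resurfacing_fraction(
    nullomer_set: Iterable[str],
    profiles: Mapping[str, ResurfacingProfile],
    threshold: float = 0.05,
) -> float:
    """Fraction of the set with aggregate probability <= threshold; words
    without a profile count as non-resurfacing."""
    words = set(nullomer_set)
    if not words:
        raise ValueError("empty nullomer set")
    n_ok = sum(
        1
        for w in words
        if w not in profiles or profiles[w].aggregate_probability <= threshold
    )
    return n_ok / len(words)
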