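"""Single-base edits that materialize absent words.

Every substitution, 1-bp deletion, and 1-bp insertion is applied to a
local window of radius k around the edit site; all k-windows of the
edited local sequence that overlap the edit are checked against the
absent-word set.  Insertions are keyed to the gap before position p
(p = 1..len+1, VCF-style left anchoring).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

from ._alphabet import revcomp
from .kmer_core import PresenceMap
from .sequence_io import ContigSequence, GeneModel

__all__ = [
    "MutationEvent",
    "MutationClassExpectation",
    "ContextSpectrum",
    "PeptideMutationEvent",
    "expected_class_counts",
    "scan_materializing_mutations",
    "materialized_words",
    "per_nullomer_event_counts",
    "mutation_type_enrichment",
    "substitution_context_spectrum",
    "region_density",
    "transcript_mutation_density",
    "cds_peptide_substitution_scan",
]

_BASES = "ACGT"

# standard genetic code (NCBI table 1), stops as '*'
from Bio.Data.CodonTable import unambiguous_dna_by_id as _codon_tables

CODON_TABLE = dict(_codon_tables[1].forward_table)
for _stop in _codon_tables[1].stop_codons:
    CODON_TABLE[_stop] = "*"


@dataclass
class MutationEvent:
    contig: str
    pos: int
    ref: str
    alt: str
    mclass: str  # SUB / INS / DEL
    materialized: frozenset

    def key(self):
        return (self.contig, self.pos, self.ref, self.alt, self.mclass)


@dataclass(frozen=True)
class MutationClassExpectation:
    """Single-base edit classes that disrupt one occurrence of a k-mer."""

    k: int
    deletions: int
    substitutions: int
    insertions: int

    @property
    def total(self) -> int:
        return self.deletions + self.substitutions + self.insertions

    @property
    def fractions(self) -> dict:
        t = self.total
        return {"DEL": self.deletions / t, "SUB": self.substitutions / t, "INS": self.insertions / t}


def expected_class_counts(k: int) -> MutationClassExpectation:
    """Counts of single-base edit classes per k-mer occurrence.

    Deletions: one per position (k).  Substitutions: three alternates per
    position (3k).  Insertions: four bases at each internal junction
    (4(k-1)); insertions outside the word leave the occurrence intact and
    are excluded.  Fractions are normalized by the total 8k-4.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    return MutationClassExpectation(k=k, deletions=k, substitutions=3 * k, insertions=4 * (k - 1))


def _new_windows(edited: str, k: int, cover_lo: int, cover_hi: int) -> Iterator[str]:
    """k-windows of ``edited`` covering some index in [cover_lo, cover_hi]."""
    for start in range(max(0, cover_lo - k + 1), min(cover_hi, len(edited) - k) + 1):
        w = edited[start : start + k]
        if "N" not in w:
            yield w


def _candidate_windows(seq: str, k: int, mclass: str, pos: int, alt: str) -> list[str]:
    """All k-windows of the edited sequence that overlap the edit.

    ``pos`` is 1-based; for INS it is the gap index (insert before pos).
    """
    L = len(seq)
    if mclass == "SUB":
        i = pos - 1
        lo, hi = max(0, i - k + 1), min(L, i + k)
        local = seq[lo:i] + alt + seq[i + 1 : hi]
        j = i - lo
        return list(_new_windows(local, k, j, j))
    if mclass == "INS":
        g = pos - 1  # insert before 0-based index g; g may equal L
        lo, hi = max(0, g - k + 1), min(L, g + k - 1)
        local = seq[lo:g] + alt + seq[g:hi]
        j = g - lo
        return list(_new_windows(local, k, j, j))
    if mclass == "DEL":
        i = pos - 1
        lo, hi = max(0, i - k + 1), min(L, i + k)
        local = seq[lo:i] + seq[i + 1 : hi]
        left_len = i - lo
        if left_len == 0 or left_len == len(local):
            return []  # deleting a terminal base creates no new adjacency
        # new windows span the junction: cover local indices left_len-1 and left_len
        return [
            w
            for start in range(max(0, left_len - k + 1), left_len)
            if start + k <= len(local) and "N" not in (w := local[start : start + k])
        ]
    raise ValueError(f"unknown mutation class {mclass!r}")


def materialized_words(
    seq: str, k: int, mclass: str, pos: int, alt: str, pmap: PresenceMap
) -> frozenset:
    """Words absent from ``pmap`` occurring in edit-overlapping windows.

    In both-strand mode each materialized word is reported together with
    its reverse complement (both flip to present simultaneously).
    """
    found = set()
    for w in _candidate_windows(seq, k, mclass, pos, alt):
        if not pmap.contains(w):
            found.add(w)
            if pmap.strand_mode == "both":
                found.add(revcomp(w))
    return frozenset(found)


def materialized_words_variant(
    seq: str, k: int, pos: int, ref: str, alt: str, pmap: PresenceMap
) -> frozenset:
    """Absent words materialized by a VCF-style replacement of ``ref`` by
    ``alt`` at 1-based ``pos``.

    All k-windows of the edited local context are checked; windows that
    pre-existed in the genome are present in the map and filter out, so
    the result contains exactly the newly occurring absent words.
    """
    L = len(seq)
    lo = max(0, pos - 1 - (k - 1))
    hi = min(L, pos - 1 + len(ref) + k - 1)
    local = seq[lo : pos - 1] + alt + seq[pos - 1 + len(ref) : hi]
    found = set()
    for start in range(len(local) - k + 1):
        w = local[start : start + k]
        if "N" not in w and not pmap.contains(w):
            found.add(w)
            if pmap.strand_mode == "both":
                found.add(revcomp(w))
    return frozenset(found)


def scan_materializing_mutations(
    genome: Iterable[ContigSequence],
    nullomer_presence: PresenceMap,
    k: int,
) -> Iterator[MutationEvent]:
    """Every single-base edit of the genome that materializes an absent word.

    Per position at most 3 SUB + 1 DEL + 4 INS candidate edits are
    evaluated (substitutions/deletions only at A/C/G/T reference bases);
    the final gap of each contig additionally receives 4 insertions.
    Events with an empty materialized set are suppressed.
    """
    if nullomer_presence.k != k:
        raise ValueError(f"presence map k={nullomer_presence.k} does not match k={k}")
    for contig in genome:
        seq = getattr(contig, "residues", contig)
        name = getattr(contig, "id", "seq")
        L = len(seq)
        for pos in range(1, L + 1):
            ref = seq[pos - 1]
            if ref in _BASES:
                for alt in _BASES:
                    if alt == ref:
                        continue
                    words = materialized_words(seq, k, "SUB", pos, alt, nullomer_presence)
                    if words:
                        yield MutationEvent(name, pos, ref, alt, "SUB", words)
                words = materialized_words(seq, k, "DEL", pos, "", nullomer_presence)
                if words:
                    yield MutationEvent(name, pos, ref, "", "DEL", words)
            for alt in _BASES:
                words = materialized_words(seq, k, "INS", pos, alt, nullomer_presence)
                if words:
                    yield MutationEvent(name, pos, "", alt, "INS", words)
        for alt in _BASES:  # final gap after the last base
            words = materialized_words(seq, k, "INS", L + 1, alt, nullomer_presence)
            if words:
                yield MutationEvent(name, L + 1, "", alt, "INS", words)


def per_nullomer_event_counts(
    events: Iterable[MutationEvent], words: Iterable[str] | None = None
) -> dict:
    """(event, word)-pair counts grouped by word; unseen words report 0."""
    counts: Counter = Counter()
    for ev in events:
        counts.update(ev.materialized)
    out = dict(counts)
    if words is not None:
        for w in words:
            out.setdefault(w, 0)
    return out


def mutation_type_enrichment(
    events: Sequence[MutationEvent], expectation: MutationClassExpectation
) -> dict:
    """Observed class fraction over expected class fraction, per class."""
    if not events:
        raise ValueError("no events; enrichment undefined")
    obs = Counter(ev.mclass for ev in events)
    total = sum(obs.values())
    expected = expectation.fractions
    return {c: (obs.get(c, 0) / total) / expected[c] for c in ("SUB", "INS", "DEL")}


@dataclass
class ContextSpectrum:
    """Substitution counts in trinucleotide context with genome normalization."""

    counts: dict  # (5' base, ref, 3' base, alt) -> count
    context_frequencies: dict  # trinucleotide -> genome frequency
    n_excluded: int = 0

    @property
    def context_counts(self) -> dict:
        out: Counter = Counter()
        for (p, r, n, _alt), c in self.counts.items():
            out[p + r + n] += c
        return dict(out)

    def normalized_rates(self) -> dict:
        """(count / total events) / genome frequency of the context."""
        total = sum(self.counts.values())
        rates = {}
        for ctx, c in self.context_counts.items():
            freq = self.context_frequencies.get(ctx, 0.0)
            if freq > 0 and total > 0:
                rates[ctx] = (c / total) / freq
        return rates


def substitution_context_spectrum(
    events: Iterable[MutationEvent], genome: Iterable[ContigSequence]
) -> ContextSpectrum:
    """Trinucleotide-context spectrum of substitution events."""
    contigs = {getattr(c, "id", "seq"): getattr(c, "residues", c) for c in genome}
    tri: Counter = Counter()
    total_tri = 0
    for seq in contigs.values():
        for i in range(len(seq) - 2):
            ctx = seq[i : i + 3]
            if "N" not in ctx:
                tri[ctx] += 1
                total_tri += 1
    freqs = {ctx: c / total_tri for ctx, c in tri.items()} if total_tri else {}

    counts: Counter = Counter()
    n_excluded = 0
    for ev in events:
        if ev.mclass != "SUB":
            continue
        seq = contigs[ev.contig]
        if ev.pos < 2 or ev.pos > len(seq) - 1:
            n_excluded += 1
            continue
        five, three = seq[ev.pos - 2], seq[ev.pos]
        if "N" in (five, three):
            n_excluded += 1
            continue
        counts[(five, ev.ref, three, ev.alt)] += 1
    return ContextSpectrum(counts=dict(counts), context_frequencies=freqs, n_excluded=n_excluded)


def region_density(events: Iterable, interval_sets: dict) -> pd.DataFrame:
    """Events overlapping each labelled interval set per bp of the set.

    ``interval_sets`` maps label -> list of (contig, start, end), 1-based
    inclusive.  Events outside all intervals of a label are excluded from
    that label's count.
    """
    events = list(events)
    rows = []
    for label, intervals in interval_sets.items():
        total_len = sum(e - s + 1 for _, s, e in intervals)
        if total_len <= 0:
            raise ValueError(f"interval set {label!r} has zero total length")
        by_contig = defaultdict(list)
        for contig, s, e in intervals:
            by_contig[contig].append((s, e))
        n = sum(
            1
            for ev in events
            if any(s <= ev.pos <= e for s, e in by_contig.get(ev.contig, ()))
        )
        rows.append({"label": label, "n_events": n, "length_bp": total_len, "density": n / total_len})
    return pd.DataFrame(rows)


def transcript_mutation_density(
    events: Iterable, gene_models: Sequence[GeneModel]
) -> pd.DataFrame:
    """Per-gene mutation density: events in the transcript span divided by
    transcript length, keeping the maximum-density isoform per gene."""
    events = list(events)
    rows = []
    for gm in gene_models:
        lo, hi = gm.span
        n = sum(1 for ev in events if ev.contig == gm.contig and lo <= ev.pos <= hi)
        rows.append(
            {"gene_id": gm.gene_id, "transcript_id": gm.transcript_id,
             "length_bp": hi - lo + 1, "density": n / (hi - lo + 1)}
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    idx = df.groupby("gene_id")["density"].idxmax()
    return df.loc[idx].reset_index(drop=True)


@dataclass
class PeptideMutationEvent:
    transcript_id: str
    cds_pos: int  # 1-based within the spliced CDS
    ref: str
    alt: str
    residue_index: int  # 0-based within the protein
    materialized: frozenset


def translate_cds(cds: str) -> str:
    aas = []
    for i in range(0, len(cds), 3):
        aas.append(CODON_TABLE[cds[i : i + 3]])
    return "".join(aas)


def cds_peptide_substitution_scan(
    cds_sequences: dict,
    nullpeptide_presence: PresenceMap,
    L: int,
) -> Iterator[PeptideMutationEvent]:
    """Single-nucleotide CDS substitutions that materialize absent peptides.

    Each substitution re-translates the affected codon; all L-residue
    windows covering the changed residue are checked.  Synonymous changes
    and stop-gains yield no event; a trailing stop codon is excluded from
    editing; a CDS with an internal stop is rejected.
    """
    for tid, cds in cds_sequences.items():
        cds = cds.upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS {tid}: length {len(cds)} not divisible by 3")
        protein = translate_cds(cds)
        if protein.endswith("*"):
            protein = protein[:-1]
            cds_coding = cds[:-3]
        else:
            cds_coding = cds
        if "*" in protein:
            raise ValueError(f"CDS {tid}: internal stop codon")
        n_res = len(protein)
        for i in range(len(cds_coding)):
            codon_idx = i // 3
            offset = i % 3
            codon = cds_coding[3 * codon_idx : 3 * codon_idx + 3]
            ref = cds_coding[i]
            for alt in _BASES:
                if alt == ref:
                    continue
                new_codon = codon[:offset] + alt + codon[offset + 1 :]
                new_aa = CODON_TABLE[new_codon]
                if new_aa == "*" or new_aa == protein[codon_idx]:
                    continue
                mutated = protein[:codon_idx] + new_aa + protein[codon_idx + 1 :]
                found = set()
                for start in range(max(0, codon_idx - L + 1), min(codon_idx, n_res - L) + 1):
                    pep = mutated[start : start + L]
                    if "X" not in pep and not nullpeptide_presence.contains(pep):
                        found.add(pep)
                if found:
                    yield PeptideMutationEvent(
                        transcript_id=tid,
                        cds_pos=i + 1,
                        ref=ref,
                        alt=alt,
                        residue_index=codon_idx,
                        materialized=frozenset(found),
                    )
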