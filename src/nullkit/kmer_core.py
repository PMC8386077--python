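"""Exhaustive k-mer presence scanning and absent-word extraction.

Presence over the full ``|alphabet|^k`` word space is held in a packed
bitmap (2-bit DNA / base-20 peptide integer addressing), so DNA words up
to k=15 fit in ~128 MiB and peptide words up to k=7 in ~160 MiB.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from ._alphabet import AA20, DNA4, Alphabet, decode_word, encode_word, revcomp_codes

__all__ = [
    "PresenceMap",
    "NullomerRecord",
    "OccurrenceCounts",
    "scan_presence",
    "find_nullomers",
    "iter_absent_words",
    "count_occurrences",
    "hamming_neighbors",
    "classify_order",
    "window_codes",
]

MAX_K = {"DNA4": 15, "AA20": 7}

_POPCOUNT = np.array([bin(i).count("1") for i in range(256)], dtype=np.int64)

# chunk length for streaming window encoding of long sequences
_CHUNK = 1 << 20


def _check_k(k: int, alphabet: Alphabet) -> None:
    cap = MAX_K[alphabet.name]
    if not 1 <= k <= cap:
        raise ValueError(f"k={k} outside supported range 1..{cap} for {alphabet.name}")


def window_codes(sequence: str, k: int, alphabet: Alphabet) -> np.ndarray:
    """Integer addresses of every valid length-``k`` window of ``sequence``.

    Windows containing any symbol outside the alphabet (N, nonstandard
    residues) are skipped.  Windows never span sequence boundaries.
    """
    n = len(sequence)
    if n < k:
        return np.empty(0, dtype=np.int64)
    codes = alphabet.codes(sequence)
    powers = alphabet.size ** np.arange(k - 1, -1, -1, dtype=np.int64)
    pieces = []
    for lo in range(0, n - k + 1, _CHUNK):
        hi = min(lo + _CHUNK + k - 1, n)
        chunk = codes[lo:hi]
        win = np.lib.stride_tricks.sliding_window_view(chunk, k)
        valid = (win < alphabet.size).all(axis=1)
        if valid.any():
            pieces.append(win[valid].astype(np.int64) @ powers)
    if not pieces:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(pieces)


class _Bitset:
    """Packed bitmap over ``range(n)``."""

    def __init__(self, n: int):
        self.n = n
        self.bits = np.zeros((n + 7) // 8, dtype=np.uint8)

    def set_many(self, idx: np.ndarray) -> None:
        if len(idx):
            np.bitwise_or.at(self.bits, idx >> 3, (1 << (idx & 7)).astype(np.uint8))

    def test(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=np.int64)
        return (self.bits[idx >> 3] >> (idx & 7).astype(np.uint8)) & 1

    def count(self) -> int:
        return int(_POPCOUNT[self.bits].sum())


@dataclass
class PresenceMap:
    """Membership of every length-``k`` word of an alphabet in a sequence set."""

    k: int
    alphabet: Alphabet
    strand_mode: str = "both"
    _bits: _Bitset = field(default=None, repr=False)

    def __post_init__(self):
        if self.strand_mode not in ("forward", "both"):
            raise ValueError(f"unknown strand_mode {self.strand_mode!r}")
        if self.strand_mode == "both" and not self.alphabet.complementable:
            raise ValueError("strand_mode='both' only applies to DNA")
        if self._bits is None:
            self._bits = _Bitset(self.alphabet.space(self.k))

    @property
    def space(self) -> int:
        return self.alphabet.space(self.k)

    def add_sequence(self, sequence: str) -> None:
        vals = window_codes(sequence, self.k, self.alphabet)
        self._bits.set_many(vals)
        if self.strand_mode == "both":
            self._bits.set_many(revcomp_codes(vals, self.k))

    def contains(self, word: str) -> bool:
        return bool(self._bits.test(np.array([encode_word(word, self.alphabet)]))[0])

    def contains_codes(self, codes: np.ndarray) -> np.ndarray:
        return self._bits.test(codes).astype(bool)

    def n_present(self) -> int:
        return self._bits.count()

    def n_absent(self) -> int:
        return self.space - self.n_present()

    def iter_absent_codes(self, chunk: int = 1 << 22) -> Iterator[np.ndarray]:
        """Yield absent-word addresses in ascending order, chunked."""
        for lo in range(0, self.space, chunk):
            hi = min(lo + chunk, self.space)
            block = np.unpackbits(
                self.bits_slice(lo, hi), bitorder="little", count=hi - lo
            )
            yield lo + np.nonzero(block == 0)[0]

    def bits_slice(self, lo: int, hi: int) -> np.ndarray:
        # lo must be byte-aligned (callers use power-of-two chunks)
        assert lo % 8 == 0
        return self._bits.bits[lo // 8 : (hi + 7) // 8]


@dataclass
class NullomerRecord:
    """An absent word with its compartment label and (optional) order/scores."""

    word: str
    k: int
    compartment: str = "genome"
    order: int | None = None
    scores: dict = field(default_factory=dict)


@dataclass
class OccurrenceCounts:
    """Occurrence counts ``A`` for a fixed-length target word set."""

    k: int
    strand_mode: str
    counts: dict

    def __getitem__(self, word: str) -> int:
        return self.counts[word]

    def get(self, word: str, default=None):
        return self.counts.get(word, default)


def scan_presence(
    sequences: Iterable,
    k: int,
    alphabet: Alphabet = DNA4,
    strand_mode: str = "both",
) -> PresenceMap:
    """Build a :class:`PresenceMap` over all valid windows of ``sequences``.

    ``sequences`` may be strings or objects with a ``residues`` attribute.
    In ``both`` mode a word is present iff it or its reverse complement
    occurs on the forward strand.
    """
    _check_k(k, alphabet)
    if not alphabet.complementable:
        strand_mode = "forward"
    pmap = PresenceMap(k=k, alphabet=alphabet, strand_mode=strand_mode)
    for seq in sequences:
        pmap.add_sequence(getattr(seq, "residues", seq))
    return pmap


def iter_absent_words(pmap: PresenceMap) -> Iterator[str]:
    for codes in pmap.iter_absent_codes():
        for c in codes:
            yield decode_word(int(c), pmap.k, pmap.alphabet)


def find_nullomers(pmap: PresenceMap, compartment_label: str = "genome") -> list[NullomerRecord]:
    """All words of the pmap's space never marked present.

    ``|result| + n_present == |alphabet|^k`` always holds; in ``both``
    mode the returned set is reverse-complement closed.
    """
    return [
        NullomerRecord(word=w, k=pmap.k, compartment=compartment_label)
        for w in iter_absent_words(pmap)
    ]


def count_occurrences(
    sequences: Iterable,
    target_words: Sequence[str],
    strand_mode: str = "both",
    alphabet: Alphabet = DNA4,
) -> OccurrenceCounts:
    """Count overlapping occurrences of each target word.

    In ``both`` mode the count is forward occurrences of the word plus
    forward occurrences of its reverse complement; palindromes contribute
    once per window.
    """
    targets = list(target_words)
    if not targets:
        return OccurrenceCounts(k=0, strand_mode=strand_mode, counts={})
    ks = {len(w) for w in targets}
    if len(ks) != 1:
        raise ValueError(f"mixed target lengths: {sorted(ks)}")
    k = ks.pop()
    _check_k(k, alphabet)
    if not alphabet.complementable:
        strand_mode = "forward"

    forward: dict[int, int] = {}
    for seq in sequences:
        vals = window_codes(getattr(seq, "residues", seq), k, alphabet)
        if len(vals):
            uniq, cnt = np.unique(vals, return_counts=True)
            for u, c in zip(uniq.tolist(), cnt.tolist()):
                forward[u] = forward.get(u, 0) + c

    counts = {}
    for w in targets:
        code = encode_word(w, alphabet)
        total = forward.get(code, 0)
        if strand_mode == "both":
            rc = int(revcomp_codes(np.array([code]), k)[0])
            if rc != code:
                total += forward.get(rc, 0)
        counts[w] = total
    return OccurrenceCounts(k=k, strand_mode=strand_mode, counts=counts)


def hamming_neighbors(word: str, alphabet: Alphabet = DNA4) -> list[str]:
    """The ``(|alphabet|-1) * k`` words at substitution distance exactly 1."""
    out = []
    for i, ch in enumerate(word):
        for sub in alphabet.letters:
            if sub != ch:
                out.append(word[:i] + sub + word[i + 1 :])
    return out


def classify_order(
    record: NullomerRecord | str,
    pmap: PresenceMap,
    max_order: int = 2,
) -> int:
    """Largest ``i <= max_order`` with every word within Hamming distance
    ``i`` absent; a plain nullomer with a present neighbor has order 0."""
    word = record.word if isinstance(record, NullomerRecord) else record
    if pmap.contains(word):
        raise ValueError(f"{word!r} is present in the map; not a nullomer")
    seen = {word}
    frontier = [word]
    order = 0
    for dist in range(1, max_order + 1):
        nxt = []
        for w in frontier:
            for nb in hamming_neighbors(w, pmap.alphabet):
                if nb not in seen:
                    seen.add(nb)
                    nxt.append(nb)
        if any(pmap.contains(w) for w in nxt):
            break
        order = dist
        frontier = nxt
    if isinstance(record, NullomerRecord):
        record.order = order
    return order


def all_words(k: int, alphabet: Alphabet = DNA4) -> Iterator[str]:
    """Lexicographic enumeration of the full word space (test helper)."""
    for tup in itertools.product(alphabet.letters, repeat=k):
        yield "".join(tup)
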