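"""Alphabet definitions and integer word encodings.

Words over an alphabet of size ``s`` are addressed as base-``s`` integers
with the leftmost character most significant, so the full length-``k``
word space maps onto ``range(s ** k)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Alphabet",
    "DNA4",
    "AA20",
    "encode_word",
    "decode_word",
    "revcomp",
    "revcomp_codes",
]


@dataclass(frozen=True)
class Alphabet:
    """A finite residue alphabet with a wildcard for invalid symbols."""

    name: str
    letters: str
    wildcard: str
    complementable: bool = False
    _lut: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        lut = np.full(256, 255, dtype=np.uint8)
        for i, ch in enumerate(self.letters):
            lut[ord(ch)] = i
        object.__setattr__(self, "_lut", lut)

    @property
    def size(self) -> int:
        return len(self.letters)

    def codes(self, sequence: str) -> np.ndarray:
        """Map a residue string to integer codes; invalid symbols -> 255."""
        raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
        return self._lut[raw]

    def space(self, k: int) -> int:
        return self.size**k


DNA4 = Alphabet("DNA4", "ACGT", "N", complementable=True)
AA20 = Alphabet("AA20", "ACDEFGHIKLMNPQRSTVWY", "X")

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode_word(word: str, alphabet: Alphabet = DNA4) -> int:
    """Encode ``word`` as its base-|alphabet| integer address."""
    val = 0
    size = alphabet.size
    for ch in word:
        c = int(alphabet._lut[ord(ch)])
        if c >= size:
            raise ValueError(f"symbol {ch!r} not in alphabet {alphabet.name}")
        val = val * size + c
    return val


def decode_word(value: int, k: int, alphabet: Alphabet = DNA4) -> str:
    """Inverse of :func:`encode_word` for a length-``k`` word."""
    size = alphabet.size
    out = []
    for _ in range(k):
        out.append(alphabet.letters[value % size])
        value //= size
    return "".join(reversed(out))


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return sequence.translate(_DNA_COMPLEMENT)[::-1]


def revcomp_codes(values: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement on encoded DNA words of length ``k``."""
    v = np.asarray(values, dtype=np.int64).copy()
    out = np.zeros_like(v)
    for _ in range(k):
        out = out * 4 + (3 - (v & 3))
        v >>= 2
    return out
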