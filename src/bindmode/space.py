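"""Enumerable combinatorial sequence spaces.

The library studied here varies a short stretch of contiguous positions (four
CDR3 residues by default) over the 20 proteinogenic amino acids, so the whole
space of ``20**L`` variants can be enumerated and scored exhaustively.  All
energies, abundances and count vectors in this package are stored densely in
the enumeration order defined by :class:`SequenceSpace`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

#: The 20 amino acids in alphabetical one-letter order; fixed so that indices,
#: one-hot blocks and enumeration order are reproducible across runs.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Refuse exhaustive enumeration above this many sequences by default.
DEFAULT_ENUMERATION_CAP = 10_000_000


class SpaceError(ValueError):
    """Raised for sequences or indices outside a :class:`SequenceSpace`."""


@dataclass(frozen=True)
class SequenceSpace:
    """The set of all ``alphabet**length`` strings, totally ordered.

    The order is lexicographic in the alphabet order (index 0 is the string of
    repeated first letters), i.e. a sequence is read as a base-``|alphabet|``
    number with the leftmost position most significant.
    """

    alphabet: str = AMINO_ACIDS
    length: int = 4

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SpaceError(f"length must be positive, got {self.length}")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise SpaceError("alphabet letters must be unique")

    @property
    def n_letters(self) -> int:
        return len(self.alphabet)

    @property
    def size(self) -> int:
        return self.n_letters ** self.length

    @cached_property
    def _letter_index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.alphabet)}

    def contains(self, sequence: str) -> bool:
        return len(sequence) == self.length and all(
            c in self._letter_index for c in sequence
        )

    def index(self, sequence: str) -> int:
        """Enumeration index of ``sequence`` (base-``n_letters`` value)."""
        if len(sequence) != self.length:
            raise SpaceError(
                f"sequence {sequence!r} has length {len(sequence)}, "
                f"space expects {self.length}"
            )
        idx = 0
        for c in sequence:
            try:
                idx = idx * self.n_letters + self._letter_index[c]
            except KeyError:
                raise SpaceError(
                    f"letter {c!r} in {sequence!r} not in alphabet"
                ) from None
        return idx

    def sequence(self, index: int) -> str:
        if not 0 <= index < self.size:
            raise SpaceError(f"index {index} outside [0, {self.size})")
        letters = []
        for _ in range(self.length):
            letters.append(self.alphabet[index % self.n_letters])
            index //= self.n_letters
        return "".join(reversed(letters))

    @cached_property
    def codes(self) -> np.ndarray:
        """Integer letter codes for every sequence, shape ``(size, length)``.

        Row ``i`` holds the alphabet indices of ``self.sequence(i)``.  This is
        the dense representation used by energy models; it is cached because
        every exhaustive evaluation needs it.
        """
        if self.size > DEFAULT_ENUMERATION_CAP:
            raise SpaceError(
                f"space of size {self.size} exceeds the enumeration cap "
                f"({DEFAULT_ENUMERATION_CAP}); subsample or reduce length"
            )
        n, L = self.n_letters, self.length
        idx = np.arange(self.size)
        cols = []
        for pos in range(L - 1, -1, -1):
            cols.append(idx % n)
            idx = idx // n
        return np.stack(cols[::-1], axis=1).astype(np.int64)

    def encode(self, sequence: str) -> np.ndarray:
        """Letter codes of a single sequence, shape ``(length,)``."""
        if not self.contains(sequence):
            raise SpaceError(f"{sequence!r} is not in this space")
        return np.array([self._letter_index[c] for c in sequence], dtype=np.int64)

    def sequences(self, indices=None) -> list[str]:
        """All sequences in enumeration order (or those at ``indices``)."""
        if indices is None:
            indices = range(self.size)
        return [self.sequence(int(i)) for i in indices]

    def one_hot(self, sequence: str) -> np.ndarray:
        """Flat one-hot vector of length ``n_letters * length``.

        Position ``i`` occupies the block ``[i*n_letters, (i+1)*n_letters)``;
        exactly ``length`` entries are 1.
        """
        codes = self.encode(sequence)
        v = np.zeros(self.n_letters * self.length)
        v[np.arange(self.length) * self.n_letters + codes] = 1.0
        return v

    def decode_one_hot(self, vector: np.ndarray) -> str:
        v = np.asarray(vector).reshape(self.length, self.n_letters)
        if not np.all(v.sum(axis=1) == 1):
            raise SpaceError("one-hot vector must have exactly one 1 per block")
        return "".join(self.alphabet[int(j)] for j in v.argmax(axis=1))


def codes_of(space: SequenceSpace, sequences) -> np.ndarray:
    """Letter-code matrix for an explicit list of sequences."""
    return np.stack([space.encode(s) for s in sequences]) if len(sequences) else (
        np.zeros((0, space.length), dtype=np.int64)
    )
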