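"""Barcode dictionary: the legal vocabulary of clone labels.

A dictionary is an ordered list of fixed-length nucleotide sequences with a
guaranteed minimum pairwise Hamming distance. The separation is what makes
mismatch-tolerant matching unambiguous: with min distance >= 2*k + 1, any
read barcode carrying <= k substitutions has a unique nearest entry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"
_ALPHABET_BYTES = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    """Position-wise mismatch count between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def encode_sequences(seqs: Sequence[str], length: int) -> np.ndarray:
    """Pack equal-length sequences into a (n, length) uint8 matrix."""
    if any(len(s) != length for s in seqs):
        raise ValueError("all sequences must have the stated length")
    if not seqs:
        return np.empty((0, length), dtype=np.uint8)
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), length
    )


@dataclass(frozen=True)
class BarcodeDictionary:
    """Ordered collection of unique same-length ACGT barcodes.

    ``min_pairwise_distance`` is the separation the dictionary was built
    (or declared) to satisfy; ``validate(full=True)`` checks it exhaustively.
    """

    entries: tuple[str, ...]
    min_pairwise_distance: int = 0
    _encoded: np.ndarray = field(init=False, repr=False, compare=False)
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("dictionary must contain at least one entry")
        length = len(self.entries[0])
        bad = [e for e in self.entries if set(e) - set(ALPHABET)]
        if bad:
            raise ValueError(f"entries restricted to {ALPHABET}: offending {bad[0]!r}")
        if any(len(e) != length for e in self.entries):
            raise ValueError("all entries must share one length")
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("dictionary entries must be unique")
        object.__setattr__(self, "_encoded", encode_sequences(self.entries, length))
        object.__setattr__(
            self, "_index", {seq: i for i, seq in enumerate(self.entries)}
        )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def length(self) -> int:
        return len(self.entries[0])

    @property
    def encoded(self) -> np.ndarray:
        """(n, L) uint8 view used by vectorized matching."""
        return self._encoded

    def index_of(self, seq: str) -> int | None:
        """Exact-match lookup; None when absent."""
        return self._index.get(seq)

    def validate(self, full: bool = False) -> None:
        """Re-check invariants; ``full`` runs the exhaustive pairwise scan."""
        if full:
            enc = self._encoded
            for i in range(len(enc)):
                d = (enc[i + 1 :] != enc[i]).sum(axis=1)
                if d.size and int(d.min()) < self.min_pairwise_distance:
                    j = i + 1 + int(d.argmin())
                    raise ValueError(
                        f"entries {i} and {j} at distance {int(d.min())} "
                        f"< declared minimum {self.min_pairwise_distance}"
                    )

    def pairwise_distances(self) -> Iterable[tuple[int, int, int]]:
        """Yield (i, j, distance) over all unordered pairs (small dicts only)."""
        enc = self._encoded
        for i, j in itertools.combinations(range(len(enc)), 2):
            yield i, j, int((enc[i] != enc[j]).sum())

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.entries) + "\n")

    @classmethod
    def from_file(
        cls, path: str | Path, min_pairwise_distance: int = 0
    ) -> "BarcodeDictionary":
        lines = [ln.strip().upper() for ln in Path(path).read_text().splitlines()]
        return cls(
            entries=tuple(ln for ln in lines if ln),
            min_pairwise_distance=min_pairwise_distance,
        )


def make_dictionary(
    n: int,
    length: int = 18,
    min_dist: int = 5,
    seed: int = 0,
    forbidden_motifs: Sequence[str] = ("CGAA",),
    max_attempts: int | None = None,
) -> BarcodeDictionary:
    """Rejection-sample ``n`` barcodes of ``length`` nt at pairwise Hamming
    distance >= ``min_dist``.

    Entries containing a forbidden motif (by default the construct spacer)
    are rejected: a barcode carrying the spacer inside itself could never be
    delimited during read extraction. Identical parameters and seed give an
    identical dictionary. Raises ``DictionaryInfeasibleError`` when the
    attempt budget is exhausted.
    """
    if n < 1 or length < 1 or min_dist < 0:
        raise ValueError("require n >= 1, length >= 1, min_dist >= 0")
    rng = np.random.default_rng(seed)
    budget = max_attempts if max_attempts is not None else max(20_000, 2_000 * n)
    accepted = np.empty((n, length), dtype=np.uint8)
    n_acc = 0
    attempts = 0
    forbidden = tuple(m.upper() for m in forbidden_motifs)
    while n_acc < n:
        if attempts >= budget:
            raise DictionaryInfeasibleError(
                f"could not place {n} barcodes of length {length} at minimum "
                f"pairwise distance {min_dist} within {budget} attempts"
            )
        attempts += 1
        cand = _ALPHABET_BYTES[rng.integers(0, 4, size=length)]
        if forbidden:
            s = cand.tobytes().decode()
            if any(m in s for m in forbidden):
                continue
        if n_acc:
            d = (accepted[:n_acc] != cand).sum(axis=1)
            if int(d.min()) < max(min_dist, 1):  # distance 0 = duplicate
                continue
        accepted[n_acc] = cand
        n_acc += 1
    entries = tuple(
        accepted[i].tobytes().decode("ascii") for i in range(n)
    )
    return BarcodeDictionary(entries=entries, min_pairwise_distance=min_dist)


class DictionaryInfeasibleError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the separation request."""
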