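"""Map extracted barcode sequences onto dictionary entries.

Matching is staged: exact lookup first, then nearest-neighbour Hamming
matching up to ``max_mismatches`` (default 2), accepting only a unique
minimum-distance entry. ``N`` bases always count as mismatches; sequences
whose length differs from the dictionary's never match. Ties yield
no-match — a read is dropped rather than assigned to an arbitrary lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .dictionary import BarcodeDictionary

CloneKey = tuple[int, int]

NO_MATCH = -1


@dataclass
class BarcodeCounts:
    """Per-sample clone abundance table keyed by (bc1 index, bc2 index)."""

    sample_id: str
    counts: dict[CloneKey, int] = field(default_factory=dict)
    total_matched: int = 0
    total_unmatched: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.counts.values()):
            raise ValueError("counts must be strictly positive")
        if self.total_matched != sum(self.counts.values()):
            raise ValueError("total_matched inconsistent with the count map")

    @property
    def keys(self) -> set[CloneKey]:
        return set(self.counts)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tbc1_index\tbc2_index\tcount\n")
            for (b1, b2), n in sorted(self.counts.items()):
                fh.write(f"{self.sample_id}\t{b1}\t{b2}\t{n}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeCounts":
        counts: dict[CloneKey, int] = {}
        sample_id = ""
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("sample_id"):
                raise ValueError(f"unexpected header in {path}")
            for line in fh:
                sid, b1, b2, n = line.rstrip("\n").split("\t")
                sample_id = sid
                counts[(int(b1), int(b2))] = counts.get((int(b1), int(b2)), 0) + int(n)
        return cls(
            sample_id=sample_id,
            counts=counts,
            total_matched=sum(counts.values()),
        )


def match_barcode(
    seq: str, dictionary: BarcodeDictionary, max_mismatches: int = 2
) -> int | None:
    """Return the dictionary index for ``seq`` or None.

    Stage 1 is exact equality; stage 2 returns the unique entry at minimum
    Hamming distance provided that distance is <= ``max_mismatches``.
    """
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) != dictionary.length:
        return None
    hit = dictionary.index_of(seq)
    if hit is not None:
        return hit
    q = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    dists = (dictionary.encoded != q).sum(axis=1)
    m = int(dists.min())
    if m > max_mismatches or int((dists == m).sum()) != 1:
        return None
    return int(dists.argmin())


def match_many(
    seqs: list[str],
    dictionary: BarcodeDictionary,
    max_mismatches: int = 2,
    chunk: int = 2048,
) -> np.ndarray:
    """Vectorized ``match_barcode`` over many sequences; -1 marks no-match."""
    out = np.full(len(seqs), NO_MATCH, dtype=np.int64)
    L = dictionary.length
    idx_pending: list[int] = []
    for i, s in enumerate(seqs):
        if len(s) != L:
            continue
        hit = dictionary.index_of(s)
        if hit is not None:
            out[i] = hit
        else:
            idx_pending.append(i)
    if not idx_pending:
        return out
    enc = dictionary.encoded
    pend = np.frombuffer(
        "".join(seqs[i] for i in idx_pending).encode("ascii"), dtype=np.uint8
    ).reshape(len(idx_pending), L)
    for start in range(0, len(idx_pending), chunk):
        block = pend[start : start + chunk]
        # (q, d): mismatch counts of each query against every entry
        dists = (block[:, None, :] != enc[None, :, :]).sum(axis=2)
        mins = dists.min(axis=1)
        unique = (dists == mins[:, None]).sum(axis=1) == 1
        ok = (mins <= max_mismatches) & unique
        arg = dists.argmin(axis=1)
        for k in np.nonzero(ok)[0]:
            out[idx_pending[start + int(k)]] = int(arg[int(k)])
    return out


def match_sample(
    raw_pair_counts: Mapping[tuple[str, str], int],
    dictionary: BarcodeDictionary,
    max_mismatches: int = 2,
    sample_id: str = "",
) -> BarcodeCounts:
    """Match both barcodes of every extracted pair against the dictionary.

    A pair contributes iff bc1 and bc2 both match; distinct raw sequences
    that correct to the same clone key merge. Unmatched pairs are tallied.
    """
    if len(dictionary) == 0:
        raise ValueError("empty dictionary")
    pairs = list(raw_pair_counts.items())
    uniq1 = sorted({p[0] for p, _ in pairs})
    uniq2 = sorted({p[1] for p, _ in pairs})
    m1 = dict(zip(uniq1, match_many(uniq1, dictionary, max_mismatches)))
    m2 = dict(zip(uniq2, match_many(uniq2, dictionary, max_mismatches)))
    counts: dict[CloneKey, int] = {}
    unmatched = 0
    for (s1, s2), n in pairs:
        i1, i2 = int(m1[s1]), int(m2[s2])
        if i1 == NO_MATCH or i2 == NO_MATCH:
            unmatched += n
        else:
            key = (i1, i2)
            counts[key] = counts.get(key, 0) + n
    return BarcodeCounts(
        sample_id=sample_id,
        counts=counts,
        total_matched=sum(counts.values()),
        total_unmatched=unmatched,
    )
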