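"""Quality filtering and barcode extraction from raw reads.

Per the construct design, a read carries bc1 + spacer + bc2 + spacer.
Processing per read: (1) reject reads with more than ``max_low_bases``
positions under the Phred threshold, then N-mask the remaining sub-threshold
positions; (2) find the first exact spacer occurrence whose start index lies
in the accepted barcode-length window, take the prefix as bc1; (3) find the
next exact spacer occurrence placing bc2's length in the same window, take
the intervening segment as bc2; everything after the second spacer is
discarded. Spacer matching is exact — an N or substitution inside a spacer
copy fails it, which is precisely how spacer-damaged reads are filtered out.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pysam

REASONS = ("too_many_low_quality", "no_spacer", "barcode_length", "truncated")


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    qualities: np.ndarray  # per-base Phred integers

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")
        if self.qualities.size and (
            self.qualities.min() < 0 or self.qualities.max() > 60
        ):
            raise ValueError("Phred qualities must lie in [0, 60]")


@dataclass(frozen=True)
class ExtractionResult:
    status: str  # "accepted" | "rejected"
    reason: str | None = None
    bc1: str | None = None
    bc2: str | None = None

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


@dataclass
class SampleStats:
    reads_total: int = 0
    reads_accepted: int = 0
    reads_rejected_by_reason: Counter = field(default_factory=Counter)

    @property
    def fraction_discarded(self) -> float:
        if self.reads_total == 0:
            return 0.0
        return 1.0 - self.reads_accepted / self.reads_total

    def check(self) -> None:
        if self.reads_accepted + sum(self.reads_rejected_by_reason.values()) != (
            self.reads_total
        ):
            raise ValueError("per-reason rejection counts do not sum to total")

    def report(self) -> str:
        lines = [
            f"reads_total\t{self.reads_total}",
            f"reads_accepted\t{self.reads_accepted}",
            f"fraction_discarded\t{self.fraction_discarded:.4f}",
        ]
        for reason in REASONS:
            lines.append(f"rejected_{reason}\t{self.reads_rejected_by_reason[reason]}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ExtractConfig:
    spacer: str = "CGAA"
    q_threshold: int = 25
    max_low_bases: int = 2
    bc_min: int = 16
    bc_max: int = 20

    @property
    def min_read_length(self) -> int:
        return 2 * self.bc_min + 2 * len(self.spacer)


def quality_filter(
    read: ReadRecord, q_threshold: int = 25, max_low_bases: int = 2
) -> ReadRecord | None:
    """Reject reads with > ``max_low_bases`` sub-threshold bases; N-mask the
    rest. Qualities and above-threshold bases are never altered."""
    low = read.qualities < q_threshold
    n_low = int(low.sum())
    if n_low > max_low_bases:
        return None
    if n_low == 0:
        return read
    seq = np.frombuffer(read.sequence.encode("ascii"), dtype=np.uint8).copy()
    seq[low] = ord("N")
    return ReadRecord(
        read_id=read.read_id,
        sequence=seq.tobytes().decode("ascii"),
        qualities=read.qualities,
    )


def locate_and_extract(
    read: ReadRecord,
    spacer: str = "CGAA",
    bc_length_range: tuple[int, int] = (16, 20),
) -> ExtractionResult:
    """Split a quality-filtered read into (bc1, bc2) via its spacer copies."""
    bc_min, bc_max = bc_length_range
    status, reason, bc1, bc2 = _extract_core(
        read.sequence, spacer, bc_min, bc_max
    )
    if status:
        return ExtractionResult(status="accepted", bc1=bc1, bc2=bc2)
    return ExtractionResult(status="rejected", reason=reason)


def _extract_core(
    seq: str, spacer: str, bc_min: int, bc_max: int
) -> tuple[bool, str | None, str | None, str | None]:
    k = len(spacer)
    if len(seq) < 2 * bc_min + 2 * k:
        return False, "truncated", None, None
    p1 = seq.find(spacer, bc_min, bc_max + k)
    if p1 < 0:
        reason = "no_spacer" if spacer not in seq else "barcode_length"
        return False, reason, None, None
    e1 = p1 + k
    p2 = seq.find(spacer, e1 + bc_min, e1 + bc_max + k)
    if p2 < 0:
        reason = "no_spacer" if seq.find(spacer, e1) < 0 else "barcode_length"
        return False, reason, None, None
    return True, None, seq[:p1], seq[e1:p2]


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, phred33 quality string) from FASTQ(.gz)."""
    n = 0
    try:
        with pysam.FastxFile(str(path)) as fh:
            for rec in fh:
                if rec.quality is None or rec.sequence is None:
                    raise ValueError("record missing sequence or quality")
                yield rec.name, rec.sequence.upper(), rec.quality
                n += 1
    except Exception as exc:  # surface the failing record index
        raise RuntimeError(f"malformed FASTQ {path!s} at record {n}: {exc}") from exc


def process_fastq(
    path: str | Path, config: ExtractConfig = ExtractConfig()
) -> tuple[dict[tuple[str, str], int], SampleStats]:
    """Run quality filtering and extraction over a whole FASTQ file.

    Returns raw (bc1, bc2) pair counts over accepted reads plus per-reason
    rejection statistics. Deterministic for a fixed file and configuration.
    """
    stats = SampleStats()
    pair_counts: Counter = Counter()
    thr = config.q_threshold
    max_low = config.max_low_bases
    # quality chars strictly below threshold (Phred+33)
    low_chars = bytes(range(33, min(33 + thr, 127)))
    spacer = config.spacer.upper()
    bc_min, bc_max = config.bc_min, config.bc_max
    rej = stats.reads_rejected_by_reason
    for _, seq, qual in iter_fastq(path):
        stats.reads_total += 1
        qb = qual.encode("ascii")
        n_low = len(qb) - len(qb.translate(None, low_chars))
        if n_low > max_low:
            rej["too_many_low_quality"] += 1
            continue
        if n_low:
            s = bytearray(seq.encode("ascii"))
            for i, q in enumerate(qb):
                if q - 33 < thr:
                    s[i] = ord("N")
            seq = s.decode("ascii")
        ok, reason, bc1, bc2 = _extract_core(seq, spacer, bc_min, bc_max)
        if not ok:
            rej[reason] += 1
            continue
        stats.reads_accepted += 1
        pair_counts[(bc1, bc2)] += 1
    stats.check()
    return dict(pair_counts), stats


def write_pair_counts(
    pair_counts: dict[tuple[str, str], int], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("bc1\tbc2\tcount\n")
        for (b1, b2), n in sorted(pair_counts.items()):
            fh.write(f"{b1}\t{b2}\t{n}\n")


def read_pair_counts(path: str | Path) -> dict[tuple[str, str], int]:
    out: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("bc1"):
            raise ValueError(f"unexpected header in {path}")
        for line in fh:
            b1, b2, n = line.rstrip("\n").split("\t")
            out[(b1, b2)] = out.get((b1, b2), 0) + int(n)
    return out
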