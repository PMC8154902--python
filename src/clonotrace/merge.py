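"""Replicate concordance and merging.

Replicate samples of the same treatment phase are compared by Jaccard index
on clone-key sets and by Pearson correlation of log2(count + 1) abundances
over common clones, then merged into one sample per time point keeping only
clones observed in at least ``min_present`` replicates — the filter that
removes single-replicate stochastic or PCR artifacts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .matching import BarcodeCounts, CloneKey


@dataclass(frozen=True)
class Concordance:
    jaccard: float
    #: None when fewer than two common clones (or degenerate abundances)
    pearson_common: float | None


def concordance(a: BarcodeCounts, b: BarcodeCounts) -> Concordance:
    """Jaccard on clone-key sets; Pearson on log2(count+1) over common keys."""
    ka, kb = a.keys, b.keys
    if not ka and not kb:
        raise ValueError("concordance of two empty samples is undefined")
    union = ka | kb
    common = sorted(ka & kb)
    jac = len(common) / len(union)
    if len(common) < 2:
        return Concordance(jaccard=jac, pearson_common=None)
    xa = np.log2(np.array([a.counts[k] for k in common], dtype=float) + 1.0)
    xb = np.log2(np.array([b.counts[k] for k in common], dtype=float) + 1.0)
    if xa.std() == 0.0 or xb.std() == 0.0:
        return Concordance(jaccard=jac, pearson_common=None)
    r = float(np.corrcoef(xa, xb)[0, 1])
    return Concordance(jaccard=jac, pearson_common=r)


@dataclass
class MergedSample:
    """One merged sample per treatment phase."""

    time_label: str
    abundance: dict[CloneKey, int] = field(default_factory=dict)
    presence: dict[CloneKey, int] = field(default_factory=dict)
    n_replicates: int = 0

    def __post_init__(self) -> None:
        if set(self.abundance) != set(self.presence):
            raise ValueError("abundance and presence must cover the same clones")
        if any(v <= 0 for v in self.abundance.values()):
            raise ValueError("retained clones must have positive abundance")

    @property
    def keys(self) -> set[CloneKey]:
        return set(self.abundance)

    @property
    def total_abundance(self) -> int:
        return sum(self.abundance.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("time_label\tbc1_index\tbc2_index\tabundance\tpresence\n")
            for (b1, b2) in sorted(self.abundance):
                fh.write(
                    f"{self.time_label}\t{b1}\t{b2}\t"
                    f"{self.abundance[(b1, b2)]}\t{self.presence[(b1, b2)]}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, n_replicates: int = 0) -> "MergedSample":
        abundance: dict[CloneKey, int] = {}
        presence: dict[CloneKey, int] = {}
        label = ""
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("time_label"):
                raise ValueError(f"unexpected header in {path}")
            for line in fh:
                label, b1, b2, ab, pr = line.rstrip("\n").split("\t")
                key = (int(b1), int(b2))
                abundance[key] = int(ab)
                presence[key] = int(pr)
        return cls(
            time_label=label,
            abundance=abundance,
            presence=presence,
            n_replicates=n_replicates,
        )


def merge_replicates(
    replicates: Sequence[BarcodeCounts],
    min_present: int = 2,
    time_label: str = "",
) -> MergedSample:
    """Merge replicates: keep clones seen in >= ``min_present`` replicates,
    abundance = summed read count across the replicates containing them."""
    if not replicates:
        raise ValueError("need at least one replicate")
    if min_present < 1:
        raise ValueError("min_present must be >= 1")
    if min_present > len(replicates):
        raise ValueError(
            f"min_present={min_present} exceeds {len(replicates)} replicates"
        )
    presence: Counter = Counter()
    total: Counter = Counter()
    for rep in replicates:
        for key, n in rep.counts.items():
            presence[key] += 1
            total[key] += n
    kept = {k for k, p in presence.items() if p >= min_present}
    return MergedSample(
        time_label=time_label,
        abundance={k: int(total[k]) for k in kept},
        presence={k: int(presence[k]) for k in kept},
        n_replicates=len(replicates),
    )


def concordance_report(
    replicates: Sequence[BarcodeCounts], path: str | Path | None = None
) -> str:
    """All pairwise replicate Jaccard/Pearson values as a TSV block."""
    lines = ["sample_a\tsample_b\tjaccard\tpearson_log2"]
    for i in range(len(replicates)):
        for j in range(i + 1, len(replicates)):
            c = concordance(replicates[i], replicates[j])
            pr = "NA" if c.pearson_common is None else f"{c.pearson_common:.4f}"
            lines.append(
                f"{replicates[i].sample_id}\t{replicates[j].sample_id}\t"
                f"{c.jaccard:.4f}\t{pr}"
            )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
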