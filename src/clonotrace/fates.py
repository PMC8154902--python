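"""Clonal fate classification across ordered time points.

Each clone detected in at least one merged sample gets an occurrence code:
a binary string with one character per time point, 1 where the clone was
observed (e.g. "110" = present at baseline and after cycle 1, gone after
cycle 2). Group counts over these codes drive the overlap statistics:
between-time-point Jaccard indices, elimination fractions, expansion
analysis, and abundance-weighted prevalence. Codes representing physically
implausible trajectories (detected only mid-course, "010", or vanishing and
reappearing, "101") can be excluded as technical artifacts — but overlap
statistics are computed before that exclusion, matching how the group
arithmetic reproduces the published numbers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matching import CloneKey
from .merge import MergedSample

DEFAULT_ARTIFACT_CODES = frozenset({"010", "101"})


@dataclass
class FateTable:
    """Per-clone occurrence codes and abundance vectors.

    ``abundance`` is a clones x time-points integer DataFrame (0 = absent);
    ``codes`` the derived per-clone binary strings. A clone absent at every
    time point never appears as a row.
    """

    time_labels: list[str]
    abundance: pd.DataFrame
    codes: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.time_labels)) != len(self.time_labels):
            raise ValueError("duplicate time labels")
        if list(self.abundance.columns) != list(self.time_labels):
            raise ValueError("abundance columns must equal time_labels")
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        present = self.abundance.to_numpy() > 0
        if len(self.abundance) and not present.any(axis=1).all():
            raise ValueError("all-zero clone rows are not allowed")
        self.codes = pd.Series(
            ["".join("1" if p else "0" for p in row) for row in present],
            index=self.abundance.index,
        )

    @property
    def n_timepoints(self) -> int:
        return len(self.time_labels)

    def __len__(self) -> int:
        return len(self.abundance)

    def to_tsv(self, path: str | Path) -> None:
        df = self.abundance.copy()
        df.insert(0, "code", self.codes)
        df.index = [f"{b1},{b2}" for b1, b2 in df.index]
        df.to_csv(path, sep="\t", index_label="clone_key")


def classify_fates(samples: Sequence[MergedSample]) -> FateTable:
    """Build the fate table from ordered merged samples (earliest first)."""
    if len(samples) < 2:
        raise ValueError("need at least two time points")
    labels = [s.time_label for s in samples]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate time labels")
    union: set[CloneKey] = set()
    for s in samples:
        union |= s.keys
    keys = sorted(union)
    mat = np.zeros((len(keys), len(samples)), dtype=np.int64)
    pos = {k: i for i, k in enumerate(keys)}
    for t, s in enumerate(samples):
        for k, a in s.abundance.items():
            mat[pos[k], t] = a
    abundance = pd.DataFrame(mat, index=clone_key_index(keys), columns=labels)
    return FateTable(time_labels=labels, abundance=abundance)


def clone_key_index(keys: Sequence[CloneKey]) -> pd.MultiIndex:
    """(bc1, bc2) clone keys as a two-level index."""
    if len(keys) == 0:
        return pd.MultiIndex.from_arrays([[], []], names=["bc1", "bc2"])
    return pd.MultiIndex.from_tuples(keys, names=["bc1", "bc2"])


def all_nonzero_codes(n_timepoints: int) -> list[str]:
    return [
        "".join(bits)
        for bits in itertools.product("01", repeat=n_timepoints)
        if "1" in bits
    ]


def group_sizes(table: FateTable) -> dict[str, int]:
    """Clone counts per occurrence code over all 2^T - 1 nonzero codes."""
    counts = table.codes.value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in all_nonzero_codes(table.n_timepoints)}


def _check_groups(groups: Mapping[str, int]) -> int:
    lengths = {len(c) for c in groups}
    if len(lengths) != 1:
        raise ValueError("all codes must have equal length")
    return lengths.pop()


def jaccard_between_timepoints(
    groups: Mapping[str, int], i: int, j: int
) -> float:
    """Jaccard index of the clone sets at time points i and j, computed
    purely from occurrence-group counts."""
    if i == j:
        raise ValueError("time points must differ")
    _check_groups(groups)
    inter = sum(n for c, n in groups.items() if c[i] == "1" and c[j] == "1")
    union = sum(n for c, n in groups.items() if c[i] == "1" or c[j] == "1")
    if union == 0:
        raise ValueError("both clone sets are empty")
    return inter / union


def fraction_eliminated(groups: Mapping[str, int], i: int, j: int) -> float:
    """Fraction of clones present at i that are eliminated as of j.

    Eliminated means never detected again: absent at j and at every later
    time point. (A clone absent at j but reappearing afterwards is not
    eliminated — with three time points that is the "101" pattern.)
    """
    if not i < j:
        raise ValueError("i must be an earlier time point than j")
    _check_groups(groups)
    at_i = sum(n for c, n in groups.items() if c[i] == "1")
    if at_i == 0:
        raise ValueError("no clones present at the earlier time point")
    gone = sum(
        n
        for c, n in groups.items()
        if c[i] == "1" and all(b == "0" for b in c[j:])
    )
    return gone / at_i


def exclude_artifact_groups(
    table: FateTable, codes_to_exclude: Iterable[str] = DEFAULT_ARTIFACT_CODES
) -> FateTable:
    """Drop clones whose codes are listed as technical artifacts; retained
    rows keep their codes and abundances untouched."""
    drop = set(codes_to_exclude)
    for c in drop:
        if len(c) != table.n_timepoints or set(c) - {"0", "1"}:
            raise ValueError(f"invalid code {c!r} for {table.n_timepoints} time points")
    keep = ~table.codes.isin(drop)
    return FateTable(
        time_labels=list(table.time_labels),
        abundance=table.abundance.loc[keep.to_numpy()].copy(),
    )


@dataclass(frozen=True)
class ExpansionResult:
    new_expanded: frozenset
    existing_expanded: frozenset


def expansion_analysis(
    table: FateTable, i: int, j: int, fold_threshold: float = 2.0
) -> ExpansionResult:
    """Clones that grew between time points i < j.

    Growth is judged on within-sample relative abundance so that sequencing
    depth differences cancel. ``existing_expanded``: present at both and
    relative abundance strictly more than ``fold_threshold``-fold higher at
    j. ``new_expanded``: absent at i, present at j, regardless of magnitude.
    """
    if not i < j:
        raise ValueError("i must be an earlier time point than j")
    ai = table.abundance.iloc[:, i].to_numpy(dtype=float)
    aj = table.abundance.iloc[:, j].to_numpy(dtype=float)
    ti, tj = ai.sum(), aj.sum()
    if ti <= 0 or tj <= 0:
        raise ValueError("zero total abundance at a compared time point")
    ri, rj = ai / ti, aj / tj
    both = (ai > 0) & (aj > 0)
    existing = both & (rj > fold_threshold * ri)
    new = (ai == 0) & (aj > 0)
    idx = table.abundance.index
    return ExpansionResult(
        new_expanded=frozenset(idx[new]),
        existing_expanded=frozenset(idx[existing]),
    )


def weighted_prevalence(table: FateTable) -> pd.DataFrame:
    """Per time point, each occurrence group's share of total abundance.

    Rows are codes, columns time labels; at every time point the shares of
    the codes present there sum to 1.
    """
    totals = table.abundance.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[(totals <= 0).to_numpy()][0]
        raise ValueError(f"zero total abundance at time point {bad!r}")
    grouped = table.abundance.groupby(table.codes).sum()
    return grouped.div(totals, axis=1)


def overlap_report(
    groups: Mapping[str, int],
    baseline: int = 0,
) -> dict:
    """Headline overlap statistics at display precision: group percentages
    to the nearest percent, Jaccard to two decimals, elimination to the
    nearest percent."""
    T = _check_groups(groups)
    total = sum(groups.values())
    out: dict = {"total_unique_barcodes": total, "group_counts": dict(groups)}
    out["group_percent"] = {
        c: round(100.0 * n / total) for c, n in groups.items() if total
    }
    out["jaccard"] = {
        (i, j): round(jaccard_between_timepoints(groups, i, j), 2)
        for i in range(T)
        for j in range(i + 1, T)
    }
    out["percent_eliminated"] = {
        (baseline, j): round(100.0 * fraction_eliminated(groups, baseline, j))
        for j in range(baseline + 1, T)
    }
    return out
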