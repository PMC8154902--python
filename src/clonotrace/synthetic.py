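"""Synthetic barcoded cell population under cyclic drug selection.

Emulates the study system end to end: a population of clones, each labeled
by an ordered pair of dictionary barcodes (bc1, bc2); a pre-existing
resistant subpopulation; treatment cycles of binomial kill followed by
regrowth; and sequencing of the 44-nt read layout bc1 + spacer + bc2 +
spacer with PCR over-dispersion and per-base substitution errors.

Replicate samples at post-treatment time points are modeled as independent
selection lineages branching from the shared baseline: two wells treated in
parallel undergo independent stochastic kill, which is exactly why clones
recurring across replicates indicate pre-existing resistance rather than
random escape.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .dictionary import BarcodeDictionary
from .matching import BarcodeCounts

DEFAULT_SPACER = "CGAA"
#: log-scale mean/sd of baseline clone sizes; mean ~30 cells per founder
DEFAULT_ABUNDANCE_MU = 2.9
DEFAULT_ABUNDANCE_SIGMA = 1.0


@dataclass(frozen=True)
class Clone:
    clone_id: str
    bc1_index: int
    bc2_index: int
    resistant: bool
    cell_count: int

    def __post_init__(self) -> None:
        if self.cell_count < 0:
            raise ValueError("cell_count must be >= 0")


@dataclass
class ClonePopulation:
    """Clones sharing one dictionary; extinct clones stay at count 0."""

    dictionary: BarcodeDictionary
    clones: list[Clone]
    time_label: str = ""

    def __post_init__(self) -> None:
        pairs = [(c.bc1_index, c.bc2_index) for c in self.clones]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate barcode pairs in population")

    @property
    def total_cells(self) -> int:
        return sum(c.cell_count for c in self.clones)

    @property
    def cell_counts(self) -> np.ndarray:
        return np.array([c.cell_count for c in self.clones], dtype=np.int64)

    @property
    def resistant_mask(self) -> np.ndarray:
        return np.array([c.resistant for c in self.clones], dtype=bool)

    def clone_keys(self) -> list[tuple[int, int]]:
        return [(c.bc1_index, c.bc2_index) for c in self.clones]

    def truth_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("clone_id\tbc1\tbc2\tresistant\tcell_count\n")
            for c in self.clones:
                fh.write(
                    f"{c.clone_id}\t{self.dictionary.entries[c.bc1_index]}\t"
                    f"{self.dictionary.entries[c.bc2_index]}\t"
                    f"{int(c.resistant)}\t{c.cell_count}\n"
                )


def simulate_population(
    dictionary: BarcodeDictionary,
    n_clones: int,
    resistant_fraction: float,
    abundance_mu: float = DEFAULT_ABUNDANCE_MU,
    abundance_sigma: float = DEFAULT_ABUNDANCE_SIGMA,
    seed: int = 0,
    time_label: str = "baseline",
) -> ClonePopulation:
    """Draw a baseline population of ``n_clones`` distinct barcode pairs.

    Exactly ``round(resistant_fraction * n_clones)`` clones are flagged
    resistant (deterministic count, random identity). Cell counts are
    log-normal, rounded, and floored at 1.
    """
    if not 0.0 <= resistant_fraction <= 1.0:
        raise ValueError("resistant_fraction must lie in [0, 1]")
    n_dict = len(dictionary)
    if n_clones > n_dict * n_dict:
        raise ValueError(
            f"{n_clones} clones exceed the {n_dict * n_dict} distinct "
            "ordered pairs available"
        )
    rng = np.random.default_rng(seed)
    pairs: set[tuple[int, int]] = set()
    ordered: list[tuple[int, int]] = []
    while len(ordered) < n_clones:
        draw = rng.integers(0, n_dict, size=(n_clones, 2))
        for b1, b2 in draw:
            key = (int(b1), int(b2))
            if key not in pairs:
                pairs.add(key)
                ordered.append(key)
                if len(ordered) == n_clones:
                    break
    n_resistant = int(math.floor(resistant_fraction * n_clones + 0.5))
    res_idx = set(rng.choice(n_clones, size=n_resistant, replace=False).tolist())
    counts = np.maximum(
        1, np.rint(rng.lognormal(abundance_mu, abundance_sigma, size=n_clones))
    ).astype(np.int64)
    clones = [
        Clone(
            clone_id=f"clone{i:06d}",
            bc1_index=b1,
            bc2_index=b2,
            resistant=i in res_idx,
            cell_count=int(counts[i]),
        )
        for i, (b1, b2) in enumerate(ordered)
    ]
    return ClonePopulation(dictionary=dictionary, clones=clones, time_label=time_label)


def apply_treatment_cycle(
    pop: ClonePopulation,
    surv_sensitive: float,
    surv_resistant: float,
    regrowth: float = 1.0,
    seed: int = 0,
    time_label: str = "",
) -> ClonePopulation:
    """One kill/regrowth cycle: binomial thinning per clone at its class's
    survival probability, then multiplication by ``regrowth`` (rounded).

    Extinct clones remain in the record at count 0 so that fate codes can be
    read off the simulation truth.
    """
    for p in (surv_sensitive, surv_resistant):
        if not 0.0 <= p <= 1.0:
            raise ValueError("survival probabilities must lie in [0, 1]")
    if regrowth < 0:
        raise ValueError("regrowth must be >= 0")
    rng = np.random.default_rng(seed)
    counts = pop.cell_counts
    probs = np.where(pop.resistant_mask, surv_resistant, surv_sensitive)
    survivors = rng.binomial(counts, probs)
    regrown = np.rint(survivors * regrowth).astype(np.int64)
    clones = [
        replace(c, cell_count=int(k)) for c, k in zip(pop.clones, regrown)
    ]
    return ClonePopulation(
        dictionary=pop.dictionary,
        clones=clones,
        time_label=time_label or pop.time_label,
    )


@dataclass
class SimulatedReads:
    """A batch of synthetic reads with per-read ground truth.

    ``sequences``/``qualities`` are (n, read_length) uint8 ASCII matrices;
    truth arrays record the source clone and the substitution count in each
    construct region, enabling exact recall accounting downstream.
    """

    read_ids: list[str]
    sequences: np.ndarray
    qualities: np.ndarray
    clone_indices: np.ndarray
    n_err_bc1: np.ndarray
    n_err_spacer1: np.ndarray
    n_err_bc2: np.ndarray
    n_err_spacer2: np.ndarray

    def __len__(self) -> int:
        return len(self.read_ids)

    def sequence(self, i: int) -> str:
        return self.sequences[i].tobytes().decode("ascii")

    def write_fastq(self, path: str | Path) -> None:
        """Write Phred+33 FASTQ; ``.gz`` suffix triggers gzip compression."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            seqs = self.sequences
            quals = self.qualities
            for i, rid in enumerate(self.read_ids):
                fh.write(
                    f"@{rid}\n{seqs[i].tobytes().decode('ascii')}\n+\n"
                    f"{quals[i].tobytes().decode('ascii')}\n"
                )


def emit_reads(
    pop: ClonePopulation,
    n_reads: int,
    seq_error_rate: float = 0.0,
    pcr_dispersion: float = 0.0,
    spacer: str = DEFAULT_SPACER,
    spacer2: str | None = None,
    seed: int = 0,
    five_prime_offset: int = 0,
    base_quality: int = 37,
    error_quality: int | None = None,
    read_prefix: str = "read",
) -> SimulatedReads:
    """Sample reads from a population, layout bc1 + spacer + bc2 + spacer.

    Clone sampling is proportional to cell counts; with ``pcr_dispersion``
    d > 0 each clone's weight is perturbed by an independent Gamma(1/d, d)
    multiplier (mean 1, variance d), mimicking amplification jackpots. Each
    base is substituted independently with ``seq_error_rate``; when
    ``error_quality`` is set, substituted positions carry that Phred score
    instead of ``base_quality``.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if n_reads > 0 and pop.total_cells == 0:
        raise ValueError("cannot emit reads from an all-extinct population")
    sp1 = spacer.upper()
    sp2 = (spacer2 if spacer2 is not None else spacer).upper()
    L = pop.dictionary.length
    layout = five_prime_offset + L + len(sp1) + L + len(sp2)
    rng = np.random.default_rng(seed)

    entries = pop.dictionary.entries
    templates = np.empty((len(pop.clones), layout), dtype=np.uint8)
    pad = "A" * five_prime_offset
    for i, c in enumerate(pop.clones):
        s = pad + entries[c.bc1_index] + sp1 + entries[c.bc2_index] + sp2
        templates[i] = np.frombuffer(s.encode("ascii"), dtype=np.uint8)

    weights = pop.cell_counts.astype(float)
    if pcr_dispersion > 0:
        shape = 1.0 / pcr_dispersion
        weights = weights * rng.gamma(shape, pcr_dispersion, size=len(weights))
    weights = np.where(pop.cell_counts > 0, weights, 0.0)
    total = weights.sum()
    if n_reads > 0 and total <= 0:
        raise ValueError("all sampling weights are zero")

    if n_reads == 0:
        empty = np.empty((0, layout), dtype=np.uint8)
        z = np.zeros(0, dtype=np.int64)
        return SimulatedReads([], empty, empty.copy(), z, z, z, z, z)

    clone_idx = rng.choice(len(pop.clones), size=n_reads, p=weights / total)
    seqs = templates[clone_idx].copy()

    err_mask = rng.random((n_reads, layout)) < seq_error_rate
    if err_mask.any():
        rows, cols = np.nonzero(err_mask)
        base_map = np.zeros(256, dtype=np.uint8)
        for k, b in enumerate(b"ACGT"):
            base_map[b] = k
        cur = base_map[seqs[rows, cols]]
        shifted = (cur + rng.integers(1, 4, size=rows.size)) % 4
        seqs[rows, cols] = np.frombuffer(b"ACGT", dtype=np.uint8)[shifted]

    quals = np.full((n_reads, layout), 33 + base_quality, dtype=np.uint8)
    if error_quality is not None and err_mask.any():
        quals[err_mask] = 33 + error_quality

    o = five_prime_offset
    r1 = slice(o, o + L)
    rs1 = slice(o + L, o + L + len(sp1))
    r2 = slice(o + L + len(sp1), o + 2 * L + len(sp1))
    rs2 = slice(o + 2 * L + len(sp1), layout)
    return SimulatedReads(
        read_ids=[f"{read_prefix}{i:07d}" for i in range(n_reads)],
        sequences=seqs,
        qualities=quals,
        clone_indices=clone_idx.astype(np.int64),
        n_err_bc1=err_mask[:, r1].sum(axis=1).astype(np.int64),
        n_err_spacer1=err_mask[:, rs1].sum(axis=1).astype(np.int64),
        n_err_bc2=err_mask[:, r2].sum(axis=1).astype(np.int64),
        n_err_spacer2=err_mask[:, rs2].sum(axis=1).astype(np.int64),
    )


def sample_counts(
    pop: ClonePopulation,
    n_reads: int,
    pcr_dispersion: float = 0.0,
    seed: int = 0,
    sample_id: str = "",
) -> BarcodeCounts:
    """Error-free sequencing shortcut: multinomial read counts per clone.

    Equivalent to emit_reads -> extract -> match at zero error rate, without
    materializing the reads; used for deep-sampling simulations.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(seed)
    weights = pop.cell_counts.astype(float)
    if pcr_dispersion > 0:
        shape = 1.0 / pcr_dispersion
        weights = weights * rng.gamma(shape, pcr_dispersion, size=len(weights))
    weights = np.where(pop.cell_counts > 0, weights, 0.0)
    total = weights.sum()
    if n_reads > 0 and total <= 0:
        raise ValueError("cannot sample reads from an all-extinct population")
    counts: dict[tuple[int, int], int] = {}
    if n_reads > 0:
        draws = rng.multinomial(n_reads, weights / total)
        keys = pop.clone_keys()
        for i in np.nonzero(draws)[0]:
            counts[keys[int(i)]] = int(draws[int(i)])
    matched = sum(counts.values())
    return BarcodeCounts(
        sample_id=sample_id, counts=counts, total_matched=matched, total_unmatched=0
    )


@dataclass
class Experiment:
    """Replicated two-cycle selection experiment.

    ``populations[t][r]`` is replicate r's population at time point t;
    baseline replicates share the founding population, post-treatment ones
    are independent lineages.
    """

    baseline: ClonePopulation
    populations: list[list[ClonePopulation]]
    time_labels: list[str]
    n_replicates: int


def simulate_experiment(
    pop: ClonePopulation,
    cycles: Sequence[tuple[float, float, float]] = ((0.02, 0.9, 2.7), (0.02, 0.9, 2.7)),
    n_replicates: int = 4,
    seed: int = 0,
    time_labels: Sequence[str] | None = None,
) -> Experiment:
    """Branch ``n_replicates`` independent treatment lineages from ``pop``.

    ``cycles`` lists (surv_sensitive, surv_resistant, regrowth) per cycle.
    Returns populations for 1 + len(cycles) time points.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    labels = list(
        time_labels
        if time_labels is not None
        else ["baseline"] + [f"post_cycle{i + 1}" for i in range(len(cycles))]
    )
    if len(labels) != len(cycles) + 1:
        raise ValueError("need one time label per time point")
    rng = np.random.default_rng(seed)
    grid: list[list[ClonePopulation]] = [[pop] * n_replicates]
    lineages = [pop] * n_replicates
    for ci, (ss, sr, rg) in enumerate(cycles):
        nxt = []
        for r in range(n_replicates):
            child_seed = int(rng.integers(0, 2**31 - 1))
            nxt.append(
                apply_treatment_cycle(
                    lineages[r], ss, sr, rg, seed=child_seed,
                    time_label=labels[ci + 1],
                )
            )
        lineages = nxt
        grid.append(nxt)
    return Experiment(
        baseline=pop, populations=grid, time_labels=labels, n_replicates=n_replicates
    )
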