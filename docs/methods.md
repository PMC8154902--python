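# Methods

This note documents the models and procedures implemented in `clonotrace`,
the parameter choices that matter, and what the synthetic data generator
does and does not emulate.

## Barcode dictionary

A dictionary is an ordered set of unique, fixed-length (default 18 nt)
ACGT sequences generated by rejection sampling under two constraints:

- **minimum pairwise Hamming distance** (default 5). With separation
  `d_min ≥ 2k + 1`, any read barcode carrying at most `k` substitutions has
  a unique nearest dictionary entry, so `k = 2`-mismatch matching is
  provably unambiguous at `d_min = 5`. Real vendor dictionaries do not
  publish their separation; the default makes the error-correction
  guarantee explicit and testable.
- **no forbidden motif** (default: the spacer `CGAA`). A barcode containing
  the spacer inside itself could never be delimited by exact spacer
  matching — its reads would be systematically discarded — so a usable
  dictionary must exclude the motif. This is a property the deployed
  construct design must have had; the generator makes it explicit.

Random 18-mers violate either constraint rarely (expected pairwise distance
13.5; spacer-containing fraction ≈ 5.7%), so rejection sampling places
dictionaries of tens of thousands of entries quickly. An exhaustive
pairwise verification (`validate(full=True)`) is feasible for the sizes
used in tests.

## Synthetic population and treatment model

A population of `n` clones is labeled with distinct ordered barcode pairs
drawn uniformly from the dictionary square. Exactly
`round(f·n)` clones are flagged resistant (deterministic count, random
identity), so fraction-recovery tests are exact at the clone level.

**Clone sizes** are LogNormal(μ = 2.9, σ = 1.0), rounded and floored at 1 —
mean ≈ 30 cells per founder. The location is anchored to the study system
(9×10⁷ cells grown from 3.06×10⁶ barcoded founders ≈ 29 cells/founder at
banking); the spread matches the roughly exponential clone-size
distribution that single-founder growth noise produces (CV ≈ 1.3). The
true abundance distribution of a barcoded library is not published; this
is a modeling stand-in, not a claim about the data.

**A treatment cycle** is binomial thinning — each cell of a clone survives
independently with its class's probability (sensitive vs resistant) —
followed by multiplication by a regrowth factor and rounding. Extinct
clones stay in the record at count 0, so fate codes can be read off the
simulation truth. The default regrowth of 2.7 per recovery phase restores
a 40%-resistant population killed at (0.02, 0.9) to its original size,
matching the observed full recovery during drug holidays.

**Replicates are independent selection lineages.** The four samples per
time point model parallel wells: they share the founding population but
undergo independent binomial kills. This is the design logic of the
original experiment — clones recurring across independent replicates
indicate pre-existing resistance, whereas stochastic escapees appear in
one replicate only and are removed by the ≥2-replicates merge filter.

**Reads** follow the construct layout `bc1 + CGAA + bc2 + CGAA` (44 nt for
18-nt barcodes), sampled per clone proportionally to cell count. PCR
over-dispersion multiplies each clone's sampling weight by an independent
Gamma(1/d, d) factor (mean 1, variance d). Each base substitutes
independently at the configured rate; qualities default to uniform Q37,
with an option to stamp substituted positions with a low quality instead.
A configurable 5' offset supports constructs whose sequenced window does
not start at the first barcode base.

Not modeled: multiple integrations per cell, cell-cycle or spatial
structure, vial-level correlation between replicates, indels, or
context-dependent error profiles. Consequences for interpretation: the
zero-error recall and ≥99.9% recovery results certify the pipeline's
bookkeeping and error correction against substitution noise, not
robustness to indels (out of scope: matching is substitution-only by
design) or to amplification chimeras.

## Read extraction

Per read, in order:

1. **Quality rule.** Reads with more than 2 bases under Phred 25 are
   rejected; in surviving reads the (≤2) sub-threshold bases are replaced
   by `N`. Qualities themselves are never altered.
2. **Truncation rule.** Reads shorter than `2·bc_min + 2·|spacer|` (40 nt
   at defaults) cannot contain the construct and are rejected.
3. **First spacer.** The first *exact* occurrence of `CGAA` whose start
   index lies in the barcode-length window [16, 20] delimits `bc1`. Exact
   means exact: an `N` or substitution inside a spacer copy fails it —
   spacer-damaged reads are how the construct filter is supposed to work.
4. **Second spacer.** The next exact occurrence placing `bc2`'s length in
   the same window delimits `bc2`; everything after it is discarded, so
   appending bases beyond the second spacer can never change the result.
   Windowing the second search mirrors the first and prevents a spurious
   in-barcode `CGAA` (created by a sequencing error 16+ bases into `bc2`
   is impossible; earlier ones fall outside the window) from truncating
   the barcode.

Reasons are tallied per read (`too_many_low_quality`, `truncated`,
`no_spacer`, `barcode_length`) and always partition the input. The search
never backtracks: the first window-satisfying occurrence is used,
deterministically and in linear time.

## Dictionary matching

Stage 1 is exact lookup. Stage 2 computes Hamming distance (N = mismatch)
to every entry of matching length and accepts the unique entry at minimum
distance when that distance is ≤ 2. Ties and distances > 2 yield no-match:
the pipeline never fabricates a lineage. An intermediate ≤1-mismatch pass
would change nothing under unique-minimum acceptance and is omitted. A
clone is the *ordered* pair (bc1, bc2); both sides must match or the read
is excluded. Distinct raw sequences correcting to the same pair merge.

The batch matcher vectorizes the distance computation but is
property-tested to agree exactly with the single-sequence routine, which
in turn is tested against an exhaustive brute-force minimum-distance scan.

## Replicate merging and fate statistics

Concordance between replicates: Jaccard on clone sets, Pearson on
log2(count+1) over common clones (undefined — reported as such — below two
common clones or at zero variance). Merging keeps clones present in at
least 2 replicates and sums their counts; the sum preserves total read
mass and is scale-equivalent to the mean downstream, where only relative
abundances are used.

Fate codes are binary strings over the ordered time points (earliest
leftmost). All overlap statistics are computable from occurrence-group
counts alone:

- Jaccard between time points i and j: groups with `1` at both, over
  groups with `1` at either.
- **Elimination fraction**: clones present at i that are *never detected
  again* from j onward, over clones present at i. A clone absent at j but
  reappearing later (the `101` pattern) is not eliminated — with three
  time points it is one of the two patterns treated as technical
  artifacts.
- Artifact exclusion removes the physically implausible codes `010`
  (appears only mid-course) and `101` (vanishes and reappears); overlap
  statistics are computed *before* this exclusion, the order that
  reproduces the published arithmetic from the published group counts.
- Expansion between i < j uses within-sample relative abundance (depth
  cancels): existing clones must exceed the fold threshold strictly; new
  clones are defined purely by absence at i.
- Weighted prevalence at time t is each group's share of total read
  abundance at t.

Display precision follows the source conventions: Jaccard to two decimals,
percentages to the nearest percent.

## Single-cell preprocessing

Cell filtering applies four rules *in order* (the order is part of the
contract): bottom 5% by expressed genes, top 1% by total UMI, >15%
mitochondrial fraction, then |z| > 3 residuals from a smoothing spline of
log2 expressed genes vs log2 total UMI fitted on the survivors. Quantile
thresholds are inclusive and computed on the unfiltered sample; ties at a
threshold are kept. Genes expressed in fewer than 1% of cells are then
removed (exactly 1% is kept).

**Normalization** adapts median-of-ratios to sparsity: the per-gene
reference is the geometric mean over *expressing* cells only, and each
cell's size factor is the median ratio over the genes it expresses (even
medians use the midpoint). Values are log2(x/s_c + 1), so zeros are
preserved exactly. Size factors are strictly positive by construction; a
cell with no usable ratio is a hard error naming the cell.

One subtlety is worth stating precisely: scaling one cell's counts by an
integer factor scales its size factor by exactly that factor *given a
fixed reference profile*, because every ratio scales uniformly and the
median follows. When the reference is recomputed from the scaled matrix,
each gene's geometric mean shifts by `scale^(1/m_g)` (m_g = number of
expressing cells), so the size factor lands in
`[scale^(1-1/m_min), scale] · s_c` rather than exactly `scale · s_c`. The
API therefore accepts an optional precomputed reference (also the natural
way to normalize treated samples against a baseline reference), and the
test suite asserts the exact property under a fixed reference and the
provable bound under recomputation.

**HVG selection** iteratively fits a smoothing spline of log2 variance vs
log2 mean over retained genes, standardizes residuals, removes |z| > 3
outliers, and accumulates the positive-residual ones as highly variable;
iteration stops when no outliers remain (each round removes at least one
gene, so termination is bounded by the gene count). Negative-residual
outliers are removed from the fit but not reported.

**Smoothing splines** (both uses) are cubic splines with a
generalized-cross-validation-selected penalty; tied abscissae are
collapsed to weighted means before fitting. A fixed penalty can be
supplied instead (`spline_lam`) where reproducibility across runs of
different sizes matters. Degenerate support (fewer than 4 distinct x
values, or constant predictor) skips the cell-outlier rule with a warning
rather than failing the whole filter.

**Knee point**: for a decreasing criterion over k = 1..K, the chosen k
maximizes the perpendicular distance to the chord from (1, v₁) to (K,
v_K); ties break toward smaller k, a constant series returns k = 1 with a
warning. The argmax is invariant under affine transforms of the criterion
because the chord normalization does not depend on k.

Known limitations: a variance outlier sitting at the extreme edge of the
mean range can bend a GCV spline through itself and escape detection
(boundary flexibility); the planted-signal tests place signal in the
interior, and real analyses should treat edge genes with care. The
cell-filter fraction removed is data-dependent and not a fixed target.

## Problem sizes and determinism

Default test and acceptance runs use a 1,000-entry dictionary, 2,000
clones, 4 replicates × 3 time points × 200,000 reads at 0.5%/base error —
a faithfully proportioned, smaller instance of the original design chosen
to keep a complete FASTQ round trip fast on a single CPU; the 20-seed
recovery studies use count-level multinomial sampling (`sample_counts`),
which is exactly equivalent to emit→extract→match at zero error rate.

Every stochastic routine takes an explicit seed and is reproducible
byte-for-byte (FASTQ output included). Derived seeds are spawned from the
caller's seed, so a single integer reproduces an entire experiment.

## Recovery of the resistant fraction: what holds and what does not

With complete sensitive kill (survival 0) the abundance-weighted baseline
share of final-survivor codes is an unbiased estimate of the planted
resistant fraction; over 20 seeds it recovers 0.40 within ±0.02 and the
final-sample survivor set is exactly a subset of the resistant clones.

With *partial* sensitive kill (survival 0.02 per cycle) the estimator is
systematically inflated by ~0.03–0.05: a clone of several hundred cells
survives a 2% kill with near certainty in every replicate (1 − 0.98^c), so
the largest sensitive clones persist through both cycles in ≥2 replicates
and their (large) baseline mass is attributed to the survivor codes. This
is a real property of incomplete kill on heavy-tailed clone sizes, not a
pipeline artifact; the replicate-consensus filter removes stochastic
escape, which is a different phenomenon from deterministic persistence of
large clones. Both regimes are computed and reported by the acceptance
script.
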