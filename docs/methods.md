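# Methods

## Model and procedure

A cohort of `n` experimental units carries `p` numeric baseline covariates
and, optionally, one categorical physical marker per unit. A *block design*
declares block sizes `b_1..b_k` (summing to at most `n`; unassigned units
form a distinguished leftover pool), non-negative per-covariate weights
(default 1), display decimals (default 2; reporting only, never
computation), optional per-block subgroup (cage) sizes, and a leaderboard
capacity (default 100).

One *block set* is a division of the cohort into the designed blocks.
Blocks store unordered membership; equal-size blocks are unlabeled
(interchangeable). The leftover pool is never interchangeable with a block,
even at equal size — with that convention the number of distinct block sets
is exactly

    n! / (Π_j b_j! · r!) / Π_s m_s!

with `r` the leftover count and `m_s` the number of blocks of size `s`
(16 units in two blocks of 8 give C(16,8)/2 = 6435).

The search engine repeatedly draws a uniform permutation of the cohort
(numpy's Fisher–Yates) and slices it into the blocks. This is uniform over
labeled partitions, and every unlabeled partition is covered by the same
number of labeled ones (the fiber size `Π_s m_s!` is constant), so the draw
is uniform over unlabeled block sets. Each draw is canonicalized — ids
sorted within blocks, blocks ordered by size then smallest member (disjoint
blocks make the minimum a complete lexicographic proxy), leftover as a
distinguished terminal segment — and a registry of canonical keys rejects
duplicates, so each unique set is scored once. Duplicates count toward
attempts but not toward the target; the run stops at the requested number or
fraction of unique sets (capped at the design's total) or at a safety cap of
50× the target (near exhaustion the duplicate-rejection scheme slows down
coupon-collector-style, so an uncapped exhaustive run is unbounded in the
tail).

### Balance score

For covariate `i`, per block: arithmetic mean and coefficient of variation
CV = SD/mean; over all blocked units: SD_blockset,i. The score is

    Σ_i ( ΔMean_max,i / SD_blockset,i + ΔCV_max,i ) · w_i

with ΔMean_max / ΔCV_max the max−min over blocks. Lower is better; the
score is 0 iff every covariate has identical block means and CVs, and is
invariant under positive rescaling of any covariate (both terms are
dimensionless).

Numerical conventions, all configurable on the design and recorded in every
report:

* **Sample SD (n−1)** for block SDs, CVs and the block-set SD — the
  convention of the spreadsheet tools cohort tables are pasted from; the
  population-SD variant is a switch.
* **CV as a proportion**, not a percentage. The score *adds* ΔCV to a
  normalized mean difference that is typically O(1); a percentage CV would
  dominate the sum ~100-fold, defeating the evident intent that the two
  terms be comparable. The percentage variant is a switch.
* A **singleton block** has SD (hence CV) defined as 0.
* A **constant covariate** (zero block-set SD) contributes a zero mean
  term: it cannot distinguish any division.
* A **block mean of exactly 0** makes the CV undefined and is a hard
  error; negative block means are allowed with a logged warning (CVs are
  then signed). Baseline measurements are in practice positive.
* The block-set SD covers **blocked units only**: leftover units are not
  part of the block set.

The engine scores accepted draws in vectorized batches; `rank_block_set`
is the scalar reference path, and the two agree to < 1e−12 (asserted over a
full 6,435-set enumeration against a third, pure-Python oracle).

### Leaderboard

Bounded, sorted ascending by (score, discovery order): among equal scores
the earlier-discovered set ranks first — deterministic under a fixed seed —
and the worst entry is evicted on overflow. Marker modifications are
reported beside the score and never enter it.

### Marker-aware subgrouping

Re-housing a block into cages requires within-cage marker uniqueness.
Maximizing the number of animals that keep their marker subject to cage
sizes and within-cage distinctness is a capacitated bipartite matching:
source → label (capacity = copies present) → cage (capacity 1 per
label/cage pair) → sink (capacity = cage size). Solved exactly with
networkx `maximum_flow`; modifications = block size − max kept. The
exhaustive-search oracle over all divisions confirms optimality on
thousands of random blocks. A useful exact floor: a label with `c` copies
and `G` cages forces at least `max(0, c − G)` modifications, summed over
labels; the floor is attained whenever every cage could hold one copy of
each distinct label present, but tighter cages can push the optimum above
it (e.g. labels {A:1, B:3, C:2} in cages of sizes 1, 1, 4 need one
modification, not zero). Without markers, subgroups are drawn uniformly at
random and modifications are reported as absent.

### Allocation

A uniformly random bijection between blocks and the user's group labels,
seeded. Unequal block sizes are allocated identically, with a logged
warning that size/label pairings are random.

## Combinatorics

Counts use exact integer arithmetic; scientific rendering rounds half-even
at 2 significant figures. The probability that a uniform
without-replacement search of `s` of `N` sets contains none of a designated
best `k` is hypergeometric, `C(N−k, s)/C(N, s)`, evaluated as an exact
rational: for N = 6435, s = 3218 (50% coverage, interpreted as ⌈N/2⌉),
k = 10 it is 9.68·10⁻⁴.

## Validation experiments

**Allocation randomness.** Two independent simulations of 10,000 unique
block sets; per block, the per-unit allocation counts are accumulated and
the two simulations' counts correlated (Pearson, scipy). Under a correct
uniform process each count is Binomial(10 000, b/n): for four blocks of 8
from 32 units the per-block mean is exactly 2,500 by conservation and the
across-unit SD concentrates near √(10⁴·¼·¾) ≈ 43.3, with cross-simulation
R² small and p-values mostly non-significant. The classical description of
this experiment ("24 units, 4 blocks of n = 8") is arithmetically
inconsistent (32 slots); the default preset resolves it as 32 units × 4
blocks of 8 — which matches both the block size and the 2,500 expectation —
with 24 units × 4 blocks of 6 available as the alternative reading. Both
give per-block allocation probability 1/4.

**Search coverage.** The full enumeration of the 16-unit design is scored
once (the oracle: global minimum, and the mean score over all sets as the
*fully random baseline* — the expected score of a single random division,
which makes the fractional reduction

    100% · (baseline − best found) / (baseline − global minimum)

equal 100% at exhaustive search by construction; the baseline itself is not
externally defined, and the mean of one random draw is the canonical
choice). For each coverage fraction `f` in a log-spaced grid that always
contains 0.093% and 6.2%, 256 independent engine runs target ⌈f·6435⌉
unique sets; lowest score, attempts and reduction are recorded. Attempts
track the systematic count ⌈f·N⌉ within 2% for f ≤ 1% (expected duplicate
excess ≈ k²/2N) and exceed it materially only at high coverage.

**Top-k discovery.** ≥ 2,000 engine runs at 50% coverage; the fraction that
discovers none of the 10 globally best sets is compared with the
hypergeometric value within 3σ binomial error.

## Synthetic cohort generator

Tests and examples run on generated cohorts: covariates are independent
normals — matching the score's own assumption of normally distributed
continuous covariates — with per-covariate (mean, SD) defaults
(4.4, 1.7), (14.6, 2.1), (1.2, 0.35), chosen to match the scale of the
published worked example's block summaries; markers default to eight
ear-mark codes used twice each (with at most two copies of a label per
block and two cages per block, a zero-modification division always exists,
consistent with the worked example's reported zero). A correlation knob
exists (default 0). The generator does **not** emulate skewed, binary or
categorical covariates, missing values (a hard error by design), or
correlated marker/covariate structure — passing tests therefore demonstrate
correctness of the search and scoring machinery, not robustness of the
balance score to non-normal data, which is a known limitation of the score
itself.

The original worked-example table is not redistributed here; when a user
supplies it (or any cohort TSV) via `load_worked_example(path)`, coverage
checks switch from property-based to exact mode automatically. Quantities
that depend on those exact covariate values (the published 51% ± 19% at
0.093% and 90% ± 5% at 6.2% coverage) are reproduced only in that mode; on
the default synthetic cohort the same experiment gives 43% ± 19% and
88% ± 7 — the same qualitative shape.

## Problem sizes and determinism

Default validation sizes — 6,435-set enumerations, 10,000-set randomness
simulations, 256 replicates per coverage point, 2,000 top-k runs, 10,000
random blocks for the re-marking oracle — run in seconds to ~1 minute each
on a single CPU. All randomness flows through numpy Generators seeded from
user-visible integers (replicate seeds are spawned from a SeedSequence);
reruns with the same seed reproduce leaderboards, curves and allocations
bit-for-bit. Engine results are deterministic given the seed at the default
internal batch size.

## Known limitations

* The balance score presumes continuous, roughly normal covariates with
  nonzero (in practice positive) block means; categorical or stratified
  covariates are out of scope.
* Only the count of marker modifications is optimized; choosing which new
  marker to apply is left to the user.
* Systematic (lexicographic) enumeration exists only as a test oracle, not
  a user-facing search mode: systematically creating a *subset* of sets
  would bias the search.
* No parallel workers; the vectorized sampler covers practical sizes.
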