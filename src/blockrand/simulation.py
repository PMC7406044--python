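"""Monte-Carlo validation experiments for the block-set engine.

Two experiments probe the engine the way the original validation did:

* a *randomness* experiment — generate many block sets twice and check that
  per-unit allocation counts per block behave binomially and are
  uncorrelated between the two independent simulations;
* a *coverage* experiment — score the full enumeration once (the oracle),
  then measure how quickly random search closes the gap between the
  expected score of a single random block set (the fully random baseline)
  and the global minimum, as a function of the fraction of all unique sets
  created, and how many attempts the duplicate-rejecting random search
  needs compared with a hypothetical systematic enumeration.

A third check estimates how often a partial search misses all of the top-k
best-balanced sets, for comparison with the closed-form hypergeometric
probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import ranking
from .combinatorics import count_unique_block_sets, top_k_miss_probability
from .fixtures import enumerate_index_partitions
from .generator import StopCriteria, UniqueSampler, run_engine
from .model import BlockDesign, CohortTable, DesignError

#: Resolutions of the ambiguous four-equal-blocks validation design:
#: 32 units x 4 blocks of 8 (default), or 24 units x 4 blocks of 6.
RANDOMNESS_PRESETS = {
    "32x4of8": (32, (8, 8, 8, 8)),
    "24x4of6": (24, (6, 6, 6, 6)),
}


@dataclass
class RandomnessResult:
    """Allocation-count matrices of two independent simulations plus
    per-block cross-simulation correlation statistics."""

    counts1: np.ndarray  # (n_units, n_blocks)
    counts2: np.ndarray
    n_sets: int
    block_sizes: tuple[int, ...]
    per_block: pd.DataFrame  # block, r, r_squared, p_value

    @property
    def mean_allocations(self) -> np.ndarray:
        """Mean per-unit allocation count per block, first simulation."""
        return self.counts1.mean(axis=0)

    @property
    def sd_allocations(self) -> np.ndarray:
        return self.counts1.std(axis=0, ddof=1)


def _allocation_counts(
    n_units: int,
    block_sizes: Sequence[int],
    n_sets: int,
    rng,
    batch_size: int,
) -> np.ndarray:
    sampler = UniqueSampler(n_units, tuple(block_sizes), rng=rng, batch_size=batch_size)
    counts = np.zeros((n_units, len(block_sizes)), dtype=np.int64)
    offsets = np.cumsum([0] + list(block_sizes))
    total = count_unique_block_sets(n_units, block_sizes).total_unique
    max_attempts = StopCriteria(target_unique=n_sets).effective_max_attempts(n_sets)
    if n_sets > total:
        raise DesignError(f"cannot create {n_sets} unique sets; only {total} exist")
    for _canon, raw in sampler.take(n_sets, max_attempts):
        for j in range(len(block_sizes)):
            np.add.at(counts[:, j], raw[:, offsets[j] : offsets[j + 1]].ravel(), 1)
    return counts


def randomness_experiment(
    n_units: int = 32,
    block_sizes: Sequence[int] = (8, 8, 8, 8),
    n_sets: int = 10_000,
    seed_pair: tuple[int, int] = (0, 1),
    *,
    batch_size: int = 4096,
) -> RandomnessResult:
    """Run two independent ``n_sets``-set simulations and correlate the
    per-unit allocation counts per block between them.

    Requires a full-coverage design (every unit allocated in every set), so
    each row of a count matrix sums to ``n_sets`` exactly and each block's
    mean per-unit count is ``n_sets * b / n_units`` by conservation.
    """
    sizes = tuple(int(b) for b in block_sizes)
    if sum(sizes) != n_units:
        raise DesignError(
            "the randomness experiment needs a full-coverage design "
            f"(sizes {sizes} vs {n_units} units)"
        )
    c1 = _allocation_counts(n_units, sizes, n_sets, seed_pair[0], batch_size)
    c2 = _allocation_counts(n_units, sizes, n_sets, seed_pair[1], batch_size)
    rows = []
    for j in range(len(sizes)):
        r, p = sps.pearsonr(c1[:, j], c2[:, j])
        rows.append(
            {"block": j + 1, "r": r, "r_squared": r * r, "p_value": p}
        )
    return RandomnessResult(
        counts1=c1,
        counts2=c2,
        n_sets=n_sets,
        block_sizes=sizes,
        per_block=pd.DataFrame(rows),
    )


@dataclass
class CoverageBaseline:
    """Exhaustive-enumeration oracle for one cohort/design."""

    total_unique: int
    scores: np.ndarray  # every unique set's ranking value
    global_min: float = field(init=False)
    baseline_mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.global_min = float(self.scores.min())
        self.baseline_mean = float(self.scores.mean())


@dataclass
class CoverageCurvePoint:
    """Search outcomes at one coverage fraction over many replicates.

    ``reductions`` is the fractional reduction in score achieved relative to
    the fully random baseline, in percent: 100 * (baseline - best) /
    (baseline - global_min).
    """

    fraction: float
    target_unique: int
    best: np.ndarray  # lowest ranking value per replicate
    attempts: np.ndarray
    reductions: np.ndarray

    @property
    def replicates(self) -> int:
        return len(self.best)

    def as_row(self) -> dict:
        return {
            "fraction": self.fraction,
            "target_unique": self.target_unique,
            "replicates": self.replicates,
            "best_mean": self.best.mean(),
            "best_sd": self.best.std(ddof=1),
            "attempts_mean": self.attempts.mean(),
            "attempts_sd": self.attempts.std(ddof=1),
            "reduction_mean": self.reductions.mean(),
            "reduction_sd": self.reductions.std(ddof=1),
        }


#: Log-spaced default grid; includes the two headline fractions 0.093% and 6.2%.
DEFAULT_FRACTIONS: tuple[float, ...] = (
    0.00093,
    0.0031,
    0.01,
    0.031,
    0.062,
    0.125,
    0.25,
    0.5,
    1.0,
)


def score_full_enumeration(
    cohort: CohortTable,
    block_sizes: Sequence[int],
    *,
    weights: Optional[Sequence[float]] = None,
    cap: int = 10**6,
    sample_sd: bool = True,
    cv_percent: bool = False,
) -> CoverageBaseline:
    """Score every unique block set once (exact oracle)."""
    sizes = tuple(sorted(int(b) for b in block_sizes))
    parts = [
        np.concatenate([np.array(b) for b in part])
        for part in enumerate_index_partitions(cohort.n_units, sizes, cap=cap)
    ]
    flat = np.stack(parts)
    X = cohort.covariate_matrix()
    w = list(weights) if weights is not None else [1.0] * cohort.n_covariates
    scores = ranking.batch_ranking_values(
        flat, sizes, X, w, sample_sd=sample_sd, cv_percent=cv_percent
    )
    return CoverageBaseline(total_unique=len(parts), scores=scores)


def coverage_experiment(
    cohort: CohortTable,
    block_sizes: Sequence[int],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    replicates: int = 256,
    seed: Optional[int] = None,
    *,
    cap: int = 10**6,
    weights: Optional[Sequence[float]] = None,
) -> tuple[list[CoverageCurvePoint], CoverageBaseline]:
    """Best-found score, attempts and fractional reduction vs coverage.

    For each fraction ``f`` the engine is run ``replicates`` times targeting
    ``ceil(f * total)`` unique sets; every run reports its lowest ranking
    value and total attempts.  Reduction is expressed against the fully
    random baseline (the mean score over the full enumeration).
    """
    baseline = score_full_enumeration(cohort, block_sizes, weights=weights, cap=cap)
    total = baseline.total_unique
    design = BlockDesign(
        block_sizes=tuple(block_sizes),
        weights=tuple(weights) if weights is not None else None,
        leaderboard_capacity=1,
    )
    root = np.random.SeedSequence(seed)
    points = []
    denom = baseline.baseline_mean - baseline.global_min
    for frac, ss in zip(fractions, root.spawn(len(fractions))):
        if not 0 < frac <= 1:
            raise DesignError(f"fractions must be in (0, 1], got {frac}")
        target = max(1, math.ceil(frac * total))
        best = np.empty(replicates)
        attempts = np.empty(replicates, dtype=np.int64)
        for rep, child in enumerate(ss.spawn(replicates)):
            board, stats = run_engine(
                cohort,
                design,
                StopCriteria(target_unique=target),
                rng=np.random.default_rng(child),
            )
            best[rep] = board.best_score
            attempts[rep] = stats.attempts
        reductions = 100.0 * (baseline.baseline_mean - best) / denom
        points.append(
            CoverageCurvePoint(
                fraction=frac,
                target_unique=target,
                best=best,
                attempts=attempts,
                reductions=reductions,
            )
        )
    return points, baseline


def coverage_table(points: Sequence[CoverageCurvePoint]) -> pd.DataFrame:
    """Mean±SD summary of a coverage curve, one row per fraction."""
    return pd.DataFrame([p.as_row() for p in points])


def attempts_vs_systematic(
    points: Sequence[CoverageCurvePoint], total_unique: int, tolerance: float = 0.05
) -> pd.DataFrame:
    """Compare mean attempts of the random search with the systematic count
    ``ceil(f * total)``; flags fractions whose mean attempts exceed the
    systematic count by more than ``tolerance`` (default 5%)."""
    rows = []
    for p in points:
        systematic = math.ceil(p.fraction * total_unique)
        mean_attempts = float(p.attempts.mean())
        rows.append(
            {
                "fraction": p.fraction,
                "systematic": systematic,
                "attempts_mean": mean_attempts,
                "excess_ratio": mean_attempts / systematic,
                "material_excess": mean_attempts > (1 + tolerance) * systematic,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MissRateResult:
    """Empirical vs hypergeometric probability of discovering none of the
    top-k best-balanced sets in a partial search."""

    replicates: int
    misses: int
    fraction: float
    k: int
    target_unique: int
    expected: float

    @property
    def empirical(self) -> float:
        return self.misses / self.replicates


def top_k_discovery_experiment(
    cohort: CohortTable,
    block_sizes: Sequence[int],
    fraction: float = 0.5,
    k: int = 10,
    replicates: int = 2000,
    seed: Optional[int] = None,
    *,
    cap: int = 10**6,
) -> MissRateResult:
    """Fraction of engine runs at partial coverage that fail to discover any
    of the k globally best-balanced block sets."""
    baseline = score_full_enumeration(cohort, block_sizes, cap=cap)
    total = baseline.total_unique
    target = max(1, math.ceil(fraction * total))
    order = np.argsort(baseline.scores, kind="stable")[:k]

    sizes = tuple(sorted(int(b) for b in block_sizes))
    probe = UniqueSampler(cohort.n_units, sizes)
    parts = list(enumerate_index_partitions(cohort.n_units, sizes, cap=cap))
    top_rows = np.stack(
        [np.concatenate([np.array(b) for b in parts[i]]) for i in order]
    )
    top_keys = set(probe._keys(top_rows))

    root = np.random.SeedSequence(seed)
    misses = 0
    max_attempts = StopCriteria(target_unique=target).effective_max_attempts(target)
    for child in root.spawn(replicates):
        sampler = UniqueSampler(
            cohort.n_units, sizes, rng=np.random.default_rng(child)
        )
        for _ in sampler.take(target, max_attempts):
            pass
        if not (sampler.seen & top_keys):
            misses += 1
    return MissRateResult(
        replicates=replicates,
        misses=misses,
        fraction=fraction,
        k=k,
        target_unique=target,
        expected=top_k_miss_probability(total, target, k),
    )


def plot_randomness(result: RandomnessResult, path=None):
    """Scatter of per-unit counts, simulation 1 vs 2, one panel per block."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(result.block_sizes)
    fig, axes = plt.subplots(1, k, figsize=(3 * k, 3), squeeze=False)
    for j, ax in enumerate(axes[0]):
        ax.scatter(result.counts1[:, j], result.counts2[:, j], s=12)
        row = result.per_block.iloc[j]
        ax.set_title(f"block {j + 1}: R²={row.r_squared:.3f}, p={row.p_value:.2f}")
        ax.set_xlabel("simulation 1")
        if j == 0:
            ax.set_ylabel("simulation 2")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_coverage(points: Sequence[CoverageCurvePoint], total_unique: int, path=None):
    """Best score and attempts vs coverage fraction (log x)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = coverage_table(points)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.2))
    ax1.errorbar(df.fraction, df.best_mean, yerr=df.best_sd, marker="o")
    ax1.set_xscale("log")
    ax1.set_xlabel("fraction of unique block sets created")
    ax1.set_ylabel("lowest ranking value")
    ax2.errorbar(df.fraction, df.attempts_mean, yerr=df.attempts_sd, marker="o")
    ax2.plot(
        df.fraction,
        [math.ceil(f * total_unique) for f in df.fraction],
        linestyle="--",
        label="systematic",
    )
    ax2.set_xscale("log")
    ax2.set_yscale("log")
    ax2.set_xlabel("fraction of unique block sets created")
    ax2.set_ylabel("block sets created (attempts)")
    ax2.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
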