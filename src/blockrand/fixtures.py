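"""Synthetic cohort generation and exhaustive block-set enumeration.

The generator emulates the worked example that drives validation: a small
cohort of dummy experimental units with independent, normally distributed
continuous covariates (the balance metric's stated assumption) and a
multiset of physical-marker labels.  The default 16-unit preset mirrors the
scale of that example: three covariates around (4.4, 1.7), (14.6, 2.1) and
(1.2, 0.35) mean/SD — think body weight-like, lipid-like, ratio-like
baseline measurements — and eight ear-mark codes used twice each.

Exhaustive enumeration of every unique block set is the test oracle for the
random engine; it is deliberately not a user-facing search mode (systematic
sampling of a subset of partitions would introduce systematic bias).
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterator, Optional, Sequence

import numpy as np

from .combinatorics import count_unique_block_sets
from .io import ColumnMap, read_cohort
from .model import BlockRandError, BlockSet, CohortError, CohortTable, ExperimentalUnit

DEFAULT_COVARIATE_SPECS: tuple[tuple[float, float], ...] = (
    (4.4, 1.7),
    (14.6, 2.1),
    (1.2, 0.35),
)
#: Eight ear-mark codes, two animals each (N = none, L/R = left/right clip, ...).
DEFAULT_MARKER_LABELS: tuple[str, ...] = tuple(
    code for code in ("N", "L", "R", "B", "LL", "RR", "LR", "RL") for _ in range(2)
)


class EnumerationCapError(BlockRandError):
    """The design has more unique block sets than the enumeration cap."""


def generate_cohort(
    n_units: int = 16,
    covariate_specs: Sequence[tuple[float, float]] = DEFAULT_COVARIATE_SPECS,
    marker_labels: Sequence[str] = DEFAULT_MARKER_LABELS,
    rng=None,
    *,
    covariate_names: Optional[Sequence[str]] = None,
    correlation: float = 0.0,
) -> CohortTable:
    """Draw a synthetic cohort with normal covariates and shuffled markers.

    Covariates are independent normals with the given (mean, sd) per
    covariate; ``correlation`` optionally imposes a common pairwise
    correlation between them (default 0, i.e. independent).  Markers are the
    given label multiset assigned in shuffled order; pass an empty sequence
    for an unmarked cohort.  Deterministic under a seeded ``rng``.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    specs = [(float(m), float(s)) for m, s in covariate_specs]
    p = len(specs)
    if marker_labels and len(marker_labels) != n_units:
        raise CohortError(
            f"{len(marker_labels)} marker labels for {n_units} units "
            "(give one per unit, or none)"
        )
    if covariate_names is None:
        covariate_names = tuple(f"cov{i + 1}" for i in range(p))
    elif len(covariate_names) != p:
        raise CohortError(f"{len(covariate_names)} names for {p} covariates")

    if p:
        if correlation:
            R = np.full((p, p), float(correlation))
            np.fill_diagonal(R, 1.0)
            z = gen.multivariate_normal(np.zeros(p), R, size=n_units)
        else:
            z = gen.standard_normal((n_units, p))
        means = np.array([m for m, _ in specs])
        sds = np.array([s for _, s in specs])
        values = means + sds * z
    else:
        values = np.zeros((n_units, 0))

    markers: list[Optional[str]] = [None] * n_units
    if marker_labels:
        order = gen.permutation(n_units)
        shuffled = [str(marker_labels[j]) for j in order]
        markers = shuffled

    width = len(str(n_units))
    units = tuple(
        ExperimentalUnit(
            id=f"m{k + 1:0{width}d}",
            covariates=tuple(values[k]),
            marker=markers[k],
        )
        for k in range(n_units)
    )
    return CohortTable(covariate_names=tuple(covariate_names), units=units)


def s1_like_cohort(seed: int = 0) -> CohortTable:
    """The default 16-unit, 3-covariate, marked synthetic cohort."""
    return generate_cohort(rng=np.random.default_rng(seed))


def load_worked_example(path=None, seed: int = 0) -> tuple[CohortTable, bool]:
    """Load a user-supplied worked-example cohort TSV, or fall back to the
    synthetic preset.

    Returns ``(cohort, exact_mode)``: ``exact_mode`` is True when a real
    table was loaded, switching downstream checks from property-based to
    exact comparisons.  The TSV must have a header with the id in the first
    column, covariates next, and an optional trailing marker column.
    """
    if path is None:
        return s1_like_cohort(seed), False
    import pandas as pd

    header = list(pd.read_csv(path, sep="\t", nrows=0).columns)
    if len(header) < 2:
        raise CohortError(f"{path}: expected id plus covariate columns")
    probe = pd.read_csv(path, sep="\t", dtype=str)
    last = header[-1]

    def _numeric(col: str) -> bool:
        try:
            probe[col].str.replace(",", ".", regex=False).astype(float)
            return True
        except ValueError:
            return False

    marker_col = None if _numeric(last) else last
    cov_cols = header[1 : -1 if marker_col else len(header)]
    colmap = ColumnMap(
        id_column=header[0],
        covariate_columns=tuple(cov_cols),
        marker_column=marker_col,
    )
    return read_cohort(path, colmap, delimiter="\t"), True


def enumerate_index_partitions(
    n_units: int, block_sizes: Sequence[int], cap: int = 10**6
) -> Iterator[tuple[tuple[int, ...], ...]]:
    """Yield every unique unlabeled partition of ``range(n_units)`` into
    blocks of the given sizes, each exactly once, as tuples of sorted index
    tuples in canonical order (ascending size, then smallest member).

    Within every run of equal-size blocks the smallest members must
    increase, which picks exactly one representative per unlabeled set.
    """
    total = count_unique_block_sets(n_units, block_sizes).total_unique
    if total > cap:
        raise EnumerationCapError(
            f"{total} unique block sets exceed the enumeration cap {cap}"
        )
    sizes = sorted(int(b) for b in block_sizes)

    def rec(pool: tuple[int, ...], j: int, prev_min: int):
        if j == len(sizes):
            yield ()
            return
        size = sizes[j]
        min_constraint = prev_min if j > 0 and sizes[j - 1] == size else -1
        for block in combinations(pool, size):
            if block[0] <= min_constraint:
                continue
            rest = tuple(x for x in pool if x not in block)
            for tail in rec(rest, j + 1, block[0]):
                yield (block, *tail)

    yield from rec(tuple(range(n_units)), 0, -1)


def enumerate_all_block_sets(
    cohort: CohortTable, block_sizes: Sequence[int], cap: int = 10**6
) -> Iterator[BlockSet]:
    """Yield every unique block set of the cohort exactly once."""
    ids = cohort.ids
    all_idx = set(range(cohort.n_units))
    for part in enumerate_index_partitions(cohort.n_units, block_sizes, cap=cap):
        blocked = set()
        blocks = []
        for blk in part:
            blocks.append(frozenset(ids[i] for i in blk))
            blocked.update(blk)
        leftover = frozenset(ids[i] for i in all_idx - blocked)
        yield BlockSet(blocks=tuple(blocks), leftover=leftover)
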