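"""Domain types for covariate-balanced block randomization.

The central objects are a cohort of experimental units (animals, dishes,
volunteers) carrying numeric baseline covariates and an optional physical
marker (e.g. an ear-mark code), and a *block design*: the number and sizes of
the blocks the cohort is to be divided into, per-covariate weights for the
balance score, and optional within-block subgroup (cage) sizes.

A *block set* is one complete division of the cohort into the designed
blocks.  Blocks of equal size are unlabeled (interchangeable); units not
assigned to any block form an explicit leftover pool which is never
interchangeable with a block, even when equal in size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Mapping, Optional, Sequence, Union

import numpy as np

UnitId = Union[str, int]


class BlockRandError(Exception):
    """Base class for all errors raised by this package."""


class CohortError(BlockRandError):
    """Invalid cohort table (duplicate ids, ragged covariates, ...)."""


class DesignError(BlockRandError):
    """Invalid block design or design/cohort mismatch."""


class RankingError(BlockRandError):
    """Balance score cannot be computed."""


class UndefinedCVError(RankingError):
    """A block mean is exactly zero, so the coefficient of variation is undefined."""


class MarkerError(BlockRandError):
    """Invalid subgroup division or missing markers."""


class AllocationError(BlockRandError):
    """Invalid block-to-group allocation request."""


@dataclass(frozen=True)
class ExperimentalUnit:
    """One independently randomizable subject.

    Parameters
    ----------
    id:
        Unique label within the cohort (text or integer).
    covariates:
        Ordered numeric baseline measurements, one per declared covariate.
    marker:
        Optional categorical physical marker (e.g. ear-mark code).
    """

    id: UnitId
    covariates: tuple[float, ...]
    marker: Optional[str] = None

    def __post_init__(self) -> None:
        if self.id is None or (isinstance(self.id, str) and not self.id.strip()):
            raise CohortError("unit id must be non-empty")
        covs = tuple(float(c) for c in self.covariates)
        if any(not np.isfinite(c) for c in covs):
            raise CohortError(
                f"unit {self.id!r}: covariates must be finite numbers "
                "(missing values are not supported)"
            )
        object.__setattr__(self, "covariates", covs)


@dataclass(frozen=True)
class CohortTable:
    """An ordered collection of experimental units sharing covariate names."""

    covariate_names: tuple[str, ...]
    units: tuple[ExperimentalUnit, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        object.__setattr__(self, "units", tuple(self.units))
        p = len(self.covariate_names)
        seen: set[str] = set()
        n_marked = 0
        for u in self.units:
            key = str(u.id)
            if key in seen:
                raise CohortError(f"duplicate unit id {u.id!r}")
            seen.add(key)
            if len(u.covariates) != p:
                raise CohortError(
                    f"unit {u.id!r} has {len(u.covariates)} covariates, expected {p}"
                )
            n_marked += u.marker is not None
        if n_marked not in (0, len(self.units)):
            raise CohortError(
                "markers must be given for every unit or for none "
                f"({n_marked}/{len(self.units)} present)"
            )

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    @property
    def has_markers(self) -> bool:
        return bool(self.units) and self.units[0].marker is not None

    @cached_property
    def ids(self) -> tuple[UnitId, ...]:
        return tuple(u.id for u in self.units)

    @cached_property
    def index(self) -> Mapping[UnitId, int]:
        """Unit id -> position in the cohort."""
        return {u.id: i for i, u in enumerate(self.units)}

    @cached_property
    def markers(self) -> tuple[Optional[str], ...]:
        return tuple(u.marker for u in self.units)

    def covariate_matrix(self) -> np.ndarray:
        """(n_units, n_covariates) float array, cohort order."""
        return np.array([u.covariates for u in self.units], dtype=float).reshape(
            self.n_units, self.n_covariates
        )

    def subset_values(self, ids: Sequence[UnitId], covariate: int) -> np.ndarray:
        idx = [self.index[i] for i in ids]
        return self.covariate_matrix()[idx, covariate]


@dataclass(frozen=True)
class BlockDesign:
    """Sizes, weights and options describing how the cohort is divided.

    ``weights`` and ``decimals`` may be left ``None`` and are resolved to
    all-ones / all-2 by :func:`validate_design` once the cohort (and hence the
    covariate count) is known.  ``decimals`` controls report rounding only and
    never affects computation.  ``subgroup_sizes`` is either one flat tuple
    applied to every block, or one tuple per block; sizes must sum to the
    block size.
    """

    block_sizes: tuple[int, ...]
    weights: Optional[tuple[float, ...]] = None
    decimals: Optional[tuple[int, ...]] = None
    subgroup_sizes: Optional[tuple] = None
    leaderboard_capacity: int = 100
    sample_sd: bool = True  # n-1 denominator for SDs and CVs
    cv_percent: bool = False  # CV as a proportion by default
    allow_random_subgroups: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(int(b) for b in self.block_sizes))
        if self.weights is not None:
            object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if self.decimals is not None:
            object.__setattr__(self, "decimals", tuple(int(d) for d in self.decimals))

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)

    def subgroup_spec(self) -> Optional[tuple[tuple[int, ...], ...]]:
        """Per-block subgroup sizes, or None when no subgroups are requested."""
        if self.subgroup_sizes is None:
            return None
        sg = tuple(self.subgroup_sizes)
        if sg and all(isinstance(s, (int, np.integer)) for s in sg):
            return tuple(tuple(int(s) for s in sg) for _ in self.block_sizes)
        return tuple(tuple(int(s) for s in spec) for spec in sg)


@dataclass(frozen=True)
class BlockSet:
    """One division of the cohort into the designed blocks plus leftovers.

    Blocks are unordered sets of unit ids; the tuple order is carried for
    reporting only.  ``leftover`` holds units assigned to no block.
    """

    blocks: tuple[frozenset, ...]
    leftover: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(frozenset(b) for b in self.blocks))
        object.__setattr__(self, "leftover", frozenset(self.leftover))
        total = sum(len(b) for b in self.blocks) + len(self.leftover)
        union: set = set(self.leftover)
        for b in self.blocks:
            if not b:
                raise DesignError("empty block")
            union |= b
        if len(union) != total:
            raise DesignError("blocks and leftover must be pairwise disjoint")

    @property
    def blocked_ids(self) -> frozenset:
        out: set = set()
        for b in self.blocks:
            out |= b
        return frozenset(out)

    def to_dict(self) -> dict:
        return {
            "blocks": [sorted(b, key=str) for b in self.blocks],
            "leftover": sorted(self.leftover, key=str),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlockSet":
        return cls(
            blocks=tuple(frozenset(b) for b in d["blocks"]),
            leftover=frozenset(d.get("leftover", ())),
        )


@dataclass(frozen=True)
class CovariateSummary:
    """Per-block balance statistics of one covariate within one block set.

    ``delta_mean_max`` is the maximal between-block difference of means,
    ``delta_cv_max`` the maximal between-block difference of coefficients of
    variation, and ``blockset_sd`` the SD of the covariate over all blocked
    units (leftover excluded).
    """

    covariate_index: int
    block_means: tuple[float, ...]
    block_sds: tuple[float, ...]
    block_cvs: tuple[float, ...]
    blockset_sd: float
    delta_mean_max: float
    delta_cv_max: float

    def mean_term(self) -> float:
        """Normalized mean-difference term; 0 by convention for a constant covariate."""
        if self.blockset_sd == 0.0:
            return 0.0
        return self.delta_mean_max / self.blockset_sd


@dataclass(frozen=True)
class RankedBlockSet:
    """A block set with its balance score and per-covariate summaries.

    Lower ``ranking_value`` means better balanced.  ``marker_modifications``
    (total minimal re-markings over blocks) is present only when subgroups
    are defined and markers are available.
    """

    block_set: BlockSet
    ranking_value: float
    summaries: tuple[CovariateSummary, ...]
    marker_modifications: Optional[int] = None


@dataclass(frozen=True)
class GroupAllocation:
    """A bijection between block indices and intervention-group labels."""

    labels_by_block: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels_by_block)
        if len(set(labels)) != len(labels):
            raise AllocationError("group labels must be distinct")
        object.__setattr__(self, "labels_by_block", labels)

    def unit_to_group(self, block_set: BlockSet) -> dict:
        """Map every blocked unit id to its group label."""
        if len(self.labels_by_block) != len(block_set.blocks):
            raise AllocationError(
                f"{len(self.labels_by_block)} labels for {len(block_set.blocks)} blocks"
            )
        out: dict = {}
        for label, block in zip(self.labels_by_block, block_set.blocks):
            for uid in block:
                out[uid] = label
        return out


def validate_design(cohort: CohortTable, design: BlockDesign) -> BlockDesign:
    """Check a design against a cohort and resolve defaulted fields.

    Returns the design unchanged when fully specified and valid; ``weights``
    defaulting to all ones and ``decimals`` to two places are filled in.
    Idempotent.
    """
    if not design.block_sizes:
        raise DesignError("at least one block is required")
    if any(b <= 0 for b in design.block_sizes):
        raise DesignError(f"block sizes must be positive, got {design.block_sizes}")
    total = sum(design.block_sizes)
    if total > cohort.n_units:
        raise DesignError(
            f"block sizes sum to {total} but the cohort has only "
            f"{cohort.n_units} units"
        )
    p = cohort.n_covariates

    weights = design.weights
    if weights is None:
        weights = tuple(1.0 for _ in range(p))
    elif len(weights) != p:
        raise DesignError(f"{len(weights)} weights for {p} covariates")
    if any(w < 0 for w in weights):
        raise DesignError("weights must be non-negative")

    decimals = design.decimals
    if decimals is None:
        decimals = tuple(2 for _ in range(p))
    elif len(decimals) != p:
        raise DesignError(f"{len(decimals)} decimal settings for {p} covariates")
    if any(d < 0 for d in decimals):
        raise DesignError("decimal places must be non-negative")

    spec = design.subgroup_spec()
    if spec is not None:
        if len(spec) != design.n_blocks:
            raise DesignError(
                f"{len(spec)} subgroup specifications for {design.n_blocks} blocks"
            )
        for b, sizes in zip(design.block_sizes, spec):
            if any(s <= 0 for s in sizes):
                raise DesignError("subgroup sizes must be positive")
            if sum(sizes) != b:
                raise DesignError(
                    f"subgroup sizes {sizes} do not sum to block size {b}"
                )
        if not cohort.has_markers and not design.allow_random_subgroups:
            raise DesignError(
                "subgroups requested but the cohort has no markers and "
                "random subgrouping is disabled"
            )

    return replace(design, weights=weights, decimals=decimals, subgroup_sizes=spec)


def validate_block_set(
    cohort: CohortTable, design: BlockDesign, block_set: BlockSet
) -> BlockSet:
    """Check a block set against cohort membership and designed sizes."""
    sizes = tuple(sorted(len(b) for b in block_set.blocks))
    if sizes != tuple(sorted(design.block_sizes)):
        raise DesignError(
            f"block sizes {sizes} do not match design {tuple(sorted(design.block_sizes))}"
        )
    all_ids = set(cohort.ids)
    covered = set(block_set.leftover)
    for b in block_set.blocks:
        covered |= b
    if covered != all_ids:
        raise DesignError("blocks plus leftover must cover the cohort exactly")
    return block_set
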