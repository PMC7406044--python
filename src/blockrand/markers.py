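"""Subgroup (cage) division and physical-marker re-marking minimization.

Animals carry physical identification markers (ear clips, toe cuts).  When a
block is re-housed into cages of predefined sizes, markers must be unique
within a cage; every clash forces a modification, which causes discomfort
and is to be minimized.  Finding a division of a block into sized subgroups
that lets the largest number of animals keep their current marker is a
capacitated bipartite matching: marker labels (capacity = copies present)
on one side, subgroups (capacity = cage size, at most one kept copy of each
label) on the other.  It is solved exactly by maximum flow; the number of
modifications is the block size minus the maximum number of keepers.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from .model import (
    BlockDesign,
    BlockSet,
    CohortTable,
    ExperimentalUnit,
    MarkerError,
)

_SOURCE = ("src",)
_SINK = ("sink",)


@dataclass(frozen=True)
class SubgroupDivision:
    """A division of one block into sized subgroups.

    ``modifications`` is the number of units that must receive a changed
    marker (None when the division was random, i.e. marker-blind), and
    ``kept_ids`` the units that keep theirs.
    """

    subgroups: tuple[frozenset, ...]
    modifications: Optional[int]
    kept_ids: frozenset = frozenset()


def _check_sizes(n: int, subgroup_sizes: Sequence[int]) -> tuple[int, ...]:
    sizes = tuple(int(s) for s in subgroup_sizes)
    if not sizes or any(s <= 0 for s in sizes):
        raise MarkerError(f"subgroup sizes must be positive, got {subgroup_sizes}")
    if sum(sizes) != n:
        raise MarkerError(
            f"subgroup sizes {sizes} sum to {sum(sizes)}, block has {n} units"
        )
    return sizes


def minimal_remarking(
    units: Sequence[ExperimentalUnit], subgroup_sizes: Sequence[int]
) -> SubgroupDivision:
    """Divide a block into subgroups so that as many units as possible keep
    their marker, subject to kept markers being distinct within a subgroup.

    The optimum is exact (max-flow).  Ties are broken deterministically
    (units ordered by id within a label; labels and subgroups in sorted /
    declared order).
    """
    sizes = _check_sizes(len(units), subgroup_sizes)
    if any(u.marker is None for u in units):
        raise MarkerError("every unit in the block needs a marker")

    by_label: dict[str, list[ExperimentalUnit]] = defaultdict(list)
    for u in sorted(units, key=lambda u: str(u.id)):
        by_label[u.marker].append(u)
    labels = sorted(by_label)

    g = nx.DiGraph()
    for lab in labels:
        g.add_edge(_SOURCE, ("lab", lab), capacity=len(by_label[lab]))
        for gi in range(len(sizes)):
            g.add_edge(("lab", lab), ("sub", gi), capacity=1)
    for gi, s in enumerate(sizes):
        g.add_edge(("sub", gi), _SINK, capacity=s)
    kept_max, flow = nx.maximum_flow(g, _SOURCE, _SINK)

    pools = {lab: list(by_label[lab]) for lab in labels}
    subgroups: list[list[ExperimentalUnit]] = [[] for _ in sizes]
    kept: list[ExperimentalUnit] = []
    for lab in labels:
        for gi in range(len(sizes)):
            if flow[("lab", lab)].get(("sub", gi), 0) > 0:
                u = pools[lab].pop(0)
                subgroups[gi].append(u)
                kept.append(u)
    # remaining units (these are re-marked) fill the remaining capacity
    remaining = sorted(
        (u for pool in pools.values() for u in pool), key=lambda u: str(u.id)
    )
    for u in remaining:
        for gi, s in enumerate(sizes):
            if len(subgroups[gi]) < s:
                subgroups[gi].append(u)
                break
    return SubgroupDivision(
        subgroups=tuple(frozenset(u.id for u in sg) for sg in subgroups),
        modifications=len(units) - kept_max,
        kept_ids=frozenset(u.id for u in kept),
    )


def random_subgroups(
    units: Sequence[ExperimentalUnit],
    subgroup_sizes: Sequence[int],
    rng=None,
) -> SubgroupDivision:
    """Uniformly random division of a block into sized subgroups (marker-blind);
    modifications are reported as absent."""
    import numpy as np

    sizes = _check_sizes(len(units), subgroup_sizes)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    perm = gen.permutation(len(units))
    subgroups = []
    pos = 0
    for s in sizes:
        subgroups.append(frozenset(units[perm[j]].id for j in range(pos, pos + s)))
        pos += s
    return SubgroupDivision(subgroups=tuple(subgroups), modifications=None)


def remarking_floor(markers: Sequence[str], n_subgroups: int) -> int:
    """Sum over labels of max(0, count - number of subgroups).

    A label with more copies than subgroups can keep at most one copy per
    subgroup, so this many modifications are unavoidable.  When every
    subgroup is large enough to hold one copy of each distinct label the
    floor is attained exactly; with tighter subgroup sizes the true optimum
    may exceed it.
    """
    return sum(max(0, c - n_subgroups) for c in Counter(markers).values())


def _aligned_subgroup_spec(
    block_set: BlockSet, design: BlockDesign
) -> list[tuple[int, ...]]:
    """Match the design's per-block subgroup sizes to the block set's blocks.

    The block set may carry its blocks in canonical order (ascending size)
    while the design declares them in user order; blocks are matched to
    specs by size, in order within each size class.
    """
    spec = design.subgroup_spec()
    if spec is None:
        raise MarkerError("design defines no subgroups")
    avail: dict[int, list[tuple[int, ...]]] = defaultdict(list)
    for b, s in zip(design.block_sizes, spec):
        avail[b].append(s)
    out = []
    for block in block_set.blocks:
        pool = avail.get(len(block))
        if not pool:
            raise MarkerError(
                f"no subgroup specification for a block of size {len(block)}"
            )
        out.append(pool.pop(0))
    return out


def total_modifications(
    block_set: BlockSet, cohort: CohortTable, design: BlockDesign
) -> int:
    """Sum of the minimal per-block marker modifications over all blocks."""
    if not cohort.has_markers:
        raise MarkerError("cohort has no markers")
    specs = _aligned_subgroup_spec(block_set, design)
    units_by_id = {u.id: u for u in cohort.units}
    total = 0
    for block, sizes in zip(block_set.blocks, specs):
        division = minimal_remarking([units_by_id[i] for i in block], sizes)
        total += division.modifications
    return total
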