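"""Random allocation of the blocks of a chosen block set to intervention groups."""

from __future__ import annotations

import logging

import numpy as np

from .model import AllocationError, BlockSet, GroupAllocation

logger = logging.getLogger(__name__)


def allocate(block_set: BlockSet, group_labels, rng=None) -> GroupAllocation:
    """Uniformly random bijection between blocks and group labels.

    Deterministic under a seeded generator.  Blocks of unequal sizes are
    allocated identically (the design may intend unequal group sizes); a
    warning is logged so users notice that size/label pairings are random.
    """
    labels = [str(x) for x in group_labels]
    k = len(block_set.blocks)
    if len(labels) != k:
        raise AllocationError(f"{len(labels)} group labels for {k} blocks")
    if len(set(labels)) != len(labels):
        raise AllocationError(f"duplicate group labels in {labels}")
    if len({len(b) for b in block_set.blocks}) > 1:
        logger.warning(
            "blocks have unequal sizes; group/size pairings are assigned at random"
        )
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    perm = gen.permutation(k)
    return GroupAllocation(labels_by_block=tuple(labels[perm[j]] for j in range(k)))
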