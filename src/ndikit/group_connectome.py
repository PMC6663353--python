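"""Consensus group-averaged connectomes.

A group connectome is built in two steps: a binary consensus mask keeps only
edges present (weight > 0) in at least a stated fraction of subjects
(default 90%), and each retained edge then carries the arithmetic mean of
its weight across *all* subjects of the group (absent edges contribute
zeros to the mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ndikit.connectome_io import Connectome

__all__ = ["GroupConnectome", "consensus_mask", "group_average", "build_group_connectome"]


@dataclass(frozen=True)
class GroupConnectome:
    """Consensus-masked, group-averaged weighted connectome."""

    connectome: Connectome
    n_subjects: int
    consensus_fraction: float

    @property
    def weights(self) -> np.ndarray:
        return self.connectome.weights


def _check_cohort(cohort: list[Connectome]) -> int:
    if not cohort:
        raise ValueError("cohort is empty")
    n = cohort[0].n_nodes
    ids = cohort[0].node_ids
    for c in cohort[1:]:
        if c.n_nodes != n or not np.array_equal(c.node_ids, ids):
            raise ValueError("all connectomes must share order and node labels")
    return n


def consensus_mask(cohort: list[Connectome], fraction: float = 0.9) -> np.ndarray:
    """Binary adjacency keeping edges present in >= ceil(fraction*N) subjects.

    "At least" is a >= comparison on the subject count, so an edge present in
    exactly fraction*N subjects is retained.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = _check_cohort(cohort)
    needed = math.ceil(fraction * len(cohort))
    counts = np.zeros((n, n), dtype=int)
    for c in cohort:
        counts += c.weights > 0
    mask = (counts >= needed).astype(int)
    np.fill_diagonal(mask, 0)
    return mask


def group_average(cohort: list[Connectome], mask: np.ndarray) -> GroupConnectome:
    """Mean weight across all subjects on the masked edges; zeros elsewhere."""
    n = _check_cohort(cohort)
    mask = np.asarray(mask)
    if mask.shape != (n, n):
        raise ValueError("mask shape does not match cohort order")
    mean_w = np.mean([c.weights for c in cohort], axis=0)
    w = np.where(mask > 0, mean_w, 0.0)
    return GroupConnectome(
        cohort[0].with_weights(w), n_subjects=len(cohort), consensus_fraction=float("nan")
    )


def build_group_connectome(cohort: list[Connectome], fraction: float = 0.9) -> GroupConnectome:
    """Consensus mask followed by group averaging, in one call."""
    mask = consensus_mask(cohort, fraction)
    g = group_average(cohort, mask)
    return GroupConnectome(g.connectome, n_subjects=len(cohort), consensus_fraction=fraction)
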