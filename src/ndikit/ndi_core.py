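"""Network Dependency Index (NDI) for weighted undirected networks.

The NDI of a node m measures how much the network depends on m for
efficient information transfer.  Pairwise "information" between nodes i and
j is the reciprocal of their shortest topological distance, where each edge
contributes the inverse of its weight 1/w_ij to path length, normalized by
a constant I_max (the cohort-wide maximum edge weight, which is 1 for
max-normalized connectomes).  Removing m can only lengthen distances, so
every surviving ordered pair suffers a non-negative information loss; a
pair disconnected by the removal is charged the maximal loss of 1.  NDI(m)
aggregates these per-pair losses into a single score in [0, 1], where 1
means the removal of m destroys all remaining pairwise communication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

from ndikit.connectome_io import Connectome

__all__ = [
    "NDIScores",
    "topological_distances",
    "information_measure",
    "cohort_i_max",
    "removal_loss",
    "ndi_scores",
]

#: Losses with magnitude below this are round-off and treated as exactly 0.
LOSS_EPS = 1e-12


@dataclass(frozen=True)
class NDIScores:
    """Per-node dependency indices plus the I_max normalization used."""

    ndi: np.ndarray
    i_max: float
    node_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.ndi)

    def ranking(self) -> np.ndarray:
        """Node indices sorted by decreasing NDI (ties broken by index)."""
        return np.argsort(-self.ndi, kind="stable")


def _length_matrix(weights: np.ndarray) -> np.ndarray:
    """Edge lengths 1/w_ij; zero weight means no edge (length 0 = absent)."""
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / np.where(weights > 0, weights, 1.0), 0.0)
    return lengths


def topological_distances(c: Connectome | np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances over edge lengths 1/w_ij.

    Disconnected pairs are reported as ``inf``; the diagonal is 0.  An empty
    graph yields an all-infinite off-diagonal.
    """
    weights = c.weights if isinstance(c, Connectome) else np.asarray(c, dtype=float)
    return dijkstra(_length_matrix(weights), directed=False)


def information_measure(d: np.ndarray, i_max: float) -> np.ndarray:
    """Normalized pairwise information I_ij = (1/D_ij)/i_max.

    Disconnected pairs carry 0 information; the diagonal is 0 by convention.
    """
    if not i_max > 0:
        raise ValueError("i_max must be positive")
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        info = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    info /= i_max
    np.fill_diagonal(info, 0.0)
    return info


def cohort_i_max(cohort: list[Connectome]) -> float:
    """Maximum edge weight across all matrices of the cohort.

    Equals 1 when every matrix is max-normalized; using a single cohort-wide
    constant makes the maximal information loss comparable across subjects.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    m = max(float(c.weights.max()) for c in cohort)
    if m <= 0:
        raise ValueError("all-zero cohort has no defined I_max")
    return m


def _pair_losses(info: np.ndarray, info_removed: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Per-surviving-pair loss matrix for one node removal.

    ``info`` is the full-graph information matrix, ``info_removed`` the one
    on the subnetwork, ``keep`` the surviving node indices.  A pair that was
    connected before and is disconnected after is charged a loss of exactly
    1; a pair disconnected in both carries no loss.
    """
    before = info[np.ix_(keep, keep)]
    loss = before - info_removed
    newly_cut = (before > 0) & (info_removed == 0)
    loss[newly_cut] = 1.0
    # negative values can only be float round-off: distances never shorten
    if loss.min(initial=0.0) < -1e-9:
        raise AssertionError("negative pairwise information loss exceeds round-off")
    loss[np.abs(loss) < LOSS_EPS] = 0.0
    np.clip(loss, 0.0, None, out=loss)
    np.fill_diagonal(loss, 0.0)
    return loss


def removal_loss(c: Connectome, m: int, i_max: float = 1.0) -> np.ndarray:
    """Per-node accumulated loss vector over the subnetwork without node m.

    Entry i is the mean loss of information from node i to every other
    surviving partner j (see `ndi_scores` for the sum variant).
    """
    if not 0 <= m < c.n_nodes:
        raise ValueError(f"node {m} not in graph of order {c.n_nodes}")
    info = information_measure(topological_distances(c), i_max)
    keep = np.array([i for i in range(c.n_nodes) if i != m])
    lengths = _length_matrix(c.weights)[np.ix_(keep, keep)]
    info_removed = information_measure(dijkstra(lengths, directed=False), i_max)
    loss = _pair_losses(info, info_removed, keep)
    return loss.sum(axis=1) / max(len(keep) - 1, 1)


def ndi_scores(
    c: Connectome,
    i_max: float = 1.0,
    aggregate: str = "mean",
    keep_losses: bool = False,
) -> NDIScores:
    """NDI of every node: aggregate per-pair information loss under removal.

    Parameters
    ----------
    c : Connectome of order >= 3 (a removal must leave at least one pair).
    i_max : positive normalization constant; use `cohort_i_max` for
        cross-subject comparability (1 for max-normalized matrices).
    aggregate : "mean" (default) averages each node's loss over its
        partners, bounding NDI in [0, 1]; "sum" accumulates raw per-pair
        losses per node before averaging over nodes, for sensitivity
        analysis (unbounded above for dense graphs).
    keep_losses : retain the per-removal loss vectors on the result
        (attribute ``losses``, a list of per-node arrays).

    Notes
    -----
    With the mean aggregation, NDI(m) is the mean loss over all surviving
    ordered pairs of the subnetwork without m; an isolated node scores 0 and
    a node whose removal disconnects every surviving pair scores 1.
    """
    if c.n_nodes < 3:
        raise ValueError("NDI requires at least 3 nodes")
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    n = c.n_nodes
    lengths = _length_matrix(c.weights)
    info = information_measure(dijkstra(lengths, directed=False), i_max)
    # 1/D_ij <= max(w) always holds, so a violation means i_max does not
    # bound this matrix's information measure; surface it, never clip.
    if info.max(initial=0.0) > 1.0 + 1e-9:
        raise ValueError(
            f"information measure exceeds 1 (max {info.max():.6g}); "
            "i_max does not bound this connectome's edge weights"
        )
    ndi = np.zeros(n)
    all_losses: list[np.ndarray] = []
    for m in range(n):
        keep = np.concatenate([np.arange(m), np.arange(m + 1, n)])
        sub = lengths[np.ix_(keep, keep)]
        info_removed = information_measure(dijkstra(sub, directed=False), i_max)
        loss = _pair_losses(info, info_removed, keep)
        if aggregate == "mean":
            delta_i = loss.sum(axis=1) / (len(keep) - 1)
        else:
            delta_i = loss.sum(axis=1)
        ndi[m] = delta_i.mean()
        if keep_losses:
            all_losses.append(delta_i)
    scores = NDIScores(ndi=ndi, i_max=float(i_max), node_ids=c.node_ids)
    if keep_losses:
        object.__setattr__(scores, "losses", all_losses)
    return scores
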