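"""Weighted topology metrics on connectomes and their induced subnetworks.

Three whole-graph measures in the Brain Connectivity Toolbox weighted
conventions:

* transitivity T — ratio of geometric-mean triangle intensity to the number
  of connected triples, summed over nodes;
* global efficiency E — mean inverse shortest-path distance over node
  pairs (inverse-weight edge lengths), disconnected pairs contributing 0;
* assortativity a — correlation of endpoint strengths over edges.

Subnetwork profiles evaluate the metrics on the subgraph induced by a
member set inside a subject's connectome (intra-subnetwork edges only),
together with mean node strength and binary edge density.  Degenerate
inputs (no triples, zero strength variance, too few members) yield missing
values (NaN), never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ndikit.connectome_io import Connectome
from ndikit.ndi_core import topological_distances

__all__ = [
    "SubnetworkProfile",
    "weighted_transitivity",
    "weighted_global_efficiency",
    "weighted_assortativity",
    "subnetwork_profile",
]


@dataclass(frozen=True)
class SubnetworkProfile:
    """Metrics of one subnetwork within one subject's connectome."""

    subject_id: str
    subnetwork: str
    n_nodes: int
    transitivity: float
    efficiency: float
    assortativity: float
    mean_strength: float
    density: float


def _as_weights(c: Connectome | np.ndarray) -> np.ndarray:
    return c.weights if isinstance(c, Connectome) else np.asarray(c, dtype=float)


def weighted_transitivity(c: Connectome | np.ndarray) -> float:
    """Whole-graph weighted transitivity (geometric-mean triangle intensity).

    T = sum_i 2 t_i / sum_i k_i (k_i - 1), with t_i the sum over neighbor
    pairs of (w_ij w_ih w_jh)^(1/3) / 2 and k_i the binary degree.  NaN when
    the graph has no connected triples.
    """
    w = _as_weights(c)
    if w.shape[0] < 3:
        raise ValueError("transitivity needs at least 3 nodes")
    k = (w > 0).sum(axis=1)
    triples = (k * (k - 1)).sum()
    if triples == 0:
        return float("nan")
    w_cbrt = np.cbrt(w)
    closed = np.trace(w_cbrt @ w_cbrt @ w_cbrt)  # = sum_i 2 t_i
    return float(closed / triples)


def weighted_global_efficiency(c: Connectome | np.ndarray) -> float:
    """Mean of 1/d_ij over ordered node pairs; disconnected pairs count 0."""
    w = _as_weights(c)
    n = w.shape[0]
    if n < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    d = topological_distances(w)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def weighted_assortativity(c: Connectome | np.ndarray) -> float:
    """Correlation of endpoint strengths over edges (weighted assortativity).

    Uses the symmetrized Pearson form over the undirected edge list; NaN
    when endpoint strengths have zero variance (e.g. regular rings).
    """
    w = _as_weights(c)
    iu, ju = np.triu_indices_from(w, k=1)
    present = w[iu, ju] > 0
    if present.sum() < 2:
        return float("nan")
    strength = w.sum(axis=1)
    x = strength[iu[present]]
    y = strength[ju[present]]
    m = len(x)
    term = ((x + y) / 2.0).sum() / m
    num = (x * y).sum() / m - term**2
    den = ((x**2 + y**2) / 2.0).sum() / m - term**2
    if den <= 0:
        return float("nan")
    return float(num / den)


def subnetwork_profile(
    c: Connectome, members: np.ndarray, subject_id: str = "", subnetwork: str = ""
) -> SubnetworkProfile:
    """Metrics on the induced subgraph of ``members`` in ``c``.

    Only intra-subnetwork edges enter; mean strength and density refer to
    the induced subgraph.  Requires at least 3 members.
    """
    members = np.asarray(members, dtype=int)
    if len(members) < 3:
        raise ValueError("subnetwork must have at least 3 members")
    if members.max() >= c.n_nodes or members.min() < 0:
        raise ValueError("member indices outside the connectome")
    sub = c.weights[np.ix_(members, members)]
    n = len(members)
    n_edges = int((sub > 0).sum() // 2)
    return SubnetworkProfile(
        subject_id=subject_id,
        subnetwork=subnetwork,
        n_nodes=n,
        transitivity=weighted_transitivity(sub),
        efficiency=weighted_global_efficiency(sub),
        assortativity=weighted_assortativity(sub),
        mean_strength=float(sub.sum(axis=1).mean()),
        density=float(n_edges / (n * (n - 1) / 2)),
    )
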