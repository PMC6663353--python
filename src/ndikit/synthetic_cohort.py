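"""Synthetic weighted connectome cohorts with planted hierarchy.

The generator emulates the statistical structure the analysis pipeline
assumes in real streamline-count connectomes: a four-level core-periphery
hierarchy (a small, dense, strongly-weighted core = planted Tier 1,
progressively sparser and weaker outer tiers), per-subject multiplicative
weight noise and edge dropout, and a linear age trend on within-core edge
weights.  Edge weights are log-normal per block so that log-transformed
nodal dependency scores separate into approximately Gaussian clusters, the
distributional assumption the Tier stratification exploits.

The shared base topology and base weights are drawn once from the spec
seed; subjects are independent noisy realizations of that base, so a
consensus mask at 90% recovers (essentially) the base topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ndikit.connectome_io import Connectome, CohortManifest, save_matrix

__all__ = ["SyntheticSpec", "base_network", "generate_subject", "generate_cohort"]

#: Block edge probabilities between planted tiers (1-4): a complete core with
#: sparse, strictly hierarchical attachment (tier 4 reaches the core only
#: through tier 3, tier 3 only through tier 2), so each node's importance is
#: set by the traffic it relays for its subtree.
DEFAULT_DENSITY = (
    (1.00, 0.30, 0.06, 0.00),
    (0.30, 0.20, 0.10, 0.00),
    (0.06, 0.10, 0.10, 0.05),
    (0.00, 0.00, 0.05, 0.03),
)
#: Log-weight location by block level max(tier_i, tier_j); strong separation
#: (>4 sd between consecutive levels) keeps core edges the strongest.
DEFAULT_WEIGHT_MU = (-0.2, -1.8, -3.2, -4.6)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic connectome cohort.

    Attributes
    ----------
    n_nodes, tier_sizes : planted partition; sizes must sum to n_nodes.
    density : 4x4 symmetric block edge probabilities.
    weight_mu : per-level location of ln(weight); block level is the worse
        (higher-numbered) of the two endpoint tiers.
    weight_sigma : common log-scale of block weight distributions.
    n_subjects, age_range : cohort layout (ages uniformly spread).
    age_slope : per-year strengthening of within-core edges, applied around
        the mid-range age as a log-space pull of each core weight toward
        the strongest core weight.  A uniform multiplicative trend would be
        removed by per-subject max-normalization (the maximum is itself a
        core edge), so the planted trend compresses the core weight spread
        instead, which survives normalization as rising core efficiency.
    noise_scale : sd of per-subject log-normal multiplicative edge noise.
    edge_dropout : probability a subject misses any given base edge.
    seed : master seed; base network and per-subject seeds derive from it.
    """

    n_nodes: int = 170
    tier_sizes: tuple[int, ...] = (20, 50, 44, 56)
    density: tuple[tuple[float, ...], ...] = DEFAULT_DENSITY
    weight_mu: tuple[float, ...] = DEFAULT_WEIGHT_MU
    weight_sigma: float = 0.35
    n_subjects: int = 196
    age_range: tuple[float, float] = (4.0, 85.0)
    age_slope: float = 0.008
    noise_scale: float = 0.1
    edge_dropout: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.tier_sizes) != self.n_nodes:
            raise ValueError("tier sizes must sum to n_nodes")
        dens = np.asarray(self.density, dtype=float)
        if dens.shape != (len(self.tier_sizes),) * 2:
            raise ValueError("density must be square over the tiers")
        if np.any(dens < 0) or np.any(dens > 1):
            raise ValueError("edge probabilities must be in [0, 1]")
        if self.noise_scale < 0 or not 0 <= self.edge_dropout < 1:
            raise ValueError("invalid noise parameters")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def tier_of_node(self) -> np.ndarray:
        """Planted tier (1-based) of every node, in node order."""
        return np.repeat(np.arange(1, len(self.tier_sizes) + 1), self.tier_sizes)


def _labels(spec: SyntheticSpec) -> pd.DataFrame:
    tiers = spec.tier_of_node
    return pd.DataFrame(
        {
            "node_id": [f"n{i:03d}" for i in range(spec.n_nodes)],
            "region_name": [f"region_{i:03d}" for i in range(spec.n_nodes)],
            "hemisphere": ["L", "R"][: 2] * (spec.n_nodes // 2) + ["M"] * (spec.n_nodes % 2),
            "anatomical_group": [f"tier{t}" for t in tiers],
        }
    )


def _within_block_edges(nodes: np.ndarray, p: float, rng: np.random.Generator):
    """Near-regular within-block topology at the requested density."""
    n = len(nodes)
    d = int(round(p * (n - 1)))
    if d <= 0:
        return []
    if d >= n - 1:
        return [(nodes[a], nodes[b]) for a in range(n) for b in range(a + 1, n)]
    if (n * d) % 2 == 1:
        d -= 1
    g = nx.random_regular_graph(d, n, seed=int(rng.integers(2**31 - 1)))
    return [(nodes[a], nodes[b]) for a, b in g.edges()]


def _cross_block_edges(
    outer: np.ndarray, inner: np.ndarray, p: float, rng: np.random.Generator
):
    """Near-biregular cross-tier attachment at the requested density.

    Every outer-tier node gets exactly round(p*|inner|) inner partners and
    inner-tier receive counts differ by at most one, so both each tier's
    upward redundancy and the inner tier's degree stratum are homogeneous.
    """
    k = min(int(round(p * len(inner))), len(inner))
    if k <= 0:
        return []
    if k == len(inner):
        return [(int(a), int(b)) for a in outer for b in inner]
    # near-biregular stub matching: inner receive counts differ by at most 1
    total = k * len(outer)
    base, extra = divmod(total, len(inner))
    counts = np.full(len(inner), base)
    if extra:
        counts[rng.choice(len(inner), size=extra, replace=False)] += 1
    stubs = np.repeat(inner, counts)
    rng.shuffle(stubs)
    rows = stubs.reshape(len(outer), k)
    for i in range(len(outer)):  # repair duplicate parents by row swaps
        guard = 0
        while len(np.unique(rows[i])) < k and guard < 10000:
            guard += 1
            vals, cnts = np.unique(rows[i], return_counts=True)
            dup = vals[cnts > 1][0]
            j = int(rng.integers(len(outer)))
            pos = int(rng.integers(k))
            if j == i:
                continue
            if rows[j, pos] not in rows[i] and dup not in rows[j]:
                didx = int(np.flatnonzero(rows[i] == dup)[0])
                rows[i, didx], rows[j, pos] = rows[j, pos], rows[i, didx]
    return [(int(outer[i]), int(b)) for i in range(len(outer)) for b in rows[i]]


def base_network(spec: SyntheticSpec) -> np.ndarray:
    """Shared base topology and weights, drawn once from the spec seed.

    Blocks are realized near-regularly at the requested densities: each
    within-tier block is a random regular graph and each cross-tier block
    gives every node of the outer tier an exact partner count in the inner
    tier.  This matches the block densities while keeping both the core
    degree stratum and each tier's upward redundancy homogeneous.
    """
    rng = np.random.default_rng(spec.seed)
    tiers = spec.tier_of_node - 1
    dens = np.asarray(spec.density, dtype=float)
    n = spec.n_nodes
    n_tiers = len(spec.tier_sizes)
    blocks = [np.flatnonzero(tiers == t) for t in range(n_tiers)]
    edges: list[tuple[int, int]] = []
    for s in range(n_tiers):
        edges += _within_block_edges(blocks[s], dens[s, s], rng)
        for t in range(s + 1, n_tiers):
            edges += _cross_block_edges(blocks[t], blocks[s], dens[s, t], rng)
    w = np.zeros((n, n))
    mu = np.asarray(spec.weight_mu, dtype=float)
    for a, b in edges:
        level = max(tiers[a], tiers[b])
        w[a, b] = w[b, a] = rng.lognormal(mu[level], spec.weight_sigma)
    return w


def generate_subject(
    spec: SyntheticSpec, age: float, seed: int, base: np.ndarray | None = None
) -> Connectome:
    """One subject's max-normalized connectome.

    Starting from the shared base network (recomputed from the spec seed
    unless passed in), each edge is kept with probability 1 - edge_dropout
    and multiplied by log-normal noise exp(N(0, noise_scale^2)).
    Within-core edge weights are additionally interpolated in log space
    toward the strongest core weight by h = age_slope * (age - mid-range
    age), i.e. w -> w^(1-h) * w_core_max^h, so the expected log-weight of
    core edges shifts linearly with age and the shift is not cancelled by
    the subsequent max-normalization.
    """
    if base is None:
        base = base_network(spec)
    rng = np.random.default_rng(seed)
    n = spec.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = base[iu, ju].copy()
    if spec.edge_dropout > 0:
        w[rng.random(len(w)) < spec.edge_dropout] = 0.0
    if spec.noise_scale > 0:
        w *= np.exp(rng.normal(0.0, spec.noise_scale, size=len(w)))
    tiers = spec.tier_of_node - 1
    core_edge = (tiers[iu] == 0) & (tiers[ju] == 0) & (base[iu, ju] > 0)
    if spec.age_slope != 0 and core_edge.any():
        age_mid = (spec.age_range[0] + spec.age_range[1]) / 2.0
        h = np.clip(spec.age_slope * (age - age_mid), -0.9, 0.9)
        w_core_max = base[iu, ju][core_edge].max()
        active = core_edge & (w > 0)
        w[active] = np.exp((1.0 - h) * np.log(w[active]) + h * np.log(w_core_max))
    mat = np.zeros((n, n))
    mat[iu, ju] = w
    mat[ju, iu] = w
    m = mat.max()
    if m <= 0:
        raise ValueError("generated subject has no edges; spec too sparse")
    mat /= m
    return Connectome(mat, np.array([f"n{i:03d}" for i in range(n)], dtype=object), _labels(spec))


def generate_cohort(
    spec: SyntheticSpec, out_dir: str | Path | None = None
) -> tuple[CohortManifest, list[Connectome]]:
    """A full cohort: manifest plus per-subject connectomes.

    Ages are spread evenly over ``age_range`` (so all four age groups are
    populated), sexes alternate, and per-subject seeds are derived from the
    master seed.  When ``out_dir`` is given, matrices are written in the
    plain-text dialect plus a ``manifest.csv`` and ``labels.tsv``.
    """
    master = np.random.default_rng(spec.seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=spec.n_subjects)
    if spec.n_subjects == 1:
        ages = np.array([np.mean(spec.age_range)])
    else:
        ages = np.linspace(*spec.age_range, spec.n_subjects)
    # deterministic shuffle so age is not confounded with subject order
    master.shuffle(ages)
    rows = []
    connectomes = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    base = base_network(spec)
    for s in range(spec.n_subjects):
        c = generate_subject(spec, float(ages[s]), int(subject_seeds[s]), base=base)
        connectomes.append(c)
        path = f"sub-{s:04d}.txt"
        if out_dir is not None:
            save_matrix(c.weights, out_dir / path)
        rows.append(
            {
                "subject_id": f"sub-{s:04d}",
                "age": float(ages[s]),
                "sex": "M" if s % 2 == 0 else "F",
                "path": str(out_dir / path) if out_dir is not None else path,
            }
        )
    manifest = CohortManifest(pd.DataFrame(rows))
    if out_dir is not None:
        manifest.table.to_csv(out_dir / "manifest.csv", index=False)
        _labels(spec).to_csv(out_dir / "labels.tsv", sep="\t", header=False, index=False)
    return manifest, connectomes
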