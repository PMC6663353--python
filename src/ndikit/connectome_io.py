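"""Reading, validation, normalization and subsetting of weighted connectomes.

A connectome is a symmetric, non-negative weighted adjacency matrix over a
fixed set of parcellated brain regions, together with a per-node label table
(region name, hemisphere, anatomical group).  Streamline-count matrices are
normalized per subject by their maximum entry so that all weights lie in
[0, 1]; regions belonging to unwanted anatomical groups (e.g. brainstem,
cerebellum) can be dropped before analysis.  Subjects are stratified into
the four life-span age groups U20, U40, U60 and O60.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "CohortManifest",
    "load_connectome",
    "load_matrix",
    "save_matrix",
    "load_labels",
    "load_manifest",
    "normalize_by_max",
    "drop_nodes",
    "assign_age_group",
    "AGE_GROUPS",
]

#: Upper (inclusive) age bound of each group; O60 is open-ended above 60.
AGE_GROUPS = ("U20", "U40", "U60", "O60")
_AGE_BOUNDS = {"U20": 20.0, "U40": 40.0, "U60": 60.0}

#: Relative asymmetry beyond which a matrix is rejected rather than symmetrized.
SYMMETRY_RTOL = 1e-8

LABEL_COLUMNS = ["node_id", "region_name", "hemisphere", "anatomical_group"]


@dataclass(frozen=True)
class Connectome:
    """Weighted undirected brain network.

    Attributes
    ----------
    weights : ndarray of shape (n, n)
        Symmetric non-negative edge weights with zero diagonal.  A weight of
        zero means no edge.
    node_ids : ndarray of str
        Ordered unique node identifiers.
    labels : pandas.DataFrame
        One row per node with columns ``node_id``, ``region_name``,
        ``hemisphere`` and ``anatomical_group``, in matrix order.
    """

    weights: np.ndarray
    node_ids: np.ndarray
    labels: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weight matrix contains non-finite entries")
        if np.any(w < 0):
            raise ValueError("negative edge weights are not allowed")
        scale = w.max() if w.size else 0.0
        tol = SYMMETRY_RTOL * max(scale, 1.0)
        if np.abs(w - w.T).max(initial=0.0) > tol:
            raise ValueError("matrix is asymmetric beyond tolerance")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)
        ids = np.asarray(self.node_ids, dtype=object)
        if ids.shape != (w.shape[0],):
            raise ValueError("node_ids length must equal matrix order")
        if len(set(ids)) != len(ids):
            raise ValueError("node_ids must be unique")
        object.__setattr__(self, "node_ids", ids)
        if len(self.labels) != w.shape[0]:
            raise ValueError("label table length must equal matrix order")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def with_weights(self, weights: np.ndarray) -> "Connectome":
        """Return a copy sharing labels but carrying new weights."""
        return Connectome(np.array(weights, dtype=float), self.node_ids, self.labels)


@dataclass(frozen=True)
class CohortManifest:
    """Table of subjects: id, age in years, sex, age-group label, matrix path."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "age", "sex", "path"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if (self.table["age"] <= 0).any():
            raise ValueError("ages must be positive")
        tab = self.table.copy()
        tab["age_group"] = [assign_age_group(a) for a in tab["age"]]
        object.__setattr__(self, "table", tab)

    def __len__(self) -> int:
        return len(self.table)

    def subjects_in_group(self, group: str) -> pd.DataFrame:
        if group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {group!r}")
        return self.table[self.table["age_group"] == group]


def default_labels(n: int) -> pd.DataFrame:
    """Placeholder label table for matrices supplied without one."""
    return pd.DataFrame(
        {
            "node_id": [f"n{i}" for i in range(n)],
            "region_name": [f"region_{i}" for i in range(n)],
            "hemisphere": ["M"] * n,
            "anatomical_group": ["unknown"] * n,
        }
    )


def load_matrix(path: str | Path) -> np.ndarray:
    """Read a square numeric matrix from whitespace- or comma-delimited text."""
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
    delimiter = "," if "," in first else None
    w = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({w.shape[0]}x{w.shape[1]})")
    return w


def save_matrix(weights: np.ndarray, path: str | Path) -> None:
    """Write a matrix in the plain-text dialect `load_matrix` reads."""
    np.savetxt(path, np.asarray(weights, dtype=float), fmt="%.17g")


def load_labels(path: str | Path) -> pd.DataFrame:
    labels = pd.read_csv(path, sep="\t", header=None, names=LABEL_COLUMNS, dtype=str)
    return labels


def load_connectome(path: str | Path, labels_path: str | Path | None = None) -> Connectome:
    """Load and validate a connectome from a matrix file plus a label table.

    Parameters
    ----------
    path : path to the plain-text square matrix (whitespace- or comma-delimited).
    labels_path : optional path to a tab-separated label file with columns
        node_id, region_name, hemisphere, anatomical_group (no header).
        When omitted, placeholder labels are generated.

    Raises
    ------
    ValueError
        For non-square matrices, label/matrix size mismatches, negative or
        non-finite entries, or asymmetry beyond tolerance.
    """
    w = load_matrix(path)
    labels = load_labels(labels_path) if labels_path is not None else default_labels(w.shape[0])
    if len(labels) != w.shape[0]:
        raise ValueError(
            f"label table has {len(labels)} rows but matrix order is {w.shape[0]}"
        )
    return Connectome(w, labels["node_id"].to_numpy(object), labels.reset_index(drop=True))


def load_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest CSV with header subject_id,age,sex,path."""
    tab = pd.read_csv(path)
    tab["age"] = tab["age"].astype(float)
    return CohortManifest(tab)


def normalize_by_max(c: Connectome) -> Connectome:
    """Divide all weights by the maximum weight, mapping them into [0, 1].

    The maximum edge becomes exactly 1 and zero edges stay zero; the
    operation is idempotent and invariant to any positive rescaling of the
    input.  An all-zero matrix is rejected.
    """
    m = c.weights.max()
    if m <= 0:
        raise ValueError("cannot normalize an all-zero connectome")
    return c.with_weights(c.weights / m)


def drop_nodes(c: Connectome, drop_groups: set[str] | frozenset[str]) -> Connectome:
    """Remove every node whose anatomical group is in `drop_groups`.

    The induced submatrix on the kept nodes is returned, the label table is
    filtered consistently, and the relative order of remaining nodes is
    preserved.  Unknown group names raise, so typos do not silently no-op.
    """
    drop_groups = set(drop_groups)
    known = set(c.labels["anatomical_group"])
    unknown = drop_groups - known
    if unknown:
        raise ValueError(f"unknown anatomical group(s): {sorted(unknown)}")
    keep = ~c.labels["anatomical_group"].isin(drop_groups).to_numpy()
    idx = np.flatnonzero(keep)
    return Connectome(
        c.weights[np.ix_(idx, idx)],
        c.node_ids[idx],
        c.labels.iloc[idx].reset_index(drop=True),
    )


def assign_age_group(age: float) -> str:
    """Map an age in years onto U20/U40/U60/O60.

    Boundaries are closed on the upper end: U20 <= 20 < U40 <= 40 < U60 <= 60
    < O60; ages above 80 fold into O60.
    """
    if not np.isfinite(age) or age <= 0:
        raise ValueError(f"age must be positive and finite, got {age}")
    for group, bound in _AGE_BOUNDS.items():
        if age <= bound:
            return group
    return "O60"
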