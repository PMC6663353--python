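"""Data-driven Tier stratification of nodes from log-transformed NDI.

Positive NDI scores, after a natural-log transform, are well described by a
mixture of g Gaussians; cutting the axis at the halfway points between
consecutive component means yields g intervals of decreasing importance
(Tier 1 = highest NDI), and a dedicated Tier g+1 collects nodes with
NDI = 0, which carry no log-score.  The number of components is chosen by
information criteria (BIC, with AIC reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from ndikit.ndi_core import NDIScores

__all__ = [
    "TierModel",
    "fit_log_gmm",
    "select_component_count",
    "tier_boundaries",
    "assign_tiers",
    "tier_confusion",
    "subject_tier_consensus",
    "tier_assignment_pipeline",
]

#: Component standard deviations below this indicate variance collapse.
MIN_COMPONENT_SD = 1e-6


@dataclass(frozen=True)
class TierModel:
    """Fitted 1-D Gaussian mixture on ln(NDI) with derived tier boundaries.

    Means/variances/weights are sorted by ascending mean; ``boundaries``
    are the g-1 midpoints between consecutive means.  Tier labels run from
    1 (highest-NDI component) through g, with g+1 reserved for NDI = 0.
    """

    g: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    log_likelihood: float

    @property
    def boundaries(self) -> np.ndarray:
        return tier_boundaries(self.means)

    @property
    def n_tiers(self) -> int:
        return self.g + 1


def _positive_log_scores(ndi: NDIScores | np.ndarray) -> np.ndarray:
    scores = ndi.ndi if isinstance(ndi, NDIScores) else np.asarray(ndi, dtype=float)
    return np.log(scores[scores > 0])


def fit_log_gmm(
    ndi: NDIScores | np.ndarray, g: int, seed: int = 0, n_restarts: int = 10
) -> TierModel:
    """Maximum-likelihood g-component Gaussian mixture on ln(NDI > 0).

    Zero scores are excluded (their log is undefined; they get the dedicated
    final Tier at assignment time).  The best of ``n_restarts`` random
    initializations is kept; a degenerate fit (collapsed component variance)
    raises rather than returning spurious boundaries.
    """
    x = _positive_log_scores(ndi)
    if len(x) < 3 * g:
        raise ValueError(
            f"need at least {3 * g} positive scores for g={g}, got {len(x)}"
        )
    if np.ptp(x) == 0:
        raise ValueError("all positive scores identical: degenerate mixture")
    gmm = GaussianMixture(
        n_components=g,
        covariance_type="full",
        n_init=n_restarts,
        random_state=seed,
        reg_covar=1e-10,
    ).fit(x.reshape(-1, 1))
    means = gmm.means_.ravel()
    variances = gmm.covariances_.ravel()
    weights = gmm.weights_.ravel()
    if np.any(np.sqrt(variances) < MIN_COMPONENT_SD):
        raise ValueError("degenerate variance collapse in mixture fit")
    order = np.argsort(means)
    return TierModel(
        g=g,
        means=means[order],
        variances=variances[order],
        weights=weights[order],
        log_likelihood=float(gmm.score(x.reshape(-1, 1)) * len(x)),
    )


def select_component_count(
    ndi: NDIScores | np.ndarray,
    g_candidates: list[int] | range = range(1, 7),
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose g by minimum BIC over the candidates; AIC reported alongside.

    Returns the chosen g and the full criterion table (columns g, aic, bic,
    log_likelihood).  Candidates that cannot be fitted (too few positive
    scores, degenerate collapse) are recorded with NaN criteria and never
    chosen.
    """
    g_candidates = list(g_candidates)
    if not g_candidates:
        raise ValueError("no candidate component counts")
    x = _positive_log_scores(ndi).reshape(-1, 1)
    rows = []
    for g in g_candidates:
        try:
            gmm = GaussianMixture(
                n_components=g,
                covariance_type="full",
                n_init=10,
                random_state=seed,
                reg_covar=1e-10,
            ).fit(x)
            rows.append(
                {
                    "g": g,
                    "aic": gmm.aic(x),
                    "bic": gmm.bic(x),
                    "log_likelihood": gmm.score(x) * len(x),
                }
            )
        except ValueError:
            rows.append({"g": g, "aic": np.nan, "bic": np.nan, "log_likelihood": np.nan})
    table = pd.DataFrame(rows)
    if table["bic"].isna().all():
        raise ValueError("no candidate could be fitted")
    chosen = int(table.loc[table["bic"].idxmin(), "g"])
    return chosen, table


def tier_boundaries(means: np.ndarray) -> np.ndarray:
    """Halfway points between consecutive (sorted) Gaussian centers."""
    m = np.sort(np.asarray(means, dtype=float))
    return (m[:-1] + m[1:]) / 2.0


def assign_tiers(
    ndi: NDIScores | np.ndarray, boundaries: np.ndarray
) -> np.ndarray:
    """Per-node Tier labels 1..g+1 from log-NDI cut points.

    ln(NDI) at or above the top boundary is Tier 1 (a score exactly on a cut
    joins the higher-NDI tier); successive intervals give Tiers 2..g; nodes
    with NDI = 0 are Tier g+1.
    """
    scores = ndi.ndi if isinstance(ndi, NDIScores) else np.asarray(ndi, dtype=float)
    boundaries = np.sort(np.asarray(boundaries, dtype=float))
    g = len(boundaries) + 1
    tiers = np.full(len(scores), g + 1, dtype=int)
    positive = scores > 0
    logx = np.log(scores[positive])
    # tier = g - (number of boundaries <= x): above all cuts -> Tier 1
    below = (logx[:, None] > boundaries[None, :]) | np.isclose(
        logx[:, None], boundaries[None, :], rtol=1e-12, atol=1e-12
    )
    tiers[positive] = g - below.sum(axis=1)
    return tiers


def tier_confusion(assign_a: np.ndarray, assign_b: np.ndarray) -> pd.DataFrame:
    """Row-normalized percentage confusion matrix between two assignments.

    Rows are A's tiers, columns B's tiers, each row summing to 100 (empty
    tiers of A give all-zero rows).  Label sets must agree in range.
    """
    a = np.asarray(assign_a)
    b = np.asarray(assign_b)
    if a.shape != b.shape:
        raise ValueError("assignments must cover the same node set")
    labels = np.union1d(np.unique(a), np.unique(b))
    mat = np.zeros((len(labels), len(labels)))
    index = {lab: i for i, lab in enumerate(labels)}
    for la, lb in zip(a, b):
        mat[index[la], index[lb]] += 1
    row_sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        pct = np.where(row_sums > 0, mat / row_sums * 100.0, 0.0)
    return pd.DataFrame(pct, index=labels, columns=labels)


def subject_tier_consensus(
    per_subject_labels: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Median Tier per node across subjects, plus its standard deviation.

    A median straddling two tiers (even subject counts) rounds toward the
    lower tier number, i.e. toward higher importance.  Spread is the
    population standard deviation of the integer labels.
    """
    labels = np.asarray(per_subject_labels, dtype=float)
    if labels.ndim != 2 or labels.shape[0] < 2:
        raise ValueError("need a subjects x nodes matrix with >= 2 subjects")
    srt = np.sort(labels, axis=0)
    low_median = srt[(labels.shape[0] - 1) // 2]
    spread = labels.std(axis=0, ddof=0)
    return low_median.astype(int), spread


def tier_assignment_pipeline(
    ndi: NDIScores | np.ndarray,
    g_candidates: list[int] | range = range(1, 7),
    seed: int = 0,
    fallback_boundaries: np.ndarray | None = None,
) -> tuple[np.ndarray, TierModel | None, bool]:
    """Model selection, fit and assignment in one call.

    Returns (tiers, model, used_fallback).  If the fit degenerates and
    ``fallback_boundaries`` are supplied (e.g. cohort-level boundaries for a
    subject whose own mixture collapses), those are used instead and the
    substitution is flagged.
    """
    try:
        g, _ = select_component_count(ndi, g_candidates, seed=seed)
        model = fit_log_gmm(ndi, g, seed=seed)
        return assign_tiers(ndi, model.boundaries), model, False
    except ValueError:
        if fallback_boundaries is None:
            raise
        return assign_tiers(ndi, fallback_boundaries), None, True
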