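"""Cross-group consistency and age-trend statistics for subnetwork profiles.

Rank consistency of nodal NDI across group connectomes is summarized by
pairwise Spearman correlations; age trends of each network measure within
each subnetwork are ordinary least-squares fits measure = m*age + b on the
subject-level data, with Bonferroni correction across the family of fitted
cells (default: measures x subnetworks).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["ndi_rank_consistency", "age_trend_regression"]


def ndi_rank_consistency(score_vectors: list[np.ndarray]) -> tuple[pd.DataFrame, float, float]:
    """Pairwise Spearman rank correlations between nodal score vectors.

    Returns (table of pairs with rho, mean rho, sd of rho).  A constant
    vector has undefined ranks; pairs involving one give NaN and are
    excluded from the mean/sd.
    """
    vectors = [np.asarray(v, dtype=float) for v in score_vectors]
    if len(vectors) < 2:
        raise ValueError("need at least two score vectors")
    n = len(vectors[0])
    if any(len(v) != n for v in vectors):
        raise ValueError("score vectors must cover the same node set")
    rows = []
    for a, b in combinations(range(len(vectors)), 2):
        if np.ptp(vectors[a]) == 0 or np.ptp(vectors[b]) == 0:
            rho = float("nan")
        else:
            rho = float(stats.spearmanr(vectors[a], vectors[b]).statistic)
        rows.append({"a": a, "b": b, "rho": rho})
    table = pd.DataFrame(rows)
    valid = table["rho"].dropna()
    mean = float(valid.mean()) if len(valid) else float("nan")
    sd = float(valid.std(ddof=1)) if len(valid) > 1 else 0.0
    return table, mean, sd


def age_trend_regression(
    profiles: pd.DataFrame,
    measures: list[str] | None = None,
    alpha: float = 0.001,
    n_tests: int | None = None,
    on_insufficient: str = "raise",
) -> pd.DataFrame:
    """Per-(measure, subnetwork) OLS of measure on age.

    ``profiles`` needs columns ``age``, ``subnetwork`` and one column per
    measure.  Missing measure values (degenerate subgraphs) drop that
    subject from that cell only.  Returns one row per cell with slope m,
    offset b, two-sided slope p-value, Bonferroni-corrected p-value over
    ``n_tests`` (default: number of fitted cells) and the significance flag
    at ``alpha`` on the corrected p-value.

    Cells left with fewer than 3 subjects raise by default; with
    ``on_insufficient="skip"`` they are omitted from the output instead
    (the Bonferroni denominator still counts them as planned tests).
    """
    if on_insufficient not in ("raise", "skip"):
        raise ValueError("on_insufficient must be 'raise' or 'skip'")
    if measures is None:
        reserved = {"age", "subnetwork", "subject_id", "n_nodes"}
        measures = [c for c in profiles.columns if c not in reserved]
    subnetworks = list(pd.unique(profiles["subnetwork"]))
    cells = [(m, s) for m in measures for s in subnetworks]
    if n_tests is None:
        n_tests = len(cells)
    rows = []
    n_dropped = 0
    for measure, sub in cells:
        block = profiles.loc[profiles["subnetwork"] == sub, ["age", measure]]
        n_dropped += int(block[measure].isna().sum())
        block = block.dropna()
        if len(block) < 3:
            if on_insufficient == "skip":
                continue
            raise ValueError(
                f"fewer than 3 subjects with data for ({measure}, {sub})"
            )
        X = sm.add_constant(block["age"].to_numpy())
        fit = sm.OLS(block[measure].to_numpy(), X).fit()
        b, m = fit.params
        p = fit.pvalues[1]
        p_corr = min(p * n_tests, 1.0)
        rows.append(
            {
                "measure": measure,
                "subnetwork": sub,
                "slope": float(m),
                "offset": float(b),
                "p_value": float(p),
                "p_corrected": float(p_corr),
                "significant": bool(p_corr < alpha),
                "n_subjects": len(block),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_missing_dropped"] = n_dropped
    return out
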