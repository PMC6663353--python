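"""Orchestration of the two life-span experiments.

Experiment 1 (`run_group_experiment`): build one consensus connectome per
age group, compute NDI, rich-club profile and Tier model for each, and
summarize cross-group consistency (pairwise Spearman of nodal NDI and
tier/RC confusion matrices).

Experiment 2 (`run_cohort_experiment`): build the cohort connectome over
all subjects, define NDI Tiers and RC/F/S subnetworks once from it, apply
those memberships to every subject's individual connectome, fit age trends
of transitivity/efficiency/assortativity per subnetwork, and (optionally)
assign Tiers per subject to measure nodal assignment stability.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from ndikit.connectome_io import (
    AGE_GROUPS,
    CohortManifest,
    Connectome,
    load_connectome,
)
from ndikit.group_connectome import build_group_connectome
from ndikit.lifespan_stats import age_trend_regression, ndi_rank_consistency
from ndikit.ndi_core import cohort_i_max, ndi_scores
from ndikit.richclub import RCProfile, rich_club_analysis
from ndikit.subnetwork_metrics import subnetwork_profile
from ndikit.tiers import (
    TierModel,
    assign_tiers,
    fit_log_gmm,
    select_component_count,
    subject_tier_consensus,
    tier_confusion,
)

logger = logging.getLogger("ndikit")

__all__ = ["RunConfig", "GroupResult", "run_group_experiment", "run_cohort_experiment"]


@dataclass(frozen=True)
class RunConfig:
    """Shared knobs of both experiments; seeds are recorded in all outputs."""

    consensus_fraction: float = 0.9
    n_rand: int = 1000
    seed: int = 0
    alpha_rc: float = 0.05
    alpha_trend: float = 0.001
    g_candidates: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    subject_level_tiers: bool = True
    output_dir: str | None = None


@dataclass(frozen=True)
class GroupResult:
    """Per-group (or cohort) analysis bundle."""

    name: str
    connectome: Connectome
    ndi: np.ndarray
    rc: RCProfile
    tier_model: TierModel
    tiers: np.ndarray
    g_table: pd.DataFrame = field(repr=False)


def _load_cohort(manifest: CohortManifest, connectomes: list[Connectome] | None):
    if connectomes is not None:
        return connectomes
    return [load_connectome(p) for p in manifest.table["path"]]


def _analyse_connectome(name: str, c: Connectome, i_max: float, cfg: RunConfig) -> GroupResult:
    scores = ndi_scores(c, i_max=i_max)
    rc = rich_club_analysis(c, n_rand=cfg.n_rand, seed=cfg.seed, alpha=cfg.alpha_rc)
    g, g_table = select_component_count(scores, list(cfg.g_candidates), seed=cfg.seed)
    model = fit_log_gmm(scores, g, seed=cfg.seed)
    tiers = assign_tiers(scores, model.boundaries)
    logger.info(
        "%s: k_max=%s |RC|=%d g=%d boundaries=%s",
        name, rc.k_max, len(rc.rc_nodes), g, np.round(model.boundaries, 2),
    )
    return GroupResult(name, c, scores.ndi, rc, model, tiers, g_table)


def run_group_experiment(
    manifest: CohortManifest,
    connectomes: list[Connectome] | None = None,
    cfg: RunConfig = RunConfig(),
) -> dict:
    """Per-age-group consensus connectomes, NDI, RC, Tiers and consistency."""
    cohort = _load_cohort(manifest, connectomes)
    i_max = cohort_i_max(cohort)
    groups: dict[str, GroupResult] = {}
    for grp in AGE_GROUPS:
        members = manifest.table["age_group"] == grp
        if not members.any():
            continue
        subset = [cohort[i] for i in np.flatnonzero(members.to_numpy())]
        g_conn = build_group_connectome(subset, cfg.consensus_fraction)
        groups[grp] = _analyse_connectome(grp, g_conn.connectome, i_max, cfg)
    if not groups:
        raise ValueError("no non-empty age group in manifest")
    names = list(groups)
    consistency = None
    if len(names) >= 2:
        _, mean_rho, sd_rho = ndi_rank_consistency([groups[n].ndi for n in names])
        consistency = {"mean_spearman": mean_rho, "sd_spearman": sd_rho}
    tier_conf = {
        f"{a}_vs_{b}": tier_confusion(groups[a].tiers, groups[b].tiers)
        for a, b in combinations(names, 2)
    }
    rc_conf = {
        f"{a}_vs_{b}": tier_confusion(groups[a].rc.labels, groups[b].rc.labels)
        for a, b in combinations(names, 2)
        if groups[a].rc.k_max is not None and groups[b].rc.k_max is not None
    }
    result = {
        "groups": groups,
        "consistency": consistency,
        "tier_confusion": tier_conf,
        "rc_confusion": rc_conf,
        "i_max": i_max,
        "config": cfg,
    }
    _maybe_write_group_outputs(result, cfg)
    return result


def _memberships(result: GroupResult) -> dict[str, np.ndarray]:
    """Subnetwork member index sets from one analysed connectome."""
    out = {}
    for t in range(1, result.tier_model.n_tiers + 1):
        out[f"Tier{t}"] = np.flatnonzero(result.tiers == t)
    for lab in ("RC", "F", "S"):
        out[lab] = np.flatnonzero(result.rc.labels == lab)
    return out


def run_cohort_experiment(
    manifest: CohortManifest,
    connectomes: list[Connectome] | None = None,
    cfg: RunConfig = RunConfig(),
) -> dict:
    """Cohort-defined subnetworks applied to every subject, plus age trends."""
    cohort = _load_cohort(manifest, connectomes)
    i_max = cohort_i_max(cohort)
    g_conn = build_group_connectome(cohort, cfg.consensus_fraction)
    cohort_result = _analyse_connectome("cohort", g_conn.connectome, i_max, cfg)
    memberships = _memberships(cohort_result)
    ages = manifest.table["age"].to_numpy(float)
    ids = manifest.table["subject_id"].to_numpy(str)
    rows = []
    for s, c in enumerate(cohort):
        for label, members in memberships.items():
            if len(members) < 3:
                continue
            prof = subnetwork_profile(c, members, subject_id=ids[s], subnetwork=label)
            rows.append(
                {
                    "subject_id": ids[s],
                    "age": ages[s],
                    "subnetwork": label,
                    "transitivity": prof.transitivity,
                    "efficiency": prof.efficiency,
                    "assortativity": prof.assortativity,
                    "mean_strength": prof.mean_strength,
                    "density": prof.density,
                }
            )
    profiles = pd.DataFrame(rows)
    trends = age_trend_regression(
        profiles,
        measures=["transitivity", "efficiency", "assortativity"],
        alpha=cfg.alpha_trend,
        on_insufficient="skip",
    )
    n_skipped = trends.attrs.get("n_missing_dropped", 0)
    if n_skipped:
        logger.info("age trends: %d degenerate metric values dropped pairwise", n_skipped)
    subnetwork_summary = (
        profiles.groupby("subnetwork")[["mean_strength", "density"]]
        .agg(["mean", "std"])
    )
    subject_tiers = None
    consensus = None
    if cfg.subject_level_tiers:
        labels = np.empty((len(cohort), cohort[0].n_nodes), dtype=int)
        n_fallback = 0
        g_fixed = cohort_result.tier_model.g
        for s, c in enumerate(cohort):
            scores = ndi_scores(c, i_max=i_max)
            try:
                model = fit_log_gmm(scores, g_fixed, seed=cfg.seed)
                labels[s] = assign_tiers(scores, model.boundaries)
            except ValueError:
                labels[s] = assign_tiers(scores, cohort_result.tier_model.boundaries)
                n_fallback += 1
        if n_fallback:
            logger.info("subject-level tiers: cohort boundaries substituted for "
                        "%d degenerate subject fits", n_fallback)
        median, spread = subject_tier_consensus(labels)
        subject_tiers = labels
        consensus = {"median": median, "spread": spread, "n_fallback": n_fallback}
    result = {
        "cohort": cohort_result,
        "memberships": memberships,
        "profiles": profiles,
        "trends": trends,
        "subnetwork_summary": subnetwork_summary,
        "subject_tiers": subject_tiers,
        "tier_consensus": consensus,
        "i_max": i_max,
        "config": cfg,
    }
    _maybe_write_cohort_outputs(result, cfg)
    return result


def _config_header(cfg: RunConfig) -> dict:
    return {"config": asdict(cfg)}


def _maybe_write_group_outputs(result: dict, cfg: RunConfig) -> None:
    if cfg.output_dir is None:
        return
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = _config_header(cfg)
    for name, g in result["groups"].items():
        summary[name] = {
            "k_max": g.rc.k_max,
            "n_rc": int(len(g.rc.rc_nodes)),
            "g": g.tier_model.g,
            "boundaries": g.tier_model.boundaries.tolist(),
            "tier_sizes": np.bincount(g.tiers)[1:].tolist(),
        }
        np.savetxt(out / f"ndi_{name}.tsv", g.ndi, fmt="%.10g")
    summary["consistency"] = result["consistency"]
    with open(out / "group_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def _maybe_write_cohort_outputs(result: dict, cfg: RunConfig) -> None:
    if cfg.output_dir is None:
        return
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["profiles"].to_csv(out / "profiles.tsv", sep="\t", index=False)
    result["trends"].to_csv(out / "trends.tsv", sep="\t", index=False)
    c = result["cohort"]
    summary = _config_header(cfg)
    summary["cohort"] = {
        "k_max": c.rc.k_max,
        "n_rc": int(len(c.rc.rc_nodes)),
        "g": c.tier_model.g,
        "boundaries": c.tier_model.boundaries.tolist(),
        "subnetwork_sizes": {k: int(len(v)) for k, v in result["memberships"].items()},
    }
    with open(out / "cohort_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
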