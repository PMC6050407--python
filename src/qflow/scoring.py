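"""Rule-based drug-target scoring of population x marker results.

A receptor is an attractive primary drug target on a cell population when
it is (i) highly available — a large fraction of cells carry it above a
therapeutically meaningful surface density (default: >= 70% of cells above
6,000 receptors/cell); (ii) homogeneously expressed — quadratic entropy
below the low/high boundary (default 0.7); and (iii) tumor-specific —
ensemble concentration at least a configurable fold (default 2x) above a
healthy-tissue reference. When no reference is supplied the specificity
criterion is skipped and the score is marked unscored on that axis rather
than failed, since healthy baselines are often unavailable.

Separately, a receptor carried at high concentration (default >= 10x the
ensemble geometric mean) by a minority subpopulation (component weight
<= 10%) is flagged as a combination-therapy candidate: such minority
high-receptor pools are plausible alternative signaling routes behind
resistance to single-agent treatment and are invisible to bulk averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import TargetCriteriaConfig
from .mixture import MixtureFit
from .stats import QEResult, ReceptorDistribution

__all__ = ["TargetCriteria", "TargetScore", "score_target", "rank_targets"]

# TargetCriteria is the validated config model; re-exported under the
# domain name so scoring can be used without touching pipeline config.
TargetCriteria = TargetCriteriaConfig


@dataclass(frozen=True)
class TargetScore:
    population: str
    marker: str
    availability: float  # fraction of cells above the receptor floor
    qe: float
    ensemble_gm: float
    specificity_fold: float | None  # None when no healthy reference exists
    specificity_scored: bool
    primary_target: bool
    combination_candidate: bool
    minority_weight: float | None = None
    minority_receptors: float | None = None


def score_target(
    dist: ReceptorDistribution,
    qe: QEResult,
    fit: MixtureFit,
    ensemble_gm: float,
    reference_gm: float | None = None,
    criteria: TargetCriteria | None = None,
) -> TargetScore:
    """Score one population x marker against the targeting criteria."""
    criteria = criteria or TargetCriteria()
    if dist.n_cells == 0:
        raise ValueError("cannot score an empty receptor distribution")
    if ensemble_gm <= 0:
        raise ValueError("ensemble geometric mean must be positive")

    availability = float(
        np.mean(dist.values > criteria.availability_receptors_min)
    )

    fold: float | None = None
    specificity_ok = True  # absent reference -> criterion skipped, not failed
    scored = reference_gm is not None
    if scored:
        if reference_gm <= 0:
            raise ValueError("reference geometric mean must be positive")
        fold = ensemble_gm / reference_gm
        specificity_ok = fold >= criteria.specificity_fold_min

    primary = (
        availability >= criteria.availability_fraction_min
        and qe.qe < criteria.qe_max
        and specificity_ok
    )

    minority_weight = minority_receptors = None
    combo = False
    for comp in fit.components:
        high = comp.receptors_per_cell >= criteria.minority_fold_min * ensemble_gm
        if comp.weight <= criteria.minority_weight_max and high:
            combo = True
            if minority_receptors is None or comp.receptors_per_cell > minority_receptors:
                minority_weight = comp.weight
                minority_receptors = comp.receptors_per_cell

    return TargetScore(
        population=dist.population,
        marker=dist.marker,
        availability=availability,
        qe=qe.qe,
        ensemble_gm=float(ensemble_gm),
        specificity_fold=fold,
        specificity_scored=scored,
        primary_target=bool(primary),
        combination_candidate=bool(combo),
        minority_weight=minority_weight,
        minority_receptors=minority_receptors,
    )


def rank_targets(scores: list[TargetScore]) -> pd.DataFrame:
    """Order scores: primary targets (descending availability), then
    combination candidates, then the rest. Stable within tiers."""
    if not scores:
        raise ValueError("need at least one score to rank")
    rows = []
    for s in scores:
        tier = 0 if s.primary_target else (1 if s.combination_candidate else 2)
        rows.append(
            {
                "population": s.population,
                "marker": s.marker,
                "tier": tier,
                "primary_target": s.primary_target,
                "combination_candidate": s.combination_candidate,
                "availability": s.availability,
                "qe": s.qe,
                "ensemble_gm": s.ensemble_gm,
                "specificity_fold": s.specificity_fold,
                "specificity_scored": s.specificity_scored,
                "minority_weight": s.minority_weight,
                "minority_receptors": s.minority_receptors,
            }
        )
    df = pd.DataFrame(rows)
    # mergesort is stable; availability descends only inside the primary tier
    df["_avail_key"] = np.where(df["tier"] == 0, -df["availability"], 0.0)
    df = df.sort_values(["tier", "_avail_key"], kind="mergesort").drop(columns="_avail_key")
    return df.reset_index(drop=True)
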