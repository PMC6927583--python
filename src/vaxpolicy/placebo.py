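"""Placebo (permutation) inference for synthetic-control effect sizes.

Synthetic-control studies of a single treated unit have no sampling-based
standard error; inference instead reassigns "treatment" to each control unit
in turn, refits the whole procedure, and asks where the true treated effect
falls in the resulting permutation distribution.  The prespecified decision
rule here flags the effect as meaningful when the treated unit lies in the
top fifth percentile of all evaluated units, after orienting effects so the
hypothesized direction (e.g. coverage up, nonmedical exemptions down) is
positive.  Ties rank against the treated unit, which is conservative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .panel import PanelDataset
from .synth import InfeasibleProblemError, SCResult, fit_synthetic_control

__all__ = ["PlaceboResult", "run_placebo_tests", "rank_and_classify"]

#: Hypothesized direction of the policy effect for each standard outcome.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "mmr": "increase",
    "overall": "increase",
    "nonmedical": "decrease",
    "medical": "increase",
}

_TOP_PERCENTILE = 5.0  # prespecified significance rule


@dataclass
class PlaceboResult:
    """Permutation distribution of effect sizes and the treated unit's rank."""

    outcome: str
    effects: dict[str, float]  # placebo unit -> raw effect size
    treated_id: str
    treated_effect: float
    direction: str
    rank: int
    n_evaluated: int
    percentile: float
    meaningful: bool
    excluded_units: list[tuple[str, str]] = field(default_factory=list)
    gap_trajectories: dict[str, dict[int, float]] = field(default_factory=dict)

    def effects_table(self) -> pd.DataFrame:
        """Per-unit effect sizes (treated unit first), plot-ready."""
        rows = [{"unit_id": self.treated_id, "effect_size": self.treated_effect,
                 "is_treated": True}]
        rows += [{"unit_id": u, "effect_size": e, "is_treated": False}
                 for u, e in sorted(self.effects.items())]
        return pd.DataFrame(rows)

    def trajectories_table(self) -> pd.DataFrame:
        """Long table of gap trajectories for every evaluated unit."""
        rows = [
            {"unit_id": u, "year": y, "gap": g, "is_treated": u == self.treated_id}
            for u, gaps in sorted(self.gap_trajectories.items())
            for y, g in sorted(gaps.items())
        ]
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "outcome": self.outcome,
                "treated_id": self.treated_id,
                "treated_effect": self.treated_effect,
                "direction": self.direction,
                "rank": self.rank,
                "n_evaluated": self.n_evaluated,
                "percentile": self.percentile,
                "meaningful": self.meaningful,
                "effects": self.effects,
                "excluded_units": [list(e) for e in self.excluded_units],
                "gap_trajectories": {
                    u: {str(y): g for y, g in gaps.items()}
                    for u, gaps in self.gap_trajectories.items()
                },
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def rank_and_classify(
    effects: Mapping[str, float],
    treated_effect: float,
    direction: str,
) -> tuple[int, float, bool]:
    """Rank the treated effect within the placebo distribution.

    Effects are oriented so the hypothesized ``direction`` is positive
    (a decrease hypothesis flips the sign).  The treated unit's rank is
    1 plus the number of placebo effects at least as large as its own —
    ties count against it.  Returns ``(rank, percentile, meaningful)`` with
    ``percentile = 100 * rank / n_evaluated`` and the meaningful flag set by
    the top-fifth-percentile rule.
    """
    if not effects:
        raise ValueError("effects must be nonempty")
    if direction not in ("increase", "decrease"):
        raise ValueError(f"direction must be 'increase' or 'decrease', got {direction!r}")
    sign = 1.0 if direction == "increase" else -1.0
    t = sign * treated_effect
    n_above = sum(1 for e in effects.values() if sign * e >= t)
    rank = 1 + n_above
    n_evaluated = len(effects) + 1
    percentile = 100.0 * rank / n_evaluated
    return rank, percentile, percentile <= _TOP_PERCENTILE


def run_placebo_tests(
    panel: PanelDataset,
    outcome: str,
    predictors: Sequence[str] = (),
    treated: str | None = None,
    policy_year: int | None = None,
    direction: str | None = None,
    treated_result: SCResult | None = None,
) -> PlaceboResult:
    """Refit the synthetic control with each control unit recast as treated.

    Every control unit c gets its own fit with the same predictor set and a
    donor pool of all units except c and except the true treated unit (which
    is exposed post-policy and would contaminate counterfactuals).  Control
    units whose fit is infeasible (missing data) are recorded in
    ``excluded_units`` rather than aborting.  Gap trajectories are retained
    for every evaluated unit.

    ``direction`` defaults by outcome name (coverage outcomes: increase;
    nonmedical exemptions: decrease); pass it explicitly for custom outcomes.
    A precomputed fit for the true treated unit can be supplied to avoid
    refitting.
    """
    if treated is None:
        treated = next(iter(panel.treated_units))
    if direction is None:
        try:
            direction = DEFAULT_DIRECTIONS[outcome]
        except KeyError:
            raise ValueError(
                f"no default direction for outcome {outcome!r}; pass direction="
            ) from None

    if treated_result is None:
        treated_result = fit_synthetic_control(
            panel, outcome, predictors, treated, policy_year
        )

    controls = [u for u in panel.units if u != treated]
    effects: dict[str, float] = {}
    excluded: list[tuple[str, str]] = []
    trajectories: dict[str, dict[int, float]] = {treated: dict(treated_result.gaps)}
    for c in controls:
        pool = [u for u in panel.units if u not in (c, treated)]
        try:
            res = fit_synthetic_control(
                panel, outcome, predictors, treated=c,
                policy_year=policy_year, donor_pool=pool,
            )
        except (InfeasibleProblemError, KeyError) as exc:
            excluded.append((c, str(exc)))
            continue
        effects[c] = res.effect_size
        trajectories[c] = dict(res.gaps)

    if not effects:
        raise InfeasibleProblemError("no placebo fit succeeded", excluded=excluded)
    rank, percentile, meaningful = rank_and_classify(
        effects, treated_result.effect_size, direction
    )
    return PlaceboResult(
        outcome=outcome,
        effects=effects,
        treated_id=treated,
        treated_effect=treated_result.effect_size,
        direction=direction,
        rank=rank,
        n_evaluated=len(effects) + 1,
        percentile=percentile,
        meaningful=meaningful,
        excluded_units=excluded,
        gap_trajectories=trajectories,
    )
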