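"""Robustness suite: leave-one-out, covariate sweep, and the overall-coverage
subanalysis.

Leave-one-out reruns the full synthetic-control or difference-in-differences
analysis once per control state excluded, exposing how much any single state
drives the effect estimate.  The covariate sweep refits the synthetic control
under alternative predictor sets.  The overall-coverage-only subanalysis
refits the county regression after dropping counties whose overall coverage
was proxied from MMR coverage during cleaning.

Failed refits (e.g. a donor pool that becomes infeasible) are recorded on the
table's ``failures`` list rather than aborting, so every control state is
accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .did import DiDResult, INTERACTION, fit_did
from .panel import CleaningReport, PanelDataset
from .synth import InfeasibleProblemError, fit_synthetic_control

__all__ = [
    "SensitivityTable",
    "leave_one_out",
    "overall_only_subanalysis",
    "covariate_sweep",
]


@dataclass
class SensitivityTable:
    """Rows of (label, effect_size, auxiliary) for one robustness analysis."""

    analysis: str  # sc_loo | did_loo | covariate_sweep | overall_only
    rows: list[tuple[str, float, dict]] = field(default_factory=list)
    failures: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        assert all(np.isfinite(e) for _, e, _ in self.rows)

    def to_frame(self) -> pd.DataFrame:
        recs = [{"label": lbl, "effect_size": eff, **aux} for lbl, eff, aux in self.rows]
        recs += [{"label": lbl, "effect_size": np.nan, "failed": reason}
                 for lbl, reason in self.failures]
        return pd.DataFrame(recs)


def leave_one_out(
    panel: PanelDataset,
    analysis: str,
    outcome: str,
    predictors: Sequence[str] = (),
    covariates: Sequence[str] = (),
    treated: str | None = None,
    policy_year: int | None = None,
) -> SensitivityTable:
    """Rerun the analysis once per control state excluded.

    ``analysis`` is ``"sc"`` (synthetic control; ``predictors`` applies) or
    ``"did"`` (county regression; ``covariates`` applies).  Rows are labeled
    by the excluded state; auxiliary columns carry donor weights for SC and
    the interaction CI for DiD.
    """
    if analysis not in ("sc", "did"):
        raise ValueError("analysis must be 'sc' or 'did'")
    if treated is None:
        treated = next(iter(panel.treated_units))
    parents = panel.parent_state_of()
    treated_states = {parents[u] for u in panel.treated_units} or {treated}
    control_states = sorted(set(parents) - treated_states)
    if len(control_states) < 3:
        raise ValueError(f"need >= 3 control states, have {len(control_states)}")

    table = SensitivityTable(analysis=f"{analysis}_loo")
    for state in control_states:
        keep = [u for u in panel.units if parents[u] != state]
        sub = panel.subset_units(keep)
        try:
            if analysis == "sc":
                res = fit_synthetic_control(sub, outcome, predictors, treated, policy_year)
                aux = {f"w[{d}]": w for d, w in res.donor_contributions.items() if w > 1e-8}
                aux["pre_mspe"] = res.weights.pre_mspe
                table.rows.append((state, res.effect_size, aux))
            else:
                res = fit_did(sub, outcome, covariates, policy_year)
                aux = {
                    "ci_low": res.ci_low[INTERACTION],
                    "ci_high": res.ci_high[INTERACTION],
                    "n_clusters": res.n_clusters,
                }
                table.rows.append((state, res.policy_effect, aux))
        except (InfeasibleProblemError, ValueError, KeyError) as exc:
            table.failures.append((state, str(exc)))
    return table


def overall_only_subanalysis(
    panel: PanelDataset,
    report: CleaningReport,
    outcome: str = "overall",
    covariates: Sequence[str] = (),
    policy_year: int | None = None,
) -> DiDResult:
    """Refit the county regression on counties that truly report overall coverage.

    Counties whose overall-coverage outcome was proxy-substituted from MMR
    (as recorded in the cleaning report) are dropped before refitting.
    """
    proxied = report.proxied_units
    keep = [u for u in panel.units if u not in proxied]
    controls_left = [u for u in keep if u not in panel.treated_units]
    if not controls_left:
        raise InfeasibleProblemError("all control counties were proxy-substituted")
    sub = panel.subset_units(keep)
    return fit_did(sub, outcome, covariates, policy_year)


def covariate_sweep(
    panel: PanelDataset,
    outcome: str,
    predictor_sets: Sequence[Sequence[str]],
    treated: str | None = None,
    policy_year: int | None = None,
) -> SensitivityTable:
    """Refit the synthetic control once per candidate predictor set."""
    table = SensitivityTable(analysis="covariate_sweep")
    for pred_set in predictor_sets:
        label = "+".join(pred_set) if pred_set else "(outcome mean only)"
        try:
            res = fit_synthetic_control(panel, outcome, list(pred_set), treated, policy_year)
            table.rows.append((label, res.effect_size, {"pre_mspe": res.weights.pre_mspe}))
        except (InfeasibleProblemError, KeyError) as exc:
            table.failures.append((label, str(exc)))
    return table
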