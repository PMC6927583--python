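"""Synthetic control construction for a single treated unit.

The synthetic control method builds a counterfactual for one treated unit
(here a state that changed its school-entry vaccination law) as a convex
combination of untreated "donor" units.  Donor weights W live on the simplex
and are chosen to match the treated unit's predictors; predictor weights V
(also on the simplex) govern how much each predictor matters and are chosen
so that the implied W reproduces the treated unit's *prepolicy outcome path*
as closely as possible.  This is the classic nested (bilevel) optimisation:

    inner:  W*(V) = argmin_{W in simplex} (X1 - X0 W)' diag(V) (X1 - X0 W)
    outer:  V*    = argmin_{V in simplex} (1/T0) || Z1 - Z0 W*(V) ||^2

The effect size is the pre-to-post change difference

    delta = mean_post gap(t) - mean_pre gap(t),   gap(t) = Y1(t) - Y0(t) W,

in percentage points; because the weights sum to one, gaps are invariant to
adding a common constant to every unit's outcome.

Predictors are the prepolicy outcome mean plus named covariates averaged over
the prepolicy window, z-scored across the treated-plus-donor pool so V is
comparable across predictors of different scales.  Forward stepwise predictor
selection with a held-out tail of prepolicy years guards against overfitting
the pre-period.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .panel import PanelDataset

__all__ = [
    "SCProblem",
    "SCWeights",
    "SCResult",
    "InfeasibleProblemError",
    "build_sc_problem",
    "solve_inner_weights",
    "optimize_v",
    "fit_synthetic_control",
    "select_predictors_stepwise",
]

#: Fixed seed for the random multi-starts of the outer V search.
_V_SEARCH_SEED = 20160701
_INNER_TOL = 1e-8


class InfeasibleProblemError(RuntimeError):
    """Raised when too few donors survive the missing-data exclusions."""

    def __init__(self, message: str, excluded: list[tuple[str, str]] | None = None):
        super().__init__(message)
        self.excluded = excluded or []


@dataclass(frozen=True)
class SCProblem:
    """Matrices of one synthetic-control fit.

    ``X1`` (k,) and ``X0`` (k, J) hold standardized predictor values for the
    treated unit and the J donors; ``Z1`` (T0,) and ``Z0`` (T0, J) the raw
    prepolicy outcome paths; ``Y1_all`` (T,) and ``Y0_all`` (T, J) the full
    outcome paths over ``years``.  ``scaling`` records the per-predictor
    (location, scale) used for the z-scoring.
    """

    treated_id: str
    donor_ids: tuple[str, ...]
    predictor_names: tuple[str, ...]
    X1: np.ndarray
    X0: np.ndarray
    Z1: np.ndarray
    Z0: np.ndarray
    Y1_all: np.ndarray
    Y0_all: np.ndarray
    years: tuple[int, ...]
    pre_years: tuple[int, ...]
    scaling: tuple[tuple[float, float], ...]
    dropped_donors: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        J, k, T0 = len(self.donor_ids), len(self.predictor_names), len(self.pre_years)
        assert self.treated_id not in self.donor_ids
        assert len(set(self.donor_ids)) == J and J >= 2
        assert self.X1.shape == (k,) and self.X0.shape == (k, J)
        assert self.Z1.shape == (T0,) and self.Z0.shape == (T0, J)
        assert np.isfinite(self.X0).all() and np.isfinite(self.Z0).all()


@dataclass(frozen=True)
class SCWeights:
    """Donor weights W, predictor weights V, and the fit diagnostics."""

    W: np.ndarray
    V: np.ndarray
    inner_objective: float
    pre_mspe: float

    def __post_init__(self):
        for vec, name in ((self.W, "W"), (self.V, "V")):
            if (vec < -1e-10).any() or abs(vec.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        assert self.pre_mspe >= 0


@dataclass(frozen=True)
class SCResult:
    """Per-year gaps and the pre/post effect size of one fit."""

    treated_id: str
    outcome: str
    weights: SCWeights
    donor_contributions: dict[str, float]
    predictor_weights: dict[str, float]
    gaps: dict[int, float]
    effect_size: float
    pre_years: tuple[int, ...]
    post_years: tuple[int, ...]
    trajectories: pd.DataFrame  # columns: year, treated, synthetic, gap

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "treated_id": self.treated_id,
                "outcome": self.outcome,
                "donor_weights": self.donor_contributions,
                "predictor_weights": self.predictor_weights,
                "gaps": {str(y): g for y, g in self.gaps.items()},
                "effect_size": self.effect_size,
                "pre_mspe": self.weights.pre_mspe,
                "trajectories": {
                    "year": [int(y) for y in self.trajectories["year"]],
                    "treated": list(self.trajectories["treated"]),
                    "synthetic": list(self.trajectories["synthetic"]),
                },
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


# ---------------------------------------------------------------------------
# Problem construction
# ---------------------------------------------------------------------------


def build_sc_problem(
    panel: PanelDataset,
    outcome: str,
    predictors: Sequence[str],
    treated: str,
    policy_year: int | None = None,
    donor_pool: Sequence[str] | None = None,
    outcome_lags: bool = False,
) -> SCProblem:
    """Assemble the matrices of a synthetic-control fit from a panel.

    Donors are all non-treated units (or ``donor_pool`` if given) that have
    complete prepolicy outcomes and complete predictor values; units with any
    missing relevant cell are dropped and recorded.  Predictor rows are the
    prepolicy outcome mean followed by each named covariate averaged over the
    prepolicy window, z-scored across the treated-plus-donor pool; rows with
    zero variance are dropped.  With ``outcome_lags`` the single prepolicy
    mean row is replaced by one row per prepolicy year, which matches the
    full pretreatment path instead of its average.
    """
    if outcome not in panel.outcomes:
        raise KeyError(f"outcome {outcome!r} not in panel (have {panel.outcomes})")
    policy_year = panel.policy_year if policy_year is None else policy_year
    years = panel.years
    pre = [y for y in years if y < policy_year]
    if len(pre) < 2:
        raise InfeasibleProblemError(f"need >= 2 prepolicy years, have {len(pre)}")

    wide = panel.wide(outcome).reindex(columns=years)
    if treated not in wide.index:
        raise KeyError(f"treated unit {treated!r} not in panel")
    candidates = list(donor_pool) if donor_pool is not None else [
        u for u in wide.index if u != treated
    ]
    candidates = [u for u in candidates if u != treated]

    cov_means = _prepolicy_covariate_means(panel, predictors, pre)
    t_pre = wide.loc[treated, pre].to_numpy(dtype=float)
    if np.isnan(t_pre).any() or (predictors and np.isnan(
            cov_means.loc[treated].to_numpy(dtype=float)).any()):
        raise InfeasibleProblemError(f"treated unit {treated!r} has missing prepolicy data")

    dropped: list[tuple[str, str]] = []
    donors: list[str] = []
    for u in candidates:
        if np.isnan(wide.loc[u, pre].to_numpy(dtype=float)).any():
            dropped.append((u, "missing_prepolicy_outcome"))
        elif predictors and np.isnan(cov_means.loc[u].to_numpy(dtype=float)).any():
            dropped.append((u, "missing_predictor"))
        else:
            donors.append(u)
    if len(donors) < 2:
        raise InfeasibleProblemError(
            f"only {len(donors)} donors survive exclusions for treated {treated!r}",
            excluded=dropped,
        )

    # predictor matrix: prepolicy outcome mean (or per-year lags), then covariates
    if outcome_lags:
        base_names = [f"lag({outcome},{y})" for y in pre]
        base1 = t_pre
        base0 = {u: wide.loc[u, pre].to_numpy(dtype=float) for u in donors}
    else:
        base_names = [f"pre_mean({outcome})"]
        base1 = np.array([t_pre.mean()])
        base0 = {u: np.array([wide.loc[u, pre].to_numpy(dtype=float).mean()])
                 for u in donors}
    names = base_names + list(predictors)
    raw1 = np.concatenate([base1,
                           cov_means.loc[treated].to_numpy(dtype=float) if predictors else []])
    raw0 = np.vstack([
        np.concatenate([base0[u],
                        cov_means.loc[u].to_numpy(dtype=float) if predictors else []])
        for u in donors
    ]).T  # k x J

    keep, scaling, X1_rows, X0_rows = [], [], [], []
    for r, name in enumerate(names):
        pool = np.concatenate([[raw1[r]], raw0[r]])
        loc, scale = float(pool.mean()), float(pool.std())
        if scale < 1e-12:
            continue  # zero variance carries no matching information
        keep.append(name)
        scaling.append((loc, scale))
        X1_rows.append((raw1[r] - loc) / scale)
        X0_rows.append((raw0[r] - loc) / scale)
    if not keep:
        raise InfeasibleProblemError("all predictors have zero variance across units")

    Z0 = wide.loc[donors, pre].to_numpy(dtype=float).T
    Y0 = wide.loc[donors, years].to_numpy(dtype=float).T
    return SCProblem(
        treated_id=treated,
        donor_ids=tuple(donors),
        predictor_names=tuple(keep),
        X1=np.array(X1_rows),
        X0=np.array(X0_rows),
        Z1=t_pre,
        Z0=Z0,
        Y1_all=wide.loc[treated, years].to_numpy(dtype=float),
        Y0_all=Y0,
        years=tuple(years),
        pre_years=tuple(pre),
        scaling=tuple(scaling),
        dropped_donors=tuple(dropped),
    )


def _prepolicy_covariate_means(
    panel: PanelDataset, predictors: Sequence[str], pre_years: list[int]
) -> pd.DataFrame:
    """Per-unit covariate means over the prepolicy window (units x predictors)."""
    if not predictors:
        return pd.DataFrame(index=pd.Index(panel.units, name="unit_id"))
    if panel.covariates is None:
        raise KeyError(f"panel has no covariates but predictors {list(predictors)} requested")
    missing = [p for p in predictors if p not in panel.covariates.columns]
    if missing:
        raise KeyError(f"covariates not in panel: {missing}")
    cov = panel.covariates
    pre = cov[cov["year"].isin(pre_years)]
    means = pre.groupby("unit_id")[list(predictors)].mean()
    return means.reindex(panel.units)


# ---------------------------------------------------------------------------
# Nested optimisation
# ---------------------------------------------------------------------------


def solve_inner_weights(problem: SCProblem, V: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve the inner simplex-constrained QP for donor weights.

    Minimises ``(X1 - X0 W)' diag(V) (X1 - X0 W)`` over the J-simplex via
    SLSQP from the uniform start (deterministic).  Returns ``(W, objective)``.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any() or V.sum() <= 0:
        raise ValueError("V must be nonnegative and not all zero")
    J = len(problem.donor_ids)
    Xv = problem.X0 * np.sqrt(V)[:, None]
    xv1 = problem.X1 * np.sqrt(V)

    def objective(w):
        r = xv1 - Xv @ w
        return float(r @ r)

    def grad(w):
        return -2.0 * Xv.T @ (xv1 - Xv @ w)

    w0 = np.full(J, 1.0 / J)
    res = minimize(
        objective,
        w0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * J,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones_like(w)}],
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    s = w.sum()
    if not np.isfinite(s) or s <= 0:
        raise RuntimeError(
            f"inner QP failed to converge (residual norm {np.sqrt(objective(w0)):.3e})"
        )
    w = w / s
    return w, objective(w)


def _pre_mspe(problem: SCProblem, W: np.ndarray) -> float:
    r = problem.Z1 - problem.Z0 @ W
    return float(r @ r) / len(problem.pre_years)


def optimize_v(problem: SCProblem, n_random_starts: int = 4) -> SCWeights:
    """Choose predictor weights V minimising prepolicy outcome MSPE.

    A deterministic multi-start Nelder-Mead search on the softmax
    parameterisation of the simplex; the start set is the uniform V, each
    simplex vertex, and ``n_random_starts`` draws from a fixed-seed RNG, so
    repeated calls are bit-identical.  The returned V is never worse (in
    prepolicy MSPE) than the uniform V.
    """
    k = len(problem.predictor_names)
    if len(problem.pre_years) < 2:
        raise InfeasibleProblemError("need >= 2 prepolicy years to calibrate V")
    if k == 1:
        V = np.array([1.0])
        W, obj = solve_inner_weights(problem, V)
        return SCWeights(W=W, V=V, inner_objective=obj, pre_mspe=_pre_mspe(problem, W))

    def mspe_of_theta(theta):
        V = _softmax(theta)
        W, _ = solve_inner_weights(problem, V)
        return _pre_mspe(problem, W)

    starts = [np.zeros(k)]
    for i in range(k):
        v = np.zeros(k)
        v[i] = 8.0  # near-vertex start
        starts.append(v)
    rng = np.random.default_rng(_V_SEARCH_SEED)
    starts.extend(rng.normal(0.0, 2.0, (n_random_starts, k)))

    best_theta, best_val = None, np.inf
    for theta0 in starts:
        res = minimize(
            mspe_of_theta,
            theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxfev": 250 * k, "disp": False},
        )
        if res.fun < best_val - 1e-12:
            best_val, best_theta = res.fun, res.x

    V = _softmax(best_theta)
    W, obj = solve_inner_weights(problem, V)
    # guarantee: no worse than uniform V
    W_u, obj_u = solve_inner_weights(problem, np.full(k, 1.0 / k))
    if _pre_mspe(problem, W_u) < _pre_mspe(problem, W):
        V, W, obj = np.full(k, 1.0 / k), W_u, obj_u
    return SCWeights(W=W, V=V, inner_objective=obj, pre_mspe=_pre_mspe(problem, W))


def _softmax(theta: np.ndarray) -> np.ndarray:
    z = np.exp(theta - theta.max())
    return z / z.sum()


# ---------------------------------------------------------------------------
# Full fit
# ---------------------------------------------------------------------------


def fit_synthetic_control(
    panel: PanelDataset,
    outcome: str,
    predictors: Sequence[str] = (),
    treated: str | None = None,
    policy_year: int | None = None,
    donor_pool: Sequence[str] | None = None,
    outcome_lags: bool = False,
) -> SCResult:
    """Fit the synthetic control and return gaps and the effect size.

    ``effect_size`` is the mean postpolicy gap minus the mean prepolicy gap,
    i.e. the pre-to-post change of the treated unit relative to its synthetic
    control, in percentage points.
    """
    if treated is None:
        if len(panel.treated_units) != 1:
            raise ValueError("treated must be given unless the panel has exactly one treated unit")
        treated = next(iter(panel.treated_units))
    problem = build_sc_problem(panel, outcome, predictors, treated, policy_year,
                               donor_pool, outcome_lags)
    weights = optimize_v(problem)

    synthetic = problem.Y0_all @ weights.W
    gaps_arr = problem.Y1_all - synthetic
    gaps = {int(y): float(g) for y, g in zip(problem.years, gaps_arr)}
    pre = problem.pre_years
    post = tuple(y for y in problem.years if y not in pre)
    effect = float(np.mean([gaps[y] for y in post]) - np.mean([gaps[y] for y in pre]))

    traj = pd.DataFrame({
        "year": list(problem.years),
        "treated": problem.Y1_all,
        "synthetic": synthetic,
        "gap": gaps_arr,
    })
    return SCResult(
        treated_id=treated,
        outcome=outcome,
        weights=weights,
        donor_contributions={d: float(w) for d, w in zip(problem.donor_ids, weights.W)},
        predictor_weights={p: float(v) for p, v in zip(problem.predictor_names, weights.V)},
        gaps=gaps,
        effect_size=effect,
        pre_years=pre,
        post_years=post,
        trajectories=traj,
    )


def select_predictors_stepwise(
    panel: PanelDataset,
    outcome: str,
    candidates: Sequence[str],
    treated: str | None = None,
    policy_year: int | None = None,
    holdout_years: int = 1,
    min_improvement: float = 1e-6,
) -> list[str]:
    """Forward stepwise covariate selection with a prepolicy holdout.

    Starting from the base predictor set (the prepolicy outcome mean alone),
    greedily add the candidate covariate that most reduces validation MSPE:
    the synthetic control is fitted on the prepolicy years excluding the last
    ``holdout_years`` and scored by mean squared gap on those held-out
    prepolicy years.  Stops when no candidate improves validation MSPE by
    more than ``min_improvement``; ties break by candidate list order.
    Returns the selected covariate names (the outcome mean is always
    implicit).
    """
    if treated is None:
        treated = next(iter(panel.treated_units))
    policy_year = panel.policy_year if policy_year is None else policy_year
    pre = [y for y in panel.years if y < policy_year]
    if not 1 <= holdout_years < len(pre):
        raise ValueError(
            f"holdout_years must be in [1, {len(pre) - 1}], got {holdout_years}"
        )
    split_year = pre[-holdout_years]  # first held-out year

    def validation_mspe(pred_set: list[str]) -> float:
        result = fit_synthetic_control(
            panel, outcome, pred_set, treated, policy_year=split_year
        )
        held = [y for y in pre if y >= split_year]
        return float(np.mean([result.gaps[y] ** 2 for y in held]))

    selected: list[str] = []
    best = validation_mspe(selected)
    remaining = [c for c in candidates]
    while remaining:
        best_cand, best_val = None, best
        for c in remaining:  # list order is the tie-break
            val = validation_mspe(selected + [c])
            if val < best_val - min_improvement:
                best_cand, best_val = c, val
        if best_cand is None:
            break
        selected.append(best_cand)
        remaining.remove(best_cand)
        best = best_val
    return selected
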