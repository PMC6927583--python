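"""County-level difference-in-differences with cluster-robust inference.

The policy effect is the coefficient on the treated x post interaction in an
ordinary-least-squares regression of the county-year outcome on an intercept,
a treated indicator (counties of the policy state), a post indicator (school
years from the policy year on), their interaction, and optional demographic
covariates:

    Y_ct = b0 + b1 treated_c + b2 post_t + b3 (treated_c x post_t) + x_ct' g + e_ct.

Because county-year errors are serially correlated within a county, the
covariance of the estimates uses the CR1 cluster-robust sandwich

    (X'X)^-1 [ sum_g X_g' e_g e_g' X_g ] (X'X)^-1 * G/(G-1) * (n-1)/(n-p),

with clusters g = counties.  Confidence intervals and p-values use a t
distribution with G - 1 degrees of freedom, a conservative standard choice
for clustered inference.  A parallel-trends diagnostic compares prepolicy
group-mean time slopes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import PanelDataset

__all__ = [
    "DiDDesign",
    "DiDResult",
    "CollinearityError",
    "build_did_design",
    "fit_ols",
    "cluster_robust_covariance",
    "fit_did",
    "parallel_trends_check",
]

INTERACTION = "treated_post"


class CollinearityError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class DiDDesign:
    """Response vector, design matrix and cluster labels of one regression."""

    y: np.ndarray
    X: np.ndarray
    cluster_ids: np.ndarray
    column_names: tuple[str, ...]

    def __post_init__(self):
        n, p = self.X.shape
        assert self.y.shape == (n,) and self.cluster_ids.shape == (n,)
        if n < p:
            raise ValueError(f"more parameters ({p}) than observations ({n})")
        cols = dict(zip(self.column_names, self.X.T))
        if {"treated", "post", INTERACTION} <= cols.keys():
            assert np.allclose(cols[INTERACTION], cols["treated"] * cols["post"])


@dataclass(frozen=True)
class DiDResult:
    """Coefficients with cluster-robust covariance, CIs and p-values."""

    coefficients: dict[str, float]
    covariance: np.ndarray
    se: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_value: dict[str, float]
    n_clusters: int
    n_obs: int
    outcome: str = ""

    @property
    def policy_effect(self) -> float:
        return self.coefficients[INTERACTION]

    def table(self) -> pd.DataFrame:
        """Regression table: one row per parameter with estimate, CI and p."""
        return pd.DataFrame(
            {
                "parameter": list(self.coefficients),
                "estimate": list(self.coefficients.values()),
                "ci_low": [self.ci_low[k] for k in self.coefficients],
                "ci_high": [self.ci_high[k] for k in self.coefficients],
                "p_value": [self.p_value[k] for k in self.coefficients],
            }
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "outcome": self.outcome,
                "coefficients": self.coefficients,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": self.p_value,
                "n_clusters": self.n_clusters,
                "n_obs": self.n_obs,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def build_did_design(
    panel: PanelDataset,
    outcome: str,
    covariates: Sequence[str] = (),
    policy_year: int | None = None,
    year_fixed_effects: bool = False,
) -> DiDDesign:
    """One row per county-year: intercept, treated, post, interaction, covariates.

    Covariates enter untransformed in their native units.  With
    ``year_fixed_effects`` the post indicator is replaced by year dummies
    (first year as reference); the interaction keeps its treated x post form.
    Raises a data error naming the first missing covariate cell.
    """
    if panel.level != "county":
        raise ValueError("difference-in-differences design requires a county-level panel")
    policy_year = panel.policy_year if policy_year is None else policy_year
    df = panel.data.sort_values(["unit_id", "year"]).reset_index(drop=True)
    if df[outcome].isna().any():
        bad = df.loc[df[outcome].isna()].iloc[0]
        raise ValueError(
            f"missing outcome cell for ({bad['unit_id']!r}, {int(bad['year'])}); "
            "clean the panel first"
        )
    if covariates:
        if panel.covariates is None:
            raise KeyError("panel has no covariate table")
        cov = panel.covariates.set_index(["unit_id", "year"])
        missing_cols = [c for c in covariates if c not in cov.columns]
        if missing_cols:
            raise KeyError(f"covariates not in panel: {missing_cols}")
        cov = cov[list(covariates)].reindex(
            pd.MultiIndex.from_frame(df[["unit_id", "year"]])
        )
        if cov.isna().any().any():
            stacked = cov.isna().stack()
            unit, year, name = stacked.index[stacked.to_numpy().argmax()]
            raise ValueError(f"missing covariate {name!r} for ({unit!r}, {int(year)})")
        cov_mat = cov.to_numpy(dtype=float)
    else:
        cov_mat = np.empty((len(df), 0))

    treated = df["unit_id"].isin(panel.treated_units).to_numpy(dtype=float)
    post = (df["year"] >= policy_year).to_numpy(dtype=float)
    cols = [np.ones(len(df)), treated]
    names = ["intercept", "treated"]
    if year_fixed_effects:
        years = sorted(df["year"].unique())
        for yv in years[1:]:
            cols.append((df["year"] == yv).to_numpy(dtype=float))
            names.append(f"year_{yv}")
    else:
        cols.append(post)
        names.append("post")
    cols.append(treated * post)
    names.append(INTERACTION)
    X = np.column_stack(cols + [cov_mat]) if cov_mat.size else np.column_stack(cols)
    names += list(covariates)
    return DiDDesign(
        y=df[outcome].to_numpy(dtype=float),
        X=X,
        cluster_ids=df["unit_id"].to_numpy(),
        column_names=tuple(names),
    )


def fit_ols(design: DiDDesign) -> tuple[dict[str, float], np.ndarray]:
    """Solve the least-squares problem; returns (coefficient map, residuals).

    Raises :class:`CollinearityError` naming candidate dependent columns when
    the design matrix is rank deficient.
    """
    X, y = design.X, design.y
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # QR with pivoting: the trailing pivots index the dependent columns
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        dep = [design.column_names[j] for j in piv[rank:]]
        raise CollinearityError(f"design matrix rank {rank} < {p}; dependent columns: {dep}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return dict(zip(design.column_names, beta)), resid


def cluster_robust_covariance(
    design: DiDDesign,
    residuals: np.ndarray,
    correction: str = "CR1",
) -> np.ndarray:
    """CR1 (Stata-style) cluster-robust sandwich covariance.

    ``correction="CR0"`` drops the small-sample factor
    G/(G-1) * (n-1)/(n-p).  With every observation its own cluster the CR1
    form reduces exactly to the HC1 heteroskedasticity-robust covariance.
    """
    X = design.X
    n, p = X.shape
    clusters = pd.unique(design.cluster_ids)
    G = len(clusters)
    if G < 2:
        raise ValueError("cluster-robust inference requires at least 2 clusters")
    bread = np.linalg.inv(X.T @ X)
    meat = np.zeros((p, p))
    for g in clusters:
        idx = design.cluster_ids == g
        s = X[idx].T @ residuals[idx]  # p-vector: X_g' e_g
        meat += np.outer(s, s)
    cov = bread @ meat @ bread
    if correction == "CR1":
        cov = cov * (G / (G - 1)) * ((n - 1) / (n - p))
    elif correction != "CR0":
        raise ValueError(f"unknown correction {correction!r}")
    return (cov + cov.T) / 2.0


def fit_did(
    panel: PanelDataset,
    outcome: str,
    covariates: Sequence[str] = (),
    policy_year: int | None = None,
    year_fixed_effects: bool = False,
    correction: str = "CR1",
) -> DiDResult:
    """Full difference-in-differences fit with cluster-robust inference."""
    design = build_did_design(panel, outcome, covariates, policy_year, year_fixed_effects)
    coefs, resid = fit_ols(design)
    cov = cluster_robust_covariance(design, resid, correction)
    G = len(pd.unique(design.cluster_ids))
    dof = G - 1
    tcrit = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    names = design.column_names
    se_map = dict(zip(names, se))
    est = np.array([coefs[k] for k in names])
    tstat = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return DiDResult(
        coefficients=coefs,
        covariance=cov,
        se=se_map,
        ci_low={k: coefs[k] - tcrit * se_map[k] for k in names},
        ci_high={k: coefs[k] + tcrit * se_map[k] for k in names},
        p_value=dict(zip(names, pvals)),
        n_clusters=G,
        n_obs=len(design.y),
        outcome=outcome,
    )


def parallel_trends_check(
    panel: PanelDataset,
    outcome: str,
    policy_year: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Prepolicy trend diagnostic for the parallel-trends assumption.

    Returns a (group, year) table of mean outcomes for the treated and
    control county groups over all years, and the difference of OLS time
    slopes (treated minus control) fitted to the *prepolicy* group means.
    A slope difference near zero supports parallel prepolicy trends.
    """
    policy_year = panel.policy_year if policy_year is None else policy_year
    pre = [y for y in panel.years if y < policy_year]
    if len(pre) < 2:
        raise ValueError("need >= 2 prepolicy years for a trend check")
    df = panel.data.copy()
    df["group"] = np.where(df["unit_id"].isin(panel.treated_units), "treated", "control")
    means = (
        df.groupby(["group", "year"])[outcome]
        .mean()
        .reset_index()
        .rename(columns={outcome: "mean"})
        .sort_values(["group", "year"])
        .reset_index(drop=True)
    )

    def slope(group: str) -> float:
        sub = means[(means["group"] == group) & (means["year"].isin(pre))]
        return float(np.polyfit(sub["year"], sub["mean"], 1)[0])

    return means, slope("treated") - slope("control")
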