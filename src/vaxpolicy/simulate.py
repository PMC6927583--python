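"""Synthetic vaccination panels with known ground truth.

The generator emulates the statistical structure of kindergarten vaccination
panels: bounded percentage outcomes with unit effects, common year effects, a
low-rank latent-factor component, AR(1) noise, counties clustered within
states, covariates correlated with the unit effects, an injected
treated-by-post policy effect of known size tau, and optional missingness.
Because tau is known, every stage of the analysis pipeline can be tested by
parameter recovery without any external data.

The outcome model for unit i in year t is

    Y_it = mu + alpha_i + delta_t + lambda_i' f_t + tau * 1{i treated, t >= policy year} + e_it,

with AR(1) errors e_it and values clamped to [0, 100] (the one nonlinearity).
Three outcomes are generated with opposite policy signs: coverage rises under
treatment while nonmedical exemptions fall and medical exemptions rise.

Default baselines (94.2 / 2.2 / 0.3 percentage points with between-unit
spreads 2.5 / 1.3 / 0.2) and default effect sizes (+4.3 / -3.9 / +2.4) are
realistic values for US kindergarten entry cohorts around 2016; they are
generator defaults, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import PanelDataset

__all__ = [
    "SimConfig",
    "simulate_state_panel",
    "simulate_county_panel",
    "inject_missingness",
    "STATE_OUTCOMES",
    "COUNTY_OUTCOMES",
    "COUNTY_COVARIATES",
]

#: Outcomes of the state panel: two-dose MMR coverage and exemption prevalences.
STATE_OUTCOMES = ("mmr", "nonmedical", "medical")
#: County panels add overall coverage (all required vaccines) alongside MMR.
COUNTY_OUTCOMES = ("overall", "mmr", "nonmedical", "medical")

#: County covariates mirroring a standard demographic adjustment set.
COUNTY_COVARIATES = (
    "median_income",
    "household_size",
    "population_100k",
    "poverty",
    "pct_white",
    "edu_lt_highschool",
    "edu_some_college",
    "edu_bachelor",
    "uninsured_children",
)


def _default_baseline() -> dict[str, tuple[float, float]]:
    return {
        "coverage": (94.2, 2.5),
        "nonmedical": (2.2, 1.3),
        "medical": (0.3, 0.2),
    }


def _default_tau() -> dict[str, float]:
    return {"coverage": 4.3, "nonmedical": -3.9, "medical": 2.4}


@dataclass
class SimConfig:
    """Parameters of the data-generating process.

    ``baseline`` maps outcome family -> (mean, between-unit sd) in percentage
    points; ``tau`` maps outcome family -> injected treated x post effect.
    The families are ``coverage`` (serves both the MMR and overall-coverage
    outcomes), ``nonmedical`` and ``medical``.
    """

    n_states: int = 45
    counties_per_state: tuple[int, int] = (3, 12)
    years: tuple[int, int] = (2011, 2017)
    policy_year: int = 2016
    treated_state: str = "CA"
    baseline: dict[str, tuple[float, float]] = field(default_factory=_default_baseline)
    common_trend: float = 0.1
    factor_loadings: int = 2
    factor_scale: float = 0.5
    noise_sd: float = 0.5
    ar1_rho: float = 0.5
    tau: dict[str, float] = field(default_factory=_default_tau)
    treated_counties: int | None = None
    county_icc: float = 0.5
    county_heterogeneity: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_states < 3:
            problems.append("n_states must be >= 3")
        lo, hi = self.counties_per_state
        if not (1 <= lo <= hi):
            problems.append("counties_per_state must be an increasing positive range")
        y0, y1 = self.years
        if y1 - y0 + 1 < 4:
            problems.append("years must span at least 4 school years")
        if not (y0 < self.policy_year <= y1):
            problems.append("policy_year must be interior to the year span")
        if not -1.0 <= self.ar1_rho <= 1.0:
            problems.append("ar1_rho must be in [-1, 1]")
        if not 0.0 <= self.county_icc <= 1.0:
            problems.append("county_icc must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            problems.append("missing_rate must be in [0, 1)")
        if self.noise_sd < 0:
            problems.append("noise_sd must be nonnegative")
        for name, (mean, sd) in self.baseline.items():
            if not (0 <= mean <= 100 and sd >= 0):
                problems.append(f"baseline[{name!r}] outside valid range")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


#: Which baseline/tau family each outcome column draws from, and the policy sign.
_FAMILY = {
    "mmr": "coverage",
    "overall": "coverage",
    "nonmedical": "nonmedical",
    "medical": "medical",
}


def _ar1(rng: np.random.Generator, n_units: int, n_years: int, rho: float, sd: float) -> np.ndarray:
    """Unit x year AR(1) noise with stationary marginal sd."""
    e = np.zeros((n_units, n_years))
    if sd == 0:
        return e
    innov_sd = sd * np.sqrt(max(1.0 - rho**2, 0.0)) if abs(rho) < 1 else 0.0
    e[:, 0] = rng.normal(0.0, sd, n_units)
    for t in range(1, n_years):
        e[:, t] = rho * e[:, t - 1] + rng.normal(0.0, innov_sd, n_units)
    return e


def _outcome_matrix(
    rng: np.random.Generator,
    cfg: SimConfig,
    outcome: str,
    alpha: np.ndarray,
    treated_mask: np.ndarray,
    effect_scale: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble one outcome's unit x year value matrix from its components."""
    mean, _sd = cfg.baseline[_FAMILY[outcome]]
    years = cfg.year_list
    n, T = alpha.shape[0], len(years)

    delta = cfg.common_trend * (np.arange(T) - (T - 1) / 2.0)
    loadings = rng.normal(0.0, 1.0, (n, cfg.factor_loadings))
    factors = rng.normal(0.0, cfg.factor_scale / max(np.sqrt(cfg.factor_loadings), 1.0),
                         (cfg.factor_loadings, T))
    noise = _ar1(rng, n, T, cfg.ar1_rho, cfg.noise_sd)

    post = np.array([y >= cfg.policy_year for y in years], dtype=float)
    tau = cfg.tau.get(_FAMILY[outcome], 0.0)
    scale = np.ones(n) if effect_scale is None else effect_scale
    effect = tau * scale[:, None] * treated_mask[:, None] * post[None, :]

    Y = mean + alpha[:, None] + delta[None, :] + loadings @ factors + effect + noise
    return np.clip(Y, 0.0, 100.0)


def _covariate_table(
    rng: np.random.Generator,
    units: list[str],
    years: list[int],
    alpha_cov: np.ndarray,
    population: np.ndarray,
) -> pd.DataFrame:
    """Covariates constant over years, several correlated with the unit effect.

    ``alpha_cov`` is the coverage-family unit effect; income and education
    load on it positively and poverty/uninsurance negatively so that
    predictor selection has genuine signal, while household size is pure
    noise.
    """
    n = len(units)
    z = alpha_cov / max(alpha_cov.std(), 1e-9)
    cov = pd.DataFrame({
        "unit_id": units,
        "median_income": 6.0 + 1.2 * z + rng.normal(0, 0.4, n),
        "household_size": rng.normal(2.6, 0.25, n),
        "population_100k": population / 1e5,
        "poverty": np.clip(14.0 - 2.5 * z + rng.normal(0, 1.5, n), 0, 100),
        "pct_white": np.clip(70.0 + 5.0 * z + rng.normal(0, 8.0, n), 0, 100),
        "edu_lt_highschool": np.clip(12.0 - 2.0 * z + rng.normal(0, 1.5, n), 0, 100),
        "edu_some_college": np.clip(30.0 + rng.normal(0, 3.0, n), 0, 100),
        "edu_bachelor": np.clip(28.0 + 4.0 * z + rng.normal(0, 3.0, n), 0, 100),
        "uninsured_children": np.clip(5.0 - 1.0 * z + rng.normal(0, 1.0, n), 0, 100),
    })
    cov = cov.loc[cov.index.repeat(len(years))].reset_index(drop=True)
    cov["year"] = years * n
    return cov[["unit_id", "year", *COUNTY_COVARIATES]]


def simulate_state_panel(config: SimConfig) -> PanelDataset:
    """Generate a state-level panel of MMR coverage and exemption prevalences.

    One treated state (``config.treated_state``) receives the injected policy
    effect from ``policy_year`` on, with the sign structure coverage up,
    nonmedical exemptions down, medical exemptions up.  Reproducible from
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, years = config.n_states, config.year_list

    units = [config.treated_state] + [f"S{i:02d}" for i in range(2, n + 1)]
    treated_mask = np.array([u == config.treated_state for u in units])
    population = np.round(rng.lognormal(mean=np.log(4e6), sigma=0.9, size=n)).astype(int)

    frames = {}
    alpha_by_family: dict[str, np.ndarray] = {}
    for outcome in STATE_OUTCOMES:
        fam = _FAMILY[outcome]
        mean, sd = config.baseline[fam]
        alpha = alpha_by_family.setdefault(fam, rng.normal(0.0, sd, n))
        frames[outcome] = _outcome_matrix(rng, config, outcome, alpha, treated_mask)

    rows = []
    for i, u in enumerate(units):
        for j, y in enumerate(years):
            rows.append({
                "unit_id": u, "parent_state": u, "year": y,
                "population": population[i],
                **{o: frames[o][i, j] for o in STATE_OUTCOMES},
            })
    data = pd.DataFrame(rows)
    covariates = _covariate_table(rng, units, years, alpha_by_family["coverage"], population.astype(float))

    panel = PanelDataset(
        level="state",
        data=data,
        treated_units=frozenset({config.treated_state}),
        policy_year=config.policy_year,
        covariates=covariates,
    )
    if config.missing_rate > 0:
        panel = inject_missingness(panel, config.missing_rate, seed=config.seed + 1)
    return panel


def simulate_county_panel(config: SimConfig) -> PanelDataset:
    """Generate a county-level panel with counties nested in states.

    Counties inherit a state-level random effect so that within-state
    intraclass correlation of the unit effects equals ``county_icc``.
    Populations are drawn heavy-tailed (lognormal) so a minimum-population
    filter binds.  All counties of the treated state are treated.  When
    ``county_heterogeneity`` > 0 the injected effect varies across treated
    counties, larger where prepolicy coverage is lower (and, for exemptions,
    where prepolicy prevalence is higher), centred so the average effect
    remains tau.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 10_000)
    years = config.year_list
    lo, hi = config.counties_per_state

    states = [config.treated_state] + [f"S{i:02d}" for i in range(2, config.n_states + 1)]
    county_units: list[str] = []
    county_state: list[str] = []
    for s in states:
        n_c = int(rng.integers(lo, hi + 1))
        if s == config.treated_state and config.treated_counties is not None:
            n_c = config.treated_counties  # treated states are often larger
        for c in range(1, n_c + 1):
            county_units.append(f"{s}-C{c:02d}")
            county_state.append(s)
    n = len(county_units)
    parent = np.array(county_state)
    treated_mask = parent == config.treated_state

    population = np.round(rng.lognormal(mean=np.log(120_000), sigma=1.1, size=n)).astype(int)

    # state effect u_s + county effect v_c with Var(u)/Var(u+v) = county_icc
    frames = {}
    alpha_by_family: dict[str, np.ndarray] = {}
    state_idx = {s: k for k, s in enumerate(states)}
    for outcome in COUNTY_OUTCOMES:
        fam = _FAMILY[outcome]
        if fam not in alpha_by_family:
            _, sd = config.baseline[fam]
            u_state = rng.normal(0.0, sd * np.sqrt(config.county_icc), len(states))
            v_county = rng.normal(0.0, sd * np.sqrt(1.0 - config.county_icc), n)
            alpha_by_family[fam] = np.array([u_state[state_idx[s]] for s in parent]) + v_county
        alpha = alpha_by_family[fam]

        scale = None
        if config.county_heterogeneity > 0:
            z = alpha / max(alpha.std(), 1e-9)
            sign = -1.0 if fam == "coverage" else 1.0  # low coverage / high exemptions -> bigger effect
            raw = np.clip(1.0 + sign * config.county_heterogeneity * z, 0.0, None)
            scale = raw / max(raw[treated_mask].mean(), 1e-9) if treated_mask.any() else raw
        frames[outcome] = _outcome_matrix(rng, config, outcome, alpha, treated_mask, scale)

    rows = []
    for i, u in enumerate(county_units):
        for j, y in enumerate(years):
            rows.append({
                "unit_id": u, "parent_state": county_state[i], "year": y,
                "population": population[i],
                **{o: frames[o][i, j] for o in COUNTY_OUTCOMES},
            })
    data = pd.DataFrame(rows)
    covariates = _covariate_table(rng, county_units, years,
                                  alpha_by_family["coverage"], population.astype(float))

    panel = PanelDataset(
        level="county",
        data=data,
        treated_units=frozenset(np.array(county_units)[treated_mask]),
        policy_year=config.policy_year,
        covariates=covariates,
    )
    if config.missing_rate > 0:
        panel = inject_missingness(panel, config.missing_rate, seed=config.seed + 10_001)
    return panel


def make_hull_panel(
    n_donors: int = 8,
    years: tuple[int, int] = (2011, 2017),
    policy_year: int = 2016,
    tau: float = 3.0,
    weights: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    outcome: str = "mmr",
) -> PanelDataset:
    """Panel whose treated unit is an exact convex combination of donors.

    Donor outcome paths and covariates follow a latent-factor model; the
    treated unit is constructed as ``weights @ donors`` in both outcomes and
    covariates, then ``tau`` is added to its post-policy years and optional
    i.i.d. noise to every cell.  With ``noise_sd = 0`` the synthetic control
    can in principle track the treated unit exactly in the prepolicy window,
    so the fitted effect should recover ``tau`` to numerical precision.
    """
    rng = np.random.default_rng(seed)
    year_list = list(range(years[0], years[1] + 1))
    T = len(year_list)
    if weights is None:
        weights = np.zeros(n_donors)
        weights[:2] = 0.5
    weights = np.asarray(weights, dtype=float)
    assert weights.shape == (n_donors,) and abs(weights.sum() - 1.0) < 1e-12

    loadings = rng.normal(0.0, 1.0, (n_donors, 2))
    factors = rng.normal(0.0, 1.0, (2, T))
    donors_Y = 85.0 + rng.normal(0.0, 2.0, n_donors)[:, None] + loadings @ factors
    treated_Y = weights @ donors_Y
    post = np.array([y >= policy_year for y in year_list], dtype=float)
    treated_Y = treated_Y + tau * post

    donor_cov = rng.normal(0.0, 1.0, (n_donors, 2)) + loadings  # correlated with outcomes
    treated_cov = weights @ donor_cov

    Y = np.vstack([treated_Y, donors_Y])
    if noise_sd > 0:
        Y = Y + rng.normal(0.0, noise_sd, Y.shape)
    Y = np.clip(Y, 0.0, 100.0)
    cov_mat = np.vstack([treated_cov, donor_cov])

    units = ["T"] + [f"D{i:02d}" for i in range(1, n_donors + 1)]
    rows = []
    for i, u in enumerate(units):
        for j, y in enumerate(year_list):
            rows.append({"unit_id": u, "parent_state": u, "year": y,
                         "population": 1_000_000, outcome: Y[i, j]})
    cov_rows = []
    for i, u in enumerate(units):
        for y in year_list:
            cov_rows.append({"unit_id": u, "year": y,
                             "cov1": cov_mat[i, 0], "cov2": cov_mat[i, 1]})
    return PanelDataset(
        level="state",
        data=pd.DataFrame(rows),
        treated_units=frozenset({"T"}),
        policy_year=policy_year,
        covariates=pd.DataFrame(cov_rows),
    )


def inject_missingness(panel: PanelDataset, missing_rate: float, seed: int) -> PanelDataset:
    """Blank each outcome cell independently with probability ``missing_rate``."""
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    if missing_rate == 0.0:
        return panel
    rng = np.random.default_rng(seed)
    df = panel.data.copy()
    for outcome in panel.outcomes:
        mask = rng.random(len(df)) < missing_rate
        df.loc[mask, outcome] = np.nan
    return panel.replace(data=df)
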