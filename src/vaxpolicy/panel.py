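"""Panel containers, validation, and cleaning rules for vaccination coverage data.

A panel is a long table of kindergarten vaccination outcomes per unit and
school year: at the state level the outcomes are MMR coverage and nonmedical /
medical exemption prevalence; at the county level an overall-coverage outcome
is added and counties are nested within states.  Values are percentages of
kindergarten entrants, stored in percentage points on [0, 100]; missing cells
are ``NaN``, never zero.

Cleaning implements three rules applied to the raw tables before analysis:

* counties below a population threshold are excluded (default 65,000);
* a county that never reports overall coverage but reports MMR coverage has
  overall coverage proxied by its MMR value, flagged so a subanalysis can
  drop proxied units;
* units whose missing fraction for an outcome exceeds a threshold are
  excluded, and the remaining gaps are filled by within-unit linear
  interpolation over year with nearest-value extension at the edges.

Every exclusion, imputation and substitution is logged in a
:class:`CleaningReport` so downstream sensitivity analyses can reconstruct
exactly what was altered.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelDataset",
    "CleaningReport",
    "PanelValidationError",
    "SchemaError",
    "read_panel",
    "write_panel",
    "apply_county_filters",
    "handle_missing",
    "DEFAULT_SCHEMA",
]


class PanelValidationError(ValueError):
    """Raised when a panel violates a structural invariant."""


class SchemaError(PanelValidationError):
    """Raised when an input file lacks a required column."""


#: Canonical column names of the long CSV dialect.
DEFAULT_SCHEMA: dict[str, str] = {
    "unit_id": "unit_id",
    "parent_state": "parent_state",
    "level": "level",
    "year": "year",
    "outcome": "outcome",
    "value": "value",
    "population": "population",
}

_ID_COLS = ["unit_id", "parent_state", "year", "population"]


@dataclass(frozen=True)
class PanelDataset:
    """A unit x year outcome table with treatment labels.

    Parameters
    ----------
    level:
        ``"state"`` or ``"county"``.
    data:
        Wide table with one row per (unit_id, year): columns ``unit_id``,
        ``parent_state``, ``year``, ``population`` plus one column per
        outcome.  Outcome values are percentage points in [0, 100] or NaN.
    treated_units:
        Units exposed to the policy from ``policy_year`` onward (the treated
        state, or its counties at county level).
    policy_year:
        First post-policy school year (encoded by school-year start, so 2016
        means the 2016-17 school year).
    covariates:
        Optional table keyed by (unit_id, year) with one column per covariate.
    """

    level: str
    data: pd.DataFrame
    treated_units: frozenset[str]
    policy_year: int
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _validate_panel(self)

    # -- convenience accessors -------------------------------------------------

    @property
    def outcomes(self) -> list[str]:
        return [c for c in self.data.columns if c not in _ID_COLS]

    @property
    def units(self) -> list[str]:
        return sorted(self.data["unit_id"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self.data["year"].unique())

    @property
    def control_units(self) -> list[str]:
        return [u for u in self.units if u not in self.treated_units]

    def pre_years(self) -> list[int]:
        return [y for y in self.years if y < self.policy_year]

    def post_years(self) -> list[int]:
        return [y for y in self.years if y >= self.policy_year]

    def wide(self, outcome: str) -> pd.DataFrame:
        """Outcome as a unit x year matrix (rows units, columns years)."""
        if outcome not in self.outcomes:
            raise KeyError(f"outcome {outcome!r} not in panel (have {self.outcomes})")
        return self.data.pivot(index="unit_id", columns="year", values=outcome)

    def parent_state_of(self) -> pd.Series:
        return self.data.drop_duplicates("unit_id").set_index("unit_id")["parent_state"]

    def covariate_names(self) -> list[str]:
        if self.covariates is None:
            return []
        return [c for c in self.covariates.columns if c not in ("unit_id", "year")]

    def replace(self, **changes) -> "PanelDataset":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def subset_units(self, units: Iterable[str]) -> "PanelDataset":
        """Restrict the panel (data and covariates) to the given units."""
        keep = set(units)
        data = self.data[self.data["unit_id"].isin(keep)].reset_index(drop=True)
        cov = self.covariates
        if cov is not None:
            cov = cov[cov["unit_id"].isin(keep)].reset_index(drop=True)
        treated = frozenset(u for u in self.treated_units if u in keep)
        return PanelDataset(self.level, data, treated, self.policy_year, cov)


def _validate_panel(panel: PanelDataset) -> None:
    if panel.level not in ("state", "county"):
        raise PanelValidationError(f"level must be 'state' or 'county', got {panel.level!r}")
    df = panel.data
    for col in ("unit_id", "parent_state", "year", "population"):
        if col not in df.columns:
            raise SchemaError(f"panel data lacks required column {col!r}")
    dup = df.duplicated(subset=["unit_id", "year"])
    if dup.any():
        bad = df.loc[dup, ["unit_id", "year"]].iloc[0]
        raise PanelValidationError(
            f"duplicate (unit_id, year) pair: ({bad['unit_id']!r}, {int(bad['year'])})"
        )
    for out in (c for c in df.columns if c not in _ID_COLS):
        vals = pd.to_numeric(df[out], errors="coerce")
        bad_mask = vals.notna() & ((vals < 0) | (vals > 100))
        if bad_mask.any():
            row = df.loc[bad_mask.idxmax()]
            raise PanelValidationError(
                f"outcome {out!r} out of [0, 100] for unit {row['unit_id']!r}, "
                f"year {int(row['year'])}: value {float(vals[bad_mask.idxmax()])}"
            )
    units = set(df["unit_id"])
    if panel.treated_units and not set(panel.treated_units) <= units:
        missing = set(panel.treated_units) - units
        raise PanelValidationError(f"treated units not in panel: {sorted(missing)}")
    years = sorted(int(y) for y in df["year"].unique())
    if years and not (years[0] < panel.policy_year <= years[-1]):
        raise PanelValidationError(
            f"policy_year {panel.policy_year} must lie in ({years[0]}, {years[-1]}]"
        )
    if panel.level == "county":
        if df["parent_state"].isna().any():
            bad = df.loc[df["parent_state"].isna(), "unit_id"].iloc[0]
            raise PanelValidationError(f"county {bad!r} has no parent_state")


@dataclass
class CleaningReport:
    """Audit trail of everything a cleaning step removed or altered."""

    excluded_units: list[tuple[str, str]] = field(default_factory=list)
    imputed_cells: list[tuple[str, int, str]] = field(default_factory=list)
    proxy_substitutions: list[tuple[str, int]] = field(default_factory=list)

    def merge(self, other: "CleaningReport") -> "CleaningReport":
        return CleaningReport(
            excluded_units=self.excluded_units + other.excluded_units,
            imputed_cells=self.imputed_cells + other.imputed_cells,
            proxy_substitutions=self.proxy_substitutions + other.proxy_substitutions,
        )

    @property
    def proxied_units(self) -> set[str]:
        return {u for u, _ in self.proxy_substitutions}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "excluded_units": [list(e) for e in self.excluded_units],
                "imputed_cells": [list(e) for e in self.imputed_cells],
                "proxy_substitutions": [list(e) for e in self.proxy_substitutions],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "CleaningReport":
        raw = json.loads(text)
        return cls(
            excluded_units=[tuple(e) for e in raw["excluded_units"]],
            imputed_cells=[tuple(e) for e in raw["imputed_cells"]],
            proxy_substitutions=[tuple(e) for e in raw["proxy_substitutions"]],
        )


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


def read_panel(
    path: str | Path,
    level: str,
    schema: Mapping[str, str] | None = None,
    covariates_path: str | Path | None = None,
    treated_units: Iterable[str] = (),
    policy_year: int = 2016,
) -> PanelDataset:
    """Read a long-format outcome CSV into a validated :class:`PanelDataset`.

    The file has one row per (unit, year, outcome) with columns named by
    ``schema`` (default :data:`DEFAULT_SCHEMA`): unit_id, parent_state, level,
    year, outcome, value, population.  Empty value cells are preserved as
    missing, never coerced to zero.  An optional second CSV keyed by
    (unit_id, year) supplies covariates.

    Raises
    ------
    SchemaError
        if a required column is absent.
    PanelValidationError
        for out-of-range outcome values or duplicate (unit, year, outcome)
        rows, citing the offending cell.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    raw = pd.read_csv(path)
    required = ["unit_id", "year", "outcome", "value"]
    for key in required:
        if schema[key] not in raw.columns:
            raise SchemaError(f"missing required column {schema[key]!r} in {path}")
    df = raw.rename(columns={v: k for k, v in schema.items() if v in raw.columns})
    try:
        df["year"] = df["year"].astype(int)
    except (TypeError, ValueError) as exc:
        raise PanelValidationError(f"year column not parseable as integer: {exc}") from exc
    if "parent_state" not in df.columns:
        df["parent_state"] = df["unit_id"] if level == "state" else np.nan
    if "population" not in df.columns:
        df["population"] = np.nan

    dup = df.duplicated(subset=["unit_id", "year", "outcome"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise PanelValidationError(
            f"duplicate row for unit {bad['unit_id']!r}, year {int(bad['year'])}, "
            f"outcome {bad['outcome']!r}"
        )

    wide = (
        df.pivot(index=["unit_id", "year"], columns="outcome", values="value")
        .rename_axis(columns=None)
        .reset_index()
    )
    parents = df.drop_duplicates("unit_id").set_index("unit_id")["parent_state"]
    wide.insert(1, "parent_state", wide["unit_id"].map(parents))
    pop = df.groupby(["unit_id", "year"])["population"].first().rename("population")
    wide = wide.merge(pop, on=["unit_id", "year"], how="left")

    covariates = None
    if covariates_path is not None:
        covariates = pd.read_csv(covariates_path)
        for key in ("unit_id", "year"):
            if key not in covariates.columns:
                raise SchemaError(f"covariate file lacks required column {key!r}")
        covariates["year"] = covariates["year"].astype(int)

    return PanelDataset(
        level=level,
        data=wide,
        treated_units=frozenset(treated_units),
        policy_year=policy_year,
        covariates=covariates,
    )


def write_panel(panel: PanelDataset, path: str | Path) -> None:
    """Write the outcome table back to the long CSV dialect ``read_panel`` reads."""
    rows = panel.data.melt(
        id_vars=["unit_id", "parent_state", "year", "population"],
        var_name="outcome",
        value_name="value",
    )
    rows.insert(2, "level", panel.level)
    rows.sort_values(["unit_id", "year", "outcome"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cleaning rules
# ---------------------------------------------------------------------------


def _rebuild(panel: PanelDataset, df: pd.DataFrame) -> PanelDataset:
    """New panel around a cleaned data table, trimming covariates and labels."""
    units = set(df["unit_id"])
    cov = panel.covariates
    if cov is not None:
        cov = cov[cov["unit_id"].isin(units)].reset_index(drop=True)
    return PanelDataset(
        level=panel.level,
        data=df.reset_index(drop=True),
        treated_units=frozenset(u for u in panel.treated_units if u in units),
        policy_year=panel.policy_year,
        covariates=cov,
    )


def apply_county_filters(
    panel: PanelDataset,
    min_population: int = 65_000,
    overall_outcome: str = "overall",
    mmr_outcome: str = "mmr",
) -> tuple[PanelDataset, CleaningReport]:
    """Apply the county-level inclusion rules: population filter and MMR proxy.

    Counties whose mean recorded population is below ``min_population`` are
    excluded (reason ``"population_below_threshold"``).  Counties that never
    report the overall-coverage outcome but do report MMR coverage have
    overall coverage set to MMR for every year where MMR is observed; each
    filled cell is logged as a proxy substitution so the overall-coverage-only
    subanalysis can later drop these units.
    """
    if panel.level != "county":
        raise PanelValidationError("apply_county_filters requires a county-level panel")
    if min_population < 0:
        raise ValueError("min_population must be nonnegative")

    report = CleaningReport()
    df = panel.data.copy()

    mean_pop = df.groupby("unit_id")["population"].mean()
    too_small = mean_pop.index[mean_pop < min_population]
    for unit in sorted(too_small):
        report.excluded_units.append((unit, "population_below_threshold"))
    df = df[~df["unit_id"].isin(set(too_small))]

    if overall_outcome in df.columns and mmr_outcome in df.columns:
        by_unit = df.groupby("unit_id")
        never_overall = by_unit[overall_outcome].apply(lambda s: s.isna().all())
        has_mmr = by_unit[mmr_outcome].apply(lambda s: s.notna().any())
        proxied = sorted(never_overall.index[never_overall & has_mmr])
        for unit in proxied:
            mask = (df["unit_id"] == unit) & df[mmr_outcome].notna()
            df.loc[mask, overall_outcome] = df.loc[mask, mmr_outcome]
            for year in sorted(df.loc[mask, "year"]):
                report.proxy_substitutions.append((unit, int(year)))

    return _rebuild(panel, df), report


def handle_missing(
    panel: PanelDataset,
    outcome: str,
    max_missing_fraction: float = 0.2,
) -> tuple[PanelDataset, CleaningReport]:
    """Impute or exclude missing cells of ``outcome``, unit by unit.

    A unit whose missing fraction (over the panel's full year span) exceeds
    ``max_missing_fraction`` is excluded with reason
    ``"missing_above_threshold"``.  For the units kept, missing cells are
    filled by linear interpolation over year within the unit, extending the
    nearest observed value at the edges.  Observed cells are never altered;
    on return the outcome has no missing cells.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError(f"max_missing_fraction must be in [0, 1], got {max_missing_fraction}")
    if outcome not in panel.outcomes:
        raise KeyError(f"outcome {outcome!r} not in panel (have {panel.outcomes})")

    report = CleaningReport()
    years = panel.years
    wide = panel.wide(outcome).reindex(columns=years)

    frac_missing = wide.isna().mean(axis=1)
    dropped = sorted(frac_missing.index[frac_missing > max_missing_fraction])
    for unit in dropped:
        report.excluded_units.append((unit, "missing_above_threshold"))
    keep = [u for u in wide.index if u not in set(dropped)]
    wide = wide.loc[keep]

    filled = wide.T  # years as the (numeric) interpolation index
    filled.index = filled.index.astype(float)
    filled = filled.interpolate(method="index", limit_area="inside").ffill().bfill().T
    filled.columns = years

    for unit in keep:
        for year in years:
            if pd.isna(wide.at[unit, year]):
                report.imputed_cells.append((unit, int(year), outcome))

    df = panel.data[panel.data["unit_id"].isin(set(keep))].copy()
    # rows absent from the original table (unit-years never reported) are added
    full_index = pd.MultiIndex.from_product([keep, years], names=["unit_id", "year"])
    df = (
        df.set_index(["unit_id", "year"])
        .reindex(full_index)
        .reset_index()
    )
    parents = panel.parent_state_of()
    df["parent_state"] = df["unit_id"].map(parents)
    df["population"] = df.groupby("unit_id")["population"].transform(
        lambda s: s.ffill().bfill()
    )
    lookup = filled.stack()
    df[outcome] = [lookup.get((u, y), np.nan) for u, y in zip(df["unit_id"], df["year"])]

    return _rebuild(panel, df), report
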