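"""Shared fixtures: tiny hand-written panels and simulated ones."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vaxpolicy import PanelDataset, SimConfig, simulate_county_panel, simulate_state_panel

#: Baseline placed well inside [0, 100] so the clamp never binds and injected
#: effects are recovered without truncation bias (mean +/- 3 sd in range).
RECOVERY_BASELINE = {
    "coverage": (88.0, 2.5),
    "nonmedical": (8.0, 1.3),
    "medical": (3.0, 0.2),
}

ZERO_TAU = {"coverage": 0.0, "nonmedical": 0.0, "medical": 0.0}


def long_rows(unit, years, outcome, values, parent=None, population=1_000_000, level="state"):
    """Rows of the long CSV dialect for one unit and one outcome."""
    parent = unit if parent is None else parent
    return [
        {"unit_id": unit, "parent_state": parent, "level": level, "year": y,
         "outcome": outcome, "value": v, "population": population}
        for y, v in zip(years, values)
    ]


def panel_from_values(values: dict[str, list[float]], years: list[int],
                      outcome: str = "mmr", level: str = "state",
                      treated: str | None = None, policy_year: int = 2016,
                      parents: dict[str, str] | None = None,
                      populations: dict[str, int] | None = None) -> PanelDataset:
    """Build a PanelDataset directly from per-unit outcome value lists."""
    rows = []
    for unit, vals in values.items():
        for y, v in zip(years, vals):
            rows.append({
                "unit_id": unit,
                "parent_state": (parents or {}).get(unit, unit),
                "year": y,
                "population": (populations or {}).get(unit, 1_000_000),
                outcome: v,
            })
    treated_units = frozenset([treated] if treated else [next(iter(values))])
    return PanelDataset(level=level, data=pd.DataFrame(rows),
                        treated_units=treated_units, policy_year=policy_year)


@pytest.fixture(scope="session")
def state_panel():
    """A 15-state simulated panel with realistic defaults and signal covariates."""
    return simulate_state_panel(SimConfig(n_states=15, seed=42, baseline=RECOVERY_BASELINE))


@pytest.fixture(scope="session")
def county_panel():
    """A 10-state county panel (clamp-safe baseline) for regression tests."""
    return simulate_county_panel(
        SimConfig(n_states=10, counties_per_state=(4, 10), seed=7,
                  baseline=RECOVERY_BASELINE)
    )
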