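"""Configuration-driven orchestration of the full analysis pipeline.

A run is described by an :class:`AnalysisConfig` (typically loaded from
YAML): either paths to panel CSVs or a simulation block, the outcomes to
analyse, predictor candidates, cleaning thresholds, and which stages to run.
``run_pipeline`` executes the stages in dependency order

    load/simulate -> clean -> predictor selection -> synthetic control
                  -> placebo tests -> sensitivity           (state track)
    load/simulate -> clean -> difference-in-differences -> sensitivity
                                                            (county track)

and writes every stage artifact (JSON results plus plot-ready CSVs) and a run
manifest recording the seed, input hashes, package version and per-stage
status.  Reporting is a pure function of stage results, so any table can be
regenerated from the stored JSONs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .did import fit_did, parallel_trends_check
from .panel import CleaningReport, PanelDataset, handle_missing, apply_county_filters, read_panel, write_panel
from .placebo import run_placebo_tests
from .sensitivity import covariate_sweep, leave_one_out, overall_only_subanalysis
from .simulate import SimConfig, simulate_county_panel, simulate_state_panel
from .synth import fit_synthetic_control, select_predictors_stepwise

__all__ = ["AnalysisConfig", "run_pipeline", "write_report", "report_from_json",
           "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce a run.

    Exactly one of ``input`` (paths to panel/covariate CSVs) or ``simulate``
    (a :class:`~vaxpolicy.simulate.SimConfig` block) must be provided.
    """

    level: str = "state"
    input: dict[str, str] | None = None  # {"panel": ..., "covariates": ...,
    #                                       "treated_units": [...], "policy_year": int}
    simulate: SimConfig | None = None
    outcomes: list[str] = field(default_factory=lambda: ["mmr"])
    predictors: list[str] = field(default_factory=list)
    select_predictors: bool = False
    covariates: list[str] = field(default_factory=list)
    policy_year: int | None = None
    min_population: int = 65_000
    max_missing_fraction: float = 0.2
    stages: list[str] = field(default_factory=lambda: ["clean", "sc", "placebo"])
    out_dir: str = "results"
    seed: int = 0

    _KNOWN_STAGES = ("clean", "select", "sc", "placebo", "did", "sensitivity")
    _DEPS = {"placebo": "sc", "sensitivity": None, "select": None}

    def validate(self) -> None:
        if (self.input is None) == (self.simulate is None):
            raise ConfigError("exactly one of 'input' and 'simulate' must be set")
        unknown = [s for s in self.stages if s not in self._KNOWN_STAGES]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}")
        if "placebo" in self.stages and "sc" not in self.stages:
            raise ConfigError("stage 'placebo' requires stage 'sc'")
        if self.level not in ("state", "county"):
            raise ConfigError(f"level must be 'state' or 'county', got {self.level!r}")
        if self.level == "county" and "sc" in self.stages:
            raise ConfigError("synthetic control runs on the state level")


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulate", None)
    cfg = AnalysisConfig(**raw)
    if sim is not None:
        if "baseline" in sim:
            sim["baseline"] = {k: tuple(v) for k, v in sim["baseline"].items()}
        for key in ("counties_per_state", "years"):
            if key in sim:
                sim[key] = tuple(sim[key])
        cfg.simulate = SimConfig(**sim)
    cfg.validate()
    return cfg


def _hash_inputs(config: AnalysisConfig) -> str:
    h = hashlib.sha256()
    if config.input:
        for key in sorted(k for k in config.input if k in ("panel", "covariates")):
            p = Path(config.input[key])
            if p.exists():
                h.update(p.read_bytes())
    else:
        h.update(json.dumps(dataclasses.asdict(config.simulate), sort_keys=True,
                            default=str).encode())
    return h.hexdigest()[:16]


def _load_or_simulate(config: AnalysisConfig) -> PanelDataset:
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        return (simulate_state_panel(sim) if config.level == "state"
                else simulate_county_panel(sim))
    spec = config.input
    return read_panel(
        spec["panel"],
        level=config.level,
        covariates_path=spec.get("covariates"),
        treated_units=spec.get("treated_units", ()),
        policy_year=spec.get("policy_year", 2016),
    )


def run_pipeline(config: AnalysisConfig) -> dict[str, Any]:
    """Execute the configured stages and write all artifacts; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "version": __version__,
        "inputs_hash": _hash_inputs(config),
        "stages": {},
        "outputs": [],
    }
    results: dict[str, Any] = {}

    def record(stage: str, status: str, detail: str = "") -> None:
        manifest["stages"][stage] = {"status": status, **({"detail": detail} if detail else {})}

    panel = _load_or_simulate(config)
    record("load", "ok")

    report = CleaningReport()
    if "clean" in config.stages:
        try:
            if panel.level == "county":
                panel, rep = apply_county_filters(panel, config.min_population)
                report = report.merge(rep)
            for outcome in config.outcomes:
                panel, rep = handle_missing(panel, outcome, config.max_missing_fraction)
                report = report.merge(rep)
            record("clean", "ok")
        except Exception as exc:  # noqa: BLE001 - status goes in the manifest
            record("clean", "failed", str(exc))
            return _finish(manifest, out)
        write_panel(panel, out / "panel_clean.csv")
        report.to_json(out / "cleaning_report.json")
        manifest["outputs"] += ["panel_clean.csv", "cleaning_report.json"]
    results["panel"], results["cleaning_report"] = panel, report

    predictors = list(config.predictors)
    if "select" in config.stages or config.select_predictors:
        try:
            chosen = {}
            for outcome in config.outcomes:
                chosen[outcome] = select_predictors_stepwise(
                    panel, outcome, predictors or panel.covariate_names(),
                    policy_year=config.policy_year,
                )
            results["selected_predictors"] = chosen
            (out / "selected_predictors.json").write_text(json.dumps(chosen, indent=2))
            manifest["outputs"].append("selected_predictors.json")
            record("select", "ok")
        except Exception as exc:  # noqa: BLE001
            record("select", "failed", str(exc))
            return _finish(manifest, out)

    if "sc" in config.stages:
        try:
            sc_results = {}
            for outcome in config.outcomes:
                preds = results.get("selected_predictors", {}).get(outcome, predictors)
                sc_results[outcome] = fit_synthetic_control(
                    panel, outcome, preds, policy_year=config.policy_year
                )
            results["sc"] = sc_results
            record("sc", "ok")
        except Exception as exc:  # noqa: BLE001
            record("sc", "failed", str(exc))
            return _finish(manifest, out)

    if "placebo" in config.stages and "sc" in results:
        try:
            pb = {}
            for outcome, sc_res in results["sc"].items():
                preds = results.get("selected_predictors", {}).get(outcome, predictors)
                pb[outcome] = run_placebo_tests(
                    panel, outcome, preds,
                    policy_year=config.policy_year, treated_result=sc_res,
                )
            results["placebo"] = pb
            record("placebo", "ok")
        except Exception as exc:  # noqa: BLE001
            record("placebo", "failed", str(exc))
            return _finish(manifest, out)

    if "did" in config.stages:
        try:
            did_results, trends = {}, {}
            for outcome in config.outcomes:
                did_results[outcome] = fit_did(
                    panel, outcome, config.covariates, config.policy_year
                )
                trends[outcome] = parallel_trends_check(panel, outcome, config.policy_year)
            results["did"], results["trends"] = did_results, trends
            record("did", "ok")
        except Exception as exc:  # noqa: BLE001
            record("did", "failed", str(exc))
            return _finish(manifest, out)

    if "sensitivity" in config.stages:
        try:
            sens = {}
            for outcome in config.outcomes:
                if "sc" in results:
                    preds = results.get("selected_predictors", {}).get(outcome, predictors)
                    sens[f"sc_loo_{outcome}"] = leave_one_out(
                        panel, "sc", outcome, predictors=preds,
                        policy_year=config.policy_year,
                    )
                if "did" in results:
                    sens[f"did_loo_{outcome}"] = leave_one_out(
                        panel, "did", outcome, covariates=config.covariates,
                        policy_year=config.policy_year,
                    )
            if "did" in results and report.proxy_substitutions:
                sens["overall_only"] = overall_only_subanalysis(
                    panel, report, config.outcomes[0], config.covariates,
                    config.policy_year,
                )
            results["sensitivity"] = sens
            record("sensitivity", "ok")
        except Exception as exc:  # noqa: BLE001
            record("sensitivity", "failed", str(exc))
            return _finish(manifest, out)

    manifest["outputs"] += write_report(results, out)
    return _finish(manifest, out)


def _finish(manifest: dict, out: Path) -> dict:
    manifest["ok"] = all(s["status"] == "ok" for s in manifest["stages"].values())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def write_report(results: dict[str, Any], out_dir: str | Path) -> list[str]:
    """Emit plot-ready CSV tables from stage results; returns the file names.

    Synthetic-control results yield trajectory, donor-weight and gap tables;
    placebo results yield per-state effect-size and gap-trajectory tables;
    the county regression yields a regression table, prepolicy trend means
    and per-county pre/post changes; sensitivity tables are written as-is.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        df.to_csv(out / name, index=False)
        written.append(name)

    for outcome, sc in results.get("sc", {}).items():
        emit(f"sc_trajectories_{outcome}.csv", sc.trajectories)
        emit(f"sc_weights_{outcome}.csv", pd.DataFrame(
            sorted(sc.donor_contributions.items()), columns=["unit_id", "weight"]))
        sc.to_json(out / f"sc_result_{outcome}.json")
        written.append(f"sc_result_{outcome}.json")

    for outcome, pb in results.get("placebo", {}).items():
        emit(f"placebo_effects_{outcome}.csv", pb.effects_table())
        emit(f"placebo_trajectories_{outcome}.csv", pb.trajectories_table())
        pb.to_json(out / f"placebo_result_{outcome}.json")
        written.append(f"placebo_result_{outcome}.json")

    for outcome, did in results.get("did", {}).items():
        emit(f"did_table_{outcome}.csv", did.table())
        did.to_json(out / f"did_result_{outcome}.json")
        written.append(f"did_result_{outcome}.json")

    for outcome, (means, slope_diff) in results.get("trends", {}).items():
        emit(f"trend_means_{outcome}.csv", means)
        (out / f"trend_slope_diff_{outcome}.json").write_text(
            json.dumps({"prepolicy_slope_difference": slope_diff}))
        written.append(f"trend_slope_diff_{outcome}.json")

    panel = results.get("panel")
    if panel is not None and panel.level == "county" and "did" in results:
        written.append(_county_change_table(panel, results["did"], out))

    for name, table in results.get("sensitivity", {}).items():
        if isinstance(table, pd.DataFrame):
            emit(f"sensitivity_{name}.csv", table)
        elif hasattr(table, "to_frame"):
            emit(f"sensitivity_{name}.csv", table.to_frame())
        else:  # a DiDResult from the overall-only subanalysis
            emit(f"sensitivity_{name}.csv", table.table())
    return written


def report_from_json(result_dir: str | Path, out_dir: str | Path) -> list[str]:
    """Regenerate every figure/table CSV from the stored stage JSONs alone.

    Reads ``sc_result_*.json``, ``placebo_result_*.json`` and
    ``did_result_*.json`` from ``result_dir`` and re-emits the corresponding
    plot-ready CSVs into ``out_dir``; reporting is a pure function of the
    stored results.
    """
    src, out = Path(result_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        df.to_csv(out / name, index=False)
        written.append(name)

    for path in sorted(src.glob("sc_result_*.json")):
        res = json.loads(path.read_text())
        outcome = res["outcome"]
        traj = pd.DataFrame(res["trajectories"])
        traj["gap"] = traj["treated"] - traj["synthetic"]
        emit(f"sc_trajectories_{outcome}.csv", traj)
        emit(f"sc_weights_{outcome}.csv", pd.DataFrame(
            sorted(res["donor_weights"].items()), columns=["unit_id", "weight"]))

    for path in sorted(src.glob("placebo_result_*.json")):
        res = json.loads(path.read_text())
        outcome = res["outcome"]
        rows = [{"unit_id": res["treated_id"], "effect_size": res["treated_effect"],
                 "is_treated": True}]
        rows += [{"unit_id": u, "effect_size": e, "is_treated": False}
                 for u, e in sorted(res["effects"].items())]
        emit(f"placebo_effects_{outcome}.csv", pd.DataFrame(rows))
        traj_rows = [
            {"unit_id": u, "year": int(y), "gap": g,
             "is_treated": u == res["treated_id"]}
            for u, gaps in sorted(res["gap_trajectories"].items())
            for y, g in sorted(gaps.items())
        ]
        emit(f"placebo_trajectories_{outcome}.csv", pd.DataFrame(traj_rows))

    for path in sorted(src.glob("did_result_*.json")):
        res = json.loads(path.read_text())
        outcome = res["outcome"]
        names = list(res["coefficients"])
        emit(f"did_table_{outcome}.csv", pd.DataFrame({
            "parameter": names,
            "estimate": [res["coefficients"][k] for k in names],
            "ci_low": [res["ci_low"][k] for k in names],
            "ci_high": [res["ci_high"][k] for k in names],
            "p_value": [res["p_value"][k] for k in names],
        }))
    return written


def _county_change_table(panel: PanelDataset, did_results: dict, out: Path) -> str:
    """Per-county pre/post change table (last pre year vs last post year)."""
    pre_year, post_year = panel.pre_years()[-1], panel.post_years()[-1]
    df = panel.data
    recs = []
    for outcome in did_results:
        pre = df[df["year"] == pre_year].set_index("unit_id")[outcome]
        post = df[df["year"] == post_year].set_index("unit_id")[outcome]
        for unit in pre.index.intersection(post.index):
            if unit in panel.treated_units:
                recs.append({
                    "unit_id": unit, "outcome": outcome,
                    "pre_value": pre[unit], "post_value": post[unit],
                    "change": post[unit] - pre[unit],
                })
    name = "county_changes.csv"
    pd.DataFrame(recs).to_csv(out / name, index=False)
    return name
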