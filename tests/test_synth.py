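"""Synthetic-control construction, nested optimisation, and predictor selection.

The inner simplex QP and the outer predictor-weight search are checked
against exhaustive grid-search oracles that share no code with the solver.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from vaxpolicy import (
    InfeasibleProblemError,
    SCProblem,
    build_sc_problem,
    fit_synthetic_control,
    make_hull_panel,
    optimize_v,
    select_predictors_stepwise,
    solve_inner_weights,
)
from vaxpolicy.synth import _pre_mspe

from conftest import panel_from_values


def toy_problem(X1, X0, Z1=None, Z0=None, years=None):
    """Hand-assembled SCProblem for solver-level tests."""
    X1, X0 = np.asarray(X1, float), np.asarray(X0, float)
    k, J = X0.shape
    Z1 = np.asarray(Z1, float) if Z1 is not None else np.zeros(2)
    Z0 = np.asarray(Z0, float) if Z0 is not None else np.zeros((2, J))
    T0 = len(Z1)
    yrs = years or tuple(range(2011, 2011 + T0 + 1))
    return SCProblem(
        treated_id="T", donor_ids=tuple(f"D{j}" for j in range(J)),
        predictor_names=tuple(f"p{r}" for r in range(k)),
        X1=X1, X0=X0, Z1=Z1, Z0=Z0,
        Y1_all=np.concatenate([Z1, [0.0]]),
        Y0_all=np.vstack([Z0, np.zeros((1, J))]),
        years=tuple(yrs), pre_years=tuple(yrs[:T0]),
        scaling=tuple((0.0, 1.0) for _ in range(k)),
    )


def grid_weights(J, step):
    """All simplex weight vectors on a grid of the given step."""
    n = round(1 / step)
    if J == 2:
        for i in range(n + 1):
            yield np.array([i, n - i]) / n
    elif J == 3:
        for i in range(n + 1):
            for j in range(n + 1 - i):
                yield np.array([i, j, n - i - j]) / n
    else:
        raise NotImplementedError


def inner_objective(problem, V, w):
    r = problem.X1 - problem.X0 @ w
    return float(r @ (np.asarray(V) * r))


class TestInnerQP:
    def test_exact_donor_match_gets_unit_mass(self):
        X0 = np.array([[1.0, 2.0, 5.0], [0.0, 1.0, 2.0]])
        problem = toy_problem(X0[:, 2], X0)
        W, obj = solve_inner_weights(problem, np.array([0.5, 0.5]))
        assert obj <= 1e-12
        assert W[2] == pytest.approx(1.0, abs=1e-6)

    def test_interior_minimum_matches_grid_oracle(self):
        # k=1: treated 2, donors (1, 4) -> w = (2/3, 1/3), objective 0
        problem = toy_problem([2.0], [[1.0, 4.0]])
        W, obj = solve_inner_weights(problem, np.array([1.0]))
        grid_best = min(inner_objective(problem, [1.0], w)
                        for w in grid_weights(2, 1e-4))
        assert W == pytest.approx([2 / 3, 1 / 3], abs=1e-5)
        assert obj <= grid_best + 1e-8

    def test_corner_solution(self):
        # treated 5 beyond donors (1, 2): all mass on the nearest donor
        problem = toy_problem([5.0], [[1.0, 2.0]])
        V = np.array([0.7])
        W, obj = solve_inner_weights(problem, V)
        assert W == pytest.approx([0.0, 1.0], abs=1e-6)
        assert obj == pytest.approx((5 - 2) ** 2 * 0.7, abs=1e-6)

    @pytest.mark.parametrize("J,k", [(2, 1), (2, 2), (3, 1), (3, 2)])
    def test_matches_grid_search_on_random_instances(self, J, k):
        rng = np.random.default_rng(100 * J + k)
        for _ in range(8):
            problem = toy_problem(rng.normal(0, 2, k), rng.normal(0, 2, (k, J)))
            V = rng.uniform(0.1, 1.0, k)
            V = V / V.sum()
            W, obj = solve_inner_weights(problem, V)
            grid_best = min(inner_objective(problem, V, w) for w in grid_weights(J, 1e-3))
            assert obj <= grid_best + 1e-4
            assert abs(W.sum() - 1.0) < 1e-8 and (W >= -1e-10).all()

    def test_weights_beat_every_vertex(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            J, k = 5, 3
            problem = toy_problem(rng.normal(0, 2, k), rng.normal(0, 2, (k, J)))
            V = np.full(k, 1 / k)
            _, obj = solve_inner_weights(problem, V)
            for j in range(J):
                vertex = np.eye(J)[j]
                assert obj <= inner_objective(problem, V, vertex) + 1e-8

    def test_invalid_v_rejected(self):
        problem = toy_problem([1.0], [[0.0, 2.0]])
        with pytest.raises(ValueError):
            solve_inner_weights(problem, np.array([-1.0]))
        with pytest.raises(ValueError):
            solve_inner_weights(problem, np.array([0.0]))


class TestOptimizeV:
    def test_single_predictor_is_trivial(self):
        problem = toy_problem([2.0], [[1.0, 4.0]],
                              Z1=[3.0, 3.0], Z0=[[1.0, 6.0], [1.0, 6.0]])
        w = optimize_v(problem)
        assert w.V == pytest.approx([1.0])
        assert abs(w.W.sum() - 1.0) < 1e-8

    def test_informative_predictor_dominates_noise(self):
        # predictor 0 reproduces the prepolicy outcome structure, predictor 1
        # is uncorrelated noise: V should load >= 0.9 on predictor 0 and beat
        # every V on a 101-point simplex grid.
        rng = np.random.default_rng(2)
        J, T0 = 6, 5
        Z0 = 90 + rng.normal(0, 2, (T0, J))
        w_true = np.array([0.4, 0.6, 0, 0, 0, 0.0])
        Z1 = Z0 @ w_true
        X0 = np.vstack([Z0.mean(axis=0), rng.normal(0, 1, J)])
        X1 = np.array([Z1.mean(), rng.normal()])
        problem = toy_problem(X1, X0, Z1=Z1, Z0=Z0)
        res = optimize_v(problem)
        assert res.V[0] >= 0.9
        grid_best = np.inf
        for i in range(101):
            V = np.array([i / 100, 1 - i / 100]) + 1e-12
            W, _ = solve_inner_weights(problem, V)
            grid_best = min(grid_best, _pre_mspe(problem, W))
        assert res.pre_mspe <= grid_best + 1e-6

    def test_repeated_calls_bit_identical(self):
        rng = np.random.default_rng(3)
        problem = toy_problem(rng.normal(0, 1, 3), rng.normal(0, 1, (3, 5)),
                              Z1=rng.normal(90, 2, 4), Z0=rng.normal(90, 2, (4, 5)))
        a, b = optimize_v(problem), optimize_v(problem)
        assert (a.W == b.W).all() and (a.V == b.V).all()
        assert a.pre_mspe == b.pre_mspe

    def test_never_worse_than_uniform_v(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            k = 3
            problem = toy_problem(rng.normal(0, 1, k), rng.normal(0, 1, (k, 4)),
                                  Z1=rng.normal(90, 2, 5), Z0=rng.normal(90, 2, (5, 4)))
            res = optimize_v(problem)
            W_u, _ = solve_inner_weights(problem, np.full(k, 1 / k))
            assert res.pre_mspe <= _pre_mspe(problem, W_u) + 1e-12


class TestBuildProblem:
    def test_donor_with_missing_covariate_dropped(self, state_panel):
        cov = state_panel.covariates.copy()
        victim = state_panel.control_units[0]
        cov.loc[cov["unit_id"] == victim, "median_income"] = np.nan
        panel = state_panel.replace(covariates=cov)
        problem = build_sc_problem(panel, "mmr", ["median_income"], "CA")
        assert victim not in problem.donor_ids
        assert (victim, "missing_predictor") in problem.dropped_donors

    def test_empty_predictors_gives_single_row(self, state_panel):
        problem = build_sc_problem(state_panel, "mmr", [], "CA")
        assert problem.predictor_names == ("pre_mean(mmr)",)
        assert problem.X0.shape[0] == 1

    def test_constant_covariate_dropped(self, state_panel):
        cov = state_panel.covariates.copy()
        cov["flat"] = 3.0
        panel = state_panel.replace(covariates=cov)
        problem = build_sc_problem(panel, "mmr", ["median_income", "flat"], "CA")
        assert "flat" not in problem.predictor_names
        assert "median_income" in problem.predictor_names

    def test_outcome_lags_replace_pre_mean(self, state_panel):
        problem = build_sc_problem(state_panel, "mmr", [], "CA", outcome_lags=True)
        assert len(problem.predictor_names) == len(problem.pre_years)
        assert all(n.startswith("lag(mmr,") for n in problem.predictor_names)

    def test_too_few_donors_is_infeasible(self):
        years = list(range(2012, 2017))
        panel = panel_from_values(
            {"T": [90] * 5, "A": [91] * 5, "B": [np.nan] * 5}, years,
            treated="T", policy_year=2016)
        with pytest.raises(InfeasibleProblemError):
            build_sc_problem(panel, "mmr", [], "T")

    def test_standardization_recorded(self, state_panel):
        problem = build_sc_problem(state_panel, "mmr", ["median_income"], "CA")
        pool = np.hstack([problem.X1[:, None], problem.X0])
        assert np.allclose(pool.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(pool.std(axis=1), 1.0, atol=1e-10)


class TestFitSyntheticControl:
    def test_hull_recovery_is_exact(self):
        panel = make_hull_panel(n_donors=4, tau=3.0, seed=3)
        res = fit_synthetic_control(panel, "mmr", ["cov1", "cov2"])
        assert res.effect_size == pytest.approx(3.0, abs=1e-6)
        assert max(abs(res.gaps[y]) for y in res.pre_years) <= 1e-6

    def test_gap_conservation_and_effect_identity(self, state_panel):
        res = fit_synthetic_control(state_panel, "mmr", ["median_income"])
        problem = build_sc_problem(state_panel, "mmr", ["median_income"], "CA")
        W = res.weights.W
        for i, y in enumerate(problem.years):
            expected = problem.Y1_all[i] - problem.Y0_all[i] @ W
            assert res.gaps[y] == pytest.approx(expected, abs=1e-10)
        pre = np.mean([res.gaps[y] for y in res.pre_years])
        post = np.mean([res.gaps[y] for y in res.post_years])
        assert res.effect_size == pytest.approx(post - pre, abs=1e-10)

    def test_common_shift_leaves_gaps_unchanged(self, state_panel):
        res = fit_synthetic_control(state_panel, "mmr", [])
        df = state_panel.data.copy()
        df["mmr"] = df["mmr"] - 10.0  # keep inside [0, 100]
        shifted = state_panel.replace(data=df)
        res2 = fit_synthetic_control(shifted, "mmr", [])
        for y in res.gaps:
            assert res2.gaps[y] == pytest.approx(res.gaps[y], abs=1e-8)
        assert res2.effect_size == pytest.approx(res.effect_size, abs=1e-8)


class TestStepwiseSelection:
    def test_no_candidates_returns_base_set(self, state_panel):
        assert select_predictors_stepwise(state_panel, "mmr", [], "CA") == []

    def test_greedy_path_matches_subset_oracle(self, state_panel):
        # one candidate copies the unit mean outcome (perfect signal), one is
        # fixed-seed noise; the oracle evaluates validation MSPE for every
        # subset directly and replays the greedy rule.
        rng = np.random.default_rng(8)
        cov = state_panel.covariates.copy()
        unit_means = state_panel.data.groupby("unit_id")["mmr"].mean()
        cov["copy_of_outcome"] = cov["unit_id"].map(unit_means)
        noise_by_unit = {u: rng.normal() for u in state_panel.units}
        cov["pure_noise"] = cov["unit_id"].map(noise_by_unit)
        panel = state_panel.replace(covariates=cov)
        candidates = ["pure_noise", "copy_of_outcome"]
        holdout = 2

        pre = [y for y in panel.years if y < panel.policy_year]
        split = pre[-holdout]
        held = [y for y in pre if y >= split]

        def val_mspe(pred_set):
            res = fit_synthetic_control(panel, "mmr", list(pred_set), "CA",
                                        policy_year=split)
            return float(np.mean([res.gaps[y] ** 2 for y in held]))

        scores = {frozenset(s): val_mspe(s)
                  for s in ([], ["pure_noise"], ["copy_of_outcome"], candidates)}
        # oracle: replay greedy forward selection from the subset scores
        expected, current = [], frozenset()
        while True:
            options = [c for c in candidates if c not in current]
            best_c, best_v = None, scores[current]
            for c in options:
                v = scores[current | {c}]
                if v < best_v - 1e-6:
                    best_c, best_v = c, v
            if best_c is None:
                break
            expected.append(best_c)
            current = current | {best_c}

        chosen = select_predictors_stepwise(
            panel, "mmr", candidates, "CA", holdout_years=holdout)
        assert chosen == expected
        assert "pure_noise" not in chosen

    def test_tied_candidates_break_by_list_order(self, state_panel):
        cov = state_panel.covariates.copy()
        cov["dup_a"] = cov["median_income"]
        cov["dup_b"] = cov["median_income"]
        panel = state_panel.replace(covariates=cov)
        first = select_predictors_stepwise(panel, "mmr", ["dup_a", "dup_b"], "CA")
        second = select_predictors_stepwise(panel, "mmr", ["dup_b", "dup_a"], "CA")
        if first:
            assert first[0] == "dup_a"
        if second:
            assert second[0] == "dup_b"

    def test_excessive_holdout_rejected(self, state_panel):
        with pytest.raises(ValueError, match="holdout_years"):
            select_predictors_stepwise(state_panel, "mmr", ["median_income"],
                                       "CA", holdout_years=5)
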