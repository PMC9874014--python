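"""LP solving, sweep behaviour, Eq.-style scalings, and calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from enerflow.fba import (
    SweepGrid,
    atp_glucose_ratio,
    calibrate,
    exchange_report,
    scale_to_measured,
    solve_fba,
    sweep,
)
from enerflow.gpr import ExchangeSpec
from enerflow.model import MetabolicModel, Reaction, write_json_model
from enerflow.synthetic import ToyModelSpec, make_toy_model


def vertex_enumeration_max(S, lb, ub, objective_index, atol=1e-9):
    """Independent LP oracle for tiny networks: enumerate polytope vertices.

    A vertex of {v : S v = 0, lb <= v <= ub} fixes at least n - rank(S)
    variables at a bound; the rest solve the equality system.  Returns
    (max objective value, feasible) by exhaustive enumeration.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    best, feasible = -np.inf, False
    n_fixed = n - rank
    for fixed_vars in itertools.combinations(range(n), n_fixed):
        free_vars = [i for i in range(n) if i not in fixed_vars]
        A_free = S[:, free_vars]
        if free_vars and np.linalg.matrix_rank(A_free) < len(free_vars):
            continue
        for choice in itertools.product(*[(lb[i], ub[i]) for i in fixed_vars]):
            v = np.zeros(n)
            for i, val in zip(fixed_vars, choice):
                v[i] = val
            rhs = -S[:, fixed_vars] @ np.asarray(choice) if fixed_vars else np.zeros(S.shape[0])
            if free_vars:
                sol, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
                v[free_vars] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < np.asarray(lb) - 1e-7) or np.any(v > np.asarray(ub) + 1e-7):
                continue
            feasible = True
            best = max(best, v[objective_index])
    return best, feasible


def _random_network(rng):
    n_mets = int(rng.integers(1, 4))
    n_rxns = int(rng.integers(2, 5))
    S = rng.integers(-2, 3, size=(n_mets, n_rxns)).astype(float)
    lb = rng.uniform(-5, 0.3, size=n_rxns).round(2)
    ub = lb + rng.uniform(0, 6, size=n_rxns).round(2)
    mets = [f"m{i}" for i in range(n_mets)]
    reactions = []
    for j in range(n_rxns):
        stoich = {mets[i]: S[i, j] for i in range(n_mets) if S[i, j] != 0}
        if not stoich:
            stoich = {mets[0]: 0.0}
        reactions.append(Reaction(f"r{j}", stoich, float(lb[j]), float(ub[j])))
    model = MetabolicModel("rand", reactions, objective_id="r0")
    return model, S, lb, ub


class TestSolveFba:
    def test_toy_optima(self, toy_model):
        sol = solve_fba(toy_model)
        assert sol.optimal and sol.objective == pytest.approx(320.0, abs=1e-6)
        anaerobic = make_toy_model(ToyModelSpec(), oxygen_bound=0.0)
        assert solve_fba(anaerobic).objective == pytest.approx(20.0, abs=1e-8)

    def test_closed_exchanges_give_zero(self, toy_model):
        model = toy_model.copy()
        for rxn in model.exchanges:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
        sol = solve_fba(model)
        assert sol.optimal and sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_contradictory_bounds_are_infeasible(self, toy_model):
        model = toy_model.copy()
        rxn = model.reaction("GLYC")
        rxn.lower_bound, rxn.upper_bound = 5.0, 1.0
        assert solve_fba(model).status == "infeasible"

    def test_missing_objective_raises(self, toy_model):
        with pytest.raises(KeyError):
            solve_fba(toy_model, "NO_SUCH_REACTION")

    def test_oracle_equivalence_on_random_tiny_networks(self, rng):
        """Solver objective matches exhaustive vertex enumeration on 100
        random networks with <= 4 reactions."""
        n_checked = 0
        for _ in range(100):
            model, S, lb, ub = _random_network(rng)
            expected, feasible = vertex_enumeration_max(S, lb, ub, 0)
            sol = solve_fba(model)
            if not feasible:
                assert sol.status == "infeasible"
                continue
            assert sol.optimal
            assert sol.objective == pytest.approx(expected, abs=1e-8)
            n_checked += 1
        assert n_checked >= 30  # enough feasible instances to be meaningful

    def test_mass_balance_residual(self, toy_model, rng):
        """Every optimal solution satisfies S v = 0 within 1e-6 * b_max."""
        for _ in range(10):
            model = make_toy_model(
                ToyModelSpec(n_carbon_sources=2),
                glucose_bound=-float(rng.uniform(0, 30)),
                oxygen_bound=-float(rng.uniform(0, 100)),
            )
            sol = solve_fba(model)
            assert sol.optimal
            S, _, rxn_ids = model.stoichiometric_matrix()
            residual = np.abs(S @ sol.fluxes[rxn_ids].to_numpy()).max()
            assert residual <= 1e-6 * 1e6

    def test_scale_equivariance(self, toy_model):
        """Multiplying all bounds by c multiplies the optimum by c."""
        base = solve_fba(toy_model).objective
        scaled = toy_model.copy()
        for rxn in scaled.reactions:
            rxn.lower_bound *= 2.5
            rxn.upper_bound *= 2.5
        assert solve_fba(scaled).objective == pytest.approx(2.5 * base, rel=1e-9)

    def test_cobra_oracle_agrees_on_toy_model(self, toy_model, tmp_path):
        """cobrapy, loading our JSON serialisation, finds the same optimum."""
        cobra = pytest.importorskip("cobra")
        path = tmp_path / "toy.json"
        write_json_model(toy_model, path)
        cb = cobra.io.load_json_model(str(path))
        value = cb.slim_optimize()
        assert value == pytest.approx(solve_fba(toy_model).objective, rel=1e-6)


class TestSweep:
    def test_single_cell_grid_matches_single_solve(self, bundle, bundle_abundance):
        from enerflow.gpr import CompressionParams, effective_abundances, exchange_bounds, internal_bounds

        ex = ExchangeSpec(mode="dmem", medium_mM=bundle.medium_mM, r=0.05)
        grid = sweep(bundle.model, bundle_abundance, ex, [0.016], [0.05])
        params = CompressionParams(k=0.016, b_max=1000.0)
        eff = effective_abundances(bundle.model, bundle_abundance)
        manual = exchange_bounds(internal_bounds(bundle.model, eff, params), ex, params)
        assert grid.objective[0, 0] == pytest.approx(solve_fba(manual).objective, rel=1e-9)

    def test_objective_monotone_in_r(self, bundle, bundle_abundance):
        ex = ExchangeSpec(mode="dmem", medium_mM=bundle.medium_mM, r=0.05)
        grid = sweep(
            bundle.model,
            bundle_abundance,
            ex,
            [0.004, 0.016, 0.25],
            [0.0125, 0.05, 0.2, 0.8, 1.6],
        )
        for i in range(grid.objective.shape[0]):
            row = grid.objective[i]
            finite = row[np.isfinite(row)]
            assert np.all(np.diff(finite) >= -1e-6)

    def test_empty_grid_rejected(self, bundle, bundle_abundance):
        ex = ExchangeSpec(mode="dmem", medium_mM=bundle.medium_mM, r=0.05)
        with pytest.raises(ValueError):
            sweep(bundle.model, bundle_abundance, ex, [], [0.05])

    def test_long_format_roundtrip(self, bundle, bundle_abundance):
        ex = ExchangeSpec(mode="dmem", medium_mM=bundle.medium_mM, r=0.05)
        grid = sweep(bundle.model, bundle_abundance, ex, [0.016, 0.25], [0.05, 0.2])
        frame = grid.to_frame()
        assert len(frame) == 4
        assert set(frame.columns) >= {"k", "r", "objective", "glucose_uptake", "ratio", "status"}


class TestScalings:
    def test_ratio_examples(self, toy_model):
        sol = solve_fba(toy_model)
        assert atp_glucose_ratio(sol, "EX_glc_e") == pytest.approx(32.0, rel=1e-9)
        anaerobic = make_toy_model(ToyModelSpec(), oxygen_bound=0.0)
        assert atp_glucose_ratio(solve_fba(anaerobic), "EX_glc_e") == pytest.approx(2.0)

    def test_ratio_undefined_without_uptake(self, toy_model):
        closed = make_toy_model(ToyModelSpec(), glucose_bound=0.0)
        assert np.isnan(atp_glucose_ratio(solve_fba(closed), "EX_glc_e"))

    @pytest.mark.parametrize(
        "ratio,measured,expected", [(32.0, 5.0, 160.0), (0.0, 7.0, 0.0), (2.0, 0.0, 0.0)]
    )
    def test_scale_to_measured(self, ratio, measured, expected):
        assert scale_to_measured(ratio, measured) == expected

    def test_scale_to_measured_rejects_negative(self):
        with pytest.raises(ValueError):
            scale_to_measured(-1.0, 5.0)


def _grid(ratio_matrix, k_values, r_values, glucose=-10.0):
    ratio = np.asarray(ratio_matrix, dtype=float)
    shape = ratio.shape
    return SweepGrid(
        k_values=np.asarray(k_values, dtype=float),
        r_values=np.asarray(r_values, dtype=float),
        objective=np.abs(ratio) * 10,
        glucose_uptake=np.full(shape, glucose),
        ratio=ratio,
        status=np.full(shape, "optimal", dtype=object),
        glucose_reaction="EX_glc_e",
    )


class TestCalibrate:
    def test_exact_cell_selected(self):
        grid = _grid([[1.0, 2.0], [3.0, 4.0]], [0.01, 0.1], [0.05, 0.2])
        cal = calibrate(grid, measured_atp=30.0, measured_glucose=10.0)
        assert (cal.k_star, cal.r_star) == (0.1, 0.05)
        assert cal.predicted_atp == pytest.approx(30.0)

    def test_single_feasible_cell(self):
        ratio = np.array([[np.nan, 2.0], [np.nan, np.nan]])
        grid = _grid(ratio, [0.01, 0.1], [0.05, 0.2])
        cal = calibrate(grid, 999.0, 10.0)
        assert (cal.k_star, cal.r_star) == (0.01, 0.2)

    def test_tie_breaks_toward_smaller_r_then_k(self):
        # capacities 10 and 30 are equally close to 20: smaller r wins
        grid = _grid([[1.0, 3.0]], [0.01], [0.05, 0.2])
        cal = calibrate(grid, 20.0, 10.0)
        assert cal.r_star == 0.05
        # within a column, smaller k wins
        grid2 = _grid([[1.0], [3.0]], [0.01, 0.1], [0.05])
        assert calibrate(grid2, 20.0, 10.0).k_star == 0.01

    def test_all_infeasible_raises(self):
        grid = _grid([[np.nan]], [0.01], [0.05])
        with pytest.raises(ValueError):
            calibrate(grid, 10.0, 10.0)

    def test_scale_factor(self):
        grid = _grid([[2.0]], [0.01], [0.05], glucose=-10.0)
        cal = calibrate(grid, 40.0, measured_glucose=20.0)
        assert cal.scale_factor == pytest.approx(2.0)


class TestExchangeReport:
    def test_identity_and_scaling(self, toy_model):
        sol = solve_fba(toy_model)
        with pytest.warns(UserWarning):
            base = exchange_report(sol, 1.0, toy_model)
            doubled = exchange_report(sol, 2.0, toy_model)
        pd.testing.assert_series_equal(doubled, base * 2.0)

    def test_proton_efflux_tracks_lactate(self):
        """Fermentation exports one proton per lactate (hand-checked from
        the toy stoichiometry): with oxygen closed they must be equal."""
        model = make_toy_model(ToyModelSpec(), oxygen_bound=0.0)
        sol = solve_fba(model)
        with pytest.warns(UserWarning):
            fluxes = exchange_report(sol, 1.0, model)
        assert fluxes["EX_h_e"] == pytest.approx(fluxes["EX_lac_e"], abs=1e-8)
        assert fluxes["EX_lac_e"] == pytest.approx(20.0, abs=1e-6)  # 2 per glucose
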