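"""Max-ATP flux balance analysis, the 2D (k x r) sweep, and calibration.

Flux balance analysis finds a steady-state flux vector v maximising an
objective c.v subject to S.v = 0 and per-reaction bounds lb <= v <= ub.
Here the objective is a generic ATP demand (hydrolysis sink) reaction, so
the optimum is the cell's maximum capacity to generate ATP under the
proteome- and medium-derived constraints.

The sweep rebuilds the bounds at every (compression k, availability ratio
r) grid point and records the optimum, the realised glucose uptake, and
the dimensionless ATP-per-glucose ratio

    ratio = max ATP flux / |glucose uptake flux|                    (supply)

which, multiplied by a measured glucose uptake rate, converts model units
to measured units (pmol ATP per ng protein per day):

    ATP capacity = ratio * measured glucose uptake.

Calibration picks the grid cell whose converted capacity is closest to a
measured total ATP production rate (Seahorse-style).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .gpr import CompressionParams, ExchangeSpec, effective_abundances, exchange_bounds, internal_bounds
from .model import MetabolicModel

__all__ = [
    "FbaSolution",
    "solve_fba",
    "SweepGrid",
    "sweep",
    "atp_glucose_ratio",
    "scale_to_measured",
    "CalibrationPoint",
    "calibrate",
    "exchange_report",
]

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class FbaSolution:
    status: str
    objective: float
    fluxes: pd.Series

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def solve_fba(model: MetabolicModel, objective_id: str | None = None) -> FbaSolution:
    """Maximise the objective reaction's flux subject to S.v = 0 and bounds.

    Infeasible/unbounded problems are returned as statuses, never raised.
    """
    objective_id = objective_id or model.objective_id
    rxn_ids = model.reaction_ids
    if objective_id not in rxn_ids:
        raise KeyError(f"objective reaction {objective_id!r} absent from model")
    S, _, _ = model.stoichiometric_matrix()
    n = len(rxn_ids)
    c = np.zeros(n)
    c[rxn_ids.index(objective_id)] = -1.0  # linprog minimises
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    if any(lb > ub for lb, ub in bounds):
        empty = pd.Series(np.nan, index=rxn_ids)
        return FbaSolution("infeasible", float("nan"), empty)
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": 1e-9, "dual_feasibility_tolerance": 1e-9},
    )
    status = _STATUS.get(res.status, f"status_{res.status}")
    if status != "optimal":
        return FbaSolution(status, float("nan"), pd.Series(np.nan, index=rxn_ids))
    return FbaSolution("optimal", float(-res.fun), pd.Series(res.x, index=rxn_ids))


# ---------------------------------------------------------------------------
# 2D parameter sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepGrid:
    """Objective / glucose-uptake / ATP-per-glucose surfaces over (k, r).

    Matrices are indexed [k, r]; infeasible cells hold NaN in the value
    matrices and their status string in ``status``.
    """

    k_values: np.ndarray
    r_values: np.ndarray
    objective: np.ndarray
    glucose_uptake: np.ndarray
    ratio: np.ndarray
    status: np.ndarray
    glucose_reaction: str

    def __post_init__(self) -> None:
        shape = (len(self.k_values), len(self.r_values))
        for mat in (self.objective, self.glucose_uptake, self.ratio, self.status):
            if mat.shape != shape:
                raise ValueError("sweep matrix shape does not match axis lengths")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (k, r, objective, glucose_uptake, ratio, status)."""
        rows = []
        for i, k in enumerate(self.k_values):
            for j, r in enumerate(self.r_values):
                rows.append(
                    {
                        "k": k,
                        "r": r,
                        "objective": self.objective[i, j],
                        "glucose_uptake": self.glucose_uptake[i, j],
                        "ratio": self.ratio[i, j],
                        "status": self.status[i, j],
                    }
                )
        return pd.DataFrame(rows)


def sweep(
    model: MetabolicModel,
    gene_abundance: Mapping[str, float],
    exchange: ExchangeSpec,
    k_values,
    r_values,
    b_max: float = 1000.0,
    objective_id: str | None = None,
) -> SweepGrid:
    """Solve the max-ATP LP at every (k, r) grid point.

    Bounds are rebuilt per cell: internal bounds from the compressed
    minsum abundances, exchange bounds from the availability spec with
    the cell's r.  Infeasible cells are recorded, not raised (they are
    the blank regions of the supply heatmaps).
    """
    k_values = np.asarray(list(k_values), dtype=float)
    r_values = np.asarray(list(r_values), dtype=float)
    if k_values.size == 0 or r_values.size == 0:
        raise ValueError("sweep grids must be non-empty")
    glc_rxn = model.exchange_for_metabolite(exchange.glucose_id)
    if glc_rxn is None:
        raise KeyError(f"no exchange reaction for {exchange.glucose_id}")
    shape = (k_values.size, r_values.size)
    objective = np.full(shape, np.nan)
    glucose = np.full(shape, np.nan)
    ratio = np.full(shape, np.nan)
    status = np.full(shape, "", dtype=object)
    for i, k in enumerate(k_values):
        params = CompressionParams(k=float(k), b_max=b_max)
        effective = effective_abundances(model, gene_abundance)
        bounded = internal_bounds(model, effective, params)
        for j, r in enumerate(r_values):
            spec = dataclasses.replace(exchange, r=float(r))
            cell_model = exchange_bounds(bounded, spec, params)
            sol = solve_fba(cell_model, objective_id)
            status[i, j] = sol.status
            if sol.optimal:
                objective[i, j] = sol.objective
                glucose[i, j] = sol.fluxes[glc_rxn.id]
                ratio[i, j] = atp_glucose_ratio(sol, glc_rxn.id)
    return SweepGrid(k_values, r_values, objective, glucose, ratio, status, glc_rxn.id)


def atp_glucose_ratio(sol: FbaSolution, glucose_reaction: str) -> float:
    """Molar ATP produced per glucose taken up (NaN when uptake is zero)."""
    if not sol.optimal:
        return float("nan")
    uptake = sol.fluxes[glucose_reaction]
    if uptake >= -1e-12:
        return float("nan")
    return sol.objective / abs(uptake)


def scale_to_measured(ratio: float, measured_glucose: float) -> float:
    """Convert the dimensionless ratio to measured ATP units.

    ``measured_glucose`` is the measured uptake magnitude in
    pmol glucose per ng protein per day; the product carries the same
    units for ATP.
    """
    if ratio < 0 or measured_glucose < 0:
        raise ValueError("ratio and measured glucose uptake must be non-negative")
    return ratio * measured_glucose


@dataclass
class CalibrationPoint:
    k_star: float
    r_star: float
    predicted_atp: float  # pmol ATP / ng protein / day at (k*, r*)
    measured_atp: float
    scale_factor: float  # measured glucose / |model glucose uptake|
    capacity: np.ndarray = field(repr=False)  # Eq.2-scaled grid


def calibrate(
    grid: SweepGrid, measured_atp: float, measured_glucose: float
) -> CalibrationPoint:
    """Pick the grid cell whose converted ATP capacity is nearest measured.

    Ties break toward smaller r, then smaller k.  All-infeasible grids
    raise.
    """
    capacity = grid.ratio * measured_glucose
    finite = np.isfinite(capacity)
    if not finite.any():
        raise ValueError("no feasible sweep cell with defined glucose uptake")
    err = np.where(finite, np.abs(capacity - measured_atp), np.inf)
    best = np.inf
    best_ij = None
    for j in range(err.shape[1]):  # r-major: smaller r wins ties
        for i in range(err.shape[0]):  # then smaller k
            if err[i, j] < best - 1e-15:
                best = err[i, j]
                best_ij = (i, j)
    i, j = best_ij
    model_uptake = abs(grid.glucose_uptake[i, j])
    return CalibrationPoint(
        k_star=float(grid.k_values[i]),
        r_star=float(grid.r_values[j]),
        predicted_atp=float(capacity[i, j]),
        measured_atp=float(measured_atp),
        scale_factor=float(measured_glucose / model_uptake),
        capacity=capacity,
    )


def exchange_report(sol: FbaSolution, scale_factor: float, model: MetabolicModel) -> pd.Series:
    """Exchange fluxes rescaled to measured units via the calibration factor.

    Positive = secretion, negative = uptake; includes proton/lactate
    exchanges for comparison with acidification measurements.  Only the
    objective value of an FBA solution is unique; individual fluxes may
    have alternate optima.
    """
    if not sol.optimal:
        raise ValueError("exchange report requires an optimal solution")
    warnings.warn(
        "FBA flux vectors may have alternate optima; only the objective value is unique",
        stacklevel=2,
    )
    ex_ids = [r.id for r in model.exchanges]
    return sol.fluxes[ex_ids] * scale_factor
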