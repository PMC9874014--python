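"""Turn time-course concentrations into normalized daily exchange rates.

Metabolite (glucose, lactate, glutamine, glutamate), cell-count and
protein time courses measured over a few days are converted to daily
fluxes, normalised per cell and per ng protein, so they can constrain the
supply model's exchange reactions and calibrate its output.  Consumption
is negative throughout (the exchange-reaction convention); magnitudes
are taken only at the bound interface.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "normalize_replicates",
    "daily_flux",
    "fba_comparison_rate",
    "net_protein_synthesis",
]


def normalize_replicates(values: pd.Series, experiment: pd.Series) -> pd.Series:
    """Rescale each experiment to the grand mean.

    Every value is divided by its experiment's mean and multiplied by the
    mean over all experiments, removing between-repeat offsets while
    preserving the grand mean.  A single experiment (or identical means)
    passes through unchanged.
    """
    values = values.astype(float)
    means = values.groupby(experiment.to_numpy()).transform("mean")
    if (means == 0).any():
        raise ValueError("an experiment has zero mean; cannot normalize")
    return values / means * values.mean()


def daily_flux(
    timecourse: pd.DataFrame,
    cell_conc: pd.DataFrame | None = None,
    protein_per_cell: pd.Series | None = None,
    symmetric: bool = False,
) -> pd.DataFrame:
    """Daily rates from a replicate time course on a matching day grid.

    ``timecourse``: rows = days (index, in days), columns = replicates,
    values in quantity per mL.  The day-d rate for a replicate is the
    replicate's value at day d minus the *replicate-average* value at
    day d-1, divided by the day gap (``symmetric=True`` averages
    replicates at both ends instead).  Decreasing analytes give negative
    rates (consumption).

    ``cell_conc`` (same layout, cells per mL) adds a per-cell rate
    dividing by the mean of the replicate-averaged cell concentration at
    days d and d-1; ``protein_per_cell`` (indexed by day, ng per cell)
    further adds a per-ng-protein rate.

    Returns a long-format frame with columns day, replicate, rate_per_ml
    and, when available, rate_per_cell / rate_per_ng.
    """
    days = np.asarray(timecourse.index, dtype=float)
    if len(days) < 2 or not np.all(np.diff(days) > 0):
        raise ValueError("need >= 2 strictly increasing time points")
    rep_mean = timecourse.mean(axis=1)
    rows = []
    for i in range(1, len(days)):
        gap = days[i] - days[i - 1]
        for rep in timecourse.columns:
            end = rep_mean.iloc[i] if symmetric else timecourse.iloc[i][rep]
            rate = (end - rep_mean.iloc[i - 1]) / gap
            row = {"day": days[i], "replicate": rep, "rate_per_ml": rate}
            if cell_conc is not None:
                cells = cell_conc.mean(axis=1)
                cell_avg = (cells.iloc[i] + cells.iloc[i - 1]) / 2.0
                row["rate_per_cell"] = rate / cell_avg
                if protein_per_cell is not None:
                    prot_avg = (protein_per_cell.iloc[i] + protein_per_cell.iloc[i - 1]) / 2.0
                    row["rate_per_ng"] = row["rate_per_cell"] / prot_avg
            rows.append(row)
    return pd.DataFrame(rows)


def fba_comparison_rate(rates: pd.DataFrame, column: str = "rate_per_ml") -> float:
    """Average the day-1->2 and day-2->3 rates (the 24-72 h window the
    supply model is compared against)."""
    window = rates[rates["day"].isin([2.0, 3.0])]
    if window.empty:
        raise ValueError("rates table lacks day-2/day-3 entries")
    return float(window.groupby("day")[column].mean().mean())


def net_protein_synthesis(p24: float, p72: float, normalize: bool = False) -> float:
    """Net protein synthesis rate from protein content at 24 h and 72 h.

    (p72 - p24) / 2 days; with ``normalize`` the result is additionally
    divided by the mean protein content, giving a per-day mass fraction.
    Net loss gives a negative rate.
    """
    if p24 <= 0 or p72 <= 0:
        raise ValueError("protein amounts must be positive")
    rate = (p72 - p24) / 2.0
    if normalize:
        rate /= (p24 + p72) / 2.0
    return rate
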