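"""Metabolite exchange rates from supernatant concentrations.

The exchange rate over a sampling interval [t1, t2] is the concentration
change in the medium converted to moles and normalized by the viable-cell
time integral:

    rate = (C(t2) - C(t1)) * V / integral N(t) dt

with the cell integral taken by trapezoid between measured densities and
expressed per 1e6 cells per hour.  Negative rates mean consumption, positive
rates release.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import SupernatantSeries, ViableCellSeries


@dataclass
class ExchangeRateSeries:
    """Per-interval exchange rates (nmol per 1e6 cells per hour)."""

    metabolite: str
    t_start: np.ndarray  # days
    t_end: np.ndarray  # days
    rate: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_start": self.t_start, "t_end": self.t_end, "rate": self.rate}
        )

    def peak_day(self) -> float:
        """End day of the interval with the maximum (most positive) rate."""
        return float(self.t_end[int(np.argmax(self.rate))])


def exchange_rates(
    supernatant: SupernatantSeries, cells: ViableCellSeries
) -> ExchangeRateSeries:
    """Per-interval consumption/release rates of one metabolite.

    Requires at least two shared timepoints, positive viable-cell densities
    and a known medium volume.
    """
    if supernatant.volume_ml is None or supernatant.volume_ml <= 0:
        raise ValueError("medium volume must be given and positive")
    sup_days = np.asarray(supernatant.days, dtype=float)
    cell_days = np.asarray(cells.days, dtype=float)
    shared = np.intersect1d(sup_days, cell_days)
    if len(shared) < 2:
        raise ValueError("need >= 2 shared timepoints")
    conc = np.interp(shared, sup_days, np.asarray(supernatant.concentration_mM, float))
    dens = np.interp(shared, cell_days, np.asarray(cells.cells_per_ml, float))
    if (dens <= 0).any():
        raise ValueError("viable-cell densities must be > 0")

    t_start, t_end, rates = [], [], []
    for i in range(len(shared) - 1):
        hours = (shared[i + 1] - shared[i]) * 24.0
        delta_nmol = (conc[i + 1] - conc[i]) * supernatant.volume_ml * 1000.0
        # trapezoid integral of total viable cells, in (1e6 cells) * hours
        total_cells = 0.5 * (dens[i] + dens[i + 1]) * supernatant.volume_ml
        integral = total_cells * hours / 1.0e6
        t_start.append(shared[i])
        t_end.append(shared[i + 1])
        rates.append(delta_nmol / integral)
    return ExchangeRateSeries(
        metabolite=supernatant.metabolite,
        t_start=np.array(t_start),
        t_end=np.array(t_end),
        rate=np.array(rates),
    )


def read_series(concentration_csv, cells_csv, metabolite: str, volume_ml: float):
    """Load (day, concentration_mM) and (day, cells_per_ml) CSV inputs."""
    conc = pd.read_csv(concentration_csv)
    dens = pd.read_csv(cells_csv)
    sup = SupernatantSeries(
        metabolite=metabolite,
        days=conc["day"].to_numpy(float),
        concentration_mM=conc["concentration_mM"].to_numpy(float),
        volume_ml=volume_ml,
    )
    cells = ViableCellSeries(
        days=dens["day"].to_numpy(float),
        cells_per_ml=dens["cells_per_ml"].to_numpy(float),
    )
    return sup, cells
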