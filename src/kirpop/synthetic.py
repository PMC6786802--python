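"""Synthetic per-cell measurements with the model's dispersion structure.

Each simulated cell draws a fraction redistribution df from a truncated
normal (mean 0, configurable sd, truncated so f1 + df stays in [0, 1]) and
optionally a multiplicative log-normal measurement noise on its control and
drugged currents.  Aggregated outputs match the layout of real
concentration-response tables (c, F, SE, n) so the fitting and ensemble
analyses can be exercised without experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ModelParams, ParameterError, rectification_g

__all__ = ["EnsembleSpec", "generate_cells", "generate_concentration_response",
           "truncated_delta_f"]

#: Reference experimental concentration grids (ethanol in mM, nicotine in nM).
EXPERIMENT_GRIDS = {"ethanol": (0.8, 8.0, 20.0, 80.0),
                    "nicotine": (4.0, 40.0, 400.0)}


@dataclass(frozen=True)
class EnsembleSpec:
    """Study design for a synthetic cell ensemble.

    Parameters
    ----------
    model : ModelParams
        Mean-cell model; per-cell fractions are (f1 + df, f2 - df).
    c_grid : sequence of float
        Drug concentrations, one group of cells per concentration.
    n_cells : int
        Cells per concentration (independent draws per concentration).
    delta_f_sd : float
        Standard deviation of the truncated-normal df distribution.
    noise_sd : float
        Log-scale sd of multiplicative measurement noise applied
        independently to control and drugged currents.
    U : float
        Measurement voltage (mV).
    seed : int or None
        Seed for the random generator; fixed seed gives identical output.
    """

    model: ModelParams
    c_grid: Sequence[float] = field(default=(0.8, 8.0, 20.0, 80.0))
    n_cells: int = 10
    delta_f_sd: float = 0.05
    noise_sd: float = 0.05
    U: float = -110.0
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "c_grid",
                           tuple(float(c) for c in self.c_grid))
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if self.delta_f_sd < 0 or self.noise_sd < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        if any(c < 0 for c in self.c_grid):
            raise ParameterError("concentrations must be non-negative")


def truncated_delta_f(f1: float, sd: float) -> stats.rv_continuous:
    """Frozen truncated-normal df distribution keeping f1 + df in [0, 1]."""
    lo, hi = -f1, 1.0 - f1
    if hi < lo or sd <= 0:
        raise ParameterError("infeasible truncation for delta_f distribution")
    return stats.truncnorm(lo / sd, hi / sd, loc=0.0, scale=sd)


def generate_cells(spec: EnsembleSpec) -> pd.DataFrame:
    """Simulate per-cell records for every concentration in the grid.

    Returns a DataFrame with columns ``cell_id``, ``c``, ``delta_f``,
    ``I_contr``, ``I_drug``, ``F``; the relative effect is always the ratio
    of the (noisy) drugged to control current of the same cell.
    """
    m = spec.model
    if m.n_populations != 2:
        raise ParameterError("synthetic ensembles require a two-population model")
    rng = np.random.default_rng(spec.seed)
    f1 = m.f1
    g = rectification_g(spec.U, m.rectification)
    m_u = m.at_voltage(spec.U)
    (_, pop1u), (_, pop2u) = m_u.populations
    drive = g * (spec.U - m.U_K)

    frames = []
    cell_counter = 0
    for c in spec.c_grid:
        if spec.delta_f_sd > 0:
            df = truncated_delta_f(f1, spec.delta_f_sd).rvs(
                size=spec.n_cells, random_state=rng)
        else:
            df = np.zeros(spec.n_cells)
        f1_cells = f1 + df
        # vectorised over cells: the factors are scalars at fixed c
        base = f1_cells * pop1u.h[0] + (1.0 - f1_cells) * pop2u.h[0]
        drugged = (f1_cells * pop1u.conductivity_factor(c)
                   + (1.0 - f1_cells) * pop2u.conductivity_factor(c))
        I_contr = base * drive
        I_drug = drugged * drive
        if spec.noise_sd > 0:
            I_contr = I_contr * rng.lognormal(0.0, spec.noise_sd, spec.n_cells)
            I_drug = I_drug * rng.lognormal(0.0, spec.noise_sd, spec.n_cells)
        frames.append(pd.DataFrame({
            "cell_id": [f"cell{cell_counter + i:04d}" for i in range(spec.n_cells)],
            "c": c,
            "delta_f": df,
            "I_contr": I_contr,
            "I_drug": I_drug,
            "F": I_drug / I_contr,
        }))
        cell_counter += spec.n_cells
    return pd.concat(frames, ignore_index=True)


def generate_concentration_response(spec: EnsembleSpec,
                                    cells: pd.DataFrame | None = None
                                    ) -> pd.DataFrame:
    """Aggregate per-cell records to a (c, F, SE, n) response table.

    ``SE`` is the sample standard deviation of F over cells divided by
    sqrt(n); it is NaN when a concentration has a single cell.
    """
    if cells is None:
        cells = generate_cells(spec)
    rows = []
    for c, grp in cells.groupby("c", sort=True):
        n = len(grp)
        se = float(grp["F"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({"c": float(c), "F": float(grp["F"].mean()),
                     "SE": se, "n": n})
    return pd.DataFrame(rows)
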