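"""Cell-to-cell dispersion and correlation analyses.

Variability between cells is modelled as a redistribution of channels
between the two populations (f1 -> f1 + df, f2 -> f2 - df).  This module
computes the resulting dispersion bands around a mean concentration-response
curve, the parametric (control current, drug effect) curve traced by a
continuous f1 sweep, and ordinary least-squares regression of per-cell data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (ModelParams, ParameterError, relative_effect,
                   steady_state_current)

__all__ = ["CellRecord", "RegressionResult", "dispersion_band",
           "correlation_curve", "fit_linear_regression", "regress_cells"]


@dataclass(frozen=True)
class CellRecord:
    """One simulated or measured cell at one drug concentration."""

    cell_id: str
    c: float
    delta_f: float
    I_contr: float
    I_drug: float
    F: float


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least-squares line y = slope*x + intercept with Pearson r.

    The two-sided p-value tests r != 0 with the t statistic on n-2 degrees
    of freedom; it is NaN for n < 3.
    """

    slope: float
    intercept: float
    r: float
    pvalue: float
    n: int


def dispersion_band(m: ModelParams, c_grid, delta_f: float,
                    U: float | None = None) -> pd.DataFrame:
    """Mean concentration-response curve bracketed by +/- delta_f variants.

    Returns columns ``c``, ``F`` (mean fractions), ``F_plus`` (f1 + delta_f)
    and ``F_minus`` (f1 - delta_f); all other parameters held fixed.  All
    three curves pass through F = 1 at c = 0.
    """
    delta_f = float(delta_f)
    if delta_f < 0:
        raise ParameterError("dispersion band magnitude delta_f must be >= 0")
    m_plus = m.redistributed(delta_f)
    m_minus = m.redistributed(-delta_f)
    c = np.asarray(c_grid, dtype=float)
    return pd.DataFrame({
        "c": c,
        "F": relative_effect(m, c, U),
        "F_plus": relative_effect(m_plus, c, U),
        "F_minus": relative_effect(m_minus, c, U),
    })


def correlation_curve(m: ModelParams, c: float, U: float,
                      f1_range: tuple[float, float] = (0.05, 0.95),
                      n_points: int = 200) -> pd.DataFrame:
    """Parametric (control current, drug effect) curve under an f1 sweep.

    For each f1 in the sweep the drug-free current I_contr(U) and the
    relative effect F(c) are evaluated with all other parameters fixed.
    ``I_contr_abs`` carries |I_contr| so that "larger control current"
    reads left to right even at voltages where the current is negative.
    """
    lo, hi = float(f1_range[0]), float(f1_range[1])
    if not (0.0 <= lo <= hi <= 1.0):
        raise ParameterError("f1_range must be an ordered interval within [0, 1]")
    if n_points < 2:
        raise ParameterError("n_points must be >= 2")
    f1s = np.linspace(lo, hi, int(n_points))
    I_contr = np.empty(f1s.size)
    F = np.empty(f1s.size)
    for i, f1 in enumerate(f1s):
        m_i = m.with_fraction(float(f1))
        I_contr[i] = steady_state_current(m_i, float(U), 0.0)
        F[i] = relative_effect(m_i, float(c), U)
    return pd.DataFrame({"f1": f1s, "I_contr": I_contr,
                         "I_contr_abs": np.abs(I_contr), "F": F})


def fit_linear_regression(x, y) -> RegressionResult:
    """Ordinary least-squares regression of y on x with Pearson correlation.

    Raises on fewer than two points or zero variance in x.  For exactly two
    points the p-value is reported as NaN (no residual degrees of freedom).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 2:
        raise ParameterError("regression requires at least two points")
    if np.ptp(x) == 0.0:
        raise ParameterError("regression requires non-zero variance in x")
    if np.ptp(y) == 0.0:  # degenerate: flat response, r defined as 0
        return RegressionResult(0.0, float(y[0]), 0.0,
                                np.nan if n < 3 else 1.0, n)
    res = stats.linregress(x, y)
    pvalue = np.nan if n < 3 else float(res.pvalue)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue), pvalue, n)


def regress_cells(cells: pd.DataFrame) -> RegressionResult:
    """Regress per-cell relative effect F on the control current magnitude.

    ``cells`` needs columns ``I_contr`` and ``F``.  When all control
    currents are non-positive (inward currents), |I_contr| is used on the
    abscissa so the slope sign matches plots drawn against current magnitude.
    """
    x = np.asarray(cells["I_contr"], dtype=float)
    if np.all(x <= 0):
        x = np.abs(x)
    return fit_linear_regression(x, np.asarray(cells["F"], dtype=float))
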