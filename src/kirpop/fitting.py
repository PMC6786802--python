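"""Bounded nonlinear least-squares calibration of the population model.

Replaces manual trial-and-error parameter setting with a weighted
least-squares fit of the relative-effect curve F(c) to concentration-response
data, using multistart ``scipy.optimize.least_squares`` with dissociation
constants optimised on a log10 scale.

Identifiability notes
---------------------
F(c) is a ratio of conductivity-factor sums, hence exactly invariant to a
common rescaling of every h factor.  A fit that frees all h factors of the
model is therefore rejected; keep at least one h fixed (h_0_1 by default)
unless absolute-current data are available.  A flat objective across the
multistart points (e.g. a parameter that multiplies an occupancy that is
identically zero) is flagged as non-identifiable; the best candidate is
still returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import ModelParams, ParameterError, relative_effect

__all__ = ["FitSpec", "FitResult", "fit_concentration_response",
           "profile_parameter", "get_param", "set_param"]

_K_NAMES = {"K_1": (1, 0), "K_2": (1, 1), "K_3": (2, 0), "K_4": (2, 1)}


def get_param(m: ModelParams, name: str) -> float:
    """Read a named scalar parameter from a two-population model."""
    if name == "f_1":
        return m.f1
    if name in _K_NAMES:
        j, idx = _K_NAMES[name]
        return m.populations[j - 1][1].K[idx]
    k, j = ModelParams._parse_h_name(name)
    return m.populations[j - 1][1].h[k]


def set_param(m: ModelParams, name: str, value: float,
              tie_K12: bool = False) -> ModelParams:
    """Return a copy of ``m`` with the named parameter replaced.

    With ``tie_K12`` true, setting ``K_1`` also sets ``K_2`` (the two
    pocket constants are printed as a single column in the reference
    parameter tables and are equal by default).
    """
    if name == "f_1":
        return m.with_fraction(float(value))
    if name in _K_NAMES:
        j, idx = _K_NAMES[name]
        f, pop = m.populations[j - 1]
        K = list(pop.K)
        K[idx] = float(value)
        if tie_K12 and name == "K_1":
            K[1] = float(value)
        return m.with_population(j, pop=replace(pop, K=tuple(K)))
    return m.with_h(name, float(value))


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    ``free`` maps parameter names (``f_1``, ``K_1``.. ``K_4``, ``h_<k>_<j>``)
    to (lower, upper) bounds.  Dissociation constants are optimised on a
    log10 scale internally.  ``weighting`` is ``"auto"`` (1/SE^2 when an SE
    column with positive values is present), ``"none"`` or
    ``"inverse_se2"``.
    """

    free: Mapping[str, tuple[float, float]]
    tie_K12: bool = True
    weighting: str = "auto"
    n_starts: int = 16
    seed: int | None = 0

    def __post_init__(self) -> None:
        free = {str(k): (float(v[0]), float(v[1]))
                for k, v in dict(self.free).items()}
        object.__setattr__(self, "free", free)
        if not free:
            raise ParameterError("at least one free parameter is required")
        for name, (lo, hi) in free.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ParameterError(f"bounds for {name} must be finite with lo < hi")
            if name.startswith(("K_", "h_")) and lo <= 0 and name.startswith("K_"):
                raise ParameterError(f"K bounds must be positive, got {lo} for {name}")
        if self.weighting not in ("auto", "none", "inverse_se2"):
            raise ParameterError(f"unknown weighting mode {self.weighting!r}")
        if self.n_starts < 1:
            raise ParameterError("n_starts must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multistart least-squares fit."""

    model: ModelParams
    estimates: dict[str, float]
    rss: float
    success: bool
    non_identifiable: bool
    start_results: pd.DataFrame
    dispersion: dict[str, float]


def _is_log(name: str) -> bool:
    return name in _K_NAMES


def _validate_data(data: pd.DataFrame, n_free: int) -> tuple[np.ndarray, ...]:
    for col in ("c", "F"):
        if col not in data.columns:
            raise ParameterError(f"concentration-response data lacks column {col!r}")
    c = np.asarray(data["c"], dtype=float)
    F = np.asarray(data["F"], dtype=float)
    if c.size < n_free:
        raise ParameterError(
            f"under-determined fit: {c.size} data points for {n_free} free parameters")
    if np.any(F <= 0) or not np.all(np.isfinite(F)):
        raise ParameterError("relative effects F must be positive and finite")
    return c, F


def _weights(data: pd.DataFrame, mode: str) -> np.ndarray:
    F = np.asarray(data["F"], dtype=float)
    w = np.ones_like(F)
    use_se = mode == "inverse_se2" or (mode == "auto" and "SE" in data.columns)
    if use_se:
        if "SE" not in data.columns:
            raise ParameterError("inverse_se2 weighting requires an SE column")
        se = np.asarray(data["SE"], dtype=float)
        good = np.isfinite(se) & (se > 0)
        w[good] = 1.0 / se[good]
    return w


def _reject_full_h_release(m0: ModelParams, names: Sequence[str]) -> None:
    all_h = {f"h_{k}_{j}" for j in range(1, m0.n_populations + 1)
             for k in range(3)}
    if all_h.issubset(set(names)):
        raise ParameterError(
            "F-only data cannot constrain a common scaling of all h factors; "
            "keep at least one h fixed (h_0_1 by default) or supply "
            "absolute-current data")


def fit_concentration_response(data: pd.DataFrame, spec: FitSpec,
                               m0: ModelParams) -> FitResult:
    """Fit free model parameters to a (c, F[, SE]) response table.

    Minimises sum_i w_i * (F_model(c_i) - F_i)^2 over the free parameters
    within their bounds, from ``spec.n_starts`` starting points (the values
    in ``m0`` plus log-/uniform draws over the bounds).  Non-convergence is
    flagged, never raised; the best candidate is always returned.
    """
    names = list(spec.free)
    _reject_full_h_release(m0, names)
    c, F = _validate_data(data, len(names))
    w = _weights(data, spec.weighting)

    lo = np.array([spec.free[n][0] for n in names])
    hi = np.array([spec.free[n][1] for n in names])
    log_mask = np.array([_is_log(n) for n in names])
    tlo = np.where(log_mask, np.log10(lo), lo)
    thi = np.where(log_mask, np.log10(hi), hi)

    def to_model(theta: np.ndarray) -> ModelParams:
        m = m0
        for name, t, is_log in zip(names, theta, log_mask):
            m = set_param(m, name, 10.0 ** t if is_log else t,
                          tie_K12=spec.tie_K12)
        return m

    def residuals(theta: np.ndarray) -> np.ndarray:
        return w * (relative_effect(to_model(theta), c) - F)

    # starting points: m0's own values first, then seeded draws over bounds
    rng = np.random.default_rng(spec.seed)
    x0 = np.array([get_param(m0, n) for n in names])
    x0 = np.clip(np.where(log_mask, np.log10(np.maximum(x0, 1e-300)), x0),
                 tlo, thi)
    starts = [x0]
    for _ in range(spec.n_starts - 1):
        starts.append(tlo + (thi - tlo) * rng.uniform(size=len(names)))

    start_obj = np.array([float(np.sum(residuals(s) ** 2)) for s in starts])
    flat = bool(np.ptp(start_obj) <= 1e-12 * max(1.0, float(np.mean(start_obj))))

    rows = []
    best = None
    for s in starts:
        sol = least_squares(residuals, s, bounds=(tlo, thi), method="trf")
        est = {n: (10.0 ** v if is_log else float(v))
               for n, v, is_log in zip(names, sol.x, log_mask)}
        rss = float(np.sum(sol.fun ** 2))
        rows.append({**est, "rss": rss, "success": bool(sol.success)})
        if best is None or rss < best[0]:
            best = (rss, sol, est)
    table = pd.DataFrame(rows)
    rss, sol, est = best
    converged = sol.success and not flat
    dispersion = {n: float(table[n].std(ddof=0)) for n in names}
    return FitResult(model=to_model(sol.x), estimates=est, rss=rss,
                     success=bool(converged), non_identifiable=flat,
                     start_results=table, dispersion=dispersion)


def profile_parameter(data: pd.DataFrame, spec: FitSpec, m0: ModelParams,
                      param: str, grid: Sequence[float]) -> pd.DataFrame:
    """RSS profile of one parameter: re-fit the remaining free parameters
    at each grid value of ``param``.

    An identifiable parameter shows a convex profile with an interior
    minimum; a structurally redundant one (e.g. any h when all other h are
    free on F-only data) shows a flat profile.  Returns a DataFrame with
    columns ``value`` and ``rss``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ParameterError("profile grid must be non-empty")
    others = {n: b for n, b in spec.free.items() if n != param}
    rows = []
    for v in grid:
        m_v = set_param(m0, param, float(v), tie_K12=spec.tie_K12)
        if others:
            sub = replace(spec, free=others)
            res = fit_concentration_response(data, sub, m_v)
            rss = res.rss
        else:
            c, F = _validate_data(data, 0)
            w = _weights(data, spec.weighting)
            rss = float(np.sum((w * (relative_effect(m_v, c) - F)) ** 2))
        rows.append({"value": float(v), "rss": rss})
    return pd.DataFrame(rows)
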