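"""First-order relaxation of population conductivities after concentration steps.

Drug binding is fast; the conformational changes that alter conductivity are
slow (transients last up to ~1e2 s).  Within a constant-concentration
segment each population conductivity relaxes exponentially toward its
equilibrium value::

    dG_j,t/dt = (G_j - G_j,t) / tau_j

with the steady state G_j = factor_j(c) * g(U) from the equilibrium model.
The closed-form solution per segment is used directly; current and relative
effect follow by substituting G_j,t for G_j in the steady-state expressions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ModelParams, ParameterError, rectification_g

__all__ = ["TransientParams", "relax_conductivities", "washout"]

#: Illustrative default time constants (s); no measured values exist for
#: I_KAch transients, so these only set a plausible slow time scale.
DEFAULT_TAU = (10.0, 10.0)


@dataclass(frozen=True)
class TransientParams:
    """Relaxation time constants, sample times and concentration protocol.

    ``tau`` holds one time constant per population (seconds).  ``c_protocol``
    is a piecewise-constant schedule of ``(t_start, c)`` segments with
    strictly increasing start times; the first segment must start at or
    before the first sample time.
    """

    tau: tuple[float, ...]
    t_grid: Sequence[float]
    c_protocol: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau", tuple(float(t) for t in self.tau))
        object.__setattr__(self, "t_grid", np.asarray(self.t_grid, dtype=float))
        object.__setattr__(
            self, "c_protocol",
            tuple((float(t), float(c)) for t, c in self.c_protocol))
        if any(t <= 0 or not np.isfinite(t) for t in self.tau):
            raise ParameterError("time constants tau must be positive and finite")
        if len(self.t_grid) == 0 or np.any(np.diff(self.t_grid) < 0):
            raise ParameterError("t_grid must be non-empty and non-decreasing")
        if len(self.c_protocol) == 0:
            raise ParameterError("concentration protocol must have >= 1 segment")
        starts = [t for t, _ in self.c_protocol]
        if np.any(np.diff(starts) <= 0):
            raise ParameterError("protocol segment start times must increase")
        if any(c < 0 for _, c in self.c_protocol):
            raise ParameterError("protocol concentrations must be non-negative")
        if self.t_grid[0] < starts[0]:
            raise ParameterError("t_grid starts before the first protocol segment")


def relax_conductivities(m: ModelParams, tp: TransientParams, U: float,
                         G0: Sequence[float] | None = None) -> pd.DataFrame:
    """Time course of population conductivities, current and relative effect.

    Within each segment ``G_j,t(t) = G_j,ss + (G_j,start - G_j,ss) *
    exp(-(t - t_start)/tau_j)``.  ``G0`` sets the initial conductivities
    (model units, including g(U)); by default the system starts at the
    steady state of the first protocol segment.

    Returns a DataFrame with columns ``t``, ``G1``..``Gn``, ``I``, ``F``.
    """
    m = m.at_voltage(float(U))
    if len(tp.tau) != m.n_populations:
        raise ParameterError(
            f"need one tau per population ({m.n_populations}), got {len(tp.tau)}")
    g = rectification_g(U, m.rectification)
    fracs = np.array(m.fractions)
    taus = np.array(tp.tau)
    t = np.asarray(tp.t_grid, dtype=float)

    # steady-state conductivities per segment, shape (n_seg, n_pop)
    ss = np.array([[pop.conductivity_factor(c) * g for _, pop in m.populations]
                   for _, c in tp.c_protocol])
    starts = np.array([s for s, _ in tp.c_protocol])
    ends = np.append(starts[1:], np.inf)

    G_cur = ss[0].copy() if G0 is None else np.asarray(G0, dtype=float).copy()
    if G_cur.shape != (m.n_populations,):
        raise ParameterError("G0 must hold one initial conductivity per population")

    G = np.empty((t.size, m.n_populations))
    for seg in range(len(tp.c_protocol)):
        last = seg == len(tp.c_protocol) - 1
        mask = (t >= starts[seg]) & ((t <= ends[seg]) if last else (t < ends[seg]))
        dt = t[mask, None] - starts[seg]
        G[mask] = ss[seg] + (G_cur - ss[seg]) * np.exp(-dt / taus)
        if not last:  # propagate the analytic state to the next segment start
            span = ends[seg] - starts[seg]
            G_cur = ss[seg] + (G_cur - ss[seg]) * np.exp(-span / taus)

    baseline = m.baseline_factor() * g
    total = G @ fracs
    out = {"t": t}
    for j in range(m.n_populations):
        out[f"G{j + 1}"] = G[:, j]
    out["I"] = total * (float(U) - m.U_K)
    out["F"] = total / baseline
    return pd.DataFrame(out)


def washout(m: ModelParams, tau: Sequence[float], U: float, c: float,
            t_on: float, t_end: float, n_points: int = 501) -> pd.DataFrame:
    """Drug application followed by washout, starting from the drug-free state.

    Convenience wrapper: the concentration steps from 0 to ``c`` at t=0 and
    back to 0 at ``t_on``; the trajectory is sampled on ``n_points`` times
    in [0, t_end].  For ``t_on`` and ``t_end - t_on`` both much longer than
    the time constants the endpoints coincide with the drug-free baseline.
    """
    if not 0.0 < t_on < t_end:
        raise ParameterError("need 0 < t_on < t_end for a washout protocol")
    tp = TransientParams(tau=tuple(tau),
                         t_grid=np.linspace(0.0, float(t_end), int(n_points)),
                         c_protocol=((0.0, float(c)), (float(t_on), 0.0)))
    m_u = m.at_voltage(float(U))
    g = rectification_g(U, m_u.rectification)
    G0 = [pop.h[0] * g for _, pop in m_u.populations]  # drug-free steady state
    return relax_conductivities(m, tp, U, G0=G0)
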