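"""Equilibrium algebra of drug action on a mixture of Kir channel populations.

The whole-cell inwardly rectifying potassium current is modelled as the sum of
``n`` independent constituents, one per population of structurally identical
channels (e.g. GIRK1/4 heterotetramers vs GIRK4 homotetramers underlying
I_KAch)::

    I(U, c) = sum_j f_j * G_j(c) * (U - U_K),      sum_j f_j = 1

where ``f_j`` is the fraction of channels belonging to population ``j``,
``U_K`` the potassium reversal voltage, and ``G_j`` the population
conductivity.  Drug binding is assumed fast relative to the conformational
changes that alter conductivity, so the binding-state probabilities
``x_k`` (``k`` drug molecules bound / site ``k`` occupied) take their
equilibrium values at every drug concentration ``c``.

Two binding schemes are supported per population:

* ``sequential_pocket`` — a hydrophobic pocket that accommodates one or two
  drug molecules in sequence (dissociation constants ``K1``, ``K2``);
  associated with drug-induced activation.
* ``two_site`` — two independent single-occupancy sites (``K3``, ``K4``);
  associated with inhibition.  ``K4`` may be infinite, meaning the second
  site never binds.

Each binding state ``k`` carries a dimensionless conductivity factor
``h_k``; the voltage dependence (inward rectification) is separated into a
common empirical conductance ``g(U)`` so that ``G_k = h_k * g(U)``.  The
relative drug effect ``F = I/I0`` is then voltage independent and depends
only on concentrations, dissociation constants and the ``h`` factors.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParameterError",
    "DegenerateModelError",
    "Scheme",
    "Occupancy",
    "PopulationParams",
    "RectificationParams",
    "DEFAULT_RECTIFICATION",
    "ModelParams",
    "occupancy_pocket",
    "occupancy_two_site",
    "population_conductivity_factor",
    "rectification_g",
    "steady_state_current",
    "relative_effect",
    "concentration_response",
    "iv_curve",
]


class ParameterError(ValueError):
    """Raised when a model parameter violates its invariants."""


class DegenerateModelError(ValueError):
    """Raised when the drug-free baseline conductivity is zero."""


class Scheme(str, Enum):
    """Drug-binding scheme of one channel population."""

    SEQUENTIAL_POCKET = "sequential_pocket"
    TWO_SITE = "two_site"


_H_NAME = re.compile(r"^h_([012])_([12])$")


def _is_scalar(x) -> bool:
    return np.ndim(x) == 0


def _check_conc(c) -> np.ndarray:
    arr = np.asarray(c, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ParameterError("drug concentration must be finite and non-negative")
    return arr


@dataclass(frozen=True)
class Occupancy:
    """Equilibrium binding-state probabilities (x0, x1, x2) of one population.

    Components are probabilities in [0, 1] and sum to 1.  Fields may be
    scalars or aligned numpy arrays (one entry per concentration).
    """

    x0: float | np.ndarray
    x1: float | np.ndarray
    x2: float | np.ndarray

    def __post_init__(self) -> None:
        tol = 1e-9
        arr = self.as_array()
        if np.any(arr < -tol) or np.any(arr > 1 + tol):
            raise ParameterError("occupancy components must lie in [0, 1]")
        if np.any(np.abs(arr.sum(axis=0) - 1.0) > tol):
            raise ParameterError("occupancy components must sum to 1")

    def as_array(self) -> np.ndarray:
        """Stack (x0, x1, x2) along a leading axis."""
        return np.stack([np.asarray(self.x0, float),
                         np.asarray(self.x1, float),
                         np.asarray(self.x2, float)])

    def as_tuple(self) -> tuple:
        return (self.x0, self.x1, self.x2)


def occupancy_pocket(c, K1: float, K2: float) -> Occupancy:
    """Equilibrium occupancy of a sequential two-molecule binding pocket.

    x0 = 1 / (1 + c/K1 + c^2/(K1*K2)), x1 = x0*c/K1, x2 = x0*c^2/(K1*K2).

    Parameters
    ----------
    c : scalar or array
        Drug concentration (same units as ``K1``/``K2``).
    K1, K2 : float
        Dissociation constants of the first and second binding step;
        both must be positive and finite.
    """
    for name, K in (("K1", K1), ("K2", K2)):
        if not (np.isfinite(K) and K > 0):
            raise ParameterError(f"{name} must be positive and finite, got {K!r}")
    arr = _check_conc(c)
    a1 = arr / K1
    a2 = arr * arr / (K1 * K2)
    x0 = 1.0 / (1.0 + a1 + a2)
    x1, x2 = x0 * a1, x0 * a2
    if _is_scalar(c):
        return Occupancy(float(x0), float(x1), float(x2))
    return Occupancy(x0, x1, x2)


def occupancy_two_site(c, K3: float, K4: float) -> Occupancy:
    """Equilibrium occupancy of two independent single-occupancy sites.

    x0 = 1 / (1 + c/K3 + c/K4), x1 = x0*c/K3, x2 = x0*c/K4.

    ``K4`` may be ``math.inf``, in which case the second site never binds
    and x2 == 0 exactly at every concentration.
    """
    if not (np.isfinite(K3) and K3 > 0):
        raise ParameterError(f"K3 must be positive and finite, got {K3!r}")
    if not K4 > 0:
        raise ParameterError(f"K4 must be positive (possibly infinite), got {K4!r}")
    arr = _check_conc(c)
    a1 = arr / K3
    a2 = arr / K4  # exact 0.0 when K4 is inf
    x0 = 1.0 / (1.0 + a1 + a2)
    x1, x2 = x0 * a1, x0 * a2
    if _is_scalar(c):
        return Occupancy(float(x0), float(x1), float(x2))
    return Occupancy(x0, x1, x2)


@dataclass(frozen=True)
class PopulationParams:
    """One population of identical channels: binding scheme, K's and h's.

    Parameters
    ----------
    scheme : Scheme
        ``sequential_pocket`` (K = (K1, K2)) or ``two_site`` (K = (K3, K4),
        K4 possibly infinite).
    K : (float, float)
        Dissociation constants in the same units as the drug concentration.
    h : (float, float, float)
        Dimensionless conductivity factors (h_0, h_1, h_2) of the three
        binding states; each multiplies the common rectification
        conductance g(U).
    """

    scheme: Scheme
    K: tuple[float, float]
    h: tuple[float, float, float]

    def __post_init__(self) -> None:
        scheme = Scheme(self.scheme)
        object.__setattr__(self, "scheme", scheme)
        object.__setattr__(self, "K", tuple(float(k) for k in self.K))
        object.__setattr__(self, "h", tuple(float(x) for x in self.h))
        if len(self.K) != 2:
            raise ParameterError("K must hold exactly two dissociation constants")
        if len(self.h) != 3:
            raise ParameterError("h must hold exactly three conductivity factors")
        if scheme is Scheme.SEQUENTIAL_POCKET:
            if not all(np.isfinite(k) and k > 0 for k in self.K):
                raise ParameterError("sequential_pocket requires finite positive K1, K2")
        else:
            if not (np.isfinite(self.K[0]) and self.K[0] > 0):
                raise ParameterError("two_site requires finite positive K3")
            if not self.K[1] > 0:
                raise ParameterError("two_site K4 must be positive (or inf)")
        if any(x < 0 or not np.isfinite(x) for x in self.h):
            raise ParameterError("h factors must be finite and non-negative")

    def occupancy(self, c) -> Occupancy:
        """Equilibrium occupancy at concentration ``c`` for this scheme."""
        if self.scheme is Scheme.SEQUENTIAL_POCKET:
            return occupancy_pocket(c, *self.K)
        return occupancy_two_site(c, *self.K)

    def conductivity_factor(self, c):
        """Occupancy-weighted conductivity factor sum_k x_k(c) * h_k."""
        occ = self.occupancy(c)
        return occ.x0 * self.h[0] + occ.x1 * self.h[1] + occ.x2 * self.h[2]


def population_conductivity_factor(p: PopulationParams, c):
    """Dimensionless population conductivity factor G_j / g(U) at concentration c."""
    return p.conductivity_factor(c)


@dataclass(frozen=True)
class RectificationParams:
    """Empirical inward-rectification conductance g(U) as a sum of logistics.

    g(U) = global_scale * prefactor * sum_i a_i / (1 + exp((U + u_i) / s_i))

    ``terms`` holds (amplitude a_i, half-voltage offset u_i in mV, slope
    s_i in mV).  The default reproduces the I_KAch control I-V shape in
    muS-like model units.  ``global_scale`` is a plain multiplier used e.g.
    to halve the conductance when matching individual-cell records.
    """

    terms: tuple[tuple[float, float, float], ...] = ((0.325, 80.0, 5.0),
                                                     (3.0, 150.0, 52.0))
    prefactor: float = 0.8
    global_scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "terms",
            tuple((float(a), float(u), float(s)) for a, u, s in self.terms))
        if any(s <= 0 for _, _, s in self.terms):
            raise ParameterError("rectification slopes must be positive")
        if self.prefactor <= 0 or self.global_scale <= 0:
            raise ParameterError("prefactor and global_scale must be positive")


DEFAULT_RECTIFICATION = RectificationParams()


def rectification_g(U, r: RectificationParams | None = None):
    """Rectification conductance g(U) (model units, muS-like) at voltage U (mV).

    Strictly positive and non-increasing in U for the default parameters.
    """
    if r is None:
        r = DEFAULT_RECTIFICATION
    u = np.asarray(U, dtype=float)
    total = np.zeros_like(u)
    with np.errstate(over="ignore"):  # exp overflow -> logistic term is 0
        for a, off, slope in r.terms:
            total = total + a / (1.0 + np.exp((u + off) / slope))
    out = r.global_scale * r.prefactor * total
    return float(out) if _is_scalar(U) else out


@dataclass(frozen=True)
class ModelParams:
    """Full population model: fractions, per-population parameters, g(U), U_K.

    ``populations`` is an ordered sequence of ``(f_j, PopulationParams)``;
    the fractions must be non-negative and sum to 1.  ``overrides``
    optionally maps an exact voltage (mV) to sparse replacements of
    individual h factors (keys like ``"h_2_1"``), the mechanism used to
    express a mildly voltage-dependent drug effect; no interpolation is
    performed between listed voltages.
    """

    populations: tuple[tuple[float, PopulationParams], ...]
    rectification: RectificationParams = DEFAULT_RECTIFICATION
    U_K: float = -85.0
    overrides: Mapping[float, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pops = tuple((float(f), p) for f, p in self.populations)
        object.__setattr__(self, "populations", pops)
        if len(pops) < 1:
            raise ParameterError("at least one channel population is required")
        fracs = np.array([f for f, _ in pops])
        if np.any(fracs < 0):
            raise ParameterError("population fractions must be non-negative")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ParameterError(
                f"population fractions must sum to 1 (got {fracs.sum():.12g})")
        if not np.isfinite(self.U_K):
            raise ParameterError("U_K must be finite")
        for volt, mapping in dict(self.overrides).items():
            for name in mapping:
                self._parse_h_name(name)

    # -- accessors ---------------------------------------------------------

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def fractions(self) -> tuple[float, ...]:
        return tuple(f for f, _ in self.populations)

    @property
    def f1(self) -> float:
        return self.populations[0][0]

    @staticmethod
    def _parse_h_name(name: str) -> tuple[int, int]:
        m = _H_NAME.match(name)
        if not m:
            raise ParameterError(
                f"invalid conductivity factor name {name!r}; expected h_<k>_<j>")
        k, j = int(m.group(1)), int(m.group(2))
        return k, j

    # -- derived models ----------------------------------------------------

    def with_h(self, name: str, value: float) -> "ModelParams":
        """Return a copy with a single conductivity factor h_<k>_<j> replaced."""
        k, j = self._parse_h_name(name)
        if j > self.n_populations:
            raise ParameterError(f"{name} refers to population {j}, model has "
                                 f"{self.n_populations}")
        f, pop = self.populations[j - 1]
        h = list(pop.h)
        h[k] = float(value)
        pops = list(self.populations)
        pops[j - 1] = (f, replace(pop, h=tuple(h)))
        return replace(self, populations=tuple(pops))

    def with_population(self, j: int, f: float | None = None,
                        pop: PopulationParams | None = None) -> "ModelParams":
        """Return a copy with population ``j`` (1-based) replaced."""
        f_old, pop_old = self.populations[j - 1]
        pops = list(self.populations)
        pops[j - 1] = (f_old if f is None else float(f),
                       pop_old if pop is None else pop)
        return replace(self, populations=tuple(pops))

    def with_fraction(self, f1: float) -> "ModelParams":
        """Return a copy with fractions set to (f1, 1 - f1); two populations only."""
        if self.n_populations != 2:
            raise ParameterError("with_fraction requires exactly two populations")
        if not 0.0 <= f1 <= 1.0:
            raise ParameterError(f"f_1 must lie in [0, 1], got {f1}")
        pops = ((float(f1), self.populations[0][1]),
                (1.0 - float(f1), self.populations[1][1]))
        return replace(self, populations=pops)

    def redistributed(self, delta_f: float) -> "ModelParams":
        """Shift a fraction ``delta_f`` of channels from population 2 to 1.

        The model's mechanism for cell-to-cell variability: f1 -> f1 + df,
        f2 -> f2 - df.  Raises if either fraction would leave [0, 1].
        """
        if delta_f == 0.0:
            return self
        new_f1 = self.f1 + float(delta_f)
        if not 0.0 <= new_f1 <= 1.0:
            raise ParameterError(
                f"redistribution delta_f={delta_f} puts f_1={new_f1:.4g} outside [0, 1]")
        return self.with_fraction(new_f1)

    def at_voltage(self, U: float) -> "ModelParams":
        """Apply any h overrides registered for voltage ``U`` (exact lookup)."""
        if not self.overrides:
            return self
        mapping = None
        for volt, repl in dict(self.overrides).items():
            if float(volt) == float(U):
                mapping = repl
                break
        if mapping is None:
            return self
        m = replace(self, overrides={})
        for name, value in mapping.items():
            m = m.with_h(name, value)
        return m

    # -- model algebra -----------------------------------------------------

    def conductivity_factor(self, c):
        """Fraction-weighted total conductivity factor sum_j f_j * (G_j/g)."""
        total = 0.0
        for f, pop in self.populations:
            total = total + f * pop.conductivity_factor(c)
        return total

    def baseline_factor(self) -> float:
        """Drug-free conductivity factor sum_j f_j * h_0_j."""
        return float(sum(f * pop.h[0] for f, pop in self.populations))


def steady_state_current(m: ModelParams, U, c):
    """Steady-state current I(U, c) = [sum_j f_j G_j(c)/g] * g(U) * (U - U_K).

    Vanishes exactly at U = U_K.  Any h override registered for voltage U is
    applied before evaluation.  ``U`` may be a scalar or an array (per-voltage
    overrides are honoured in both cases).
    """
    if _is_scalar(U):
        m_u = m.at_voltage(float(U))
        g = rectification_g(U, m_u.rectification)
        return m_u.conductivity_factor(c) * g * (float(U) - m_u.U_K)
    u = np.asarray(U, dtype=float)
    if m.overrides:
        return np.array([steady_state_current(m, float(ui), c) for ui in u])
    g = rectification_g(u, m.rectification)
    return m.conductivity_factor(c) * g * (u - m.U_K)


def relative_effect(m: ModelParams, c, U: float | None = None):
    """Relative drug effect F(c) = I(U, c) / I(U, 0).

    With the separable conductance G_k_j = h_k_j * g(U), the rectification
    and driving force cancel, so F is voltage independent unless an h
    override applies at ``U``:

        F(c) = sum_j f_j * factor_j(c) / sum_j f_j * h_0_j

    F(0) == 1 exactly; F > 1 means activation, F < 1 inhibition.
    """
    m_u = m if U is None else m.at_voltage(float(U))
    denom = m_u.baseline_factor()
    if denom <= 0.0:
        raise DegenerateModelError(
            "drug-free baseline conductivity is zero; relative effect undefined")
    return m_u.conductivity_factor(c) / denom


def concentration_response(m: ModelParams, c_grid: Sequence[float],
                           U: float | None = None) -> pd.DataFrame:
    """Concentration-response table: F(c) plus per-population constituents.

    Returns a DataFrame with columns ``c``, ``F``, ``I_total`` and one
    ``I_pop<j>`` per population.  When ``U`` is given the constituents are
    currents f_j * factor_j(c) * g(U) * (U - U_K); otherwise they are the
    dimensionless current factors f_j * factor_j(c).  Constituents sum to
    ``I_total`` in either case.
    """
    c = _check_conc(c_grid)
    m_u = m if U is None else m.at_voltage(float(U))
    scale = 1.0
    if U is not None:
        scale = rectification_g(U, m_u.rectification) * (float(U) - m_u.U_K)
    data = {"c": c, "F": relative_effect(m_u, c)}
    parts = []
    for idx, (f, pop) in enumerate(m_u.populations, start=1):
        parts.append(f * pop.conductivity_factor(c) * scale)
    data["I_total"] = np.sum(parts, axis=0)
    for idx, part in enumerate(parts, start=1):
        data[f"I_pop{idx}"] = part
    return pd.DataFrame(data)


def iv_curve(m: ModelParams, U_grid: Sequence[float], c: float,
             delta_f: float = 0.0) -> pd.DataFrame:
    """Current-voltage curves in control (c=0) and under drug, after a
    redistribution ``delta_f`` of channels between populations 1 and 2.

    Returns a DataFrame with columns ``U``, ``I_control``, ``I_drug``; both
    curves share the redistributed fractions and vanish at U_K.
    """
    m_cell = m.redistributed(delta_f)
    u = np.asarray(U_grid, dtype=float)
    return pd.DataFrame({
        "U": u,
        "I_control": steady_state_current(m_cell, u, 0.0),
        "I_drug": steady_state_current(m_cell, u, float(c)),
    })
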