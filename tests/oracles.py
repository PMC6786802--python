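"""Independent reference computations used to check the implementation.

These deliberately avoid the closed forms and code paths of the package:
occupancies are obtained by solving the linear detailed-balance system of
the binding scheme numerically, regressions by explicit normal equations,
and transients by adaptive Runge-Kutta integration of the relaxation ODE.
"""

import numpy as np
from scipy.integrate import solve_ivp


def balance_occupancy_pocket(c: float, K1: float, K2: float) -> np.ndarray:
    """Solve the sequential-pocket equilibrium as a linear system.

    Detailed balance between successive states: c*x0 = K1*x1 and
    c*x1 = K2*x2, plus normalisation.
    """
    A = np.array([
        [c, -K1, 0.0],
        [0.0, c, -K2],
        [1.0, 1.0, 1.0],
    ])
    return np.linalg.solve(A, np.array([0.0, 0.0, 1.0]))


def balance_occupancy_two_site(c: float, K3: float, K4: float) -> np.ndarray:
    """Solve the independent-two-site equilibrium as a linear system.

    Balance of each site against the empty state: c*x0 = K3*x1 and
    c*x0 = K4*x2 (x2 = 0 when K4 is infinite), plus normalisation.
    """
    if np.isinf(K4):
        A = np.array([
            [c, -K3, 0.0],
            [0.0, 0.0, 1.0],
            [1.0, 1.0, 1.0],
        ])
    else:
        A = np.array([
            [c, -K3, 0.0],
            [c, 0.0, -K4],
            [1.0, 1.0, 1.0],
        ])
    return np.linalg.solve(A, np.array([0.0, 0.0, 1.0]))


def ols_normal_equations(x: np.ndarray, y: np.ndarray):
    """Slope/intercept from the explicit normal equations X'X b = X'y."""
    X = np.column_stack([x, np.ones_like(x)])
    slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
    return slope, intercept


def integrate_relaxation(G0, G_ss, taus, t_eval, rtol=1e-10, atol=1e-12):
    """Numerically integrate dG_j/dt = (G_ss_j - G_j)/tau_j."""

    def rhs(_t, G):
        return (np.asarray(G_ss) - G) / np.asarray(taus)

    sol = solve_ivp(rhs, (t_eval[0], t_eval[-1]), np.asarray(G0, float),
                    t_eval=t_eval, rtol=rtol, atol=atol, method="RK45")
    assert sol.success
    return sol.y.T
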