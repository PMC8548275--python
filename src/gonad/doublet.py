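"""Two-cell (two-balloon) instability model.

Dynamics of the relative volume difference nu = (V2 - V1) / (V1 + V2) of
two pressure-coupled germ cells sharing a rachis: material uptake and a
cell-to-rachis pressure head stabilise the symmetric state, while the
balloon-like dependence of internal pressure on size (Delta P ~ T nu / R)
destabilises it.  Provides the vector field, its effective potential,
linear stability of nu = 0, trajectory integration with absorbing
boundaries at |nu| = 1, and the fixed-point branches along the gonad.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

__all__ = [
    "DoubletParams",
    "lambda_basal",
    "delta_P",
    "dnu_dt",
    "effective_potential",
    "linear_growth_rate",
    "integrate_doublet",
    "find_fixed_points",
    "bifurcation_along_gonad",
    "bifurcation_point",
]


@dataclass
class DoubletParams:
    """Parameters of the doublet equation of motion.

    S             : material uptake, fl/min
    A_c           : combined cross-sectional area of the two cells, um^2
    alpha0        : bridge hydraulic conductivity, fl/min per pressure unit
    Pc_minus_Pr   : mean cell-to-rachis pressure difference
    T             : effective cortical tension (pressure * um)
    R             : gonad radius, um
    area_exponent : p in basal area ~ V^p (2/3 for sphere-like scaling)
    """

    S: float = 0.0
    A_c: float = 100.0
    alpha0: float = 1.0
    Pc_minus_Pr: float = 0.0
    T: float = 1.0
    R: float = 10.0
    area_exponent: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.A_c <= 0:
            raise ValueError("A_c must be positive")
        if self.alpha0 < 0:
            raise ValueError("alpha0 must be non-negative")
        if self.R <= 0:
            raise ValueError("R must be positive")


def lambda_basal(nu, p: float = 2.0 / 3.0):
    """Relative basal-area difference of the two cells.

    With basal area proportional to V^p:
    lambda(nu) = ((1+nu)^p - (1-nu)^p) / ((1+nu)^p + (1-nu)^p).
    Odd in nu; lambda(0) = 0, lambda(+-1) = +-1, slope p at the origin.
    """
    nu = np.asarray(nu, dtype=float)
    up = np.power(1.0 + nu, p)
    dn = np.power(1.0 - nu, p)
    return (up - dn) / (up + dn)


def delta_P(nu, params: DoubletParams):
    """Cell-to-cell pressure difference, linearised balloon law T nu / R."""
    return params.T * np.asarray(nu, dtype=float) / params.R


def dnu_dt(nu, params: DoubletParams):
    """Equation of motion for the relative volume difference (per minute).

    Three terms: uptake (stabilising for S > 0), cell-to-rachis exchange
    (stabilising for Pc > Pr), and the balloon pressure difference
    (destabilising for T > 0).
    """
    nu = np.asarray(nu, dtype=float)
    p = params.area_exponent
    term_uptake = -params.S / params.A_c * (lambda_basal(nu, p) + nu)
    term_exchange = (
        -params.alpha0 * params.Pc_minus_Pr / (2.0 * params.A_c) * nu * (1.0 - nu) * (1.0 + nu)
    )
    term_balloon = (
        params.alpha0 * delta_P(nu, params) / (8.0 * params.A_c) * (1.0 + 6.0 * nu**2 + nu**4)
    )
    return term_uptake + term_exchange + term_balloon


def linear_growth_rate(params: DoubletParams) -> float:
    """Analytic growth rate sigma of perturbations around nu = 0.

    sigma = [alpha0 T / (8 R) - S (1 + p) - alpha0 (Pc - Pr) / 2] / A_c;
    sigma < 0 means the symmetric state is stable.
    """
    p = params.area_exponent
    return (
        params.alpha0 * params.T / (8.0 * params.R)
        - params.S * (1.0 + p)
        - params.alpha0 * params.Pc_minus_Pr / 2.0
    ) / params.A_c


def effective_potential(
    params: DoubletParams,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Effective potential W with dnu/dt = -dW/dnu, W(0) = 0.

    Each grid value is an adaptive quadrature of the vector field from 0.
    Returns a frame with nu, W and W_norm (W scaled by max |W|, the shape
    used for display; scaling does not alter stability classification).
    """
    if grid is None:
        grid = np.linspace(-1.0, 1.0, 201)
    grid = np.asarray(grid, dtype=float)
    f = lambda s: float(dnu_dt(s, params))
    W = np.empty_like(grid)
    for i, nu in enumerate(grid):
        val, _ = quad(f, 0.0, nu, limit=200)
        W[i] = -val
    scale = np.abs(W).max()
    W_norm = W / scale if scale > 0 else W.copy()
    return pd.DataFrame({"nu": grid, "W": W, "W_norm": W_norm})


def integrate_doublet(
    nu0: float,
    params: DoubletParams,
    t_span: tuple[float, float],
    max_step: float | None = None,
    boundary: float = 1.0 - 1e-9,
) -> pd.DataFrame:
    """Integrate the doublet ODE from nu0 over t_span (minutes).

    Integration stops at the absorbing boundaries |nu| = 1 (the smaller
    cell has lost its cytoplasm); the returned frame carries a
    ``coarsened`` flag in ``attrs``.
    """
    if not -1.0 <= nu0 <= 1.0:
        raise ValueError("nu0 must lie in [-1, 1]")

    def rhs(t, y):
        return [float(dnu_dt(np.clip(y[0], -1.0, 1.0), params))]

    def hit_boundary(t, y):
        return abs(y[0]) - boundary

    hit_boundary.terminal = True
    kw = {"max_step": max_step} if max_step else {}
    sol = solve_ivp(
        rhs, t_span, [nu0], method="LSODA", events=hit_boundary,
        dense_output=False, rtol=1e-8, atol=1e-10, **kw,
    )
    nu = np.clip(sol.y[0], -1.0, 1.0)
    out = pd.DataFrame({"t": sol.t, "nu": nu})
    out.attrs["coarsened"] = bool(sol.t_events[0].size)
    out.attrs["end_state"] = float(nu[-1])
    return out


def find_fixed_points(params: DoubletParams, n_scan: int = 2001) -> pd.DataFrame:
    """All fixed points of the doublet flow in [-1, 1] with stability.

    Interior roots come from a sign-change scan refined by bisection
    (brentq); the boundaries nu = +-1 are absorbing attractors whenever the
    flow points into them, and are reported as stable fixed points then.
    """
    nus = np.linspace(-1.0, 1.0, n_scan)
    f = dnu_dt(nus, params)
    roots: list[float] = []
    for i in range(n_scan - 1):
        if f[i] == 0.0 and abs(nus[i]) < 1.0:
            roots.append(float(nus[i]))
        elif f[i] * f[i + 1] < 0:
            roots.append(float(brentq(lambda s: float(dnu_dt(s, params)), nus[i], nus[i + 1])))
    if f[-1] == 0.0:
        roots.append(float(nus[-1]))
    # dedupe
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or abs(r - uniq[-1]) > 1e-8:
            uniq.append(r)

    eps = 1e-6
    rows = []
    for r in uniq:
        if abs(r) >= 1.0 - 1e-12:
            continue  # boundaries handled below
        df = (float(dnu_dt(min(r + eps, 1.0), params)) - float(dnu_dt(max(r - eps, -1.0), params))) / (2 * eps)
        rows.append({"nu": r, "stable": df < 0})
    # absorbing boundaries
    if float(dnu_dt(1.0 - 1e-9, params)) > 0:
        rows.append({"nu": 1.0, "stable": True})
    elif any(abs(r - 1.0) < 1e-8 for r in uniq):
        rows.append({"nu": 1.0, "stable": False})
    if float(dnu_dt(-1.0 + 1e-9, params)) < 0:
        rows.append({"nu": -1.0, "stable": True})
    elif any(abs(r + 1.0) < 1e-8 for r in uniq):
        rows.append({"nu": -1.0, "stable": False})
    return pd.DataFrame(rows).sort_values("nu", ignore_index=True)


def bifurcation_along_gonad(
    model_solution,
    template: DoubletParams,
    uptake_scale: float = 1.0,
    pressure_scale: float = 1.0,
) -> pd.DataFrame:
    """Fixed-point branches of the doublet versus position along the gonad.

    For every grid point of a hydromodel solution, S(x) and Pc(x) - Pr(x)
    (optionally rescaled into doublet units) are inserted into the
    template parameters and the fixed points are classified.  Returns rows
    (x, nu, stable, sigma) — sigma being the linear growth rate of the
    symmetric state at that position.
    """
    from dataclasses import replace

    prof = model_solution.profile
    rows = []
    for _, rec in prof.iterrows():
        p = replace(
            template,
            S=float(rec["S"]) * uptake_scale,
            Pc_minus_Pr=float(rec["Pc"] - rec["Pr"]) * pressure_scale,
        )
        sigma = linear_growth_rate(p)
        fps = find_fixed_points(p)
        for _, fp in fps.iterrows():
            rows.append(
                {"x": float(rec["x"]), "nu": fp["nu"], "stable": bool(fp["stable"]), "sigma": sigma}
            )
    return pd.DataFrame(rows)


def bifurcation_point(branches: pd.DataFrame) -> float:
    """Position where the symmetric state loses stability (sigma crosses 0)."""
    per_x = branches.drop_duplicates("x").sort_values("x")
    x = per_x["x"].to_numpy()
    sig = per_x["sigma"].to_numpy()
    sign = np.sign(sig)
    idx = np.nonzero(np.diff(sign) > 0)[0]
    if idx.size == 0:
        return float("nan")
    i = idx[0]
    if sig[i + 1] == sig[i]:
        return float(x[i])
    return float(x[i] - sig[i] * (x[i + 1] - x[i]) / (sig[i + 1] - sig[i]))
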