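"""Deterministic dynamics of the full five-species binding model.

The mass-action ODE system for the scheme
``R + L <=> RL* <=> RL <=> C`` is::

    d[R]/dt   = d[L]/dt = -d+ [R][L] + d- [RL*]
    d[RL*]/dt = d+ [R][L] - (d- + e+) [RL*] + e- [RL]
    d[RL]/dt  = e+ [RL*] - (e- + k+) [RL] + k- [C]
    d[C]/dt   = k+ [RL] - k- [C]

Receptor and ligand totals are conserved along every trajectory.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import FundamentalConstants, SpeciesState, Trajectory

__all__ = ["rate_equations", "simulate", "equilibrium"]


def _rhs(params: FundamentalConstants, y: np.ndarray) -> np.ndarray:
    R, L, RLs, RL, C = y
    diff_net = params.d_plus * R * L - params.d_minus * RLs
    rot_net = params.e_plus * RLs - params.e_minus * RL
    bind_net = params.k_plus * RL - params.k_minus * C
    return np.array([-diff_net, -diff_net, diff_net - rot_net, rot_net - bind_net, bind_net])


def rate_equations(params: FundamentalConstants, state: SpeciesState) -> dict[str, float]:
    """Per-species time derivatives of the full model at ``state``.

    Returns a mapping species name -> d[species]/dt.  Negative
    concentrations are rejected (the dataclass already enforces this, but a
    raw state built elsewhere may bypass it).
    """
    y = state.as_array()
    if np.any(y < 0):
        raise ValueError("concentrations must be non-negative")
    d = _rhs(params, y)
    return {"R": d[0], "L": d[1], "RL_star": d[2], "RL": d[3], "C": d[4]}


def simulate(
    params: FundamentalConstants,
    initial: SpeciesState,
    times: np.ndarray,
    rtol: float = 1e-10,
    atol: float | None = None,
) -> Trajectory:
    """Integrate the five-species ODE system over a strictly increasing grid.

    A stiff-capable implicit method (LSODA) is used because
    timescale-separated regimes -- the regimes in which the effective
    models are derived -- are stiff by construction.  The default absolute
    tolerance is 1e-12 x the larger conserved total.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D grid with >= 2 points")
    y0 = initial.as_array()
    scale = max(initial.R_total, initial.L_total, 1e-300)
    if atol is None:
        atol = 1e-12 * scale
    t0 = times[0]
    sol = solve_ivp(
        lambda t, y: _rhs(params, y),
        (t0, times[-1]),
        y0,
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"stiff integration failed: {sol.message}; params={params.as_dict()}, "
            f"dimension={params.dimension}, t_span=({t0}, {times[-1]})"
        )
    return Trajectory(times=sol.t, y=sol.y.T, params=params)


def _sigma(params: FundamentalConstants) -> float:
    # total complexed mass per unit of C: C + RL + RL* = sigma * C
    K_A, E = params.K_A, params.E
    return 1.0 + 1.0 / K_A + 1.0 / (K_A * E)


def equilibrium(
    params: FundamentalConstants, R_total: float, L_total: float
) -> SpeciesState:
    """Closed-form equilibrium of the full model.

    Uses the three detailed-balance relations ``RL*/( [R][L] ) = K_D``,
    ``RL/RL* = E``, ``C/RL = K_A`` plus the two conservation laws, which
    reduce the problem to a quadratic in ``C``; the unique root with all
    species non-negative is returned (bisection fallback for robustness).

    All three off-rates must be positive, otherwise the intermediate
    species have no finite equilibrium.
    """
    if R_total < 0 or L_total < 0:
        raise ValueError("totals must be >= 0")
    for name in ("d_minus", "e_minus", "k_minus"):
        if getattr(params, name) <= 0:
            raise ValueError(f"equilibrium requires {name} > 0")
    if R_total == 0 or L_total == 0 or params.d_plus == 0:
        return SpeciesState(R=R_total, L=L_total, RL_star=0.0, RL=0.0, C=0.0)
    if params.k_plus == 0 and params.e_plus == 0:
        return SpeciesState(R=R_total, L=L_total, RL_star=0.0, RL=0.0, C=0.0)
    if params.k_plus == 0 or params.e_plus == 0:
        # no productive path to C: two-step (or one-step) equilibrium in RL*
        return _equilibrium_no_binding(params, R_total, L_total)

    K = params.K_D * params.E * params.K_A  # overall C / ([R][L])
    sig = _sigma(params)

    # K*(R_t - sig*C)(L_t - sig*C) = C
    a = K * sig * sig
    b = -(K * sig * (R_total + L_total) + 1.0)
    c = K * R_total * L_total
    disc = b * b - 4 * a * c
    C = 2 * c / (-b + np.sqrt(max(disc, 0.0)))  # numerically stable smaller root
    upper = min(R_total, L_total) / sig

    def f(x: float) -> float:
        return K * (R_total - sig * x) * (L_total - sig * x) - x

    if not (0.0 <= C <= upper) or abs(f(C)) > 1e-9 * max(C, upper):
        C = brentq(f, 0.0, upper, xtol=1e-300, rtol=8.9e-16)
    RL = C / params.K_A
    RLs = RL / params.E
    return SpeciesState(
        R=max(R_total - sig * C, 0.0),
        L=max(L_total - sig * C, 0.0),
        RL_star=RLs,
        RL=RL,
        C=C,
    )


def _equilibrium_no_binding(
    params: FundamentalConstants, R_total: float, L_total: float
) -> SpeciesState:
    # binding step frozen forward (k+ = 0): C = 0 at equilibrium, two-step
    # scheme R + L <=> RL* <=> RL with combined affinity K_D(1+E) per RL*.
    K = params.K_D
    E = params.E
    sig = 1.0 + E  # RL* + RL = sig * RL*

    def f(x: float) -> float:  # x = RL*
        return K * (R_total - sig * x) * (L_total - sig * x) - x

    upper = min(R_total, L_total) / sig
    x = brentq(f, 0.0, upper, xtol=1e-300, rtol=8.9e-16) if upper > 0 else 0.0
    return SpeciesState(
        R=R_total - sig * x, L=L_total - sig * x, RL_star=x, RL=E * x, C=0.0
    )
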