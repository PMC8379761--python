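"""Nondimensionalization and singular-perturbation reduction.

Time is rescaled by the free-ACh decay rate (tau = t * k_decay), free ACh by
its site-1 equilibrium constant (x_A = [A]/K_A1), and every receptor state
by the total receptor concentration.  Eleven dimensionless groups remain:
normalized rates kappa_*, affinities lambda_A1 = R_total/K_A1 and
lambda_A2 = R_total/K_A2, the site-selectivity ratios mu_A = K_A1/K_A2 and
mu_D = K_D1/K_D2, and the scaled drug concentration delta = [D]/K_D1.

Blocker exchange is slow on the synaptic time scale (kappa_D1, kappa_D2 of
order 1e-3 for clinically used blockers versus kappa_A of order 1).  In the
singular-perturbation limit kappa_D -> 0 the drug-bound pool is frozen:
x_DRD, x_ORD + x_ARD and x_DRO + x_DRA become constants of motion fixed by
the pre-event equilibrium occupancies, and the dynamics collapse to seven
states.  In that limit the blocker enters only through mu_D and delta, so
mu_D alone characterizes a slowly dissociating blocker.

The reduced right-hand side here is the exact kappa_D -> 0 limit of the
full dimensionless system under the substitution x_ORD = O_ORD - x_ARD,
x_DRO = O_DRO - x_DRA, with the free-receptor fraction reconstructed from
full receptor conservation (including the open state); it is verified
against the dimensional model rather than transcribed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import (
    STATE_NAMES,
    OccupancyFractions,
    PeakNotBracketedError,
    ReceptorState,
    SolverError,
    occupancy_fractions,
)
from .parameters import KineticParameters

__all__ = [
    "DimensionlessParameters",
    "FULL_X_NAMES",
    "REDUCED_X_NAMES",
    "DimensionlessTrajectory",
    "nondimensionalize",
    "scale_state",
    "unscale_state",
    "rhs_dimensionless_full",
    "rhs_reduced",
    "simulate_reduced",
    "simulate_dimensionless_full",
    "peak_x_ara_star",
]

#: Dimensionless state components, mirroring the dimensional storage order.
FULL_X_NAMES = (
    "x_A",
    "x_ARA_star",
    "x_ARA",
    "x_DRD",
    "x_ARD",
    "x_DRA",
    "x_ARO",
    "x_ORA",
    "x_DRO",
    "x_ORD",
)

#: Dynamical components of the reduced (kappa_D -> 0) model; x_DRD is frozen
#: and x_ORD, x_DRO are reconstructed from the frozen occupancies.
REDUCED_X_NAMES = (
    "x_A",
    "x_ARA_star",
    "x_ARA",
    "x_ARO",
    "x_ORA",
    "x_ARD",
    "x_DRA",
)

DEFAULT_TAU_MAX = 60.0  # k_decay * 5 ms at the base-case decay rate


@dataclass(frozen=True)
class DimensionlessParameters:
    """The eleven dimensionless groups of the competition model."""

    kappa_A1: float
    kappa_A2: float
    kappa_D1: float
    kappa_D2: float
    kappa_open: float
    kappa_close: float
    lambda_A1: float
    lambda_A2: float
    mu_A: float
    mu_D: float
    delta: float

    def __post_init__(self) -> None:
        strict = (
            "kappa_A1",
            "kappa_A2",
            "kappa_open",
            "kappa_close",
            "lambda_A1",
            "lambda_A2",
            "mu_A",
            "mu_D",
        )
        for name in strict:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("kappa_D1", "kappa_D2", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def evolve(self, **changes: float) -> "DimensionlessParameters":
        return replace(self, **changes)


def nondimensionalize(
    params: KineticParameters, drug: float
) -> DimensionlessParameters:
    """Compute the dimensionless groups from dimensional constants.

    Given k_decay, K_A1, R_total and K_D1 the map is invertible, so no
    information relevant to the scaled dynamics is lost.
    """
    if drug < 0:
        raise ValueError("drug concentration must be >= 0")
    kd = params.k_decay
    return DimensionlessParameters(
        kappa_A1=params.k_dissA1 / kd,
        kappa_A2=params.k_dissA2 / kd,
        kappa_D1=params.k_dissD1 / kd,
        kappa_D2=params.k_dissD2 / kd,
        kappa_open=params.k_open / kd,
        kappa_close=params.k_close / kd,
        lambda_A1=params.R_total / params.K_A1,
        lambda_A2=params.R_total / params.K_A2,
        mu_A=params.K_A1 / params.K_A2,
        mu_D=params.mu_D,
        delta=drug / params.K_D1,
    )


def scale_state(state: ReceptorState, params: KineticParameters) -> np.ndarray:
    """Map a dimensional state to the x-vector (FULL_X_NAMES order)."""
    y = state.to_array()
    x = y / params.R_total
    x[0] = y[0] / params.K_A1
    return x


def unscale_state(x: np.ndarray, params: KineticParameters) -> ReceptorState:
    """Inverse of :func:`scale_state`; exact bijection."""
    x = np.asarray(x, dtype=float)
    y = x * params.R_total
    y[0] = x[0] * params.K_A1
    return ReceptorState.from_array(y, params.R_total)


def rhs_dimensionless_full(
    x: np.ndarray, dp: DimensionlessParameters
) -> np.ndarray:
    """d/dtau of the full ten-component dimensionless system.

    The free-receptor fraction x_ORO is reconstructed from conservation
    (the nine stored receptor fractions sum with it to 1).
    """
    xA, xARAs, xARA, xDRD, xARD, xDRA, xARO, xORA, xDRO, xORD = np.asarray(
        x, dtype=float
    )
    p = dp
    xORO = 1.0 - (
        xARAs + xARA + xDRD + xARD + xDRA + xARO + xORA + xDRO + xORD
    )

    dxA = (
        -xA
        + p.kappa_A1
        * p.lambda_A1
        * ((xARA + xARD + xARO) - xA * (xORA + xORD + xORO))
        + p.kappa_A2
        * (
            p.lambda_A1 * (xARA + xDRA + xORA)
            - p.lambda_A2 * xA * (xARO + xDRO + xORO)
        )
    )
    dxARAs = -p.kappa_close * xARAs + p.kappa_open * xARA
    dxARA = (
        p.kappa_A1 * (xORA * xA - xARA)
        + p.kappa_A2 * (p.mu_A * xARO * xA - xARA)
        + p.kappa_close * xARAs
        - p.kappa_open * xARA
    )
    dxDRD = p.kappa_D1 * (xORD * p.delta - xDRD) + p.kappa_D2 * (
        p.mu_D * xDRO * p.delta - xDRD
    )
    dxARD = p.kappa_A1 * (xORD * xA - xARD) + p.kappa_D2 * (
        p.mu_D * xARO * p.delta - xARD
    )
    dxDRA = p.kappa_D1 * (xORA * p.delta - xDRA) + p.kappa_A2 * (
        p.mu_A * xDRO * xA - xDRA
    )
    dxARO = (
        p.kappa_A1 * (xORO * xA - xARO)
        + p.kappa_A2 * (xARA - p.mu_A * xARO * xA)
        + p.kappa_D2 * (xARD - p.mu_D * xARO * p.delta)
    )
    dxORA = (
        p.kappa_A2 * (p.mu_A * xORO * xA - xORA)
        + p.kappa_A1 * (xARA - xORA * xA)
        + p.kappa_D1 * (xDRA - xORA * p.delta)
    )
    dxDRO = (
        p.kappa_D1 * (xORO * p.delta - xDRO)
        + p.kappa_A2 * (xDRA - p.mu_A * xDRO * xA)
        + p.kappa_D2 * (xDRD - p.mu_D * xDRO * p.delta)
    )
    dxORD = (
        p.kappa_D2 * (p.mu_D * xORO * p.delta - xORD)
        + p.kappa_A1 * (xARD - xORD * xA)
        + p.kappa_D1 * (xDRD - xORD * p.delta)
    )
    return np.array(
        [
            dxA,
            dxARAs,
            dxARA,
            dxDRD,
            dxARD,
            dxDRA,
            dxARO,
            dxORA,
            dxDRO,
            dxORD,
        ]
    )


def rhs_reduced(
    x: np.ndarray,
    dp: DimensionlessParameters,
    occ: OccupancyFractions,
) -> np.ndarray:
    """d/dtau of the seven-state reduced model (REDUCED_X_NAMES order).

    ``occ`` must be the occupancies at (dp.delta, dp.mu_D); they freeze the
    drug-bound pool: x_DRD = O_DRD, x_ORD = O_ORD - x_ARD and
    x_DRO = O_DRO - x_DRA for all tau.
    """
    ref = occupancy_fractions(dp.delta, dp.mu_D)
    if not (
        np.isclose(ref.O_ORD, occ.O_ORD, rtol=1e-9, atol=1e-12)
        and np.isclose(ref.O_DRO, occ.O_DRO, rtol=1e-9, atol=1e-12)
        and np.isclose(ref.O_total, occ.O_total, rtol=1e-9, atol=1e-12)
    ):
        raise ValueError(
            "occupancies inconsistent with dp.delta and dp.mu_D"
        )
    xA, xARAs, xARA, xARO, xORA, xARD, xDRA = np.asarray(x, dtype=float)
    p = dp
    xORD = occ.O_ORD - xARD
    xDRO = occ.O_DRO - xDRA
    # free receptor by full conservation, open state included
    xORO = 1.0 - xARAs - xARA - xARO - xORA - occ.O_total

    dxA = (
        -xA
        + p.kappa_A1
        * p.lambda_A1
        * ((xARA + xARD + xARO) - xA * (xORA + xORD + xORO))
        + p.kappa_A2
        * (
            p.lambda_A1 * (xARA + xDRA + xORA)
            - p.lambda_A2 * xA * (xARO + xDRO + xORO)
        )
    )
    dxARAs = -p.kappa_close * xARAs + p.kappa_open * xARA
    dxARA = (
        p.kappa_A1 * (xORA * xA - xARA)
        + p.kappa_A2 * (p.mu_A * xARO * xA - xARA)
        + p.kappa_close * xARAs
        - p.kappa_open * xARA
    )
    dxARO = p.kappa_A1 * (xORO * xA - xARO) + p.kappa_A2 * (
        xARA - p.mu_A * xARO * xA
    )
    dxORA = p.kappa_A2 * (p.mu_A * xORO * xA - xORA) + p.kappa_A1 * (
        xARA - xORA * xA
    )
    dxARD = p.kappa_A1 * (xORD * xA - xARD)
    dxDRA = p.kappa_A2 * (p.mu_A * xDRO * xA - xDRA)
    return np.array([dxA, dxARAs, dxARA, dxARO, dxORA, dxARD, dxDRA])


@dataclass
class DimensionlessTrajectory:
    """Time course in tau of either dimensionless variant.

    ``names`` is FULL_X_NAMES or REDUCED_X_NAMES depending on the model.
    """

    tau: np.ndarray
    states: np.ndarray
    names: tuple[str, ...]
    dp: DimensionlessParameters

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.names.index(name)]


def _integrate(
    fun, x0: np.ndarray, tau_max: float, rtol: float, atol: float, n: int
):
    sol = solve_ivp(
        fun,
        (0.0, tau_max),
        x0,
        method="LSODA",
        t_eval=np.linspace(0.0, tau_max, n),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(sol.message)
    return sol


def simulate_reduced(
    dp: DimensionlessParameters,
    x_A_init: float,
    tau_max: float = DEFAULT_TAU_MAX,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    n_points: int = 2001,
) -> DimensionlessTrajectory:
    """Integrate the reduced model from the pre-event equilibrium.

    The initial condition is x_A = x_A_init with x_ARD = x_DRA = 0 (no mixed
    ACh/blocker complexes before the event); the frozen occupancies follow
    from (dp.delta, dp.mu_D).
    """
    if tau_max <= 0:
        raise ValueError("tau_max must be > 0")
    occ = occupancy_fractions(dp.delta, dp.mu_D)
    x0 = np.zeros(len(REDUCED_X_NAMES))
    x0[0] = x_A_init
    sol = _integrate(
        lambda t, x: rhs_reduced(x, dp, occ), x0, tau_max, rtol, atol, n_points
    )
    return DimensionlessTrajectory(
        tau=sol.t, states=sol.y.T.copy(), names=REDUCED_X_NAMES, dp=dp
    )


def simulate_dimensionless_full(
    dp: DimensionlessParameters,
    x_A_init: float,
    tau_max: float = DEFAULT_TAU_MAX,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    n_points: int = 2001,
) -> DimensionlessTrajectory:
    """Integrate the full ten-component dimensionless system.

    Initial receptor fractions are the pre-event equilibrium occupancies
    (x_DRD = O_DRD, x_ORD = O_ORD, x_DRO = O_DRO, everything else 0) with
    x_A stepped to ``x_A_init`` at tau = 0.
    """
    if tau_max <= 0:
        raise ValueError("tau_max must be > 0")
    occ = occupancy_fractions(dp.delta, dp.mu_D)
    x0 = np.zeros(len(FULL_X_NAMES))
    x0[FULL_X_NAMES.index("x_A")] = x_A_init
    x0[FULL_X_NAMES.index("x_DRD")] = occ.O_DRD
    x0[FULL_X_NAMES.index("x_ORD")] = occ.O_ORD
    x0[FULL_X_NAMES.index("x_DRO")] = occ.O_DRO
    sol = _integrate(
        lambda t, x: rhs_dimensionless_full(x, dp),
        x0,
        tau_max,
        rtol,
        atol,
        n_points,
    )
    return DimensionlessTrajectory(
        tau=sol.t, states=sol.y.T.copy(), names=FULL_X_NAMES, dp=dp
    )


def peak_x_ara_star(traj: DimensionlessTrajectory) -> tuple[float, float]:
    """Peak open-state fraction and its tau, quadratically refined."""
    from .kinetics import _quadratic_refine  # shared refinement

    y = traj.column("x_ARA_star")
    i = int(np.argmax(y))
    if y[i] <= 0.0:
        raise PeakNotBracketedError("x_ARA_star trace has no positive peak")
    if i == y.size - 1:
        raise PeakNotBracketedError("x_ARA_star maximum at final tau")
    tau_peak, peak = _quadratic_refine(traj.tau, y, i)
    return peak, tau_peak
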