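"""Full dimensional kinetics of ACh/blocker competition at the AChR.

The state of the system is the free-ACh concentration plus nine
receptor–ligand complexes, named by three-letter symbols: the first and last
letters give the ligand bound at sites 1 and 2 (``A`` ACh, ``D`` blocker,
``O`` empty) and the middle letter is the receptor.  ``ARA*`` is the
diliganded open (conducting) state.  The free receptor ``ORO`` is never
integrated; it is reconstructed from receptor conservation, which makes
total receptor mass exact by construction.

A synaptic event is simulated as an instantaneous ACh bolus at t=0 on top of
the pre-event steady state of the blocker binding equilibrium, with the
blocker concentration clamped for the duration of the event.  The quantity
of pharmacological interest is the peak of the open-state trace ``[ARA*]``;
its ratio to the drug-free peak is the model's relative current.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import KineticParameters

__all__ = [
    "STATE_NAMES",
    "ReceptorState",
    "Trajectory",
    "EventSummary",
    "OccupancyFractions",
    "occupancy_fractions",
    "pre_release_steady_state",
    "rhs_full",
    "simulate_event",
    "peak_activation",
    "relative_current",
    "PeakNotBracketedError",
    "SolverError",
]

#: Integrated state components, in storage order.  ORO is derived.
STATE_NAMES = (
    "A",
    "ARA_star",
    "ARA",
    "DRD",
    "ARD",
    "DRA",
    "ARO",
    "ORA",
    "DRO",
    "ORD",
)

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-14  # M; state magnitudes span ~1e-14..1e-4 across the grid
DEFAULT_HORIZON = 5e-3  # s
DENSE_POINTS = 2001


class PeakNotBracketedError(RuntimeError):
    """The open-state maximum lies at the end of the integration window."""


class SolverError(RuntimeError):
    """ODE integration failed; carries the solver status message."""


@dataclass(frozen=True)
class OccupancyFractions:
    """Equilibrium blocker occupancies before ACh release.

    ``O_DRD`` both sites blocked, ``O_ORD`` site 2 only, ``O_DRO`` site 1
    only; ``O_total`` their sum, the fraction of receptors with at least one
    site occupied by the drug.
    """

    O_DRD: float
    O_ORD: float
    O_DRO: float
    O_total: float


def occupancy_fractions(delta: float, mu_D: float) -> OccupancyFractions:
    """Closed-form equilibrium occupancies of the two-site blocker binding.

    Parameters
    ----------
    delta : float
        Dimensionless drug concentration, [D]/K_D1.  Must be >= 0.
    mu_D : float
        Site selectivity K_D1/K_D2.  Must be > 0.

    With independent sites at equilibrium the joint occupancy factorises
    over sites, giving

        O_DRD = mu_D d^2 / ((1 + d)(1 + mu_D d))
        O_ORD = mu_D d   / ((1 + d)(1 + mu_D d))
        O_DRO = d        / ((1 + d)(1 + mu_D d))

    and O_total their sum; the free fraction is 1/((1+d)(1+mu_D d)).
    """
    if not np.isfinite(delta) or delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta!r}")
    if not np.isfinite(mu_D) or mu_D <= 0:
        raise ValueError(f"mu_D must be > 0, got {mu_D!r}")
    den = (1.0 + delta) * (1.0 + mu_D * delta)
    o_drd = mu_D * delta * delta / den
    o_ord = mu_D * delta / den
    o_dro = delta / den
    return OccupancyFractions(o_drd, o_ord, o_dro, o_drd + o_ord + o_dro)


@dataclass(frozen=True)
class ReceptorState:
    """One instantaneous state of the dimensional model (concentrations, M)."""

    A: float
    ARA_star: float
    ARA: float
    DRD: float
    ARD: float
    DRA: float
    ARO: float
    ORA: float
    DRO: float
    ORD: float
    R_total: float

    @property
    def ORO(self) -> float:
        """Free-receptor concentration by conservation of receptor mass."""
        return self.R_total - (
            self.ARA_star
            + self.ARA
            + self.DRD
            + self.ARD
            + self.DRA
            + self.ARO
            + self.ORA
            + self.DRO
            + self.ORD
        )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray, R_total: float) -> "ReceptorState":
        return cls(*(float(v) for v in y), R_total=R_total)


def pre_release_steady_state(
    params: KineticParameters, drug: float
) -> ReceptorState:
    """Steady state of blocker binding before the ACh release.

    Before the synaptic event there is no free ACh, so the only populated
    states are the free receptor and the three drug-bound complexes, whose
    fractions are the equilibrium occupancies at delta = drug/K_D1.
    """
    if drug < 0:
        raise ValueError(f"drug concentration must be >= 0, got {drug!r}")
    occ = occupancy_fractions(drug / params.K_D1, params.mu_D)
    r = params.R_total
    return ReceptorState(
        A=0.0,
        ARA_star=0.0,
        ARA=0.0,
        DRD=r * occ.O_DRD,
        ARD=0.0,
        DRA=0.0,
        ARO=0.0,
        ORA=0.0,
        DRO=r * occ.O_DRO,
        ORD=r * occ.O_ORD,
        R_total=r,
    )


def _rhs(y: np.ndarray, p: KineticParameters, D: float) -> np.ndarray:
    """Mass-action right-hand side on the raw state vector."""
    A, ARAs, ARA, DRD, ARD, DRA, ARO, ORA, DRO, ORD = y
    ORO = p.R_total - (ARAs + ARA + DRD + ARD + DRA + ARO + ORA + DRO + ORD)

    dA = (
        -p.k_decay * A
        + p.k_dissA1 * (ARA + ARD + ARO)
        - p.k_assocA1 * A * (ORA + ORD + ORO)
        + p.k_dissA2 * (ARA + DRA + ORA)
        - p.k_assocA2 * A * (ARO + DRO + ORO)
    )
    dARAs = -p.k_close * ARAs + p.k_open * ARA
    dARA = (
        p.k_assocA1 * ORA * A
        - p.k_dissA1 * ARA
        + p.k_assocA2 * ARO * A
        - p.k_dissA2 * ARA
        + p.k_close * ARAs
        - p.k_open * ARA
    )
    dDRD = (
        p.k_assocD1 * ORD * D
        - p.k_dissD1 * DRD
        + p.k_assocD2 * DRO * D
        - p.k_dissD2 * DRD
    )
    dARD = (
        p.k_assocA1 * ORD * A
        - p.k_dissA1 * ARD
        + p.k_assocD2 * ARO * D
        - p.k_dissD2 * ARD
    )
    dDRA = (
        p.k_assocD1 * ORA * D
        - p.k_dissD1 * DRA
        + p.k_assocA2 * DRO * A
        - p.k_dissA2 * DRA
    )
    dARO = (
        p.k_assocA1 * ORO * A
        - p.k_dissA1 * ARO
        + p.k_dissA2 * ARA
        - p.k_assocA2 * ARO * A
        + p.k_dissD2 * ARD
        - p.k_assocD2 * ARO * D
    )
    dORA = (
        p.k_assocA2 * ORO * A
        - p.k_dissA2 * ORA
        + p.k_dissA1 * ARA
        - p.k_assocA1 * ORA * A
        + p.k_dissD1 * DRA
        - p.k_assocD1 * ORA * D
    )
    dDRO = (
        p.k_assocD1 * ORO * D
        - p.k_dissD1 * DRO
        + p.k_dissD2 * DRD
        - p.k_assocD2 * DRO * D
        + p.k_dissA2 * DRA
        - p.k_assocA2 * DRO * A
    )
    dORD = (
        p.k_assocD2 * ORO * D
        - p.k_dissD2 * ORD
        + p.k_dissD1 * DRD
        - p.k_assocD1 * ORD * D
        + p.k_dissA1 * ARD
        - p.k_assocA1 * ORD * A
    )
    return np.array(
        [dA, dARAs, dARA, dDRD, dARD, dDRA, dARO, dORA, dDRO, dORD]
    )


def rhs_full(
    state: ReceptorState, params: KineticParameters, drug: float
) -> np.ndarray:
    """Time derivative of the ten integrated concentrations (M/s).

    The blocker concentration ``drug`` is clamped (no pharmacokinetics
    during an event).  ORO enters through receptor conservation, so the
    nine receptor-state derivatives implicitly sum to -d[ORO]/dt.
    """
    if drug < 0:
        raise ValueError(f"drug concentration must be >= 0, got {drug!r}")
    y = state.to_array()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite value in receptor state")
    return _rhs(y, params, drug)


@dataclass
class Trajectory:
    """A simulated time course of the dimensional model.

    ``states`` has one row per time point in ``STATE_NAMES`` order; ORO is
    derived on demand.  Solver diagnostics record the tolerances and step
    count actually used.
    """

    times: np.ndarray
    states: np.ndarray
    parameters: KineticParameters
    drug_concentration: float
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    n_steps: int = 0
    horizon: float = field(default=DEFAULT_HORIZON)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or self.states.shape != (
            self.times.size,
            len(STATE_NAMES),
        ):
            raise ValueError("times/states shape mismatch")
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must start at 0 and strictly increase")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("non-finite value in trajectory")

    def column(self, name: str) -> np.ndarray:
        if name == "ORO":
            return self.parameters.R_total - self.states[:, 1:].sum(axis=1)
        return self.states[:, _IDX[name]]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with a derived ORO column (concentrations in M)."""
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_s", self.times)
        df["ORO"] = self.parameters.R_total - self.states[:, 1:].sum(axis=1)
        return df


@dataclass(frozen=True)
class EventSummary:
    """Peak activation of one synaptic event and its drug-free reference."""

    ara_star_peak: float
    t_peak: float
    ara_star_max_reference: float
    relative_current: float


def simulate_event(
    params: KineticParameters,
    drug: float,
    horizon: float = DEFAULT_HORIZON,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    n_points: int = DENSE_POINTS,
    auto_extend: bool = True,
) -> Trajectory:
    """Simulate one synaptic event under a clamped blocker concentration.

    The initial condition is the pre-event blocker-binding steady state with
    the free-ACh concentration stepped to ``A_init`` at t=0.  Integration
    uses a stiff-capable LSODA solver with dense output on ``n_points``
    evenly spaced times over ``[0, horizon]``.

    If the open-state trace is still rising at the end of the window the
    horizon is doubled, up to three times, before raising
    :class:`PeakNotBracketedError` (unless ``auto_extend`` is False, in
    which case the first failure raises).
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    y0 = pre_release_steady_state(params, drug).to_array()
    y0[_IDX["A"]] = params.A_init

    attempts = 4 if auto_extend else 1
    h = float(horizon)
    for attempt in range(attempts):
        t_eval = np.linspace(0.0, h, n_points)
        sol = solve_ivp(
            lambda t, y: _rhs(y, params, drug),
            (0.0, h),
            y0,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SolverError(
                f"integration failed at drug={drug:g} M: {sol.message}"
            )
        ara_star = sol.y[_IDX["ARA_star"]]
        peak_bracketed = (params.A_init == 0.0) or (
            int(np.argmax(ara_star)) < ara_star.size - 1
        )
        if peak_bracketed or attempt == attempts - 1:
            traj = Trajectory(
                times=sol.t,
                states=sol.y.T.copy(),
                parameters=params,
                drug_concentration=drug,
                rtol=rtol,
                atol=atol,
                n_steps=int(sol.nfev),
                horizon=h,
            )
            if not peak_bracketed:
                raise PeakNotBracketedError(
                    f"ARA* still rising at t={h:g} s after "
                    f"{attempt} horizon extensions"
                )
            return traj
        h *= 2.0
    raise AssertionError("unreachable")


def _quadratic_refine(
    t: np.ndarray, y: np.ndarray, i: int
) -> tuple[float, float]:
    """Vertex of the parabola through three samples around index ``i``."""
    if i == 0 or i == t.size - 1:
        return float(t[i]), float(y[i])
    t0, t1, t2 = t[i - 1 : i + 2]
    y0, y1, y2 = y[i - 1 : i + 2]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (y1 - y0) + t1 * (y0 - y2) + t0 * (y2 - y1)) / denom
    b = (t2**2 * (y0 - y1) + t1**2 * (y2 - y0) + t0**2 * (y1 - y2)) / denom
    if a >= 0:  # flat or degenerate: keep the grid point
        return float(t[i]), float(y[i])
    tv = -b / (2 * a)
    c = (
        t1 * t2 * (t1 - t2) * y0
        + t2 * t0 * (t2 - t0) * y1
        + t0 * t1 * (t0 - t1) * y2
    ) / denom
    return float(tv), float(a * tv * tv + b * tv + c)


def peak_activation(
    traj: Trajectory, component: str = "ARA_star"
) -> tuple[float, float]:
    """Peak of a trace and its time, quadratically refined off the grid.

    Returns ``(peak_value, t_peak)``.  The trajectory must bracket the
    maximum: a maximum at the final sample (or an identically zero trace)
    raises :class:`PeakNotBracketedError`.  On exact grid ties the first
    maximum wins.
    """
    y = traj.column(component)
    i = int(np.argmax(y))
    if y[i] <= 0.0:
        raise PeakNotBracketedError(f"{component} trace has no positive peak")
    if i == y.size - 1:
        raise PeakNotBracketedError(
            f"{component} maximum lies at the final time point"
        )
    t_peak, peak = _quadratic_refine(traj.times, y, i)
    return peak, t_peak


def relative_current(ara_star_peak: float, ara_star_max: float) -> float:
    """Fractional response surviving the block: peak over drug-free peak.

    Under the proportionality of end-plate conductance to the number of open
    channels this equals the relative current I_antag/I_0 measured in patch
    recordings.  Values a hair above 1 (numerical jitter) are clipped to 1.
    """
    if ara_star_max <= 0:
        raise ValueError("reference peak must be > 0")
    if ara_star_peak < 0:
        raise ValueError("peak must be >= 0")
    return min(ara_star_peak / ara_star_max, 1.0)


def summarize_event(
    params: KineticParameters,
    drug: float,
    *,
    ara_star_max: float | None = None,
    horizon: float = DEFAULT_HORIZON,
    **solver_options,
) -> EventSummary:
    """Run one event and report its peak against the drug-free reference.

    If ``ara_star_max`` is not supplied it is computed by a drug-free run
    under the same parameters (the reference is configuration-specific).
    """
    if ara_star_max is None:
        ref = simulate_event(params, 0.0, horizon, **solver_options)
        ara_star_max, _ = peak_activation(ref)
    traj = simulate_event(params, drug, horizon, **solver_options)
    peak, t_peak = peak_activation(traj)
    return EventSummary(
        ara_star_peak=peak,
        t_peak=t_peak,
        ara_star_max_reference=ara_star_max,
        relative_current=relative_current(peak, ara_star_max),
    )
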