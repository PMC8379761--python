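"""Numerical-experiment protocol: inhibition-vs-occupancy curves and sweeps.

The central object is the inhibition curve: for a fixed parameter
configuration, pair each blocker concentration with (a) the analytic
equilibrium occupancy O_total and (b) the simulated relative current
[ARA*]_peak/[ARA*]_max.  Plotting (b) against (a) and comparing with the
diagonal 1 - O_total is the whole analysis; the distance from the diagonal
(``nonlinearity_index``) measures how far the system departs from
"inhibition proportional to occupancy".

Sweeps vary one knob at a time following fixed rules: the ACh equilibrium
constant K_A through the association constants, the blocker selectivity
mu_D through k_assocD2, the initial-ACh multiple of R_total directly, and
the blocker dissociation rate k_dissD with both K_D held fixed.  Everything
here is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import fit_hill, ic50_from_curve
from .kinetics import (
    occupancy_fractions,
    peak_activation,
    relative_current,
    simulate_event,
)
from .parameters import KineticParameters, base_parameters

__all__ = [
    "InhibitionCurve",
    "SweepSpec",
    "standard_drug_grid",
    "inhibition_occupancy_curve",
    "run_sweep",
    "ach_concentration_response",
    "nonlinearity_index",
    "ic50_shift_analysis",
    "K_A_SWEEP_VALUES",
    "MU_D_SWEEP_VALUES",
    "A_INIT_MULTIPLIERS",
    "K_DISSD_SWEEP_VALUES",
    "IN_VITRO_K_A",
]

#: Published sweep anchors: ACh equilibrium constants spanning the
#: mouse-to-human affinity range, blocker selectivities, initial-ACh
#: multiples of R_total in half-decade steps, and blocker dissociation
#: rates up to the ACh dissociation rate.
K_A_SWEEP_VALUES = (1.0e-4, 3.16e-5, 1.0e-5)
MU_D_SWEEP_VALUES = (1.0, 10.0, 100.0)
A_INIT_MULTIPLIERS = (0.0562, 0.1, 0.178, 0.316, 0.562, 1.0, 1.78, 3.16, 5.62)
K_DISSD_SWEEP_VALUES = (10.0, 100.0, 1000.0, 1.2e4, 1.8e4)

#: K_A used for the initial-ACh and dissociation-rate sweeps (the setting
#: where the nonlinearity is most prominent).
IN_VITRO_K_A = 1.0e-5

SWEEP_PARAMETERS = ("K_A", "mu_D", "A_init_multiplier", "k_dissD")


def standard_drug_grid() -> np.ndarray:
    """Zero plus 100 log-equidistant concentrations from 1e-14 to 1e-5 M."""
    return np.concatenate(([0.0], np.logspace(-14.0, -5.0, 100)))


@dataclass
class InhibitionCurve:
    """Paired occupancy/response arrays for one parameter configuration."""

    drug_concentrations: np.ndarray
    O_total: np.ndarray
    relative_current: np.ndarray
    parameters: KineticParameters
    label: str = ""

    def __post_init__(self) -> None:
        self.drug_concentrations = np.asarray(
            self.drug_concentrations, dtype=float
        )
        self.O_total = np.asarray(self.O_total, dtype=float)
        self.relative_current = np.asarray(self.relative_current, dtype=float)
        n = self.drug_concentrations.size
        if self.O_total.size != n or self.relative_current.size != n:
            raise ValueError("curve arrays must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_M": self.drug_concentrations,
                "O_total": self.O_total,
                "relative_current": self.relative_current,
            }
        )


@dataclass
class SweepSpec:
    """One-parameter sweep over a base configuration.

    ``parameter`` names the knob; ``values`` the settings; ``base`` the
    configuration every other constant is taken from.  The rule mapping
    each knob onto underlying rate constants is fixed (see module
    docstring and :meth:`apply`).
    """

    parameter: str
    values: tuple[float, ...]
    base: KineticParameters = field(default_factory=base_parameters)

    def __post_init__(self) -> None:
        if self.parameter not in SWEEP_PARAMETERS:
            raise ValueError(
                f"unsupported sweep parameter {self.parameter!r}; "
                f"expected one of {SWEEP_PARAMETERS}"
            )
        self.values = tuple(float(v) for v in self.values)
        if any(v <= 0 for v in self.values):
            raise ValueError("sweep values must be > 0")

    def apply(self, value: float) -> KineticParameters:
        """The parameter set for one sweep value."""
        if self.parameter == "K_A":
            return self.base.with_K_A(value)
        if self.parameter == "mu_D":
            return self.base.with_mu_D(value)
        if self.parameter == "A_init_multiplier":
            return self.base.evolve(A_init=value * self.base.R_total)
        return self.base.with_k_dissD(value)

    def configurations(self):
        for v in self.values:
            yield v, self.apply(v)


def inhibition_occupancy_curve(
    params: KineticParameters,
    grid: np.ndarray | None = None,
    *,
    label: str = "",
    **solver_options,
) -> InhibitionCurve:
    """Simulate the relative current across a drug grid.

    The grid must contain 0: the drug-free run supplies the reference peak
    [ARA*]_max for the configuration.  Occupancies are analytic; responses
    come from one stiff ODE solve per concentration.
    """
    grid = standard_drug_grid() if grid is None else np.asarray(grid, float)
    if not np.any(grid == 0.0):
        raise ValueError("drug grid must contain 0 (reference run)")

    ref_traj = simulate_event(params, 0.0, **solver_options)
    ara_star_max, _ = peak_activation(ref_traj)

    occ = np.empty(grid.size)
    rc = np.empty(grid.size)
    for i, d in enumerate(grid):
        occ[i] = occupancy_fractions(d / params.K_D1, params.mu_D).O_total
        if d == 0.0:
            rc[i] = 1.0
            continue
        try:
            traj = simulate_event(params, float(d), **solver_options)
            peak, _ = peak_activation(traj)
        except Exception as exc:
            raise RuntimeError(
                f"simulation failed at drug={d:g} M ({label or 'unlabelled'})"
            ) from exc
        rc[i] = relative_current(peak, ara_star_max)
    return InhibitionCurve(grid, occ, rc, params, label=label)


def run_sweep(
    spec: SweepSpec,
    grid: np.ndarray | None = None,
    **solver_options,
) -> list[InhibitionCurve]:
    """One inhibition curve per sweep value, labelled with the setting."""
    return [
        inhibition_occupancy_curve(
            p, grid, label=f"{spec.parameter}={v:g}", **solver_options
        )
        for v, p in spec.configurations()
    ]


def ach_concentration_response(
    params: KineticParameters,
    a_init_values: np.ndarray,
    **solver_options,
) -> pd.DataFrame:
    """Drug-free peak activated fraction versus initial ACh.

    For each initial concentration the event is simulated without blocker
    and the peak [ARA*] is reported as a fraction of R_total.  Columns:
    ``A_init_M``, ``activated_fraction``.
    """
    rows = []
    for a in np.asarray(a_init_values, dtype=float):
        if a < 0:
            raise ValueError("A_init must be >= 0")
        if a == 0.0:
            rows.append((0.0, 0.0))
            continue
        p = params.evolve(A_init=float(a))
        traj = simulate_event(p, 0.0, **solver_options)
        peak, _ = peak_activation(traj)
        rows.append((float(a), peak / params.R_total))
    return pd.DataFrame(rows, columns=["A_init_M", "activated_fraction"])


def nonlinearity_index(curve: InhibitionCurve) -> float:
    """Maximum gap between the simulated curve and the occupancy diagonal.

    max over the grid of |relative_current - (1 - O_total)|; zero exactly
    when inhibition is proportional to occupancy on the grid.  Invariant
    under reordering of grid points.
    """
    return float(
        np.max(np.abs(curve.relative_current - (1.0 - curve.O_total)))
    )


def ic50_shift_analysis(
    params: KineticParameters,
    a_init_values: np.ndarray,
    grid: np.ndarray | None = None,
    **solver_options,
) -> pd.DataFrame:
    """IC50 of the simulated concentration–inhibition curve per A_init.

    For each initial-ACh setting the relative-current-vs-drug series is
    fitted with the Hill curve; the model-free 0.5-crossing is the fallback
    when the regression fails.  Configurations whose responses never cross
    0.5 are reported with IC50 = NaN rather than raising.  Columns:
    ``A_init_M``, ``IC50_M``, ``n_H``, ``method``.
    """
    rows = []
    for a in np.asarray(a_init_values, dtype=float):
        p = params.evolve(A_init=float(a))
        curve = inhibition_occupancy_curve(p, grid, **solver_options)
        r = curve.relative_current
        if not (np.any(r < 0.5) and np.any(r > 0.5)):
            rows.append((float(a), np.nan, np.nan, "missing"))
            continue
        try:
            fit = fit_hill(curve.drug_concentrations, r)
            rows.append((float(a), fit.IC50, fit.n_H, "hill_fit"))
        except Exception:
            ic50 = ic50_from_curve(curve.drug_concentrations, r)
            rows.append((float(a), ic50, np.nan, "interpolated"))
    return pd.DataFrame(rows, columns=["A_init_M", "IC50_M", "n_H", "method"])
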