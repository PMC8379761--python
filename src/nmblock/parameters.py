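"""Kinetic parameters of the two-site nicotinic-receptor competition model.

The muscle nicotinic acetylcholine receptor (AChR) carries two nonequivalent
agonist binding sites.  Acetylcholine (ACh, ``A``) and a nondepolarizing
neuromuscular blocking drug (NDNB, ``D``) compete for both sites by mass
action; the receptor opens (state ``ARA*``) only when both sites are
ACh-bound.  This module holds the dimensional rate constants and
concentrations of that scheme, with the base values used throughout the
package, and the closed-form derivations of the synaptic concentrations from
end-plate anatomy.

Units are SI throughout: molar (M) for concentrations, 1/s for first-order
rate constants, 1/(M s) for association rate constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Any, Iterator, Mapping

__all__ = [
    "KineticParameters",
    "base_parameters",
    "derived_constants",
    "AVOGADRO",
]

AVOGADRO = 6.02214076e23  # 1/mol, exact (2019 SI)

#: Base-case parameter values: concentrations of receptor and released ACh at
#: the end plate, free-ACh decay (hydrolysis + diffusion), ACh and NDNB
#: association/dissociation rate constants for both sites, and channel gating.
_BASE = {
    "R_total": 7.75e-5,
    "A_init": 7.75e-6,
    "k_decay": 1.2e4,
    "k_dissA1": 1.8e4,
    "k_dissA2": 1.8e4,
    "k_assocA1": 1.1e8,
    "k_assocA2": 1.1e8,
    "k_dissD1": 10.0,
    "k_dissD2": 10.0,
    "k_assocD1": 1.0e8,
    "k_assocD2": 1.0e8,
    "k_close": 1.2e3,
    "k_open": 5.0e4,
}


@dataclass(frozen=True)
class KineticParameters:
    """Dimensional parameters of the full competition model.

    Attributes
    ----------
    R_total : float
        Concentration of post-junctional AChRs in the synaptic cleft (M).
    A_init : float
        Concentration of free ACh immediately after release at t=0 (M).
    k_decay : float
        First-order decay rate of free ACh (hydrolysis by
        acetylcholinesterase plus diffusion out of the cleft), 1/s.
    k_dissA1, k_dissA2 : float
        ACh dissociation rate constants for sites 1 and 2 (1/s).
    k_assocA1, k_assocA2 : float
        ACh association rate constants for sites 1 and 2 (1/(M s)).
    k_dissD1, k_dissD2 : float
        NDNB dissociation rate constants for sites 1 and 2 (1/s).
    k_assocD1, k_assocD2 : float
        NDNB association rate constants for sites 1 and 2 (1/(M s)).
    k_open, k_close : float
        Channel opening/closing rate constants of the diliganded
        receptor (1/s).
    """

    R_total: float
    A_init: float
    k_decay: float
    k_dissA1: float
    k_dissA2: float
    k_assocA1: float
    k_assocA2: float
    k_dissD1: float
    k_dissD2: float
    k_assocD1: float
    k_assocD2: float
    k_close: float
    k_open: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
            if f.name == "A_init":
                if v < 0:
                    raise ValueError(f"A_init must be >= 0, got {v!r}")
            elif v <= 0:
                raise ValueError(f"{f.name} must be > 0, got {v!r}")

    # -- derived equilibrium constants (dissociation over association) ------

    @property
    def K_A1(self) -> float:
        """ACh dissociation equilibrium constant at site 1 (M)."""
        return self.k_dissA1 / self.k_assocA1

    @property
    def K_A2(self) -> float:
        """ACh dissociation equilibrium constant at site 2 (M)."""
        return self.k_dissA2 / self.k_assocA2

    @property
    def K_D1(self) -> float:
        """NDNB dissociation equilibrium constant at site 1 (M)."""
        return self.k_dissD1 / self.k_assocD1

    @property
    def K_D2(self) -> float:
        """NDNB dissociation equilibrium constant at site 2 (M)."""
        return self.k_dissD2 / self.k_assocD2

    @property
    def mu_D(self) -> float:
        """Site-selectivity of the blocker, K_D1/K_D2 (dimensionless)."""
        return self.K_D1 / self.K_D2

    # -- convenience constructors -------------------------------------------

    def evolve(self, **changes: float) -> "KineticParameters":
        """Return a copy with the named fields replaced."""
        return replace(self, **changes)

    def with_K_A(self, K_A: float) -> "KineticParameters":
        """Set both ACh equilibrium constants to ``K_A``.

        Follows the convention of varying the association rate constants
        while holding the dissociation rate constants fixed, so that
        K_A1 = K_A2 = K_A (hence mu_A = 1).
        """
        if K_A <= 0:
            raise ValueError("K_A must be > 0")
        return self.evolve(
            k_assocA1=self.k_dissA1 / K_A, k_assocA2=self.k_dissA2 / K_A
        )

    def with_mu_D(self, mu_D: float) -> "KineticParameters":
        """Set the blocker site-selectivity by adjusting ``k_assocD2`` only.

        k_dissD1, k_dissD2 and k_assocD1 are held fixed, so K_D1 is
        unchanged and K_D2 = K_D1/mu_D.
        """
        if mu_D <= 0:
            raise ValueError("mu_D must be > 0")
        return self.evolve(k_assocD2=self.k_dissD2 * mu_D / self.K_D1)

    def with_k_dissD(self, k_dissD: float) -> "KineticParameters":
        """Set both NDNB dissociation rate constants to ``k_dissD``.

        Association constants are rescaled proportionally so K_D1 and K_D2
        (hence delta, mu_D, and the equilibrium occupancy) are unchanged;
        only the exchange kinetics speed up or slow down.
        """
        if k_dissD <= 0:
            raise ValueError("k_dissD must be > 0")
        return self.evolve(
            k_dissD1=k_dissD,
            k_dissD2=k_dissD,
            k_assocD1=k_dissD / self.K_D1,
            k_assocD2=k_dissD / self.K_D2,
        )

    # -- mapping interface ---------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "KineticParameters":
        """Build from a flat mapping; unknown keys are rejected."""
        known = set(cls.field_names())
        unknown = sorted(set(data) - known)
        if unknown:
            raise KeyError(f"unknown parameter keys: {unknown}")
        merged = dict(_BASE)
        merged.update({k: float(v) for k, v in data.items()})
        return cls(**merged)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())


def base_parameters(**overrides: float) -> KineticParameters:
    """The base-case parameter set, optionally with field overrides."""
    return KineticParameters.from_dict(overrides)


def derived_constants(
    n_receptors: float = 2.1e7,
    cleft_volume_L: float = 4.5e-13,
    ach_vesicles: int = 300,
    ach_per_vesicle: int = 7000,
) -> dict[str, float]:
    """Derive the synaptic concentrations and ACh half-life from anatomy.

    The receptor concentration follows from the number of AChRs at the end
    plate of human deltoid muscle divided by the synaptic-cleft volume of rat
    diaphragm.  The cleft volume has appeared in print with a positive
    exponent (4.5e+13 L); only 4.5e-13 L is physically plausible and
    reproduces R_total = 7.75e-5 M, so the negative exponent is used here.

    The released ACh is taken as 300 vesicles of 7000 molecules each —
    one tenth of the receptor count — giving A_init = R_total/10.

    Returns a dict with keys ``R_total`` (M), ``A_init`` (M),
    ``n_ach_molecules`` (count), and ``ach_half_life_s`` (s, ln 2/k_decay at
    the base-case decay rate).
    """
    r_total = n_receptors / (cleft_volume_L * AVOGADRO)
    n_ach = float(ach_vesicles * ach_per_vesicle)
    a_init = n_ach / (cleft_volume_L * AVOGADRO)
    return {
        "R_total": r_total,
        "A_init": a_init,
        "n_ach_molecules": n_ach,
        "ach_half_life_s": math.log(2.0) / _BASE["k_decay"],
    }
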