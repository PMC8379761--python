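"""Independent, deliberately naive re-implementations used as test oracles.

Kept separate from the package and written in a different style (dict-based,
one reaction term at a time) so that a transcription error in the package
and in the oracle are unlikely to coincide.
"""

import numpy as np


def naive_rhs(state: dict, p, D: float) -> dict:
    """Term-by-term transcription of the mass-action balance equations.

    ``state`` maps complex names to concentrations; ``p`` is any object
    with the rate-constant attributes; ``D`` is the clamped blocker
    concentration.  Returns the time derivative of each stored component.
    """
    A = state["A"]
    ARAs = state["ARA_star"]
    ARA = state["ARA"]
    DRD = state["DRD"]
    ARD = state["ARD"]
    DRA = state["DRA"]
    ARO = state["ARO"]
    ORA = state["ORA"]
    DRO = state["DRO"]
    ORD = state["ORD"]
    ORO = (
        p.R_total
        - ARAs
        - ARA
        - DRD
        - ARD
        - DRA
        - ARO
        - ORA
        - DRO
        - ORD
    )

    d = {}
    d["A"] = (
        -p.k_decay * A
        + p.k_dissA1 * ARA
        + p.k_dissA1 * ARD
        + p.k_dissA1 * ARO
        - p.k_assocA1 * A * ORA
        - p.k_assocA1 * A * ORD
        - p.k_assocA1 * A * ORO
        + p.k_dissA2 * ARA
        + p.k_dissA2 * DRA
        + p.k_dissA2 * ORA
        - p.k_assocA2 * A * ARO
        - p.k_assocA2 * A * DRO
        - p.k_assocA2 * A * ORO
    )
    d["ARA_star"] = -p.k_close * ARAs + p.k_open * ARA
    d["ARA"] = (
        p.k_assocA1 * ORA * A
        - p.k_dissA1 * ARA
        + p.k_assocA2 * ARO * A
        - p.k_dissA2 * ARA
        + p.k_close * ARAs
        - p.k_open * ARA
    )
    d["DRD"] = (
        p.k_assocD1 * ORD * D
        - p.k_dissD1 * DRD
        + p.k_assocD2 * DRO * D
        - p.k_dissD2 * DRD
    )
    d["ARD"] = (
        p.k_assocA1 * ORD * A
        - p.k_dissA1 * ARD
        + p.k_assocD2 * ARO * D
        - p.k_dissD2 * ARD
    )
    d["DRA"] = (
        p.k_assocD1 * ORA * D
        - p.k_dissD1 * DRA
        + p.k_assocA2 * DRO * A
        - p.k_dissA2 * DRA
    )
    d["ARO"] = (
        p.k_assocA1 * ORO * A
        - p.k_dissA1 * ARO
        + p.k_dissA2 * ARA
        - p.k_assocA2 * ARO * A
        + p.k_dissD2 * ARD
        - p.k_assocD2 * ARO * D
    )
    d["ORA"] = (
        p.k_assocA2 * ORO * A
        - p.k_dissA2 * ORA
        + p.k_dissA1 * ARA
        - p.k_assocA1 * ORA * A
        + p.k_dissD1 * DRA
        - p.k_assocD1 * ORA * D
    )
    d["DRO"] = (
        p.k_assocD1 * ORO * D
        - p.k_dissD1 * DRO
        + p.k_dissD2 * DRD
        - p.k_assocD2 * DRO * D
        + p.k_dissA2 * DRA
        - p.k_assocA2 * DRO * A
    )
    d["ORD"] = (
        p.k_assocD2 * ORO * D
        - p.k_dissD2 * ORD
        + p.k_dissD1 * DRD
        - p.k_assocD1 * ORD * D
        + p.k_dissA1 * ARD
        - p.k_assocA1 * ORD * A
    )
    return d


def random_states(p, n: int, seed: int = 12345):
    """Nonnegative random states respecting receptor conservation."""
    rng = np.random.default_rng(seed)
    names = (
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
    for _ in range(n):
        fracs = rng.dirichlet(np.ones(10))[:9]  # leaves room for ORO
        state = {k: p.R_total * f for k, f in zip(names, fracs)}
        state["A"] = rng.uniform(0.0, 2.0 * p.A_init + 1e-9)
        yield state
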