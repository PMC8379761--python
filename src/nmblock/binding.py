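"""Classical descriptive models of competitive block: Hill and two-site.

These are the curves fitted to concentration–inhibition data in patch-clamp
work.  The Hill curve is an empirical sigmoid parameterized by the half-
inhibitory concentration IC50 and the Hill coefficient n_H.  The two-site
receptor-binding curve assumes the response is proportional to the fraction
of receptors with neither site drug-bound; in the dimensionless variables of
the kinetic model it is identically 1 - O_total(delta), which is what makes
it the "inhibition proportional to occupancy" null model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .kinetics import occupancy_fractions

__all__ = [
    "HillFit",
    "hill_curve",
    "two_site_curve",
    "fit_hill",
    "ic50_from_curve",
    "FitError",
]


class FitError(RuntimeError):
    """Regression failed to converge; message carries solver diagnostics."""


@dataclass(frozen=True)
class HillFit:
    """Result of a Hill-equation regression.

    ``ill_posed`` is set when the data never cross 0.5, in which case the
    IC50 is an extrapolation and should be treated with suspicion.
    """

    IC50: float
    n_H: float
    residual_sum_of_squares: float
    converged: bool
    ill_posed: bool = False
    covariance: np.ndarray | None = None


def hill_curve(drug, IC50: float, n_H: float):
    """Relative current under the Hill model.

        I/I0 = IC50^nH / (IC50^nH + [D]^nH)

    Evaluated in the log domain as a logistic in n_H*(ln[D] - ln IC50) so
    extreme concentrations neither overflow nor underflow.  Scalar or array
    ``drug``; drug = 0 maps to the exact limit 1.
    """
    if IC50 <= 0 or n_H <= 0:
        raise ValueError("IC50 and n_H must be > 0")
    scalar = np.ndim(drug) == 0
    d = np.atleast_1d(np.asarray(drug, dtype=float))
    if np.any(d < 0):
        raise ValueError("drug concentrations must be >= 0")
    out = np.ones_like(d)
    pos = d > 0
    z = n_H * (np.log(d[pos]) - np.log(IC50))
    out[pos] = 1.0 / (1.0 + np.exp(np.minimum(z, 700.0)))
    return float(out[0]) if scalar else out


def two_site_curve(drug, K_D1: float, K_D2: float):
    """Relative current under the two-site receptor-binding model.

        I/I0 = K1 K2 / (K1 K2 + (K1 + K2)[D] + [D]^2)

    i.e. the equilibrium fraction of receptors free of drug at both sites;
    algebraically identical to 1 - O_total([D]/K1, K1/K2).
    """
    if K_D1 <= 0 or K_D2 <= 0:
        raise ValueError("K_D1 and K_D2 must be > 0")
    scalar = np.ndim(drug) == 0
    d = np.atleast_1d(np.asarray(drug, dtype=float))
    if np.any(d < 0):
        raise ValueError("drug concentrations must be >= 0")
    k12 = K_D1 * K_D2
    out = k12 / (k12 + (K_D1 + K_D2) * d + d * d)
    return float(out[0]) if scalar else out


def ic50_from_curve(drug_grid, responses) -> float:
    """Model-free IC50: log-linear interpolation of the 0.5 crossing.

    Requires the responses to cross 0.5 from above somewhere on the
    (sorted, positive) part of the grid.  Zero-drug points are used only to
    confirm the curve starts above 0.5.
    """
    d = np.asarray(drug_grid, dtype=float)
    r = np.asarray(responses, dtype=float)
    if d.shape != r.shape or d.ndim != 1:
        raise ValueError("drug_grid and responses must be 1-D and aligned")
    order = np.argsort(d)
    d, r = d[order], r[order]
    pos = d > 0
    d, r = d[pos], r[pos]
    below = np.nonzero(r <= 0.5)[0]
    if below.size == 0 or below[0] == 0:
        raise ValueError("responses do not cross 0.5 on the grid")
    j = below[0]
    if r[j] == 0.5:
        return float(d[j])
    i = j - 1
    t = (0.5 - r[i]) / (r[j] - r[i])
    return float(np.exp(np.log(d[i]) + t * (np.log(d[j]) - np.log(d[i]))))


def fit_hill(
    drug_grid,
    responses,
    init: HillFit | None = None,
) -> HillFit:
    """Ordinary least squares fit of the Hill curve.

    Optimizes over (log IC50, log n_H), which enforces positivity without
    constraints.  The IC50 is seeded at the model-free 0.5 crossing when one
    exists (geometric-mean of the positive grid otherwise) and n_H at 1.
    Zero-drug points participate as exact response-1 constraints.

    Data that never cross 0.5 are fitted anyway but flagged ``ill_posed``.
    Non-convergence raises :class:`FitError` with the solver message.
    """
    d = np.asarray(drug_grid, dtype=float)
    r = np.asarray(responses, dtype=float)
    if d.shape != r.shape or d.ndim != 1:
        raise ValueError("drug_grid and responses must be 1-D and aligned")
    if d.size < 4:
        raise ValueError("need at least 4 points to fit the Hill curve")
    if np.any((r < -1e-9) | (r > 1 + 1e-9)):
        raise ValueError("responses must lie in [0, 1]")

    has_low = np.any(r < 0.5)
    has_high = np.any(r > 0.5)
    ill_posed = not (has_low and has_high)

    if init is not None:
        ic50_0, nh_0 = init.IC50, init.n_H
    else:
        try:
            ic50_0 = ic50_from_curve(d, r)
        except ValueError:
            ic50_0 = float(np.exp(np.mean(np.log(d[d > 0]))))
        nh_0 = 1.0

    def residuals(theta):
        ic50, nh = np.exp(theta)
        return hill_curve(d, ic50, nh) - r

    res = least_squares(
        residuals,
        x0=np.log([ic50_0, nh_0]),
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        raise FitError(f"Hill regression did not converge: {res.message}")
    ic50, nh = np.exp(res.x)
    rss = float(2.0 * res.cost)

    cov = None
    try:
        jtj = res.jac.T @ res.jac
        dof = max(d.size - 2, 1)
        cov = np.linalg.inv(jtj) * rss / dof
    except np.linalg.LinAlgError:
        pass

    return HillFit(
        IC50=float(ic50),
        n_H=float(nh),
        residual_sum_of_squares=rss,
        converged=True,
        ill_posed=ill_posed,
        covariance=cov,
    )


def occupancy_complement(drug, K_D1: float, K_D2: float):
    """1 - O_total on a dimensional drug axis; equals two_site_curve."""
    d = np.atleast_1d(np.asarray(drug, dtype=float))
    out = np.array(
        [
            1.0 - occupancy_fractions(di / K_D1, K_D1 / K_D2).O_total
            for di in d
        ]
    )
    return out if np.ndim(drug) else float(out[0])
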