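"""Production/degradation kinetics of plasma-membrane protein density.

A membrane protein inserted at rate P and degraded with first-order rate
k = ln2 / t_half has relative density

    D(t) = (1 - P/k) exp(-kt) + P/k        (D0 = 1, endogenous steady state)
    D(t) = (P/k) (1 - exp(-kt))            (D0 = 0, exogenous, starts empty)

so P/k is the steady-state relative density. Under transient transfection
the total density relaxes from 1 toward the summed endogenous + exogenous
P/k; inverting the solution at a measured time point yields the
production/degradation ratio, and subtracting the exogenous percentage from
the total percentage quantifies competition against endogenous expression.

Time is in hours throughout; the default half-life is 40 h (literature
value for membrane Na,K-ATPase alpha1, surfaced in output metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ParameterError

DEFAULT_HALFLIFE_H = 40.0


@dataclass
class KineticModel:
    """Parameters of the membrane density solution.

    ``P_over_k`` is the dimensionless production/degradation ratio,
    ``D0`` the initial relative density (1 for the endogenous steady
    state, 0 for an exogenous protein appearing at transfection).
    """

    P_over_k: float
    t_half_h: float = DEFAULT_HALFLIFE_H
    D0: float = 1.0
    P_over_k_se: float | None = None
    t_half_se: float | None = None
    metadata: dict = field(default_factory=lambda: {"halflife_source": "literature 40 h"})

    def __post_init__(self) -> None:
        if self.t_half_h <= 0:
            raise ParameterError("t_half_h must be positive")
        if self.P_over_k < 0:
            raise ParameterError("P_over_k must be non-negative")

    @property
    def k_per_h(self) -> float:
        return rate_from_halflife(self.t_half_h)


@dataclass
class CompetitionDecomposition:
    """Endogenous/exogenous split of a percent-of-control total density."""

    total_pct: float
    exogenous_pct: float
    endogenous_pct: float
    endogenous_reduction_pct: float


def rate_from_halflife(t_half_h: float) -> float:
    """Degradation rate k = ln 2 / t_half, in 1/hours."""
    if t_half_h <= 0:
        raise ParameterError("t_half_h must be positive")
    return float(np.log(2) / t_half_h)


def membrane_density(t_h, model: KineticModel):
    """Relative membrane density D(t) of the production/degradation model."""
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t must be non-negative")
    decay = np.exp(-model.k_per_h * t)
    out = (model.D0 - model.P_over_k) * decay + model.P_over_k
    return float(out) if np.isscalar(t_h) else out


def solve_production_rate(D_target: float, t_h: float, k_per_h: float) -> float:
    """Invert D(t) = (1 - P/k) e^{-kt} + P/k for P/k (closed form, D0 = 1).

    P/k = (D - e^{-kt}) / (1 - e^{-kt}); requires D_target > e^{-kt} for a
    non-negative solution.
    """
    if t_h <= 0 or k_per_h <= 0:
        raise ParameterError("t and k must be positive")
    decay = np.exp(-k_per_h * t_h)
    if D_target < decay:
        raise ParameterError(
            f"D_target={D_target} below e^(-kt)={decay:.4f}: no non-negative "
            "production rate reaches this density by time t"
        )
    return float((D_target - decay) / (1.0 - decay))


def decompose_competition(total_pct: float, exogenous_pct: float) -> CompetitionDecomposition:
    """Split a total percent-of-control density into endogenous + exogenous.

    ``endogenous = total - exogenous``; the endogenous reduction is
    ``100 - endogenous`` percentage points relative to untransfected control.
    """
    if not (0 <= exogenous_pct <= total_pct):
        raise ParameterError("need 0 <= exogenous_pct <= total_pct")
    endo = total_pct - exogenous_pct
    return CompetitionDecomposition(
        total_pct=float(total_pct),
        exogenous_pct=float(exogenous_pct),
        endogenous_pct=float(endo),
        endogenous_reduction_pct=float(100.0 - endo),
    )


def fit_timecourse(
    times_h,
    densities,
    D0: float = 1.0,
    t_half_h: float | None = DEFAULT_HALFLIFE_H,
) -> KineticModel:
    """Least-squares fit of the density solution to a measured time course.

    With ``t_half_h`` given, only P/k is estimated (>= 2 points needed);
    ``t_half_h=None`` frees the half-life too (>= 3 points). Standard
    errors come from the Jacobian at the optimum.
    """
    times = np.asarray(times_h, dtype=float)
    dens = np.asarray(densities, dtype=float)
    if times.shape != dens.shape or times.ndim != 1:
        raise ParameterError("times and densities must be 1D of equal length")
    free_thalf = t_half_h is None
    n_min = 3 if free_thalf else 2
    if len(times) < n_min:
        raise ParameterError(f"need at least {n_min} time points")

    def residuals(theta):
        ratio = theta[0]
        th = theta[1] if free_thalf else t_half_h
        model = KineticModel(P_over_k=max(ratio, 0.0), t_half_h=max(th, 1e-9), D0=D0)
        return membrane_density(times, model) - dens

    x0 = [max(dens[-1], 0.1)] + ([DEFAULT_HALFLIFE_H] if free_thalf else [])
    lo = [0.0] + ([1e-3] if free_thalf else [])
    hi = [np.inf] * len(x0)
    res = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15)

    dof = max(len(times) - len(x0), 1)
    s2 = float(res.cost * 2 / dof)
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(len(x0), np.nan)
    return KineticModel(
        P_over_k=float(res.x[0]),
        t_half_h=float(res.x[1]) if free_thalf else float(t_half_h),
        D0=D0,
        P_over_k_se=float(se[0]),
        t_half_se=float(se[1]) if free_thalf else None,
    )
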