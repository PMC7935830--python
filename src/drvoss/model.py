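"""Structural PK model: covariate model, steady-state concentrations, AUC.

One-compartment disposition with first-order absorption and first-order
elimination, oral dosing at steady state.  All quantities are on the
apparent (dose/F) scale, so bioavailability never appears explicitly.
"""

from __future__ import annotations

import numpy as np

from .parameters import (
    CovariateProfile,
    IndividualParameters,
    PopulationParameters,
    Regimen,
)

__all__ = ["individual_parameters", "css_concentration", "steady_state_conc", "auc24"]

#: below this |ka - ke| (1/h) the equal-rates analytic limit is used
EQUAL_RATES_TOL = 1e-8


def individual_parameters(
    pop: PopulationParameters,
    cov: CovariateProfile,
    eta: tuple[float, float, float] | np.ndarray = (0.0, 0.0, 0.0),
) -> IndividualParameters:
    """Derive individual CL/F, V/F and ka from covariates and random effects.

    The covariate model is proportional: each indicator scales the typical
    value by ``(1 + theta)``; the log-normal random effects then multiply by
    ``exp(eta)``.

    Raises
    ------
    ValueError
        If a genotype flag is still missing (``None``) — imputation must
        happen before parameter derivation.
    """
    if not cov.resolved:
        raise ValueError(
            "covariate profile has unresolved missing genotypes; impute them "
            "(see drvoss.population) before deriving individual parameters"
        )
    e1, e2, e3 = (float(x) for x in eta)
    cl = (
        pop.cl_pop
        * (1.0 + pop.theta_sex * cov.female)
        * (1.0 + pop.theta_cyp3a5 * cov.cyp3a5_flag)
        * np.exp(e1)
    )
    v = pop.v_pop * (1.0 + pop.theta_slco3a1 * cov.slco3a1_flag) * np.exp(e2)
    ka = pop.ka_pop * np.exp(e3)
    return IndividualParameters(cl=cl, v=v, ka=ka, eta=(e1, e2, e3))


def steady_state_conc(dose, tau, cl, v, ka, t):
    """Vectorised steady-state concentration of the one-compartment oral model.

    Broadcasts over all arguments.  ``t`` is time after the reference dose
    (h) and is reduced modulo ``tau``, so times beyond one interval evaluate
    on the periodic steady-state profile.  The removable singularity at
    ka = ke is evaluated with its analytic limit.
    """
    dose, tau, cl, v, ka, t = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (dose, tau, cl, v, ka, t))
    )
    if np.any(t < 0):
        raise ValueError("time after dose must be nonnegative")
    for name, arr in (("dose", dose), ("tau", tau), ("cl", cl), ("v", v), ("ka", ka)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite {name} in steady-state evaluation")
    ke = cl / v
    tprime = np.mod(t, tau)
    ek_tau = np.exp(-ke * tau)
    ea_tau = np.exp(-ka * tau)
    ek_t = np.exp(-ke * tprime)
    ea_t = np.exp(-ka * tprime)

    degenerate = np.abs(ka - ke) < EQUAL_RATES_TOL
    denom = np.where(degenerate, 1.0, ka - ke)
    regular = (dose * ka) / (v * denom) * (ek_t / (1.0 - ek_tau) - ea_t / (1.0 - ea_tau))
    # limit ka -> ke = k:  C = D k e^{-kt'} [t'(1-e^{-k tau}) + tau e^{-k tau}]
    #                          / (V (1-e^{-k tau})^2)
    limit = (
        dose
        * ke
        * ek_t
        * (tprime * (1.0 - ek_tau) + tau * ek_tau)
        / (v * (1.0 - ek_tau) ** 2)
    )
    out = np.where(degenerate, limit, regular)
    return out


def css_concentration(ind: IndividualParameters, reg: Regimen, t) -> np.ndarray | float:
    """Steady-state concentration (mg/L) for one subject at time(s) ``t`` (h)."""
    c = steady_state_conc(reg.dose, reg.tau, ind.cl, ind.v, ind.ka, t)
    return float(c) if np.ndim(t) == 0 else c


def auc24(ind: IndividualParameters, reg: Regimen) -> float:
    """Steady-state AUC over 24 h (mg*h/L): daily dose / CL."""
    return reg.daily_dose / ind.cl
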