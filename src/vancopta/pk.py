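"""Two-compartment IV-infusion pharmacokinetic model for vancomycin.

The structural model is a linear two-compartment model with zero-order
(infusion) input into the central compartment and first-order elimination
from it.  Clearance depends on renal function through a power model on the
estimated glomerular filtration rate (eGFR), centred on the reference value
144 mL/min/1.73 m2:

    CL_pop(eGFR) = theta0 * (eGFR / 144) ** theta1

Concentrations are evaluated with the closed-form biexponential solution
(micro constants k10 = CL/V1, k12 = Q/V1, k21 = Q/V2; hybrid rates alpha,
beta) superposed over all administered doses.  The closed form is the
primary evaluator because probability-of-target-attainment work needs
millions of profile evaluations; a numerical ODE integration is used only
as an independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = [
    "PopulationParameters",
    "DosingRegimen",
    "SubjectRealization",
    "default_population",
    "clearance_for_egfr",
    "concentration",
    "concentration_profile",
    "one_compartment_concentration",
]

#: reference eGFR (sample median) on which the clearance model is centred
EGFR_REF = 144.0

# relative alpha/beta gap below which the biexponential form is degenerate
_DEGENERACY_TOL = 1e-9
_DEGENERACY_PERTURB = 1e-7


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, between-subject variability and residual error.

    Parameters
    ----------
    theta0_cl : float
        Clearance (L/h) at the reference eGFR of 144 mL/min/1.73 m2.
    theta1_cl : float
        Dimensionless exponent of the eGFR power model on clearance.
    q : float
        Intercompartmental clearance (L/h).
    v1, v2 : float
        Central and peripheral distribution volumes (L).
    egfr_ref : float
        Reference eGFR (mL/min/1.73 m2) used for centring.
    omega_cl, omega_q, omega_v1 : float
        Between-subject SDs of the log-scale random effects eta on CL, Q
        and V1.  V2 carries no random effect.
    rho_v1_cl : float
        Correlation between eta_V1 and eta_CL (the only nonzero
        off-diagonal term of the eta covariance matrix).
    b : float
        Proportional residual-error parameter (dimensionless).
    """

    theta0_cl: float = 5.2
    theta1_cl: float = 0.62
    q: float = 4.99
    v1: float = 21.22
    v2: float = 28.28
    egfr_ref: float = EGFR_REF
    omega_cl: float = 0.223
    omega_q: float = 0.767
    omega_v1: float = 0.223
    rho_v1_cl: float = 0.62
    b: float = 0.025

    def __post_init__(self) -> None:
        for name in ("theta0_cl", "q", "v1", "v2", "egfr_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("omega_cl", "omega_q", "omega_v1", "b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not abs(self.rho_v1_cl) < 1:
            raise ValueError("|rho_v1_cl| must be < 1")
        if np.linalg.eigvalsh(self.eta_covariance()).min() < -1e-12:
            raise ValueError("eta covariance matrix is not positive semi-definite")

    def eta_covariance(self) -> np.ndarray:
        """3x3 covariance of (eta_CL, eta_Q, eta_V1)."""
        sd = np.array([self.omega_cl, self.omega_q, self.omega_v1])
        corr = np.eye(3)
        corr[0, 2] = corr[2, 0] = self.rho_v1_cl
        return corr * np.outer(sd, sd)


def default_population() -> PopulationParameters:
    """Reference parameter set of the final vancomycin model for adults
    with chemotherapy-associated febrile neutropenia."""
    return PopulationParameters()


@dataclass(frozen=True)
class DosingRegimen:
    """A repeated intravenous-infusion maintenance regimen.

    Doses of ``dose_per_admin`` mg are infused over ``infusion_time_tinf``
    hours every ``interdose_interval_ii`` hours, starting at
    ``first_dose_time`` (hours from time origin), ``n_doses`` times.
    """

    dose_per_admin: float
    interdose_interval_ii: float
    infusion_time_tinf: float
    n_doses: int
    first_dose_time: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_per_admin < 0:
            raise ValueError("dose_per_admin must be >= 0")
        if not 0 < self.infusion_time_tinf <= self.interdose_interval_ii:
            raise ValueError("need 0 < Tinf <= II")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")

    @property
    def daily_dose(self) -> float:
        """Total daily dose DD = dose_per_admin * 24 / II (mg/day)."""
        return self.dose_per_admin * 24.0 / self.interdose_interval_ii

    @property
    def dose_times(self) -> np.ndarray:
        return self.first_dose_time + self.interdose_interval_ii * np.arange(self.n_doses)

    @classmethod
    def from_daily_dose(
        cls,
        daily_dose: float,
        interdose_interval_ii: float = 12.0,
        infusion_time_tinf: float = 2.0,
        horizon: float = 96.0,
        first_dose_time: float = 0.0,
    ) -> "DosingRegimen":
        """Build a regimen from a daily dose, with enough doses to span
        ``horizon`` hours."""
        n = max(1, int(math.ceil((horizon - first_dose_time) / interdose_interval_ii)))
        return cls(
            dose_per_admin=daily_dose * interdose_interval_ii / 24.0,
            interdose_interval_ii=interdose_interval_ii,
            infusion_time_tinf=infusion_time_tinf,
            n_doses=n,
            first_dose_time=first_dose_time,
        )


@dataclass(frozen=True)
class SubjectRealization:
    """Individual pharmacokinetic parameters for one simulated subject."""

    cl: float
    q: float
    v1: float
    v2: float
    egfr: float
    eta: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("cl", "q", "v1", "v2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def clearance_for_egfr(pop: PopulationParameters, egfr) -> float | np.ndarray:
    """Population (typical) clearance at a given eGFR.

    CL = theta0 * (eGFR / eGFR_ref) ** theta1, with eGFR_ref = 144.
    """
    egfr = np.asarray(egfr, dtype=float)
    if np.any(egfr <= 0):
        raise ValueError("egfr must be positive")
    out = pop.theta0_cl * (egfr / pop.egfr_ref) ** pop.theta1_cl
    return float(out) if out.ndim == 0 else out


def _hybrid_rates(cl, q, v1, v2):
    """Hybrid rate constants and superposition coefficients.

    All inputs broadcastable arrays.  Returns (alpha, beta, cA, cB) such
    that the concentration from a unit-rate infusion of duration te, at
    time tau >= te after infusion start, is
        (1/v1) * [cA (1 - e^{-a te}) e^{-a (tau-te)}
                  + cB (1 - e^{-b te}) e^{-b (tau-te)}].
    """
    cl = np.asarray(cl, dtype=float)
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    # alpha ~= beta can only arise for contrived parameter sets; nudge k21
    # off the degeneracy rather than carrying the L'Hopital limit form.
    degenerate = np.abs(alpha - beta) / alpha < _DEGENERACY_TOL
    if np.any(degenerate):
        k21 = np.where(degenerate, k21 * (1.0 + _DEGENERACY_PERTURB), k21)
        s = k10 + k12 + k21
        disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
    denom = alpha - beta
    c_a = (alpha - k21) / (alpha * denom)
    c_b = (k21 - beta) / (beta * denom)
    return alpha, beta, c_a, c_b


def _profile(t, dose_times, dose_amts, tinf, cl, q, v1, v2):
    """Central concentration at times ``t`` for vectorized subjects.

    Parameters are broadcast: subject parameter arrays of shape S against
    a time grid of shape T yield an output of shape S x T (or T for scalar
    subjects).  ``dose_times``/``dose_amts``/``tinf`` may be per-subject
    arrays with a trailing dose axis or common 1-D arrays.
    """
    t = np.asarray(t, dtype=float)
    cl, q, v1, v2 = np.broadcast_arrays(
        np.asarray(cl, float), np.asarray(q, float), np.asarray(v1, float), np.asarray(v2, float)
    )
    scalar_subject = cl.ndim == 0
    cl = np.atleast_1d(cl)[:, None]
    q = np.atleast_1d(q)[:, None]
    v1 = np.atleast_1d(v1)[:, None]
    v2 = np.atleast_1d(v2)[:, None]
    alpha, beta, c_a, c_b = _hybrid_rates(cl, q, v1, v2)

    dose_times = np.atleast_1d(np.asarray(dose_times, float))
    dose_amts = np.broadcast_to(np.asarray(dose_amts, float), dose_times.shape)
    tinf_arr = np.broadcast_to(np.asarray(tinf, float), dose_times.shape)

    tt = np.atleast_1d(t)[None, :]
    conc = np.zeros(np.broadcast_shapes(cl.shape, tt.shape), dtype=float)
    for t0, amt, ti in zip(dose_times, dose_amts, tinf_arr):
        if amt == 0.0:
            continue
        tau = tt - t0
        active = tau > 0.0
        if not np.any(active):
            continue
        tau = np.where(active, tau, 0.0)
        te = np.minimum(tau, ti)
        rest = tau - te
        rate = amt / ti
        term = c_a * np.expm1(-alpha * te) * np.exp(-alpha * rest) + c_b * np.expm1(
            -beta * te
        ) * np.exp(-beta * rest)
        conc += np.where(active, -(rate / v1) * term, 0.0)
    if scalar_subject:
        conc = conc[0]
    if t.ndim == 0:
        conc = conc[..., 0] if conc.ndim else conc
        return float(conc) if np.ndim(conc) == 0 else conc
    return conc


def concentration(t, regimen: DosingRegimen, subj: SubjectRealization):
    """Central-compartment concentration (mg/L) at time ``t`` (hours).

    ``t`` may be a scalar or an array; times before the first dose give 0.
    The solution is continuous in t, including at infusion stop.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    return _profile(
        t,
        regimen.dose_times,
        regimen.dose_per_admin,
        regimen.infusion_time_tinf,
        subj.cl,
        subj.q,
        subj.v1,
        subj.v2,
    )


def concentration_profile(grid, regimen: DosingRegimen, subj: SubjectRealization) -> np.ndarray:
    """Vectorized :func:`concentration` over a sorted time grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    return np.atleast_1d(concentration(grid, regimen, subj))


def one_compartment_concentration(t, regimen: DosingRegimen, cl: float, v1: float):
    """Closed-form one-compartment infusion solution (limit Q -> 0)."""
    t = np.asarray(t, dtype=float)
    k = cl / v1
    tt = np.atleast_1d(t)
    conc = np.zeros_like(tt)
    for t0 in np.atleast_1d(regimen.dose_times):
        tau = tt - t0
        active = tau > 0
        if not np.any(active):
            continue
        tau = np.where(active, tau, 0.0)
        te = np.minimum(tau, regimen.infusion_time_tinf)
        rate = regimen.dose_per_admin / regimen.infusion_time_tinf
        conc += np.where(active, (rate / cl) * -np.expm1(-k * te) * np.exp(-k * (tau - te)), 0.0)
    return float(conc[0]) if t.ndim == 0 else conc
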