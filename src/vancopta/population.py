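"""Between-subject variability and residual-error simulation.

Individual parameters follow the lognormal convention beta_i =
theta * exp(eta_i) with eta ~ MVN(0, Sigma); Sigma couples eta_V1 and
eta_CL through a single correlation rho while eta_Q is independent and V2
carries no random effect.

Two residual-error models are provided.  The default, ``eq1_literal``,
applies the noise multiplicatively on the log prediction,

    ln y = ln f * (1 + b * eps),        eps ~ N(0, 1),

so that SD(ln y | f) = b * |ln f| grows with ln f.  The alternative
``conventional_proportional`` model is the usual y = f * (1 + b * eps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pk import DosingRegimen, PopulationParameters, SubjectRealization, _profile, clearance_for_egfr

__all__ = [
    "RandomEffectsSpec",
    "ResidualErrorSpec",
    "sample_eta",
    "sample_individual",
    "sample_individuals",
    "apply_residual_error",
    "simulate_observations",
]


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Log-scale SDs and correlation structure of the random effects."""

    sd_log: tuple[float, float, float]  # (CL, Q, V1)
    rho_v1_cl: float = 0.0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sd_log):
            raise ValueError("sd_log entries must be >= 0")
        if not abs(self.rho_v1_cl) < 1:
            raise ValueError("|rho_v1_cl| must be < 1")

    @classmethod
    def from_population(cls, pop: PopulationParameters) -> "RandomEffectsSpec":
        return cls((pop.omega_cl, pop.omega_q, pop.omega_v1), pop.rho_v1_cl)

    def covariance(self) -> np.ndarray:
        sd = np.asarray(self.sd_log, float)
        corr = np.eye(3)
        corr[0, 2] = corr[2, 0] = self.rho_v1_cl
        cov = corr * np.outer(sd, sd)
        # Cholesky must succeed (possibly on the PSD boundary with zero SDs)
        np.linalg.cholesky(cov + 1e-15 * np.eye(3))
        return cov


@dataclass(frozen=True)
class ResidualErrorSpec:
    b: float
    mode: str = "eq1_literal"

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.mode not in ("eq1_literal", "conventional_proportional"):
            raise ValueError(f"unknown residual error mode {self.mode!r}")


def sample_eta(spec: RandomEffectsSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n rows of eta = (eta_CL, eta_Q, eta_V1) ~ MVN(0, Sigma)."""
    cov = spec.covariance()
    sd = np.asarray(spec.sd_log, float)
    # build via Cholesky of the correlation on the nonzero-SD block so that
    # zero SDs degenerate cleanly to zero columns
    z = rng.standard_normal((n, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(np.outer(sd, sd) > 0, cov / np.outer(sd, sd), np.eye(3))
    lower = np.linalg.cholesky(corr + 1e-15 * np.eye(3))
    return (z @ lower.T) * sd


def individual_parameters(
    pop: PopulationParameters, egfr, eta: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Map eta draws to individual (CL, Q, V1, V2) arrays."""
    eta = np.atleast_2d(eta)
    cl = clearance_for_egfr(pop, egfr) * np.exp(eta[:, 0])
    q = pop.q * np.exp(eta[:, 1])
    v1 = pop.v1 * np.exp(eta[:, 2])
    v2 = np.full_like(np.atleast_1d(cl), pop.v2, dtype=float)
    return np.atleast_1d(cl), q, v1, v2


def sample_individuals(
    pop: PopulationParameters,
    egfr,
    n: int,
    rng_seed=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sample n correlated-lognormal subjects; returns (CL, Q, V1, V2, eta)."""
    rng = np.random.default_rng(rng_seed)
    eta = sample_eta(RandomEffectsSpec.from_population(pop), n, rng)
    cl, q, v1, v2 = individual_parameters(pop, egfr, eta)
    return cl, q, v1, v2, eta


def sample_individual(
    pop: PopulationParameters, egfr: float, rng_seed=None
) -> SubjectRealization:
    """Sample a single subject realization at the given eGFR."""
    if egfr <= 0:
        raise ValueError("egfr must be positive")
    cl, q, v1, v2, eta = sample_individuals(pop, egfr, 1, rng_seed)
    return SubjectRealization(cl=cl[0], q=q[0], v1=v1[0], v2=v2[0], egfr=egfr, eta=eta[0])


def apply_residual_error(f, spec: ResidualErrorSpec, rng_seed=None):
    """Apply the residual-error model to model predictions ``f`` (mg/L)."""
    rng = np.random.default_rng(rng_seed)
    f = np.asarray(f, dtype=float)
    if spec.mode == "eq1_literal" and np.any(f <= 0):
        raise ValueError("eq1_literal residual error requires f > 0 (log undefined)")
    if spec.b == 0.0:
        out = f.copy()
        return float(out) if out.ndim == 0 else out
    eps = rng.standard_normal(f.shape)
    if spec.mode == "eq1_literal":
        y = np.exp(np.log(f) * (1.0 + spec.b * eps))
    else:
        y = np.maximum(f * (1.0 + spec.b * eps), np.finfo(float).tiny)
    return float(y) if y.ndim == 0 else y


def simulate_observations(
    sample_times,
    regimen: DosingRegimen,
    pop: PopulationParameters,
    egfr_values,
    rng_seed=None,
    error_spec: ResidualErrorSpec | None = None,
    blq_limit: float = 3.0,
) -> pd.DataFrame:
    """Simulate one noisy observation table for the given design.

    One row per (subject, time) with the noiseless prediction ``f``, the
    noisy observation ``y``, the covariate and a below-quantification flag.
    Fully reproducible given ``rng_seed``; per-subject substreams keep the
    draws comparable across designs.
    """
    egfr_values = np.atleast_1d(np.asarray(egfr_values, float))
    sample_times = np.asarray(sample_times, float)
    if error_spec is None:
        error_spec = ResidualErrorSpec(b=pop.b)
    n = len(egfr_values)
    seeds = np.random.SeedSequence(rng_seed).spawn(n)
    rows = []
    for i, (egfr, ss) in enumerate(zip(egfr_values, seeds)):
        rng = np.random.default_rng(ss)
        eta = sample_eta(RandomEffectsSpec.from_population(pop), 1, rng)[0]
        cl, q, v1, v2 = (x[0] for x in individual_parameters(pop, egfr, eta))
        f = np.atleast_1d(
            _profile(
                sample_times,
                regimen.dose_times,
                regimen.dose_per_admin,
                regimen.infusion_time_tinf,
                cl,
                q,
                v1,
                v2,
            )
        )
        y = np.zeros_like(f)
        pos = f > 0
        if np.any(pos):
            y[pos] = apply_residual_error(f[pos], error_spec, rng)
        for t, fi, yi in zip(sample_times, f, y):
            rows.append(
                {
                    "ID": i + 1,
                    "TIME": float(t),
                    "F": float(fi),
                    "DV": float(yi),
                    "EGFR": float(egfr),
                    "BLQ": int(yi < blq_limit),
                    "ETA_CL": eta[0],
                    "ETA_Q": eta[1],
                    "ETA_V1": eta[2],
                }
            )
    return pd.DataFrame(rows)
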