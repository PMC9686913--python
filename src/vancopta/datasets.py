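"""Synthetic study-like datasets.

Emulates the clinical sampling design that produced the reference model:
adults with chemotherapy-associated febrile neutropenia receiving 1 g of
vancomycin every 12 h in 2 h infusions, with 7 serum samples per subject
(1, 2, 4, 6, 8 and 10 h after the start of an infusion, plus a trough
30 min before the next dose), drawn around the dose nearest 48 h after
the start of therapy.  Covariates are sampled to match the published
cohort summaries; only eGFR enters the model — the others exercise the
data-format path.

The eGFR SD is back-derived from the reported mean's 95% CI for n = 14
(SE = half-width / t_{13,0.975}, SD = SE * sqrt(14)); this is a
reconstruction, not a reported value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd

from .pk import DosingRegimen, PopulationParameters
from .population import (
    RandomEffectsSpec,
    ResidualErrorSpec,
    apply_residual_error,
    individual_parameters,
    sample_eta,
)
from .pk import _profile

__all__ = ["StudyDesign", "CovariateSampler", "generate_study", "truth_bundle"]

# t_{13, 0.975} for the CI back-derivation
_T13 = 2.160


def _default_sampling_times() -> tuple[float, ...]:
    return (1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 11.5)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of the emulated study."""

    n_subjects: int = 14
    dose_per_admin: float = 1000.0
    interdose_interval_ii: float = 12.0
    infusion_time_tinf: float = 2.0
    sampling_times_after_dose: tuple[float, ...] = field(default_factory=_default_sampling_times)
    sampling_start: float = 48.0  # sample around the dose nearest this time

    def __post_init__(self) -> None:
        if any(t >= self.interdose_interval_ii for t in self.sampling_times_after_dose):
            raise ValueError("sampling times must fall within one interdose interval")

    @property
    def sampling_dose_time(self) -> float:
        k = round(self.sampling_start / self.interdose_interval_ii)
        return k * self.interdose_interval_ii

    def regimen(self) -> DosingRegimen:
        last_obs = self.sampling_dose_time + max(self.sampling_times_after_dose)
        n = int(math.floor(last_obs / self.interdose_interval_ii)) + 1
        return DosingRegimen(
            dose_per_admin=self.dose_per_admin,
            interdose_interval_ii=self.interdose_interval_ii,
            infusion_time_tinf=self.infusion_time_tinf,
            n_doses=n,
        )


@dataclass(frozen=True)
class CovariateSampler:
    """Covariate distributions matched to the cohort summaries."""

    egfr_mean: float = 120.3
    egfr_sd: float = (130.7 - 109.9) / (2 * _T13) * math.sqrt(14)  # ~= 18.0, reconstructed
    egfr_bounds: tuple[float, float] = (60.0, 180.0)
    weight_median: float = 60.0
    weight_log_sd: float = math.log(67.0 / 55.0) / (2 * 0.6745)  # lognormal matched to the IQR
    age_mean: float = 44.0
    age_sd: float = (54.4 - 33.6) / (2 * _T13) * math.sqrt(14)
    age_bounds: tuple[float, float] = (18.0, 90.0)
    p_male: float = 8.0 / 14.0

    def _truncated_normal(self, rng, mean, sd, bounds, n):
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(mean, sd, n)
            ok = draw[(draw >= bounds[0]) & (draw <= bounds[1])]
            take = min(len(ok), n - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
        return out

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "EGFR": self._truncated_normal(rng, self.egfr_mean, self.egfr_sd, self.egfr_bounds, n),
                "WEIGHT": self.weight_median * np.exp(rng.normal(0.0, self.weight_log_sd, n)),
                "AGE": self._truncated_normal(rng, self.age_mean, self.age_sd, self.age_bounds, n),
                "SEX": (rng.uniform(size=n) < self.p_male).astype(int),
            }
        )


def generate_study(
    design: StudyDesign | None = None,
    pop: PopulationParameters | None = None,
    sampler: CovariateSampler | None = None,
    rng_seed=None,
    error_spec: ResidualErrorSpec | None = None,
    blq_limit: float = 3.0,
) -> pd.DataFrame:
    """Generate one study-like dataset in the NONMEM-style dialect.

    Dose rows (EVID=1) for every administration through the sampling
    window are included, so the dataset is self-contained for refitting.
    Deterministic given ``rng_seed``.
    """
    design = design or StudyDesign()
    pop = pop or PopulationParameters()
    sampler = sampler or CovariateSampler()
    if error_spec is None:
        error_spec = ResidualErrorSpec(b=pop.b)
    children = np.random.SeedSequence(rng_seed).spawn(design.n_subjects + 1)
    cov_rng = np.random.default_rng(children[0])
    covs = sampler.sample(design.n_subjects, cov_rng)
    regimen = design.regimen()
    obs_times = design.sampling_dose_time + np.asarray(design.sampling_times_after_dose)
    subject_seeds = children[1:]
    rows = []
    spec = RandomEffectsSpec.from_population(pop)
    for i in range(design.n_subjects):
        rng = np.random.default_rng(subject_seeds[i])
        eta = sample_eta(spec, 1, rng)[0]
        egfr = float(covs.loc[i, "EGFR"])
        cl, q, v1, v2 = (x[0] for x in individual_parameters(pop, egfr, eta))
        f = np.atleast_1d(
            _profile(
                obs_times,
                regimen.dose_times,
                regimen.dose_per_admin,
                regimen.infusion_time_tinf,
                cl,
                q,
                v1,
                v2,
            )
        )
        y = apply_residual_error(f, error_spec, rng)
        common = {
            "EGFR": round(egfr, 6),
            "WEIGHT": round(float(covs.loc[i, "WEIGHT"]), 6),
            "AGE": round(float(covs.loc[i, "AGE"]), 6),
            "SEX": int(covs.loc[i, "SEX"]),
        }
        for t0 in regimen.dose_times:
            rows.append(
                {
                    "ID": i + 1,
                    "TIME": float(t0),
                    "DV": np.nan,
                    "AMT": regimen.dose_per_admin,
                    "RATE": regimen.dose_per_admin / regimen.infusion_time_tinf,
                    "EVID": 1,
                    "MDV": 1,
                    **common,
                }
            )
        for t, yi in zip(obs_times, np.atleast_1d(y)):
            rows.append(
                {
                    "ID": i + 1,
                    "TIME": float(t),
                    "DV": round(float(yi), 8),
                    "AMT": 0.0,
                    "RATE": 0.0,
                    "EVID": 0,
                    "MDV": 0,
                    **common,
                }
            )
    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    df["BLQ"] = ((df["EVID"] == 0) & (df["DV"] < blq_limit)).astype(int)
    return df


def truth_bundle(rng_seed=None, design: StudyDesign | None = None, pop: PopulationParameters | None = None):
    """Dataset plus the ground truth that generated it.

    Returns (observation table, true PopulationParameters, per-subject
    eta table) for parameter-recovery tests.  Regenerating with the same
    seed reproduces the bundle exactly.
    """
    design = design or StudyDesign()
    pop = pop or PopulationParameters()
    table = generate_study(design, pop, rng_seed=rng_seed)
    # recover the per-subject eta from the identical substream layout
    subject_seeds = np.random.SeedSequence(rng_seed).spawn(design.n_subjects + 1)[1:]
    spec = RandomEffectsSpec.from_population(pop)
    etas = []
    for i in range(design.n_subjects):
        rng = np.random.default_rng(subject_seeds[i])
        eta = sample_eta(spec, 1, rng)[0]
        etas.append({"ID": i + 1, "ETA_CL": eta[0], "ETA_Q": eta[1], "ETA_V1": eta[2]})
    return table, pop, pd.DataFrame(etas)
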