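"""Population parameter estimation by stochastic-approximation EM.

The nonlinear mixed-effects model is fitted with a stochastic EM scheme:
a random-walk Metropolis E-step samples the individual random effects
eta_i given the data, and a stochastic-approximation M-step updates the
population parameters from the complete-data estimates.  During burn-in
the step size is 1 and the variance components are simulated-annealed
(never allowed to shrink by more than 5% per iteration) to keep the
sampler exploring; during the smoothing phase the step size decays as
1/k so the estimates average out the Monte-Carlo noise.

The structural model is the closed-form one- or two-compartment infusion
model (``pk``), with clearance tied to eGFR through the power covariate
model and the log-scale residual error of the observation model
ln y = ln f * (1 + b * eps).  V2 carries no random effect and is updated
by a one-dimensional conditional-likelihood search inside the M-step.

The marginal -2 log-likelihood is computed at the end by importance
sampling around the per-subject conditional means, and the BIC penalizes
it with (number of population parameters) * ln(number of subjects).
"""

from __future__ import annotations

from dataclasses import dataclass
import hashlib
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .pk import PopulationParameters

__all__ = [
    "FitResult",
    "SaemEstimator",
    "fit_population",
    "individual_map",
    "gof_metrics",
    "bootstrap_ci",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class FitResult:
    estimates: dict
    population: PopulationParameters | None
    objective: float
    bic: float
    trace: pd.DataFrame
    eta: np.ndarray
    eta_mean: np.ndarray
    n_subjects: int
    n_obs: int
    n_blq_dropped: int
    converged: bool


class _ParsedData:
    """Padded per-subject arrays from a NONMEM-style dataset."""

    def __init__(self, data: pd.DataFrame, blq_limit: float):
        ids = list(dict.fromkeys(data["ID"].tolist()))
        self.ids = ids
        n = len(ids)
        obs_t, obs_y, dose_t, dose_a, dose_ti, egfr = [], [], [], [], [], []
        n_blq = 0
        for sid in ids:
            sub = data[data["ID"] == sid]
            doses = sub[sub["EVID"] == 1]
            if len(doses) == 0:
                raise ValueError(f"subject {sid} has no dose records")
            obs = sub[sub["EVID"] == 0]
            if "MDV" in sub.columns:
                obs = obs[obs["MDV"] == 0]
            keep = obs["DV"].astype(float) >= blq_limit
            n_blq += int((~keep).sum())
            obs = obs[keep]
            if len(obs) == 0:
                raise ValueError(f"subject {sid} has no usable observations")
            obs_t.append(obs["TIME"].to_numpy(float))
            obs_y.append(obs["DV"].to_numpy(float))
            dose_t.append(doses["TIME"].to_numpy(float))
            amt = doses["AMT"].to_numpy(float)
            rate = doses["RATE"].to_numpy(float)
            if np.any(rate <= 0):
                raise ValueError(f"subject {sid} has a dose with non-positive RATE")
            dose_a.append(amt)
            dose_ti.append(amt / rate)
            egfr.append(float(sub["EGFR"].iloc[0]))
        self.n_subjects = n
        self.n_blq_dropped = n_blq
        self.egfr = np.asarray(egfr)
        mo = max(len(t) for t in obs_t)
        md = max(len(t) for t in dose_t)
        self.obs_time = np.zeros((n, mo))
        self.obs_lny = np.zeros((n, mo))
        self.obs_y = np.zeros((n, mo))
        self.obs_mask = np.zeros((n, mo), dtype=bool)
        self.dose_time = np.full((n, md), 1e9)
        self.dose_amt = np.zeros((n, md))
        self.dose_tinf = np.ones((n, md))
        for i in range(n):
            k = len(obs_t[i])
            self.obs_time[i, :k] = obs_t[i]
            self.obs_y[i, :k] = obs_y[i]
            self.obs_lny[i, :k] = np.log(obs_y[i])
            self.obs_mask[i, :k] = True
            kd = len(dose_t[i])
            self.dose_time[i, :kd] = dose_t[i]
            self.dose_amt[i, :kd] = dose_a[i]
            self.dose_tinf[i, :kd] = dose_ti[i]
        self.n_obs = int(self.obs_mask.sum())
        self.mean_dv = float(self.obs_y[self.obs_mask].mean())
        self.max_dv_per_subject = np.array(
            [self.obs_y[i, self.obs_mask[i]].max() for i in range(n)]
        )


def _predict_two_cpt(parsed: _ParsedData, cl, q, v1, v2):
    """Concentration matrix at the padded observation times."""
    cl = cl[:, None]
    q = q[:, None]
    v1 = v1[:, None]
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    denom = np.maximum(alpha - beta, 1e-12)
    c_a = (alpha - k21) / (alpha * denom)
    c_b = (k21 - beta) / (beta * denom)
    conc = np.zeros_like(parsed.obs_time)
    for d in range(parsed.dose_time.shape[1]):
        tau = parsed.obs_time - parsed.dose_time[:, [d]]
        active = (tau > 0) & (parsed.dose_amt[:, [d]] > 0)
        if not np.any(active):
            continue
        tau = np.where(active, tau, 0.0)
        ti = parsed.dose_tinf[:, [d]]
        te = np.minimum(tau, ti)
        rest = tau - te
        rate = parsed.dose_amt[:, [d]] / ti
        term = c_a * np.expm1(-alpha * te) * np.exp(-alpha * rest) + c_b * np.expm1(
            -beta * te
        ) * np.exp(-beta * rest)
        conc += np.where(active, -(rate / v1) * term, 0.0)
    return conc


def _predict_one_cpt(parsed: _ParsedData, cl, v1):
    cl = cl[:, None]
    k = cl / np.asarray(v1)[:, None]
    conc = np.zeros_like(parsed.obs_time)
    for d in range(parsed.dose_time.shape[1]):
        tau = parsed.obs_time - parsed.dose_time[:, [d]]
        active = (tau > 0) & (parsed.dose_amt[:, [d]] > 0)
        if not np.any(active):
            continue
        tau = np.where(active, tau, 0.0)
        ti = parsed.dose_tinf[:, [d]]
        te = np.minimum(tau, ti)
        rate = parsed.dose_amt[:, [d]] / ti
        conc += np.where(active, (rate / cl) * -np.expm1(-k * te) * np.exp(-k * (tau - te)), 0.0)
    return conc


def _loglik_obs(parsed: _ParsedData, conc, b, error_mode):
    """Per-subject observation log-likelihood given predicted conc."""
    f = np.maximum(conc, 1e-10)
    if error_mode == "eq1_literal":
        lnf = np.log(f)
        sd = np.maximum(b * np.abs(lnf), 1e-8)
        z = (parsed.obs_lny - lnf) / sd
        ll = -0.5 * z * z - np.log(sd) - 0.5 * _LOG2PI - parsed.obs_lny
    else:
        sd = np.maximum(b * f, 1e-8)
        z = (parsed.obs_y - f) / sd
        ll = -0.5 * z * z - np.log(sd) - 0.5 * _LOG2PI
    return np.where(parsed.obs_mask, ll, 0.0).sum(axis=1)


class SaemEstimator(BaseEstimator):
    """Stochastic-EM estimator for the population vancomycin model.

    Parameters
    ----------
    n_compartments : 1 or 2.
    n_burn, n_smooth : iterations of the exploratory (step size 1, with
        simulated annealing of the variance terms) and smoothing
        (step size 1/k) phases.
    mh_steps : Metropolis transitions per subject per iteration.
    estimate_theta1 : include the eGFR exponent as a free parameter.
    error_mode : ``eq1_literal`` (default) or ``conventional_proportional``.
    blq_limit : observations below this concentration (mg/L) are dropped
        (count reported in the fit result).
    init : optional dict overriding the data-driven initial values.
    compute_objective : importance-sampling -2LL and BIC at the end.
    """

    def __init__(
        self,
        n_compartments: int = 2,
        n_burn: int = 600,
        n_smooth: int = 300,
        mh_steps: int = 6,
        estimate_theta1: bool = True,
        error_mode: str = "eq1_literal",
        blq_limit: float = 3.0,
        init: dict | None = None,
        compute_objective: bool = True,
        n_importance: int = 300,
        anneal: float = 0.95,
        random_state=None,
    ):
        self.n_compartments = n_compartments
        self.n_burn = n_burn
        self.n_smooth = n_smooth
        self.mh_steps = mh_steps
        self.estimate_theta1 = estimate_theta1
        self.error_mode = error_mode
        self.blq_limit = blq_limit
        self.init = init
        self.compute_objective = compute_objective
        self.n_importance = n_importance
        self.anneal = anneal
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _initial_values(self, parsed: _ParsedData) -> dict:
        # crude mass-balance starting values: CL ~ dosing rate / mean level,
        # V1 ~ dose / peak level
        span = np.maximum(parsed.obs_time.max(axis=1), 12.0)
        rate = parsed.dose_amt.sum(axis=1) / span
        cl0 = float(np.median(rate) / parsed.mean_dv)
        cl0 = min(max(cl0, 0.5), 30.0)
        dose0 = float(np.median(parsed.dose_amt[parsed.dose_amt > 0]))
        v10 = min(max(float(np.median(dose0 / parsed.max_dv_per_subject)), 5.0), 100.0)
        init = {
            "theta0_cl": cl0,
            "theta1_cl": 1.0,
            "q": cl0,
            "v1": v10,
            "v2": v10,
            "omega_cl": 0.3,
            "omega_q": 0.5,
            "omega_v1": 0.3,
            "rho_v1_cl": 0.0,
            "b": 0.1,
        }
        if self.init:
            init.update(self.init)
        return init

    def _mu(self, parsed, th: dict) -> np.ndarray:
        c = np.log(parsed.egfr / 144.0)
        if self.n_compartments == 2:
            mu = np.column_stack(
                [
                    np.log(th["theta0_cl"]) + th["theta1_cl"] * c,
                    np.full(parsed.n_subjects, np.log(th["q"])),
                    np.full(parsed.n_subjects, np.log(th["v1"])),
                ]
            )
        else:
            mu = np.column_stack(
                [
                    np.log(th["theta0_cl"]) + th["theta1_cl"] * c,
                    np.full(parsed.n_subjects, np.log(th["v1"])),
                ]
            )
        return mu

    def _omega(self, th: dict) -> np.ndarray:
        if self.n_compartments == 2:
            sd = np.array([th["omega_cl"], th["omega_q"], th["omega_v1"]])
            corr = np.eye(3)
            corr[0, 2] = corr[2, 0] = th["rho_v1_cl"]
        else:
            sd = np.array([th["omega_cl"], th["omega_v1"]])
            corr = np.eye(2)
            corr[0, 1] = corr[1, 0] = th["rho_v1_cl"]
        return corr * np.outer(sd, sd)

    def _conc(self, parsed, phi, th):
        if self.n_compartments == 2:
            return _predict_two_cpt(
                parsed, np.exp(phi[:, 0]), np.exp(phi[:, 1]), np.exp(phi[:, 2]), th["v2"]
            )
        return _predict_one_cpt(parsed, np.exp(phi[:, 0]), np.exp(phi[:, 1]))

    def _joint_ll(self, parsed, phi, th, omega_inv, omega_logdet):
        """Observation + prior log density per subject for eta = phi - mu."""
        eta = phi - self._mu(parsed, th)
        lp = -0.5 * (np.einsum("ij,jk,ik->i", eta, omega_inv, eta) + omega_logdet)
        ll = _loglik_obs(parsed, self._conc(parsed, phi, th), th["b"], self.error_mode)
        return ll, lp

    # ------------------------------------------------------------------
    def fit(self, data: pd.DataFrame):
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        parsed = _ParsedData(data, self.blq_limit)
        if parsed.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        rng = np.random.default_rng(self.random_state)
        th = self._initial_values(parsed)
        k_eta = 3 if self.n_compartments == 2 else 2
        n = parsed.n_subjects
        c = np.log(parsed.egfr / 144.0)
        var_c = float(np.var(c))
        free_theta1 = self.estimate_theta1 and var_c > 1e-8

        phi = self._mu(parsed, th) + 0.1 * rng.standard_normal((n, k_eta))
        scale = np.full(n, 0.4)
        trace = []
        eta_sum = np.zeros((n, k_eta))
        eta_sq_sum = np.zeros((n, k_eta))
        n_collect = 0

        total = self.n_burn + self.n_smooth
        for it in range(total):
            gamma = 1.0 if it < self.n_burn else 1.0 / (it - self.n_burn + 1)
            omega = self._omega(th)
            lower = np.linalg.cholesky(omega + 1e-10 * np.eye(k_eta))
            omega_inv = np.linalg.inv(omega + 1e-10 * np.eye(k_eta))
            omega_logdet = float(np.linalg.slogdet(omega + 1e-10 * np.eye(k_eta))[1])

            ll, lp = self._joint_ll(parsed, phi, th, omega_inv, omega_logdet)
            acc = np.zeros(n)
            for _ in range(self.mh_steps):
                prop = phi + scale[:, None] * (rng.standard_normal((n, k_eta)) @ lower.T)
                ll_p, lp_p = self._joint_ll(parsed, prop, th, omega_inv, omega_logdet)
                log_alpha = (ll_p + lp_p) - (ll + lp)
                accept = np.log(rng.uniform(size=n)) < log_alpha
                phi = np.where(accept[:, None], prop, phi)
                ll = np.where(accept, ll_p, ll)
                lp = np.where(accept, lp_p, lp)
                acc += accept
            scale *= np.exp(0.4 * (acc / self.mh_steps - 0.3))
            np.clip(scale, 0.01, 5.0, out=scale)

            # ---- complete-data M-step quantities ----
            hat = dict(th)
            phi_cl = phi[:, 0]
            if free_theta1:
                beta = np.polyfit(c, phi_cl, 1)
                hat["theta1_cl"] = float(beta[0])
                hat["theta0_cl"] = float(np.exp(beta[1]))
            else:
                hat["theta0_cl"] = float(np.exp(np.mean(phi_cl - th["theta1_cl"] * c)))
            if self.n_compartments == 2:
                hat["q"] = float(np.exp(phi[:, 1].mean()))
                hat["v1"] = float(np.exp(phi[:, 2].mean()))
            else:
                hat["v1"] = float(np.exp(phi[:, 1].mean()))
            resid = phi - self._mu(parsed, hat)
            cov_hat = resid.T @ resid / n
            conc = self._conc(parsed, phi, th)
            f = np.maximum(conc, 1e-10)
            if self.error_mode == "eq1_literal":
                lnf = np.log(f)
                r = (parsed.obs_lny - lnf) / np.where(np.abs(lnf) > 1e-8, lnf, 1e-8)
            else:
                r = (parsed.obs_y - f) / f
            b2_hat = float(np.mean(r[parsed.obs_mask] ** 2))

            # ---- stochastic approximation with annealing ----
            def blend(old, new):
                return (1.0 - gamma) * old + gamma * new

            th["theta0_cl"] = blend(th["theta0_cl"], hat["theta0_cl"])
            if free_theta1:
                th["theta1_cl"] = blend(th["theta1_cl"], hat["theta1_cl"])
            th["v1"] = blend(th["v1"], hat["v1"])
            if self.n_compartments == 2:
                th["q"] = blend(th["q"], hat["q"])

            idx_v1 = 2 if self.n_compartments == 2 else 1
            var_cl = cov_hat[0, 0]
            var_v1 = cov_hat[idx_v1, idx_v1]
            if it < self.n_burn:  # annealing floor on the variance terms
                var_cl = max(var_cl, self.anneal * th["omega_cl"] ** 2)
                var_v1 = max(var_v1, self.anneal * th["omega_v1"] ** 2)
                b2_hat = max(b2_hat, self.anneal * th["b"] ** 2)
            th["omega_cl"] = float(np.sqrt(blend(th["omega_cl"] ** 2, var_cl)))
            th["omega_v1"] = float(np.sqrt(blend(th["omega_v1"] ** 2, var_v1)))
            if self.n_compartments == 2:
                var_q = cov_hat[1, 1]
                if it < self.n_burn:
                    var_q = max(var_q, self.anneal * th["omega_q"] ** 2)
                th["omega_q"] = float(np.sqrt(blend(th["omega_q"] ** 2, var_q)))
            rho_hat = cov_hat[0, idx_v1] / max(np.sqrt(var_cl * var_v1), 1e-12)
            th["rho_v1_cl"] = float(np.clip(blend(th["rho_v1_cl"], rho_hat), -0.95, 0.95))
            th["b"] = float(np.sqrt(blend(th["b"] ** 2, b2_hat)))

            if self.n_compartments == 2 and (it % 2 == 0 or it >= self.n_burn):
                th_v2 = dict(th)

                def v2_obj(logv2):
                    th_v2["v2"] = float(np.exp(logv2))
                    conc_v2 = self._conc(parsed, phi, th_v2)
                    return -float(
                        _loglik_obs(parsed, conc_v2, th["b"], self.error_mode).sum()
                    )

                res = minimize_scalar(v2_obj, bounds=(0.0, np.log(500.0)), method="bounded")
                th["v2"] = blend(th["v2"], float(np.exp(res.x)))

            if it >= self.n_burn:
                eta = phi - self._mu(parsed, th)
                eta_sum += eta
                eta_sq_sum += eta * eta
                n_collect += 1
            trace.append({"iteration": it, "phase": "burn" if it < self.n_burn else "smooth", **th})

        if not all(np.isfinite(v) for v in th.values()):
            raise RuntimeError("estimation diverged to non-finite parameters")

        eta_mean = eta_sum / max(n_collect, 1)
        eta_var = np.maximum(eta_sq_sum / max(n_collect, 1) - eta_mean**2, 1e-6)
        self.params_ = dict(th)
        objective = bic = float("nan")
        if self.compute_objective:
            objective = self._objective_is(parsed, th, eta_mean, eta_var, rng)
            n_par = (10 if self.n_compartments == 2 else 6) - (0 if free_theta1 else 1)
            bic = objective + n_par * np.log(n)
        population = None
        if self.n_compartments == 2:
            try:
                population = PopulationParameters(
                    theta0_cl=th["theta0_cl"],
                    theta1_cl=th["theta1_cl"],
                    q=th["q"],
                    v1=th["v1"],
                    v2=th["v2"],
                    omega_cl=th["omega_cl"],
                    omega_q=th["omega_q"],
                    omega_v1=th["omega_v1"],
                    rho_v1_cl=th["rho_v1_cl"],
                    b=th["b"],
                )
            except ValueError:
                population = None
        self.result_ = FitResult(
            estimates=dict(th),
            population=population,
            objective=objective,
            bic=bic,
            trace=pd.DataFrame(trace),
            eta=phi - self._mu(parsed, th),
            eta_mean=eta_mean,
            n_subjects=n,
            n_obs=parsed.n_obs,
            n_blq_dropped=parsed.n_blq_dropped,
            converged=True,
        )
        self.objective_ = objective
        self.bic_ = bic
        self.eta_ = self.result_.eta
        self._parsed = parsed
        return self

    def _objective_is(self, parsed, th, eta_mean, eta_var, rng) -> float:
        """-2 log-likelihood by importance sampling around the
        per-subject conditional eta means."""
        n, k_eta = eta_mean.shape
        omega = self._omega(th)
        jitter = 1e-10 * np.eye(k_eta)
        omega_inv = np.linalg.inv(omega + jitter)
        omega_logdet = float(np.linalg.slogdet(omega + jitter)[1])
        prop_sd = np.sqrt(1.5 * eta_var)
        mu = self._mu(parsed, th)
        m = self.n_importance
        ll_draws = np.empty((m, n))
        for j in range(m):
            eta = eta_mean + prop_sd * rng.standard_normal((n, k_eta))
            phi = mu + eta
            ll, lp = self._joint_ll(parsed, phi, th, omega_inv, omega_logdet)
            lq = -0.5 * np.sum(
                ((eta - eta_mean) / prop_sd) ** 2 + 2.0 * np.log(prop_sd) + _LOG2PI, axis=1
            )
            # prior normalization for lp
            lp = lp - 0.5 * k_eta * _LOG2PI
            ll_draws[j] = ll + lp - lq
        ll_subj = logsumexp(ll_draws, axis=0) - np.log(m)
        return float(-2.0 * ll_subj.sum())


def fit_population(
    dataset: pd.DataFrame,
    init: PopulationParameters | dict | None = None,
    rng_seed=None,
    **kwargs,
) -> FitResult:
    """Functional wrapper over :class:`SaemEstimator`."""
    if isinstance(init, PopulationParameters):
        init = {
            "theta0_cl": init.theta0_cl,
            "theta1_cl": init.theta1_cl,
            "q": init.q,
            "v1": init.v1,
            "v2": init.v2,
            "omega_cl": init.omega_cl,
            "omega_q": init.omega_q,
            "omega_v1": init.omega_v1,
            "rho_v1_cl": init.rho_v1_cl,
            "b": init.b,
        }
    est = SaemEstimator(init=init, random_state=rng_seed, **kwargs)
    est.fit(dataset)
    return est.result_


def individual_map(
    pop: PopulationParameters,
    subject_data: pd.DataFrame,
    error_mode: str = "eq1_literal",
    blq_limit: float = 3.0,
):
    """Empirical-Bayes (MAP) random effects for one subject.

    Maximizes p(eta | y) under the population prior and residual model.
    Returns (eta, fitted concentrations, converged flag).
    """
    parsed = _ParsedData(subject_data.assign(ID=subject_data["ID"].iloc[0]), blq_limit)
    est = SaemEstimator(error_mode=error_mode)
    th = {
        "theta0_cl": pop.theta0_cl,
        "theta1_cl": pop.theta1_cl,
        "q": pop.q,
        "v1": pop.v1,
        "v2": pop.v2,
        "omega_cl": pop.omega_cl,
        "omega_q": pop.omega_q,
        "omega_v1": pop.omega_v1,
        "rho_v1_cl": pop.rho_v1_cl,
        "b": pop.b,
    }
    omega = est._omega(th)
    # near-zero prior variances pin eta to 0
    jitter = 1e-12 * np.eye(3)
    omega_inv = np.linalg.inv(omega + jitter)
    mu = est._mu(parsed, th)[0]

    def neg_post(eta):
        phi = (mu + eta)[None, :]
        conc = est._conc(parsed, phi, th)
        ll = _loglik_obs(parsed, conc, th["b"], error_mode)[0]
        return -(ll - 0.5 * eta @ omega_inv @ eta)

    res = minimize(neg_post, np.zeros(3), method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    if not res.success:
        warnings.warn("individual MAP did not fully converge; best iterate returned")
    eta = res.x
    conc = est._conc(parsed, (mu + eta)[None, :], th)[0][parsed.obs_mask[0]]
    return eta, conc, bool(res.success)


def gof_metrics(observations, predictions) -> dict:
    """MAE, MAPE (%) and RMSE between paired vectors.

    Observations equal to zero are excluded from MAPE (count reported).
    """
    obs = np.asarray(observations, float)
    pred = np.asarray(predictions, float)
    if obs.shape != pred.shape:
        raise ValueError("paired vectors must have the same shape")
    err = pred - obs
    nonzero = obs != 0
    return {
        "mae": float(np.mean(np.abs(err))),
        "mape": float(100.0 * np.mean(np.abs(err[nonzero] / obs[nonzero]))),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "n_excluded_mape": int((~nonzero).sum()),
    }


def _content_seed(data: pd.DataFrame, base_seed: int) -> int:
    digest = hashlib.sha256(
        pd.util.hash_pandas_object(data.reset_index(drop=True), index=False).values.tobytes()
    ).digest()
    return (int.from_bytes(digest[:4], "little") ^ int(base_seed)) % (2**31 - 1)


def bootstrap_ci(
    dataset: pd.DataFrame,
    n_boot: int = 200,
    rng_seed=None,
    **fit_kwargs,
) -> dict:
    """Nonparametric bootstrap of the population fit.

    Subjects are resampled with replacement and refitted; per-parameter
    2.5/50/97.5 percentiles are reported.  Each refit's seed is derived
    from the resampled dataset content, so identical resamples produce
    identical fits (and are cached rather than refitted).  Failed refits
    are dropped and counted.
    """
    if n_boot < 50:
        warnings.warn("n_boot < 50 gives unstable percentile intervals")
    rng = np.random.default_rng(rng_seed)
    base_seed = int(rng.integers(0, 2**31 - 1))
    ids = list(dict.fromkeys(dataset["ID"].tolist()))
    cache: dict[int, dict | None] = {}
    samples = []
    n_failed = 0
    for _ in range(n_boot):
        chosen = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for new_id, sid in enumerate(sorted(chosen), start=1):
            sub = dataset[dataset["ID"] == sid].copy()
            sub["ID"] = new_id
            parts.append(sub)
        resampled = pd.concat(parts, ignore_index=True)
        seed = _content_seed(resampled, base_seed)
        if seed not in cache:
            try:
                cache[seed] = fit_population(resampled, rng_seed=seed, **fit_kwargs).estimates
            except Exception:
                cache[seed] = None
        if cache[seed] is None:
            n_failed += 1
        else:
            samples.append(cache[seed])
    if not samples:
        raise RuntimeError("all bootstrap refits failed")
    table = pd.DataFrame(samples)
    summary = table.quantile([0.025, 0.5, 0.975]).T
    summary.columns = ["ci_lo", "median", "ci_hi"]
    return {"table": summary, "n_failed": n_failed, "n_fits": len(cache)}
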