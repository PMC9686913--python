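"""Independent oracles used only by the test suite.

These deliberately avoid the package's closed-form evaluation paths:
the ODE oracle integrates the two-compartment mass-balance system
numerically, and the Shapley oracle applies the combinatorial Shapley
formula directly to enumerated coalition values.
"""

from __future__ import annotations

from math import factorial

import numpy as np
from scipy.integrate import solve_ivp


def ode_concentrations(times, regimen, subj, rtol=1e-10, atol=1e-12):
    """Central concentration by numerical integration of the ODE system.

    dA1/dt = R(t) - (k10 + k12) A1 + k21 A2
    dA2/dt = k12 A1 - k21 A2

    integrated piecewise between infusion start/stop boundaries so the
    discontinuous input never crosses a step.
    """
    times = np.asarray(times, float)
    k10 = subj.cl / subj.v1
    k12 = subj.q / subj.v1
    k21 = subj.q / subj.v2
    rate = regimen.dose_per_admin / regimen.infusion_time_tinf
    windows = [(t0, t0 + regimen.infusion_time_tinf) for t0 in regimen.dose_times]

    def infusing(t):
        return any(lo < t < hi for lo, hi in windows)

    def rhs(t, y, r):
        a1, a2 = y
        return [r - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    t_end = float(times.max())
    bounds = sorted({0.0, t_end} | {b for w in windows for b in w if b < t_end})
    bounds.append(t_end)
    bounds = sorted(set(b for b in bounds if b <= t_end))
    y = np.array([0.0, 0.0])
    out = np.full(times.shape, np.nan)
    mass_ok = True
    infused = 0.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            continue
        r = rate if infusing(0.5 * (lo + hi)) else 0.0
        sol = solve_ivp(
            rhs, (lo, hi), y, args=(r,), dense_output=True, rtol=rtol, atol=atol, method="LSODA"
        )
        sel = (times >= lo) & (times <= hi)
        if np.any(sel):
            out[sel] = sol.sol(times[sel])[0] / subj.v1
        y = sol.y[:, -1]
        infused += r * (hi - lo)
        if y.sum() > infused * (1 + 1e-6):
            mass_ok = False
    out[times <= 0] = 0.0
    assert mass_ok, "ODE oracle mass balance violated: amounts exceed infused dose"
    return out


def shapley_direct(masks: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Exact Shapley values by the combinatorial formula.

    phi_j = sum over S not containing j of
            |S|! (M - |S| - 1)! / M! * (v(S + j) - v(S)).
    """
    m = masks.shape[1]
    lookup = {tuple(mask): v for mask, v in zip(masks.astype(bool).tolist(), values)}
    phi = np.zeros(m)
    for j in range(m):
        for mask, v in lookup.items():
            if mask[j]:
                continue
            s = sum(mask)
            with_j = tuple(x or (i == j) for i, x in enumerate(mask))
            weight = factorial(s) * factorial(m - s - 1) / factorial(m)
            phi[j] += weight * (lookup[with_j] - v)
    return phi
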