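"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's closed-form solver: the ODE oracle
integrates the two-compartment mass-balance system with a stiff adaptive
integrator, and the quadrature oracle evaluates the exact marginal
likelihood of a one-random-effect model by adaptive quadrature.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad, solve_ivp

from polypk.pk_core import DosingRegimen, PKParameters


def ode_concentration(params: PKParameters, regimen: DosingRegimen, times) -> np.ndarray:
    """Central concentration by stiff ODE integration of the 2-cpt system."""
    V = float(np.asarray(params.V))
    V2 = float(np.asarray(params.V2))
    CL = float(np.asarray(params.CL))
    Q = float(np.asarray(params.Q))
    k10, k12, k21 = CL / V, Q / V, Q / V2

    events = sorted(regimen.events, key=lambda e: e.start_time)

    def rate_in(t: float) -> float:
        r = 0.0
        for ev in events:
            if ev.start_time <= t < ev.start_time + ev.duration:
                r += ev.rate
        return r

    def rhs(t, y):
        a1, a2 = y
        return [rate_in(t) - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    times = np.atleast_1d(np.asarray(times, dtype=float))
    t_end = float(times.max())
    # max_step below the shortest infusion keeps the integrator from
    # stepping over rate discontinuities
    sol = solve_ivp(rhs, (0.0, t_end), [0.0, 0.0], method="LSODA",
                    t_eval=times, rtol=1e-10, atol=1e-12, max_step=0.5)
    if not sol.success:
        raise RuntimeError(sol.message)
    return sol.y[0] / V


def ode_auc(params: PKParameters, regimen: DosingRegimen, t0: float, t1: float) -> float:
    """AUC by integrating concentration as a third state variable."""
    V = float(np.asarray(params.V))
    V2 = float(np.asarray(params.V2))
    CL = float(np.asarray(params.CL))
    Q = float(np.asarray(params.Q))
    k10, k12, k21 = CL / V, Q / V, Q / V2
    events = sorted(regimen.events, key=lambda e: e.start_time)

    def rate_in(t: float) -> float:
        r = 0.0
        for ev in events:
            if ev.start_time <= t < ev.start_time + ev.duration:
                r += ev.rate
        return r

    def rhs(t, y):
        a1, a2, _ = y
        return [rate_in(t) - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2, a1 / V]

    sol = solve_ivp(rhs, (0.0, t1), [0.0, 0.0, 0.0], t_eval=[t0, t1], method="LSODA",
                    rtol=1e-10, atol=1e-12, max_step=0.5)
    if not sol.success:
        raise RuntimeError(sol.message)
    return float(sol.y[2][-1] - sol.y[2][0])


def marginal_m2ll_quadrature(y, times, regimen, theta, omega2_cl, sigma) -> float:
    """Exact −2 log marginal likelihood for one subject with a single
    lognormal random effect on clearance and proportional residual error,
    by adaptive quadrature over the random effect."""
    from polypk.pk_core import concentration

    y = np.asarray(y, dtype=float)
    times = np.asarray(times, dtype=float)
    w = np.sqrt(omega2_cl)

    def integrand(eta):
        p = PKParameters(V=theta["V"], V2=theta["V2"], CL=theta["CL"] * np.exp(eta), Q=theta["Q"])
        f = np.asarray(concentration(p, regimen, times), dtype=float)
        var = sigma**2 * f**2
        loglik = -0.5 * np.sum((y - f) ** 2 / var + np.log(2 * np.pi * var))
        prior = -0.5 * (eta**2 / omega2_cl + np.log(2 * np.pi * omega2_cl))
        return np.exp(loglik + prior)

    val, _ = quad(integrand, -8 * w, 8 * w, limit=200, epsabs=1e-13, epsrel=1e-10)
    return -2.0 * np.log(val)
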