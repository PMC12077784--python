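"""Solutions of the illness-death-model prevalence ODEs.

For a chronic condition whose prevalence depends on age only, the partial
differential equation linking prevalence ``p``, incidence ``i`` and the
mortality rates reduces to an ordinary differential equation in age.  Three
forms are solved here, one per mortality scenario:

* non-differential mortality:  ``p' = (1 - p) i``  — closed form;
* diseased + general mortality:  ``p' = i - p (i + m1 - m)`` — integrating
  factor ``exp(G)`` with ``G(a) = ∫ (i + m1 - m)``, the remaining integral
  evaluated by adaptive quadrature;
* general mortality + rate ratio:  ``p' = (1-p) { i - m p (R-1) / (1 + p (R-1)) }``
  — used in the inverse direction, where the plug-in formula recovers ``i``
  from a fitted prevalence surface.

A fixed-step Runge-Kutta forward integrator is provided as an independent
numerical oracle for the analytic forms; it is intended for tests and
cross-checks, not for fitting.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import integrate

from .rates import (
    ExpitPrevalenceSurface,
    GompertzRate,
    MortalityScenario,
    RateRatioCurve,
)

__all__ = [
    "prevalence_nondiff",
    "cumulative_G",
    "prevalence_diff_m1m",
    "incidence_plugin",
    "ode_forward",
    "NegativeIncidenceWarning",
]


class NegativeIncidenceWarning(UserWarning):
    """A plug-in incidence estimate came out negative.

    A negative rate is mathematically possible whenever the fitted prevalence
    declines faster than differential mortality can explain; it diagnoses
    misspecified mortality inputs (or a poorly fitting prevalence model) and
    is therefore reported, never silently clamped.
    """


def _check_initial(a, a0, p0):
    if np.any(np.asarray(a) < a0):
        raise ValueError(f"age a must be >= initial age a0={a0}")
    if not 0.0 <= p0 < 1.0:
        raise ValueError(f"initial prevalence p0 must be in [0, 1), got {p0}")


def prevalence_nondiff(i: GompertzRate, a, a0=20.0, p0=0.0):
    """Prevalence at age ``a`` under non-differential mortality.

    Closed-form solution ``p(a) = 1 - (1 - p0) exp(-∫_{a0}^{a} i)`` of
    ``p' = (1 - p) i`` with ``p(a0) = p0``.  For a Gompertz incidence the
    cumulative hazard has the exponential closed form, so no quadrature is
    involved.

    Parameters
    ----------
    i : GompertzRate
        Age-specific incidence rate.
    a : float or array
        Age(s) at which to evaluate, ``a >= a0``.
    a0, p0 : float
        Initial condition: prevalence ``p0`` at age ``a0``.
    """
    _check_initial(a, a0, p0)
    cum = i.integral(a0, a)
    # -expm1 keeps full precision for small cumulative hazards
    out = -np.expm1(np.log1p(-p0) - cum)
    return float(out) if np.ndim(out) == 0 else out


def cumulative_G(i: GompertzRate, m1: GompertzRate, m: GompertzRate, a, a0=20.0):
    """Cumulative net hazard ``G(a) = ∫_{a0}^{a} (i + m1 - m)(τ) dτ``.

    The integrating factor exponent of the differential-mortality ODE.  Each
    Gompertz component integrates in closed form, so ``G`` is the sum of
    three exponential terms.  May be negative where general mortality
    exceeds ``i + m1``.
    """
    if np.any(np.asarray(a) < a0):
        raise ValueError(f"age a must be >= initial age a0={a0}")
    out = i.integral(a0, a) + m1.integral(a0, a) - m.integral(a0, a)
    return float(out) if np.ndim(out) == 0 else out


def prevalence_diff_m1m(
    i: GompertzRate,
    m1: GompertzRate,
    m: GompertzRate,
    a,
    a0=20.0,
    p0=0.0,
    epsabs=1e-10,
    epsrel=1e-10,
):
    """Prevalence under differential mortality given ``m1`` and ``m``.

    Integrating-factor solution of ``p' = i - p (i + m1 - m)``:

    ``p(a) = exp(-G(a)) { p0 + ∫_{a0}^{a} i(τ) exp(G(τ)) dτ }``

    The inner integral is evaluated by adaptive Gauss-Kronrod quadrature on
    the numerically stable form ``∫ i(τ) exp(G(τ) - G(a)) dτ`` (the exponent
    is kept near zero to avoid overflow); ``G`` itself is closed-form.  When
    the cumulative hazard spans many e-foldings the integrand collapses into
    a boundary layer at ``τ = a``; geometrically spaced break points are then
    passed to the quadrature so the layer cannot be stepped over.

    Note: the solution is a proportion by construction only while the
    mortality inputs are mutually consistent (``m`` at least the diseased
    contribution ``p·m1``); with inconsistent inputs — e.g. rates
    extrapolated far beyond the ages they were estimated from — the exact
    solution can exceed 1 and is returned as computed.

    Raises
    ------
    RuntimeError
        If the quadrature reports a larger error estimate than the requested
        tolerance allows.
    """
    _check_initial(a, a0, p0)
    a_arr = np.atleast_1d(np.asarray(a, dtype=float))
    out = np.empty_like(a_arr)
    for j, aj in enumerate(a_arr):
        if aj == a0:
            out[j] = p0
            continue
        G_a = cumulative_G(i, m1, m, aj, a0)
        saturated = G_a > 30.0
        if saturated:
            # deep saturation (p near 1): solve for the complement
            # q = 1 - p, whose ODE q' = (m1 - m) - q (i + m1 - m) has the
            # same integrating factor but a small, benign integrand, where
            # the direct form would need a boundary layer resolved beyond
            # machine precision
            def integrand(tau, G_a=G_a):
                return (m1(tau) - m(tau)) * np.exp(cumulative_G(i, m1, m, tau, a0) - G_a)
        else:

            def integrand(tau, G_a=G_a):
                return i(tau) * np.exp(cumulative_G(i, m1, m, tau, a0) - G_a)

        points = None
        if G_a > 25.0:
            # geometric break points resolve the exp(G(τ)-G(a)) layer at τ = a
            d = (aj - a0) / 2.0
            points = []
            while d > 1e-9 * (aj - a0):
                points.append(aj - d)
                d /= 3.0
            points = sorted(points)
        val, err = integrate.quad(
            integrand, a0, aj, epsabs=epsabs, epsrel=epsrel, limit=500, points=points
        )
        # fail hard only when the error bound threatens the 1e-6 level at
        # which the solution is certified against the Runge-Kutta oracle;
        # extreme trial parameters during optimization may stop short of
        # the (much tighter) requested tolerance without any consequence
        if err > max(1e-6, abs(val) * 1e-6):
            raise RuntimeError(
                f"quadrature did not converge at a={aj}: "
                f"estimate {val!r}, error bound {err!r}"
            )
        if saturated:
            out[j] = 1.0 - ((1.0 - p0) * np.exp(-G_a) + val)
        else:
            out[j] = p0 * np.exp(-G_a) + val
    return float(out[0]) if np.ndim(a) == 0 else out


def incidence_plugin(
    surface: ExpitPrevalenceSurface,
    t,
    a,
    m: GompertzRate,
    R: RateRatioCurve,
    warn_negative=True,
):
    """Plug-in incidence rate from a fitted prevalence surface.

    Solving the illness-death PDE for the incidence under known general
    mortality ``m`` and rate ratio ``R`` gives

    ``i = (∂t + ∂a)p / (1 - p) + m p (R - 1) / (1 + p (R - 1))``

    and with ``p = expit(f)`` the first term simplifies to ``p · ∂f`` where
    ``∂f = (∂/∂t + ∂/∂a) f``.  Substituting the maximum-likelihood surface
    estimate makes this the plug-in estimator of the incidence rate.

    A negative result is returned as-is with a :class:`NegativeIncidenceWarning`.
    """
    p = surface.prevalence(t, a)
    df = surface.drift(a)
    r = R(a)
    out = p * df + m(a) * p * (r - 1.0) / (1.0 + p * (r - 1.0))
    if warn_negative and np.any(np.asarray(out) < 0.0):
        warnings.warn(
            "plug-in incidence is negative at some ages; "
            "mortality inputs or the prevalence model may be misspecified",
            NegativeIncidenceWarning,
            stacklevel=2,
        )
    return float(out) if np.ndim(out) == 0 else out


def ode_forward(scenario: MortalityScenario, incidence, a0, p0, a_grid, max_step=0.01):
    """Forward-integrate the scenario's prevalence ODE by classic Runge-Kutta.

    Fixed-step fourth-order Runge-Kutta with step at most ``max_step`` years.
    This is a deliberately independent numerical oracle for the closed-form
    and quadrature solutions; use those for anything performance-sensitive.

    Parameters
    ----------
    scenario : MortalityScenario
        Determines the ODE right-hand side.
    incidence : callable
        ``i(a)``, e.g. a :class:`~previnc.rates.GompertzRate`.
    a_grid : array
        Ascending ages starting at ``a0`` at which to report the solution.

    Returns
    -------
    ndarray
        Prevalence at each grid age.
    """
    a_grid = np.asarray(a_grid, dtype=float)
    if a_grid[0] != a0 or np.any(np.diff(a_grid) <= 0):
        raise ValueError("a_grid must be strictly ascending and start at a0")
    rhs = scenario.ode_rhs(incidence)
    # the non-differential and rate-ratio ODEs preserve [0, 1] exactly, so a
    # violation there is a genuine integration failure; the m1/m ODE has no
    # such guarantee when the mortality inputs are mutually inconsistent
    # (typically rates extrapolated beyond their estimation range), so there
    # an excursion is reported but the integration continues
    strict = scenario.variant != "diseased_and_general"
    warned = False
    out = np.empty(len(a_grid))
    out[0] = p = p0
    a = a0
    for j in range(1, len(a_grid)):
        target = a_grid[j]
        n_steps = max(1, int(np.ceil((target - a) / max_step)))
        h = (target - a) / n_steps
        for _ in range(n_steps):
            k1 = rhs(a, p)
            k2 = rhs(a + h / 2, p + h / 2 * k1)
            k3 = rhs(a + h / 2, p + h / 2 * k2)
            k4 = rhs(a + h, p + h * k3)
            p = p + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            a += h
        if p < -1e-9 or p > 1 + 1e-9:
            if strict:
                raise RuntimeError(
                    f"Runge-Kutta solution left [0, 1] at age {a}: p={p!r}; "
                    "the step size or the rates are inconsistent"
                )
            if not warned:
                warnings.warn(
                    f"prevalence solution left [0, 1] at age {a:.1f} (p={p:.4f}); "
                    "the mortality inputs are not mutually consistent there",
                    stacklevel=2,
                )
                warned = True
        a = target
        out[j] = p
    return out
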