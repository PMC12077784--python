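"""Transition-rate primitives of the illness-death model.

The illness-death model for a chronic (irreversible) condition has three
states -- Healthy, Diseased, Dead -- and three transition rates: the
age-specific incidence rate ``i(a)`` (Healthy -> Diseased), the mortality of
the non-diseased ``m0(a)`` and the mortality of the diseased ``m1(a)``.  The
population-average (general) mortality ``m`` is the prevalence-weighted
convex combination ``m = (1-p) m0 + p m1``.

All rates here are per person-year and ages are in years.  Prevalences are
proportions in [0, 1); conversion to percent happens only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "GompertzRate",
    "RateRatioCurve",
    "ExpitPrevalenceSurface",
    "MortalityScenario",
    "expit",
    "logit",
    "m0_from_general",
]


def expit(x):
    """Inverse logit, ``exp(x) / (1 + exp(x))``; maps the real line to (0, 1)."""
    return special.expit(x)


def logit(p):
    """Log-odds ``log(p / (1 - p))``.

    Raises
    ------
    ValueError
        If ``p`` is outside the open interval (0, 1), where the log-odds
        are undefined.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("logit is defined only on the open interval (0, 1)")
    out = special.logit(p)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GompertzRate:
    """A Gompertz (log-linear in age) hazard rate ``exp(intercept + slope * a)``.

    Used for the incidence rate and for the mortality rates of both the
    general and the diseased population; log-linearity in age is the standard
    adult-mortality law and a common parameterization for chronic-disease
    incidence.

    Parameters
    ----------
    intercept : float
        Log rate at age zero (dimensionless on the log scale).
    slope : float
        Change of the log rate per year of age.
    """

    intercept: float
    slope: float

    def __call__(self, a):
        """Evaluate the rate at age ``a`` (scalar or array), per person-year."""
        a = np.asarray(a, dtype=float)
        out = np.exp(self.intercept + self.slope * a)
        return float(out) if out.ndim == 0 else out

    def integral(self, a0, a):
        """Cumulative hazard ``∫_{a0}^{a} exp(intercept + slope·τ) dτ``.

        Closed form ``[exp(intercept + slope·a) - exp(intercept + slope·a0)] / slope``
        with the linear limit ``exp(intercept)·(a - a0)`` when the slope is zero.
        """
        a = np.asarray(a, dtype=float)
        a0 = np.asarray(a0, dtype=float)
        if self.slope == 0.0:
            out = np.exp(self.intercept) * (a - a0)
        else:
            # expm1 form stays accurate as slope -> 0
            out = (
                np.exp(self.intercept + self.slope * a0)
                * np.expm1(self.slope * (a - a0))
                / self.slope
            )
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RateRatioCurve:
    """Mortality rate ratio ``R(a) = m1(a) / m0(a)`` declining log-linearly in age.

    The log-ratio falls from ``log(r_start)`` at the reference age to
    ``log(2)`` after ``halving_span`` years and the curve is floored (the
    relative excess mortality of, e.g., diabetes shrinks with age but never
    drops below parity):

    ``R(a) = max{ exp( log r_start - (a - a_ref) * (log r_start - log 2) / halving_span ), floor }``

    Defaults reproduce the rate-ratio curve transferred from the Danish
    diabetes register: 6.5 at age 20, declining to 2 at age 70, floored at 1.
    """

    r_start: float = 6.5
    a_ref: float = 20.0
    halving_span: float = 50.0
    floor: float = 1.0

    def __post_init__(self):
        if self.r_start < self.floor:
            raise ValueError(
                f"r_start ({self.r_start}) must not be below the floor ({self.floor})"
            )
        if self.floor < 0:
            raise ValueError("floor must be non-negative")
        if self.halving_span <= 0:
            raise ValueError("halving_span must be positive")

    def __call__(self, a):
        a = np.asarray(a, dtype=float)
        log_r = math.log(self.r_start) - (a - self.a_ref) * (
            (math.log(self.r_start) - math.log(2.0)) / self.halving_span
        )
        out = np.maximum(np.exp(log_r), self.floor)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ExpitPrevalenceSurface:
    """Prevalence surface ``p(t, a) = expit(b0 + b1·(t - t_ref) + b2·a + b3·a²)``.

    A logistic-quadratic model of prevalence over calendar time ``t`` and age
    ``a``.  Calendar time enters centered at ``t_ref`` so that the intercept
    refers to the reference year and the drift coefficient ``b1`` is on an
    interpretable per-year scale.
    """

    b0: float
    b1: float
    b2: float
    b3: float
    t_ref: float = 2009.0

    @property
    def params(self) -> np.ndarray:
        return np.array([self.b0, self.b1, self.b2, self.b3])

    def linear_predictor(self, t, a):
        """The linear predictor ``f(t, a)`` on the log-odds scale."""
        t = np.asarray(t, dtype=float)
        a = np.asarray(a, dtype=float)
        out = self.b0 + self.b1 * (t - self.t_ref) + self.b2 * a + self.b3 * a**2
        return float(out) if out.ndim == 0 else out

    def prevalence(self, t, a):
        """Prevalence ``expit(f(t, a))`` in (0, 1)."""
        return expit(self.linear_predictor(t, a))

    def drift(self, a):
        """Directional derivative ``(∂/∂t + ∂/∂a) f = b1 + b2 + 2·b3·a``.

        This is the rate of change of the log-odds along the life-course
        diagonal (one year of calendar time per year of age), the quantity
        the plug-in incidence formula needs.
        """
        a = np.asarray(a, dtype=float)
        out = self.b1 + self.b2 + 2.0 * self.b3 * a
        return float(out) if out.ndim == 0 else out


def m0_from_general(m, p, R):
    """Split the general mortality into non-diseased and diseased rates.

    From ``m = (1-p) m0 + p m1`` and ``R = m1/m0``:
    ``m0 = m / (1 + p (R - 1))`` and ``m1 = R m0``.

    Parameters
    ----------
    m : float or array
        General (all-cause) mortality rate, per person-year.
    p : float or array
        Prevalence of the condition, in [0, 1].
    R : float or array
        Mortality rate ratio ``m1 / m0``, non-negative.

    Returns
    -------
    (m0, m1)
        Mortality of the non-diseased and of the diseased; the convex
        combination ``(1-p) m0 + p m1`` reconstructs ``m`` exactly.
    """
    m = np.asarray(m, dtype=float)
    p = np.asarray(p, dtype=float)
    R = np.asarray(R, dtype=float)
    denom = 1.0 + p * (R - 1.0)
    if np.any(denom <= 0.0):
        raise ValueError("1 + p(R-1) must be positive; inconsistent mortality inputs")
    m0 = m / denom
    m1 = R * m0
    if m0.ndim == 0:
        return float(m0), float(m1)
    return m0, m1


_VARIANTS = ("nondifferential", "diseased_and_general", "general_and_ratio")


@dataclass(frozen=True)
class MortalityScenario:
    """The mortality information available for incidence estimation.

    Three variants, matching what epidemiological practice typically offers:

    ``nondifferential``
        Diseased and non-diseased share one mortality rate; no mortality
        input is needed at all.
    ``diseased_and_general``
        The mortality of the diseased ``m1`` and the general mortality ``m``
        are known (e.g. from paired life tables).
    ``general_and_ratio``
        The general mortality ``m`` and the mortality rate ratio ``R`` are
        known (the most common situation: ``m`` from a statistical office,
        ``R`` transferred from a register study).
    """

    variant: str
    m1: GompertzRate | None = None
    m: GompertzRate | None = None
    R: RateRatioCurve | None = None

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}, got {self.variant!r}")
        if self.variant == "diseased_and_general" and (self.m1 is None or self.m is None):
            raise ValueError("diseased_and_general requires both m1 and m")
        if self.variant == "general_and_ratio" and (self.m is None or self.R is None):
            raise ValueError("general_and_ratio requires both m and R")

    def ode_rhs(self, incidence):
        """Right-hand side ``dp/da`` of the scenario's prevalence ODE.

        Parameters
        ----------
        incidence : callable
            Age-specific incidence rate ``i(a)``.

        Returns
        -------
        callable
            ``f(a, p)`` suitable for an ODE integrator.
        """
        if self.variant == "nondifferential":
            return lambda a, p: (1.0 - p) * incidence(a)
        if self.variant == "diseased_and_general":
            m1, m = self.m1, self.m
            return lambda a, p: incidence(a) - p * (incidence(a) + m1(a) - m(a))
        m, R = self.m, self.R

        def rhs(a, p):
            r = R(a)
            return (1.0 - p) * (
                incidence(a) - m(a) * p * (r - 1.0) / (1.0 + p * (r - 1.0))
            )

        return rhs
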