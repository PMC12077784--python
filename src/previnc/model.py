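"""Maximum-likelihood models for incidence estimation from aggregated prevalence.

The observed counts per age group are modelled as binomial,
``c_k ~ Binomial(n_k, p_k)``, where the group prevalence ``p_k`` is a
deterministic function of the incidence parameters through the
illness-death-model ODE of the chosen mortality scenario.  Three model
classes cover the three scenarios:

* :class:`NonDifferentialIncidenceModel` — Gompertz incidence, closed-form
  prevalence, no mortality input;
* :class:`DifferentialMortalityIncidenceModel` — Gompertz incidence with
  known ``m1`` and ``m`` (quadrature prevalence);
* :class:`PrevalenceSurfaceModel` — logistic-quadratic prevalence surface
  over calendar time and age with known ``m`` and rate ratio ``R``; the
  incidence comes out through the plug-in formula.

Each model's :meth:`fit` maximizes the binomial likelihood kernel by BFGS and
returns a results object with the estimates, the inverse observed Fisher
information as the variance-covariance matrix, Wald confidence intervals and
an age-specific incidence curve with delta-method uncertainty.

The reported log-likelihood is the kernel
``Σ [c_k log p_k + (n_k - c_k) log(1 - p_k)]``: the binomial coefficients do
not depend on the parameters and are omitted throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .data import AggregatedPrevalenceTable
from .prevalence import incidence_plugin, prevalence_diff_m1m, prevalence_nondiff
from .rates import ExpitPrevalenceSurface, GompertzRate, RateRatioCurve, logit

__all__ = [
    "binom_negloglik",
    "fit_ml",
    "wald_ci",
    "delta_method",
    "logit_linear_fit",
    "FitResult",
    "NonDifferentialIncidenceModel",
    "DifferentialMortalityIncidenceModel",
    "PrevalenceSurfaceModel",
    "GompertzIncidenceResults",
    "PrevalenceSurfaceResults",
]

_PENALTY = 1e10


def binom_negloglik(p, n, c):
    """Negative binomial log-likelihood kernel for aggregated counts.

    ``-Σ [c_k log p_k + (n_k - c_k) log(1 - p_k)]`` — the parameter-free
    binomial coefficients are omitted.  A prevalence of exactly 0 (with
    ``c_k > 0``) or 1 (with ``c_k < n_k``) has likelihood zero; to keep
    quasi-Newton optimizers moving, such points return a large finite
    penalty (1e10) instead of infinity.
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    c = np.asarray(c, dtype=float)
    if p.shape != n.shape or p.shape != c.shape:
        raise ValueError("p, n, c must have identical shapes")
    invalid = ((p <= 0.0) & (c > 0)) | ((p >= 1.0) & (c < n)) | ~np.isfinite(p)
    if np.any(invalid):
        return _PENALTY
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(c > 0, c * np.log(p), 0.0) + np.where(
            n - c > 0, (n - c) * np.log1p(-p), 0.0
        )
    return float(-terms.sum())


@dataclass(frozen=True)
class FitResult:
    """Raw optimizer output: estimates, curvature-based vcov, diagnostics."""

    params: np.ndarray
    vcov: np.ndarray
    llf: float
    converged: bool
    nfev: int
    message: str

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def bse(self) -> np.ndarray:
        """Standard errors from the vcov diagonal."""
        return np.sqrt(np.diag(self.vcov))


def _hessian_central(f, x, rel_step=1e-5):
    """Central-finite-difference Hessian with per-parameter steps.

    Step for parameter j is ``max(rel_step, rel_step * |x_j|)`` — the
    absolute floor matters because parameters can span several orders of
    magnitude (a surface curvature coefficient near 1e-3 next to an
    intercept near -10).
    """
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = np.maximum(rel_step, rel_step * np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _hessian_from_grad(grad, x, rel_step=1e-5):
    """Central differences of an analytic gradient, symmetrized.

    Differencing the gradient loses far less precision than differencing the
    objective twice, which matters when the information matrix is
    ill-conditioned (covariate columns on very different scales).
    """
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = np.maximum(rel_step, rel_step * np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i] = (np.asarray(grad(x + ei)) - np.asarray(grad(x - ei))) / (2.0 * h[i])
    return (H + H.T) / 2.0


def fit_ml(objective, init, grad=None, gtol=1e-8, max_restarts=3, seed=0):
    """Minimize a negative log-likelihood by BFGS and invert the Hessian.

    On non-convergence the optimization is restarted from slightly jittered
    initial values (deterministic jitter).  The variance-covariance matrix is
    the inverse of the central-finite-difference Hessian of the objective at
    the optimum (the inverse observed Fisher information).

    Parameters
    ----------
    grad : callable, optional
        Analytic gradient of the objective; finite differences otherwise.

    Raises
    ------
    RuntimeError
        If no restart converges, or the Hessian is not invertible (flat
        likelihood).
    """
    init = np.asarray(init, dtype=float)
    if not np.isfinite(objective(init)):
        raise ValueError("objective must be finite at the initial values")
    rng = np.random.default_rng(seed)
    trace = []
    res = None

    def _grad_ok(r):
        # BFGS often stops on 'precision loss' with the optimum in hand;
        # accept any point whose gradient is numerically negligible relative
        # to the likelihood scale
        return np.max(np.abs(r.jac)) < 1e-4 * max(1.0, abs(r.fun))

    for attempt in range(max_restarts + 1):
        x0 = init if attempt == 0 else init * (1 + 0.05 * rng.standard_normal(len(init)))
        res = optimize.minimize(
            objective, x0, jac=grad, method="BFGS", options={"gtol": gtol}
        )
        trace.append(f"attempt {attempt}: {res.message} (nfev={res.nfev})")
        if res.success or _grad_ok(res):
            break
    converged = bool(res.success or _grad_ok(res))
    if not converged:
        raise RuntimeError("optimization failed after restarts:\n" + "\n".join(trace))
    H = _hessian_from_grad(grad, res.x) if grad is not None else _hessian_central(objective, res.x)
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("Hessian is singular: the likelihood is flat "
                           "in some parameter direction") from exc
    if np.any(np.diag(vcov) < 0):
        warnings.warn(
            "negative variance from the inverted Hessian; the reported optimum "
            "may be a saddle point", stacklevel=2,
        )
    return FitResult(
        params=res.x,
        vcov=vcov,
        llf=-float(res.fun),
        converged=converged,
        nfev=int(res.nfev),
        message=str(res.message),
    )


def wald_ci(fit: FitResult, index: int, level: float = 0.95):
    """Wald interval ``estimate ± z_{(1+level)/2} · se`` for one parameter."""
    var = fit.vcov[index, index]
    if var < 0:
        raise ValueError(f"negative variance for parameter {index}; invalid fit")
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(var)
    point = fit.params[index]
    return point - z * se, point + z * se


def delta_method(gradient, vcov):
    """First-order variance of a smooth transform: ``gᵀ V g``.

    ``gradient`` holds the partial derivatives of the transform with respect
    to each parameter, evaluated at the estimate.
    """
    gradient = np.asarray(gradient, dtype=float)
    vcov = np.asarray(vcov, dtype=float)
    if gradient.shape[-1] != vcov.shape[0] or vcov.shape[0] != vcov.shape[1]:
        raise ValueError("gradient length must match the vcov dimension")
    return float(gradient @ vcov @ gradient)


def logit_linear_fit(table: AggregatedPrevalenceTable):
    """Descriptive OLS of the observed log-odds on the group midpoint age.

    Fits ``logit(c_k / n_k) = b0 + b1 · a_k`` by least squares.  Used for
    initialization and as a quick descriptive incidence estimate
    (``i(a) ≈ b1 · p(a)`` under non-differential mortality).
    """
    props = table.proportions
    if np.any((props <= 0) | (props >= 1)):
        raise ValueError("logit undefined: some groups have c=0 or c=n")
    y = logit(props)
    a = table.midpoints
    X = np.column_stack([np.ones_like(a), a])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[0]), float(coef[1])


def _incidence_curve_gompertz(fit: FitResult, ages, level):
    """Incidence curve with delta-method CIs for log-linear incidence.

    The log incidence ``log i(a) = γ0 + γ1 a`` is linear in the parameters,
    so its variance is exact (not just first-order): ``(1, a) V (1, a)ᵀ``.
    The interval is formed on the log scale and exponentiated, which keeps
    the bounds positive.
    """
    import pandas as pd

    ages = np.asarray(ages, dtype=float)
    z = stats.norm.ppf(0.5 + level / 2.0)
    g0, g1 = fit.params
    log_i = g0 + g1 * ages
    var_log = np.array([delta_method([1.0, a], fit.vcov) for a in ages])
    se_log = np.sqrt(var_log)
    inc = np.exp(log_i)
    return pd.DataFrame(
        {
            "age": ages,
            "incidence": inc,
            "se": inc * se_log,  # delta method back to the rate scale
            "ci_lower": np.exp(log_i - z * se_log),
            "ci_upper": np.exp(log_i + z * se_log),
        }
    )


class _ResultsBase:
    """Shared results surface: params, bse, conf_int, summary."""

    def __init__(self, model, fit: FitResult):
        self.model = model
        self._fit = fit

    @property
    def params(self) -> np.ndarray:
        return self._fit.params

    @property
    def vcov(self) -> np.ndarray:
        return self._fit.vcov

    @property
    def bse(self) -> np.ndarray:
        return self._fit.bse

    @property
    def llf(self) -> float:
        return self._fit.llf

    @property
    def converged(self) -> bool:
        return self._fit.converged

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Wald intervals, one row per parameter."""
        return np.array([wald_ci(self._fit, i, level) for i in range(self._fit.n_params)])

    def summary(self, level: float = 0.95) -> str:
        ci = self.conf_int(level)
        lines = [
            f"{type(self.model).__name__} results",
            f"  log-likelihood kernel: {self.llf:.4f}",
            f"  converged: {self.converged}   function evals: {self._fit.nfev}",
            "",
            f"  {'param':>8} {'estimate':>12} {'std err':>10} "
            f"{f'[{level:.0%} conf int]':>24}",
        ]
        for name, est, se, (lo, hi) in zip(self.param_names, self.params, self.bse, ci):
            lines.append(f"  {name:>8} {est:>12.5g} {se:>10.4g} {lo:>12.5g} {hi:>11.5g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-ready export of estimates and fit diagnostics."""
        return {
            "param_names": list(self.param_names),
            "params": self.params.tolist(),
            "bse": self.bse.tolist(),
            "vcov": self.vcov.tolist(),
            "conf_int": self.conf_int().tolist(),
            "loglik_kernel": self.llf,
            "converged": self.converged,
        }


class GompertzIncidenceResults(_ResultsBase):
    """Results for the Gompertz-incidence scenarios (parameters γ0, γ1)."""

    param_names = ("gamma0", "gamma1")

    @property
    def incidence_rate(self) -> GompertzRate:
        """The fitted incidence rate ``exp(γ0 + γ1 a)``."""
        return GompertzRate(*map(float, self.params))

    def incidence(self, ages=None, level: float = 0.95):
        """Age-specific incidence with delta-method confidence band.

        Defaults to the group midpoints of the model's table.
        """
        if ages is None:
            ages = self.model.table.midpoints
        return _incidence_curve_gompertz(self._fit, ages, level)

    def fitted_prevalence(self, ages=None) -> np.ndarray:
        if ages is None:
            ages = self.model.table.midpoints
        return self.model.predict_prevalence(self.params, ages)

    def plot_incidence(self, ages=None, ax=None, level: float = 0.95):
        """Minimal incidence-curve figure: point estimates with a CI band."""
        import matplotlib.pyplot as plt

        curve = self.incidence(ages, level)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve["age"], curve["incidence"], color="black")
        ax.fill_between(curve["age"], curve["ci_lower"], curve["ci_upper"], alpha=0.3)
        ax.set_xlabel("age (years)")
        ax.set_ylabel("incidence rate (per person-year)")
        return ax


class NonDifferentialIncidenceModel:
    """ML incidence estimation assuming equal mortality with and without disease.

    Under non-differential mortality the prevalence ODE has the closed-form
    solution ``p(a) = 1 - (1-p0) exp(-∫ i)``; with a Gompertz incidence
    ``i(a) = exp(γ0 + γ1 a)`` the whole likelihood is analytic and the fit
    takes milliseconds.

    Parameters
    ----------
    table : AggregatedPrevalenceTable
        Aggregated current-status counts.
    a0, p0 : float
        Initial condition (age below which the condition does not occur and
        the prevalence there); defaults 20 years / 0.
    """

    def __init__(self, table: AggregatedPrevalenceTable, a0: float = 20.0, p0: float = 0.0):
        if table.midpoints.min() < a0:
            raise ValueError("a0 must not exceed the first group midpoint")
        self.table = table
        self.a0 = a0
        self.p0 = p0

    def predict_prevalence(self, params, ages) -> np.ndarray:
        return np.asarray(
            prevalence_nondiff(GompertzRate(*map(float, params)), ages, self.a0, self.p0)
        )

    def negloglik(self, params) -> float:
        p = self.predict_prevalence(params, self.table.midpoints)
        return binom_negloglik(p, self.table.n, self.table.c)

    def default_start_params(self) -> np.ndarray:
        # the descriptive logit line is an excellent starting point: under
        # the model, log i ≈ logit p up to curvature
        try:
            b0, b1 = logit_linear_fit(self.table)
            return np.array([b0, max(b1, 1e-3)])
        except ValueError:
            return np.array([-7.0, 0.05])

    def fit(self, start_params=None) -> GompertzIncidenceResults:
        if start_params is None:
            start_params = self.default_start_params()
        return GompertzIncidenceResults(self, fit_ml(self.negloglik, start_params))


class DifferentialMortalityIncidenceModel:
    """ML incidence estimation with known diseased and general mortality.

    The prevalence solves ``p' = i - p (i + m1 - m)``; the likelihood calls
    the integrating-factor solution (adaptive quadrature) at every group
    midpoint, so a fit costs seconds rather than milliseconds.

    Parameters
    ----------
    table : AggregatedPrevalenceTable
    m1 : GompertzRate
        Mortality of the diseased.
    m : GompertzRate
        General (all-cause) mortality.
    a0, p0 : float
        Initial condition.
    """

    def __init__(
        self,
        table: AggregatedPrevalenceTable,
        m1: GompertzRate,
        m: GompertzRate,
        a0: float = 20.0,
        p0: float = 0.0,
    ):
        if table.midpoints.min() < a0:
            raise ValueError("a0 must not exceed the first group midpoint")
        self.table = table
        self.m1 = m1
        self.m = m
        self.a0 = a0
        self.p0 = p0

    def predict_prevalence(self, params, ages) -> np.ndarray:
        return np.atleast_1d(
            prevalence_diff_m1m(
                GompertzRate(*map(float, params)), self.m1, self.m, ages, self.a0, self.p0
            )
        )

    def negloglik(self, params) -> float:
        p = self.predict_prevalence(params, self.table.midpoints)
        return binom_negloglik(p, self.table.n, self.table.c)

    def default_start_params(self) -> np.ndarray:
        # start from the non-differential optimum: cheap and close
        return NonDifferentialIncidenceModel(self.table, self.a0, self.p0).fit().params

    def fit(self, start_params=None) -> GompertzIncidenceResults:
        if start_params is None:
            start_params = self.default_start_params()
        return GompertzIncidenceResults(self, fit_ml(self.negloglik, start_params))


class PrevalenceSurfaceResults(_ResultsBase):
    """Results for the logistic-quadratic prevalence surface (β0..β3)."""

    param_names = ("beta0", "beta1", "beta2", "beta3")

    @property
    def surface(self) -> ExpitPrevalenceSurface:
        return ExpitPrevalenceSurface(*map(float, self.params), t_ref=self.model.t_ref)

    def incidence(self, ages=None, year=None, level: float = 0.95):
        """Plug-in incidence per age with delta-method confidence intervals.

        The incidence at each age is a smooth function of the four surface
        coefficients; its gradient is taken by central finite differences
        and propagated through the vcov.  Intervals are normal-based on the
        rate scale, so a very uncertain estimate can have a negative lower
        bound.  Rows where the point estimate itself is negative are flagged.
        """
        import pandas as pd

        model = self.model
        if ages is None:
            ages = np.unique(model.table.midpoints)
        ages = np.asarray(ages, dtype=float)
        year = model.t_ref if year is None else year
        z = stats.norm.ppf(0.5 + level / 2.0)

        def inc_at(params, a):
            surf = ExpitPrevalenceSurface(*map(float, params), t_ref=model.t_ref)
            return incidence_plugin(surf, year, a, model.m, model.R, warn_negative=False)

        point = np.array([inc_at(self.params, a) for a in ages])
        se = np.empty_like(point)
        h = np.maximum(1e-6, 1e-6 * np.abs(self.params))
        for idx, a in enumerate(ages):
            grad = np.empty(4)
            for j in range(4):
                step = np.zeros(4)
                step[j] = h[j]
                grad[j] = (inc_at(self.params + step, a) - inc_at(self.params - step, a)) / (
                    2.0 * h[j]
                )
            se[idx] = np.sqrt(delta_method(grad, self.vcov))
        flagged = point < 0
        if flagged.any():
            warnings.warn(
                f"negative plug-in incidence at ages {ages[flagged].tolist()}",
                stacklevel=2,
            )
        return pd.DataFrame(
            {
                "age": ages,
                "incidence": point,
                "se": se,
                "ci_lower": point - z * se,
                "ci_upper": point + z * se,
                "flagged": flagged,
            }
        )

    def plot_incidence(self, ages=None, year=None, ax=None, level: float = 0.95):
        """Point estimates with vertical CI bars, one per age midpoint."""
        import matplotlib.pyplot as plt

        curve = self.incidence(ages, year, level)
        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(
            curve["age"],
            curve["incidence"],
            yerr=[curve["incidence"] - curve["ci_lower"], curve["ci_upper"] - curve["incidence"]],
            fmt="o",
            color="black",
            capsize=2,
        )
        ax.set_xlabel("age (years)")
        ax.set_ylabel("incidence rate (per person-year)")
        return ax


class PrevalenceSurfaceModel:
    """Joint ML fit of a prevalence surface over several calendar years.

    Models ``p(t, a) = expit(β0 + β1 (t - t_ref) + β2 a + β3 a²)`` with the
    binomial likelihood taken over every (year, age-group) cell.  Requires
    the general mortality ``m`` and the mortality rate ratio ``R`` — the
    most commonly available mortality information — which enter not the fit
    itself but the plug-in incidence computed from the fitted surface.

    Parameters
    ----------
    table : AggregatedPrevalenceTable
        Must carry a ``year`` column (a single year is allowed, but then the
        drift coefficient β1 is unidentified and should be fixed at 0 via
        ``start_params`` — with one year the likelihood does not constrain it).
    m : GompertzRate
        General mortality.
    R : RateRatioCurve
        Mortality rate ratio of diseased over non-diseased.
    t_ref : float
        Reference calendar year; time enters as ``t - t_ref``.
    """

    DEFAULT_START = np.array([-2.3, 0.1, 0.0, -0.001])

    def __init__(
        self,
        table: AggregatedPrevalenceTable,
        m: GompertzRate,
        R: RateRatioCurve,
        t_ref: float | None = None,
    ):
        if table.year is None:
            raise ValueError("table must have a year column for the surface model")
        self.table = table
        self.m = m
        self.R = R
        self.t_ref = float(table.year.min()) if t_ref is None else float(t_ref)

    def predict_prevalence(self, params, years, ages) -> np.ndarray:
        surf = ExpitPrevalenceSurface(*map(float, params), t_ref=self.t_ref)
        return np.asarray(surf.prevalence(years, ages))

    def negloglik(self, params) -> float:
        t = self.table
        p = self.predict_prevalence(params, t.year, t.midpoints)
        return binom_negloglik(p, t.n, t.c)

    def _design(self) -> np.ndarray:
        t = self.table
        a = t.midpoints
        return np.column_stack([np.ones_like(a), t.year - self.t_ref, a, a**2])

    def score(self, params) -> np.ndarray:
        """Analytic gradient of the negative log-likelihood kernel.

        For the logistic link the score has the standard GLM form
        ``Σ_k (n_k p_k - c_k) x_k``; supplying it keeps BFGS stable despite
        the strong curvature imbalance between the intercept and the
        quadratic age coefficient.
        """
        t = self.table
        p = self.predict_prevalence(params, t.year, t.midpoints)
        return self._design().T @ (t.n * p - t.c)

    def fit(self, start_params=None) -> PrevalenceSurfaceResults:
        if start_params is None:
            start_params = self.DEFAULT_START
        return PrevalenceSurfaceResults(
            self, fit_ml(self.negloglik, start_params, grad=self.score)
        )
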