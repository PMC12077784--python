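"""Gompertz mortality estimation from abridged (5-year) life tables.

Single-decrement theory converts the survivor column into one-year death
probabilities: if ``Sx_k`` people are alive at the start of group k, the
5-year survival ratio is ``Sx_{k+1} / Sx_k`` and the one-year probability of
dying is

    q1_k = 1 - (Sx_{k+1} / Sx_k)^(1/5)

assigned to the group midpoint.  A log-linear ("Gompertz") regression
``log q1 = b0 + b1 * a`` then yields a smooth mortality rate function; at the
small annual probabilities typical of working ages the probability and the
rate coincide to first order, so the fitted line is used directly as the log
mortality rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import SurvivorTable
from .rates import GompertzRate

__all__ = ["annual_death_probabilities", "fit_gompertz_mortality", "gompertz_from_lifetable"]


def annual_death_probabilities(table: SurvivorTable, population: str) -> pd.DataFrame:
    """One-year death probabilities from a 5-year survivor column.

    Returns a DataFrame with columns ``age`` (group midpoint) and ``q1``; the
    last group has no successor and is dropped, so the result has one row
    fewer than the table.
    """
    if population not in table.survivors:
        raise KeyError(
            f"population {population!r} not in table; available: {table.populations}"
        )
    if table.n_groups < 2:
        raise ValueError("need at least two age groups to compute death probabilities")
    s = table.survivors[population]
    w = table.group_width
    ratio = s[1:] / s[:-1]  # 5-year survival per group
    q1 = 1.0 - ratio ** (1.0 / w)
    ages = table.age_start[:-1] + w / 2.0
    return pd.DataFrame({"age": ages, "q1": q1})


def fit_gompertz_mortality(points: pd.DataFrame) -> GompertzRate:
    """Ordinary least squares of ``log(q1)`` on age.

    Parameters
    ----------
    points : DataFrame
        Columns ``age`` and ``q1`` with ``q1 > 0`` (as returned by
        :func:`annual_death_probabilities`).

    Returns
    -------
    GompertzRate
        Fitted mortality rate ``exp(intercept + slope * a)``.
    """
    age = np.asarray(points["age"], dtype=float)
    q1 = np.asarray(points["q1"], dtype=float)
    if len(age) < 3:
        raise ValueError("need at least three points for a stable Gompertz fit")
    if np.any(q1 <= 0):
        raise ValueError("all death probabilities must be positive for the log fit")
    if np.ptp(age) == 0:
        raise ValueError("all ages identical; the regression design is singular")
    res = sm.OLS(np.log(q1), sm.add_constant(age)).fit()
    return GompertzRate(intercept=float(res.params[0]), slope=float(res.params[1]))


def gompertz_from_lifetable(table: SurvivorTable, population: str) -> GompertzRate:
    """Convenience: survivor column -> one-year probabilities -> Gompertz fit."""
    return fit_gompertz_mortality(annual_death_probabilities(table, population))
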