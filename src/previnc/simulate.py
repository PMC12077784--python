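"""Synthetic aggregated current-status data from known incidence and mortality.

The generator forward-simulates the exact generative model the estimators
assume: group prevalences come from the mortality scenario's own prevalence
solution evaluated at the group midpoints, and counts are independent
binomial draws per (year, age-group) cell.  That makes it the right tool for
parameter-recovery experiments and Wald-interval coverage studies — and also
means it shares the estimators' assumptions (no shared-cohort correlation
between age groups, no secular mortality trends, no remission), so agreement
says nothing about those.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AggregatedPrevalenceTable
from .prevalence import prevalence_diff_m1m, prevalence_nondiff
from .rates import ExpitPrevalenceSurface, GompertzRate, MortalityScenario

__all__ = ["SimulationDesign", "simulate_counts", "recovery_experiment", "default_groups"]


def default_groups(start=20, stop=65, width=5):
    """5-year group bounds ``[(20, 24), (25, 29), ...]`` up to ``stop`` (exclusive)."""
    return [(lo, lo + width - 1) for lo in range(start, stop, width)]


@dataclass(frozen=True)
class SimulationDesign:
    """Everything needed to draw one synthetic prevalence table.

    Parameters
    ----------
    truth : GompertzRate or ExpitPrevalenceSurface
        The generating incidence rate (Gompertz scenarios) or the generating
        prevalence surface (rate-ratio scenario).
    scenario : MortalityScenario
        Mortality structure; decides which prevalence solution is used.
    group_bounds : list of (lower, upper)
        Closed integer age-group bounds.
    n_per_group : int or sequence
        Persons observed per group (scalar broadcasts to all groups and years).
    years : sequence of int, optional
        Calendar years to simulate (surface scenario); omit for cross-sectional.
    a0, p0 : float
        Initial condition of the prevalence ODE (Gompertz scenarios).
    seed : int
        Seeds the bit generator; identical designs are reproducible
        bit-for-bit.
    """

    truth: object
    scenario: MortalityScenario
    group_bounds: tuple = tuple(default_groups())
    n_per_group: object = 2000
    years: tuple | None = None
    a0: float = 20.0
    p0: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "group_bounds", tuple(map(tuple, self.group_bounds)))
        if self.years is not None:
            object.__setattr__(self, "years", tuple(self.years))
        n = np.broadcast_to(np.asarray(self.n_per_group), (len(self.group_bounds),))
        if np.any(n < 1):
            raise ValueError("n_per_group must be >= 1")

    @property
    def midpoints(self) -> np.ndarray:
        b = np.asarray(self.group_bounds)
        return (b[:, 0] + b[:, 1] + 1) / 2.0

    def true_prevalence(self, year=None) -> np.ndarray:
        """Group-midpoint prevalences under the generating model."""
        mid = self.midpoints
        v = self.scenario.variant
        if v == "general_and_ratio":
            if not isinstance(self.truth, ExpitPrevalenceSurface):
                raise TypeError("general_and_ratio design needs an ExpitPrevalenceSurface truth")
            year = self.truth.t_ref if year is None else year
            return np.asarray(self.truth.prevalence(year, mid))
        if not isinstance(self.truth, GompertzRate):
            raise TypeError(f"{v} design needs a GompertzRate truth")
        if v == "nondifferential":
            return np.asarray(prevalence_nondiff(self.truth, mid, self.a0, self.p0))
        return np.asarray(
            prevalence_diff_m1m(self.truth, self.scenario.m1, self.scenario.m, mid, self.a0, self.p0)
        )


def simulate_counts(design: SimulationDesign) -> AggregatedPrevalenceTable:
    """Draw one aggregated prevalence table from the design's generative model.

    ``c_k ~ Binomial(n_k, p_k)`` independently per cell, with ``p_k`` the
    scenario's prevalence solution at the group midpoint.  Deterministic
    given the design (including its seed).
    """
    rng = np.random.default_rng(design.seed)
    bounds = np.asarray(design.group_bounds)
    n = np.broadcast_to(np.asarray(design.n_per_group), (len(bounds),)).astype(int)
    years = design.years
    blocks = []
    for year in years if years is not None else [None]:
        p = design.true_prevalence(year)
        if np.any((p < 0) | (p >= 1)):
            raise ValueError("design produces prevalences outside [0, 1); inconsistent inputs")
        c = rng.binomial(n, p)
        blocks.append((year, c))
    k = len(bounds)
    return AggregatedPrevalenceTable(
        np.tile(bounds[:, 0], len(blocks)),
        np.tile(bounds[:, 1], len(blocks)),
        np.tile(n, len(blocks)),
        np.concatenate([c for _, c in blocks]),
        None if years is None else np.repeat([y for y, _ in blocks], k),
    )


def _make_estimator(design: SimulationDesign, estimator: str):
    # local import: simulate must stay importable without the model layer
    from .model import (
        DifferentialMortalityIncidenceModel,
        NonDifferentialIncidenceModel,
        PrevalenceSurfaceModel,
    )

    if estimator == "nondifferential":
        return lambda tab: NonDifferentialIncidenceModel(tab, design.a0, design.p0).fit()
    if estimator == "diseased_and_general":
        return lambda tab: DifferentialMortalityIncidenceModel(
            tab, design.scenario.m1, design.scenario.m, design.a0, design.p0
        ).fit()
    if estimator == "general_and_ratio":
        return lambda tab: PrevalenceSurfaceModel(
            tab, design.scenario.m, design.scenario.R, t_ref=design.truth.t_ref
        ).fit()
    raise ValueError(f"unknown estimator {estimator!r}")


def recovery_experiment(
    design: SimulationDesign, n_replicates: int, estimator: str | None = None
) -> pd.DataFrame:
    """Repeated simulate-and-refit: bias, RMSE and Wald-interval coverage.

    Replicate ``r`` uses seed ``design.seed + r``, so any slice of the
    replicate range can be re-run independently.  Estimator failures are
    counted (``attrs['n_failed']``), never silently dropped.

    Parameters
    ----------
    estimator : str, optional
        ``nondifferential``, ``diseased_and_general`` or ``general_and_ratio``;
        defaults to the design's own scenario variant.

    Returns
    -------
    DataFrame
        One row per parameter: true value, mean bias, RMSE, empirical
        coverage of the 95% Wald interval.  ``attrs`` carries
        ``n_replicates`` and ``n_failed``.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    estimator = estimator or design.scenario.variant
    fit_one = _make_estimator(design, estimator)
    truth = np.asarray(
        design.truth.params
        if isinstance(design.truth, ExpitPrevalenceSurface)
        else [design.truth.intercept, design.truth.slope]
    )
    estimates, covered = [], []
    n_failed = 0
    for r in range(n_replicates):
        rep = SimulationDesign(
            truth=design.truth,
            scenario=design.scenario,
            group_bounds=design.group_bounds,
            n_per_group=design.n_per_group,
            years=design.years,
            a0=design.a0,
            p0=design.p0,
            seed=design.seed + r,
        )
        try:
            res = fit_one(simulate_counts(rep))
            ci = res.conf_int(0.95)
            estimates.append(res.params)
            covered.append((ci[:, 0] <= truth) & (truth <= ci[:, 1]))
        except (RuntimeError, ValueError):
            n_failed += 1
    est = np.asarray(estimates)
    out = pd.DataFrame(
        {
            "truth": truth,
            "bias": est.mean(axis=0) - truth,
            "rmse": np.sqrt(((est - truth) ** 2).mean(axis=0)),
            "coverage": np.asarray(covered).mean(axis=0),
        }
    )
    out.attrs["n_replicates"] = n_replicates
    out.attrs["n_failed"] = n_failed
    return out
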