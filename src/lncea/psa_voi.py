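"""Probabilistic sensitivity analysis and value-of-information analysis.

The outer loop draws every model parameter once per iteration from its
uncertainty distribution (second-order uncertainty) and evaluates both
strategies on the *same* draw.  The inner evaluation is cohort expectation by
default (noise-free conditional on the draw); a microsimulation inner loop
(first-order uncertainty, the two-dimensional simulation design) is
available with a configurable number of simulated individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import ln_model
from .param_model import ParamSet

__all__ = ["PSASample", "run_psa", "ice_ellipse", "Ellipse",
           "evpi", "population_evpi", "EvpiResult"]


@dataclass
class PSASample:
    """Paired (cost, QALY) draws per strategy across outer iterations.

    ``data`` is long-form with columns (iteration, strategy, cost, qaly);
    strategies share each iteration's parameter draw.
    """

    data: pd.DataFrame
    seed: int
    n_outer: int
    inner_mode: str
    n_inner: int | None = None
    renormalizations: int = 0

    def __post_init__(self) -> None:
        if self.n_outer < 1:
            raise ValueError("n_outer must be >= 1")

    @property
    def strategies(self) -> list[str]:
        return list(dict.fromkeys(self.data["strategy"]))

    def wide(self, column: str) -> pd.DataFrame:
        """Iterations x strategies table of one outcome column."""
        return self.data.pivot(index="iteration", columns="strategy",
                               values=column)[self.strategies]

    def incremental(self) -> pd.DataFrame:
        """Per-iteration (delta_qaly, delta_cost), second strategy minus
        first — the incremental cost-effectiveness cloud."""
        costs = self.wide("cost")
        qalys = self.wide("qaly")
        a, b = self.strategies[0], self.strategies[1]
        return pd.DataFrame({"delta_qaly": qalys[b] - qalys[a],
                             "delta_cost": costs[b] - costs[a]})

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def run_psa(evaluator, param_set: ParamSet, n_outer: int, seed: int,
            *, inner_mode: str = "cohort", n_inner: int = 1000) -> PSASample:
    """Second-order Monte Carlo over the parameter distributions.

    Each iteration samples every parameter independently, then evaluates all
    strategies of ``evaluator`` on the shared draw — by cohort expectation
    (``inner_mode="cohort"``) or by simulating ``n_inner`` individuals per
    strategy (``inner_mode="microsim"``).  Reproducible under ``seed``.
    """
    if inner_mode not in ("cohort", "microsim"):
        raise ValueError("inner_mode must be 'cohort' or 'microsim'")
    rng = np.random.default_rng(seed)
    renorm_before = ln_model._renormalize_rows.count
    rows = []
    for it in range(n_outer):
        values = param_set.sample_all(rng)
        if inner_mode == "cohort":
            out = evaluator.outcomes_from_values(values)
        else:
            inner_seed = int(rng.integers(0, 2**31 - 1))
            out = evaluator.microsim_outcomes(values, n_inner, inner_seed)
        for label, (cost, qaly) in out.items():
            rows.append((it, label, cost, qaly))
    data = pd.DataFrame(rows, columns=["iteration", "strategy", "cost", "qaly"])
    return PSASample(
        data=data, seed=seed, n_outer=n_outer, inner_mode=inner_mode,
        n_inner=n_inner if inner_mode == "microsim" else None,
        renormalizations=ln_model._renormalize_rows.count - renorm_before)


@dataclass(frozen=True)
class Ellipse:
    """A 95% bivariate-normal confidence ellipse for the incremental cloud.

    ``axes`` are the semi-axis lengths along the covariance eigenvectors;
    ``angle`` is the orientation of the major axis in radians from the
    effectiveness axis.
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    angle: float
    level: float = 0.95

    @property
    def area(self) -> float:
        return float(np.pi * self.axes[0] * self.axes[1])

    def contains(self, de: np.ndarray, dc: np.ndarray) -> np.ndarray:
        """Membership test for points, handling the degenerate case."""
        pts = np.column_stack([de, dc]) - np.asarray(self.center)
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        rot = pts @ np.array([[ca, -sa], [sa, ca]])
        a = self.axes[0] if self.axes[0] > 0 else np.inf
        b = self.axes[1] if self.axes[1] > 0 else np.inf
        with np.errstate(invalid="ignore"):
            r = (rot[:, 0] / a) ** 2 + (rot[:, 1] / b) ** 2
        r = np.where(np.isnan(r), 0.0, r)
        return r <= 1.0 + 1e-12


def ice_ellipse(samples: PSASample, level: float = 0.95) -> Ellipse:
    """Confidence ellipse of the incremental (effectiveness, cost) cloud,
    from the sample mean and covariance under a bivariate-normal model.

    A degenerate covariance (all points identical, or perfectly collinear)
    yields zero-length axes along the degenerate directions.
    """
    inc = samples.incremental()
    if len(inc) < 3:
        raise ValueError("need at least 3 iterations for an ellipse")
    pts = inc[["delta_qaly", "delta_cost"]].to_numpy()
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    k = float(chi2.ppf(level, df=2))
    # order by descending eigenvalue: major axis first
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    axes = tuple(float(np.sqrt(k * ev)) for ev in evals)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse(center=(float(center[0]), float(center[1])),
                   axes=axes, angle=angle, level=level)


def evpi(samples: PSASample, wtp: float) -> float:
    """Per-person expected value of perfect information at one WTP.

    Mean over iterations of the best achievable NMB minus the best NMB
    attainable by a single fixed choice; nonnegative by Jensen's
    inequality.
    """
    costs = samples.wide("cost").to_numpy()
    qalys = samples.wide("qaly").to_numpy()
    nmbs = qalys * wtp - costs
    value = float(nmbs.max(axis=1).mean() - nmbs.mean(axis=0).max())
    return max(value, 0.0)  # guard against float cancellation at ~0


@dataclass(frozen=True)
class EvpiResult:
    """Per-person and population EVPI at one willingness-to-pay."""

    wtp: float
    per_person: float
    population: float | None = None
    annual_population: float | None = None
    horizon_years: int | None = None
    discount_rate: float | None = None


def population_evpi(per_person: float, annual_population: float,
                    years: int, discount: float) -> float:
    """Population EVPI: the per-person value scaled over the annual incident
    decision population for ``years`` years, discounted at ``discount``."""
    if min(per_person, annual_population, years, discount) < 0:
        raise ValueError("all inputs must be nonnegative")
    t = np.arange(years)
    return float(per_person * np.sum(annual_population / (1.0 + discount) ** t))


def voi_report(samples: PSASample, wtp_grid: Sequence[float],
               annual_population: float | None = None,
               years: int = 10, discount: float = 0.03) -> pd.DataFrame:
    """EVPI at each WTP, with population scaling when a population is given.

    The size of the annual decision population is deliberately an explicit
    input: no national default is asserted.
    """
    rows = []
    for w in wtp_grid:
        pp = evpi(samples, w)
        pop = (population_evpi(pp, annual_population, years, discount)
               if annual_population is not None else np.nan)
        rows.append(dict(wtp=float(w), evpi_per_person=pp, evpi_population=pop))
    return pd.DataFrame(rows)
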