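"""Deterministic sensitivity machinery.

One-way parameter sweeps, tornado ranking with uncertainty shares, threshold
(break-even price) search, and named scenario runs.  All deterministic
analyses use cohort expectation, so results carry no Monte Carlo noise.

Two expected-value metrics are available:

* ``"decision"`` — the decision-node expected value, i.e. the net monetary
  benefit of the optimal strategy at the working willingness-to-pay.  This
  is the conventional tornado metric and the default for tornado diagrams.
* ``"incremental"`` — the incremental NMB (second arm minus first arm,
  MMF minus AZA in the shipped evaluators).  Threshold searches root-find
  this quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .econ import CEResult, StrategyOutcome, icer
from .ln_model import (LifetimeEvaluator, LifetimeScenario, RescuePolicy,
                       ThreeYearEvaluator)
from .param_model import CostParam, ProbabilityParam, UtilityParam

__all__ = ["TornadoBar", "Scenario", "one_way", "tornado", "threshold_price",
           "ThresholdResult", "run_scenario", "default_ranges",
           "three_year_scenarios", "lifetime_scenarios", "evaluate_metric"]


def _outcomes_to_nmb(outcomes: Mapping[str, tuple[float, float]], wtp: float) -> dict[str, float]:
    return {label: q * wtp - c for label, (c, q) in outcomes.items()}


def evaluate_metric(evaluator, wtp: float, metric: str = "decision",
                    overrides: Mapping[str, float] | None = None,
                    arm_overrides: Mapping[str, Mapping[str, float]] | None = None,
                    ) -> float:
    """Expected value of the model under point overrides (see module doc)."""
    nmbs = _outcomes_to_nmb(evaluator.outcomes(overrides, arm_overrides), wtp)
    if metric == "decision":
        return max(nmbs.values())
    if metric == "incremental":
        labels = [a.label for a in evaluator.arms]
        return nmbs[labels[1]] - nmbs[labels[0]]
    raise ValueError(f"unknown metric {metric!r}")


def one_way(evaluator, name: str, low: float, high: float, wtp: float,
            *, metric: str = "decision") -> tuple[float, float]:
    """Expected values with one parameter at each end of its range, all other
    parameters at their base means."""
    if low > high:
        raise ValueError("low must not exceed high")
    ev_low = evaluate_metric(evaluator, wtp, metric, {name: low})
    ev_high = evaluate_metric(evaluator, wtp, metric, {name: high})
    return ev_low, ev_high


@dataclass(frozen=True)
class TornadoBar:
    """One tornado bar: expected values at a parameter's range ends."""

    name: str
    low: float
    high: float
    ev_low: float
    ev_high: float

    @property
    def width(self) -> float:
        return abs(self.ev_high - self.ev_low)


def default_ranges(evaluator) -> list[tuple[str, float, float]]:
    """(name, low, high) for every parameter the evaluator's phase uses,
    with published ranges.  The 3-year evaluator excludes the annual-cycle
    parameters of the posttreatment phase (they cannot move its results)."""
    three_year_only = isinstance(evaluator, ThreeYearEvaluator)
    out = []
    for p in evaluator.params:
        if three_year_only and p.name.startswith(("py_", "costy_")):
            continue
        if isinstance(p, ProbabilityParam):
            out.append((p.name, p.ci_low, p.ci_high))
        elif isinstance(p, (CostParam, UtilityParam)):
            out.append((p.name, p.range_low, p.range_high))
    return out


def tornado(evaluator, wtp: float,
            param_ranges: Sequence[tuple[str, float, float]] | None = None,
            *, metric: str = "decision") -> pd.DataFrame:
    """One-way sweeps over every parameter, ranked by bar width.

    Returns a DataFrame sorted by descending width with two uncertainty-share
    columns: ``share`` (linear, width / sum of widths) and ``share_sq``
    (squared, width^2 / sum of squared widths).  Both columns sum to 1.
    """
    if param_ranges is None:
        param_ranges = default_ranges(evaluator)
    if not param_ranges:
        raise ValueError("no parameters to vary")
    base_ev = evaluate_metric(evaluator, wtp, metric)
    bars = []
    for name, low, high in param_ranges:
        ev_low, ev_high = one_way(evaluator, name, low, high, wtp, metric=metric)
        bars.append(TornadoBar(name, low, high, ev_low, ev_high))
    df = pd.DataFrame(
        [dict(parameter=b.name, low=b.low, high=b.high,
              ev_low=b.ev_low, ev_high=b.ev_high, width=b.width)
         for b in bars]
    ).sort_values(["width", "parameter"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    wsum = df["width"].sum()
    w2sum = (df["width"] ** 2).sum()
    df["share"] = df["width"] / wsum if wsum > 0 else 0.0
    df["share_sq"] = df["width"] ** 2 / w2sum if w2sum > 0 else 0.0
    df.attrs["base_ev"] = base_ev
    df.attrs["wtp"] = wtp
    df.attrs["metric"] = metric
    return df


def top_share(tornado_df: pd.DataFrame, k: int = 3, convention: str = "linear") -> float:
    """Combined uncertainty share of the ``k`` widest tornado bars."""
    col = {"linear": "share", "squared": "share_sq"}[convention]
    return float(tornado_df[col].iloc[:k].sum())


@dataclass(frozen=True)
class ThresholdResult:
    """Break-even search outcome; ``value`` is None when the incremental NMB
    does not change sign over the bracket."""

    parameter: str
    wtp: float
    value: float | None
    bracket: tuple[float, float]

    @property
    def found(self) -> bool:
        return self.value is not None


def threshold_price(evaluator, name: str, wtp: float,
                    bracket: tuple[float, float], *, xtol: float = 0.005,
                    ) -> ThresholdResult:
    """Find the parameter value at which the incremental NMB (second arm
    minus first) crosses zero, by bisection to within ±$0.01.

    Monotonicity over the bracket is the caller's premise; it holds for the
    drug-price sweeps this is used for and is validated in the test suite
    rather than assumed silently here.
    """
    lo, hi = bracket
    if lo >= hi:
        raise ValueError("bracket must be (low, high) with low < high")

    def f(x: float) -> float:
        return evaluate_metric(evaluator, wtp, "incremental", {name: x})

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return ThresholdResult(name, wtp, lo, bracket)
    if f_hi == 0.0:
        return ThresholdResult(name, wtp, hi, bracket)
    if np.sign(f_lo) == np.sign(f_hi):
        return ThresholdResult(name, wtp, None, bracket)
    root = brentq(f, lo, hi, xtol=xtol)
    return ThresholdResult(name, wtp, float(root), bracket)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """A named set of overrides on parameters, policies and phase settings.

    ``overrides`` apply to both arms; ``arm_overrides`` (keyed by arm label)
    to one arm only; ``policies`` replace an arm's rescue policy.  The
    remaining fields override phase-level settings where the evaluator
    supports them (horizon and extrapolation apply to lifetime evaluators
    only).
    """

    name: str
    overrides: Mapping[str, float] = field(default_factory=dict)
    arm_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    policies: Mapping[str, RescuePolicy] = field(default_factory=dict)
    discount_rate: float | None = None
    horizon_years: int | None = None
    extrapolation: str | None = None
    esrd_increment_per_year: float | None = None


def _apply_scenario(evaluator, scenario: Scenario):
    changes: dict = {}
    if scenario.policies:
        changes["arms"] = tuple(
            replace(arm, policy=scenario.policies.get(arm.label, arm.policy))
            for arm in evaluator.arms)
    if scenario.discount_rate is not None:
        changes["discount_rate"] = scenario.discount_rate
    if isinstance(evaluator, LifetimeEvaluator):
        if scenario.horizon_years is not None:
            changes["horizon_years"] = scenario.horizon_years
        if scenario.extrapolation is not None or scenario.esrd_increment_per_year is not None:
            changes["scenario"] = LifetimeScenario(
                extrapolation=scenario.extrapolation or evaluator.scenario.extrapolation,
                esrd_increment_per_year=(
                    scenario.esrd_increment_per_year
                    if scenario.esrd_increment_per_year is not None
                    else evaluator.scenario.esrd_increment_per_year))
    elif scenario.horizon_years is not None or scenario.extrapolation is not None \
            or scenario.esrd_increment_per_year is not None:
        raise ValueError(f"scenario {scenario.name!r} carries lifetime-phase "
                         "settings but the evaluator is a 3-year evaluator")
    return replace(evaluator, **changes) if changes else evaluator


def run_scenario(evaluator, scenario: Scenario,
                 wtp_grid: Sequence[float] = (50_000.0, 100_000.0)) -> CEResult:
    """Evaluate the second arm against the first under a scenario's
    overrides and return the incremental comparison."""
    ev = _apply_scenario(evaluator, scenario)
    out = ev.outcomes(dict(scenario.overrides),
                      {k: dict(v) for k, v in scenario.arm_overrides.items()})
    labels = [a.label for a in ev.arms]
    ref = StrategyOutcome(labels[0], *out[labels[0]])
    comp = StrategyOutcome(labels[1], *out[labels[1]])
    return icer(ref, comp, wtp_grid)


def scenario_table(evaluator, scenarios: Sequence[Scenario],
                   wtp_grid: Sequence[float] = (50_000.0, 100_000.0)) -> pd.DataFrame:
    """Run a list of scenarios and tabulate their incremental results."""
    rows = []
    for sc in scenarios:
        res = run_scenario(evaluator, sc, wtp_grid)
        rows.append(dict(scenario=sc.name,
                         delta_cost=res.delta_cost,
                         delta_qaly=res.delta_qaly,
                         icer=res.icer if res.icer is not None else np.nan,
                         verdict=res.verdict or ""))
    return pd.DataFrame(rows)


def three_year_scenarios() -> list[Scenario]:
    """The named sensitivity/scenario rows of the 3-year analysis.

    The biased-against-AZA rows raise the remission indirect cost to the top
    of its range in both arms (its published incremental effect is
    proportional to the small remission-occupancy difference between arms,
    which identifies the both-arm application), raise the remission utility,
    and price AZA at the top of its range in the AZA arm.
    """
    biased_indirect = {"cost_indirect_remission": 10_041.49}
    return [
        Scenario("base_case"),
        Scenario("exclude_indirect_costs",
                 overrides={"cost_indirect_remission": 0.0,
                            "cost_indirect_relapse": 0.0}),
        Scenario("utility_remission_0.8", overrides={"u_remission": 0.8}),
        Scenario("utility_relapse_mmf_0.5", overrides={"u_relapse_mmf": 0.5}),
        Scenario("utility_relapse_cyc_equals_mmf", overrides={"u_relapse_cyc": 0.6}),
        Scenario("biased_indirect", overrides=dict(biased_indirect)),
        Scenario("biased_indirect_utility",
                 overrides={**biased_indirect, "u_remission": 0.8}),
        Scenario("biased_indirect_utility_price",
                 overrides={**biased_indirect, "u_remission": 0.8},
                 arm_overrides={"AZA": {"cost_drug_aza": 2_626.0}}),
        Scenario("aza_rescue_mmf3",
                 policies={"AZA": RescuePolicy(aza_rescue_drug="mmf3")}),
        Scenario("aza_maintenance_after_cyc_remission",
                 policies={"AZA": RescuePolicy(post_cyc_maintenance="aza")}),
    ]


def lifetime_scenarios() -> list[Scenario]:
    """The named sensitivity/scenario rows of the lifetime analysis."""
    out = [
        Scenario("base_case"),
        Scenario("exclude_indirect_costs",
                 overrides={"cost_indirect_remission": 0.0,
                            "cost_indirect_relapse": 0.0,
                            "costy_indirect_remission": 0.0,
                            "costy_indirect_relapse": 0.0}),
        Scenario("utility_remission_0.8", overrides={"u_remission": 0.8}),
        Scenario("utility_relapse_0.5", overrides={"u_relapse_mmf": 0.5}),
        Scenario("utility_relapse_0.7", overrides={"u_relapse_mmf": 0.7}),
    ]
    for pct in (0.5, 1.0, 2.0):
        out.append(Scenario(f"esrd_increment_{pct}pct_per_year",
                            esrd_increment_per_year=pct / 100.0))
    for name in ("persist", "no_effect", "decay_1pct", "decay_2pct"):
        out.append(Scenario(f"extrapolation_{name}", extrapolation=name))
    for years in (5, 10, 20, 30):
        out.append(Scenario(f"horizon_{years}y", horizon_years=years))
    for rate in (0.0, 0.05, 0.07):
        out.append(Scenario(f"discount_{int(rate * 100)}pct", discount_rate=rate))
    return out
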