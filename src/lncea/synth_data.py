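"""Synthetic stand-ins for the external data the lifetime model needs.

The posttreatment phase requires two age-indexed mortality tables that are
not part of the parameter tables: an all-population life table and a
dialysis-population mortality table.  This module generates monotone,
realistic-order synthetic versions of both from two-parameter Gompertz
mortality curves so the full pipeline runs with no downloads; user-supplied
CSV tables (age, annual death probability) drop in with no code change.
Files and objects produced here are synthetic and make no claim of
demographic fidelity.

It also simulates trial-style event counts for parameter-recovery testing of
the Beta machinery: binomial event counts at known true probabilities, with
Beta(events + 1, at_risk - events + 1) posteriors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ln_model import LifeTable
from .param_model import ProbabilityParam, convert_probability, prob_to_rate

__all__ = ["GompertzSpec", "make_life_table", "make_dialysis_table",
           "calibrate_dialysis_table", "TrialCounts", "simulate_trial_counts"]


@dataclass(frozen=True)
class GompertzSpec:
    """Gompertz mortality: annual death rate ``a * exp(b * age)``.

    Defaults give adult mortality of a realistic order (q(30) ~ 0.0015,
    q(70) ~ 0.05).  The implied annual death probability
    ``q(age) = 1 - exp(-a e^{b age})`` must stay inside (0, 1) over the span.
    """

    a: float = 1e-4
    b: float = 0.09
    age_min: int = 0
    age_max: int = 105

    def __post_init__(self) -> None:
        if self.a <= 0.0 or self.b < 0.0:
            raise ValueError("need baseline rate a > 0 and slope b >= 0")
        if self.age_min >= self.age_max:
            raise ValueError("need age_min < age_max")

    def q(self, age: float) -> float:
        return -math.expm1(-self.a * math.exp(self.b * age))


def make_life_table(spec: GompertzSpec | None = None) -> LifeTable:
    """Deterministic synthetic life table from a Gompertz curve.

    Strictly increasing in age whenever the slope is positive; raises if the
    implied probability leaves (0, 1) anywhere on the span.
    """
    spec = spec or GompertzSpec()
    ages = np.arange(spec.age_min, spec.age_max + 1)
    qx = np.array([spec.q(age) for age in ages])
    if np.any(qx >= 1.0) or np.any(qx <= 0.0):
        raise ValueError("Gompertz spec implies death probabilities outside "
                         "(0, 1) on the requested age span")
    return LifeTable(ages, qx)


def make_dialysis_table(base_q25: float = 0.085, slope: float = 0.03,
                        age_min: int = 18, age_max: int = 105) -> LifeTable:
    """Synthetic dialysis-population mortality table.

    The annual death rate at age 25 is ``-ln(1 - base_q25)`` and grows
    exponentially with ``slope`` per year of age — a monotone stand-in for
    registry dialysis mortality, which is far flatter in age than general
    mortality but starts an order of magnitude higher.
    """
    if not 0.0 < base_q25 < 1.0:
        raise ValueError("base_q25 must be in (0, 1)")
    if slope < 0.0:
        raise ValueError("slope must be nonnegative")
    r25 = prob_to_rate(base_q25, 1.0)
    ages = np.arange(age_min, age_max + 1)
    qx = -np.expm1(-r25 * np.exp(slope * (ages - 25)))
    if np.any(qx >= 1.0):
        raise ValueError("dialysis spec implies death probabilities >= 1")
    return LifeTable(ages, qx)


def calibrate_dialysis_table(six_month_q: float = 0.0513,
                             calibration_age: float = 31.0,
                             slope: float = 0.03) -> LifeTable:
    """Dialysis table tuned so the implied 6-month death probability at the
    calibration age equals the maintenance-phase dialysis-death probability,
    keeping the two phases' ESRD mortality mutually consistent at the age a
    base-case entrant reaches dialysis."""
    annual_q = convert_probability(six_month_q, 0.5, 1.0)
    r_cal = prob_to_rate(annual_q, 1.0)
    r25 = r_cal / math.exp(slope * (calibration_age - 25.0))
    base_q25 = -math.expm1(-r25)
    return make_dialysis_table(base_q25=base_q25, slope=slope)


@dataclass(frozen=True)
class TrialCounts:
    """Simulated per-transition event counts, as a trial would report them."""

    data: pd.DataFrame  # columns: name, events, at_risk, duration_years
    seed: int

    def posterior(self, name: str) -> tuple[float, float]:
        """Beta(events + 1, at_risk - events + 1) posterior shape pair."""
        row = self.data.set_index("name").loc[name]
        return float(row.events + 1), float(row.at_risk - row.events + 1)

    def posterior_params(self, template: dict[str, ProbabilityParam],
                         ) -> dict[str, ProbabilityParam]:
        """Rebuild probability parameters from the simulated counts.

        The Beta posterior lives on the trial follow-up time scale; the
        parameter mean and interval are converted back to the template's
        cycle length through the rate scale, and draws convert the same way
        via ``dist_cycle_length``.
        """
        durations = self.data.set_index("name")["duration_years"]
        out = {}
        for name, p in template.items():
            a, b = self.posterior(name)
            duration = float(durations.loc[name])
            mean_dur = a / (a + b)
            sd = math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
            lo_dur = max(0.0, min(mean_dur, mean_dur - 1.96 * sd))
            hi_dur = min(1.0 - 1e-12, max(mean_dur, mean_dur + 1.96 * sd))
            conv = lambda x: convert_probability(x, duration, p.cycle_length)
            out[name] = ProbabilityParam(
                name, conv(mean_dur), conv(lo_dur), conv(hi_dur), a, b,
                p.cycle_length, dist_cycle_length=duration)
        return out


def simulate_trial_counts(true_probs: dict[str, ProbabilityParam],
                          n_per_arm: int, duration_years: float,
                          seed: int) -> TrialCounts:
    """Binomial event counts at the given true per-cycle probabilities.

    Each parameter's per-cycle probability is re-expressed over the
    follow-up duration (constant-rate assumption) and ``n_per_arm`` subjects
    are observed once over that duration.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for name, p in sorted(true_probs.items()):
        p_dur = convert_probability(p.mean, p.cycle_length, duration_years)
        events = int(rng.binomial(n_per_arm, p_dur))
        rows.append(dict(name=name, events=events, at_risk=n_per_arm,
                         duration_years=duration_years))
    return TrialCounts(pd.DataFrame(rows), seed)
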