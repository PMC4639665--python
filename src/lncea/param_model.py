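"""Model parameters and their uncertainty distributions.

Every transition probability, cost and utility weight in the lupus-nephritis
maintenance model is represented here together with its sampling distribution:
Beta for probabilities and utilities, Gamma for costs, or a fixed point value.
The module also provides the rate/probability conversion identities used to
move event probabilities between cycle lengths, and the method-of-moments
parameterizations for Beta and Gamma distributions.

Conventions
-----------
* Probabilities are per cycle; each :class:`ProbabilityParam` records the
  cycle length (in years) its mean refers to.
* Costs are 2013 US dollars per cycle.
* Utility weights live on [0, 1] with death anchored at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ProbabilityParam",
    "CostParam",
    "UtilityParam",
    "ParamSet",
    "prob_to_rate",
    "rate_to_prob",
    "convert_probability",
    "gamma_from_moments",
    "beta_mean",
    "beta_from_mean_ci",
    "sample",
    "base_case",
]

#: Width of a central 95% normal interval in standard-deviation units.
_Z95_WIDTH = 3.92


# ---------------------------------------------------------------------------
# rate <-> probability conversions
# ---------------------------------------------------------------------------

def prob_to_rate(p: float, t: float) -> float:
    """Convert an event probability over duration ``t`` years to a constant
    annual event rate, via ``r = -(1/t) ln(1 - p)``.

    Raises
    ------
    ValueError
        If ``p`` is outside ``[0, 1)`` or ``t`` is not positive.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p!r}")
    if t <= 0.0:
        raise ValueError(f"duration must be positive, got {t!r}")
    return -math.log1p(-p) / t


def rate_to_prob(r: float, t: float) -> float:
    """Convert a constant annual rate to an event probability over ``t``
    years, via ``p = 1 - exp(-r t)``."""
    if r < 0.0:
        raise ValueError(f"rate must be nonnegative, got {r!r}")
    if t <= 0.0:
        raise ValueError(f"duration must be positive, got {t!r}")
    return -math.expm1(-r * t)


def convert_probability(p: float, t_from: float, t_to: float) -> float:
    """Re-express a probability observed over ``t_from`` years as the
    equivalent probability over ``t_to`` years, assuming a constant rate."""
    return rate_to_prob(prob_to_rate(p, t_from), t_to)


# ---------------------------------------------------------------------------
# distribution parameterization
# ---------------------------------------------------------------------------

def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Shape/rate of the Gamma distribution with the given mean and standard
    deviation: ``shape = mean^2 / sd^2``, ``rate = mean / sd^2``."""
    if mean <= 0.0 or sd <= 0.0:
        raise ValueError("mean and sd must be positive")
    var = sd * sd
    return mean * mean / var, mean / var


def beta_mean(shape1: float, shape2: float) -> float:
    """Mean ``a / (a + b)`` of a Beta(a, b) distribution."""
    if shape1 <= 0.0 or shape2 <= 0.0:
        raise ValueError("Beta shapes must be positive")
    return shape1 / (shape1 + shape2)


def beta_from_mean_ci(mean: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Method-of-moments Beta fit from a mean and a 95% interval.

    The interval width is read as 3.92 standard deviations.  Used only when a
    parameter needs a Beta that was not reported directly.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must be inside (0, 1)")
    if not ci_low <= mean <= ci_high:
        raise ValueError("mean must lie within the interval")
    sd = (ci_high - ci_low) / _Z95_WIDTH
    if sd <= 0.0:
        raise ValueError("interval must have positive width")
    var = sd * sd
    common = mean * (1.0 - mean) / var - 1.0
    if common <= 0.0:
        raise ValueError("interval too wide for a Beta with this mean")
    return mean * common, (1.0 - mean) * common


# ---------------------------------------------------------------------------
# parameter types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbabilityParam:
    """A per-cycle transition/event probability with a Beta distribution.

    ``cycle_length`` is the cycle the *mean* refers to; ``dist_cycle_length``
    is the cycle the Beta parameters refer to.  They differ only for
    parameters whose published distribution was reported on a different time
    scale than the model cycle, in which case draws are converted through the
    rate scale.
    """

    name: str
    mean: float
    ci_low: float
    ci_high: float
    beta_shape1: float
    beta_shape2: float
    cycle_length: float
    dist_cycle_length: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.mean <= self.ci_high <= 1.0:
            raise ValueError(f"{self.name}: need 0 <= low <= mean <= high <= 1")
        if self.beta_shape1 <= 0.0 or self.beta_shape2 <= 0.0:
            raise ValueError(f"{self.name}: Beta shapes must be positive")
        if self.cycle_length <= 0.0:
            raise ValueError(f"{self.name}: cycle length must be positive")

    @property
    def dist_scale(self) -> float:
        return self.dist_cycle_length if self.dist_cycle_length is not None else self.cycle_length

    def draw(self, rng: np.random.Generator) -> float:
        x = rng.beta(self.beta_shape1, self.beta_shape2)
        if self.dist_scale != self.cycle_length:
            x = convert_probability(x, self.dist_scale, self.cycle_length)
        return x


@dataclass(frozen=True)
class CostParam:
    """A per-cycle cost (2013 USD) with a Gamma distribution.

    Draws use a moment-matched Gamma derived from the mean and the range
    (range read as a central 95% interval, sd = range / 3.92).  The published
    (shape, rate) pair, where available, is retained as metadata in
    ``printed_gamma`` but is not used for sampling because the published
    pairs do not reproduce the published means.
    """

    name: str
    mean: float
    range_low: float
    range_high: float
    printed_gamma: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mean <= 0.0:
            raise ValueError(f"{self.name}: cost mean must be positive")
        if not self.range_low <= self.mean <= self.range_high:
            raise ValueError(f"{self.name}: need low <= mean <= high")

    @property
    def sd(self) -> float:
        return (self.range_high - self.range_low) / _Z95_WIDTH

    @property
    def gamma(self) -> tuple[float, float]:
        """Moment-matched (shape, rate) actually used for sampling."""
        return gamma_from_moments(self.mean, self.sd)

    def draw(self, rng: np.random.Generator) -> float:
        shape, rate = self.gamma
        return rng.gamma(shape, 1.0 / rate)


@dataclass(frozen=True)
class UtilityParam:
    """A utility weight (or disutility decrement) on [0, 1].

    Parameters flagged ``fixed`` are not sampled and return their mean on
    every draw.
    """

    name: str
    mean: float
    range_low: float
    range_high: float
    beta_shape1: float | None = None
    beta_shape2: float | None = None
    fixed: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError(f"{self.name}: utility must be in [0, 1]")
        if not self.fixed and (self.beta_shape1 is None or self.beta_shape2 is None):
            raise ValueError(f"{self.name}: non-fixed utility needs Beta shapes")

    def draw(self, rng: np.random.Generator) -> float:
        if self.fixed:
            return self.mean
        return rng.beta(self.beta_shape1, self.beta_shape2)


Param = ProbabilityParam | CostParam | UtilityParam


def sample(param: Param, rng: np.random.Generator) -> float:
    """Draw one value from a parameter's uncertainty distribution.

    Fixed parameters return their mean; probabilities and utilities are
    Beta draws on [0, 1]; costs are strictly positive Gamma draws.
    """
    return param.draw(rng)


# ---------------------------------------------------------------------------
# the parameter set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamSet:
    """The complete collection of model parameters plus scalar constants.

    This is the single source of truth consumed by the model builders: every
    parameter name a model references must resolve here.
    """

    probabilities: dict[str, ProbabilityParam] = field(default_factory=dict)
    costs: dict[str, CostParam] = field(default_factory=dict)
    utilities: dict[str, UtilityParam] = field(default_factory=dict)
    constants: dict[str, float] = field(default_factory=dict)

    def __iter__(self) -> Iterator[Param]:
        yield from self.probabilities.values()
        yield from self.costs.values()
        yield from self.utilities.values()

    def __getitem__(self, name: str) -> Param:
        for group in (self.probabilities, self.costs, self.utilities):
            if name in group:
                return group[name]
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(name in g for g in (self.probabilities, self.costs, self.utilities))

    def names(self) -> list[str]:
        return [p.name for p in self]

    def means(self, overrides: Mapping[str, float] | None = None) -> dict[str, float]:
        """Point values for every parameter, optionally overridden by name."""
        values = {p.name: p.mean for p in self}
        if overrides:
            unknown = set(overrides) - set(values)
            if unknown:
                raise KeyError(f"unknown parameter override(s): {sorted(unknown)}")
            values.update(overrides)
        return values

    def sample_all(self, rng: np.random.Generator) -> dict[str, float]:
        """One joint independent draw of every parameter (fixed ones at their
        means).  Iteration order is fixed, so a seeded generator yields an
        identical stream."""
        return {p.name: p.draw(rng) for p in self}

    def constant(self, name: str) -> float:
        return self.constants[name]

    def with_param_mean(self, name: str, mean: float) -> "ParamSet":
        """A copy with one parameter's mean replaced (distribution collapsed
        around the new point for deterministic analyses)."""
        p = self[name]
        if isinstance(p, ProbabilityParam):
            lo, hi = min(p.ci_low, mean), max(p.ci_high, mean)
            newp = replace(p, mean=mean, ci_low=lo, ci_high=hi)
            group = dict(self.probabilities)
            group[name] = newp
            return replace(self, probabilities=group)
        if isinstance(p, CostParam):
            lo, hi = min(p.range_low, mean), max(p.range_high, mean)
            newp = replace(p, mean=mean, range_low=lo, range_high=hi)
            group = dict(self.costs)
            group[name] = newp
            return replace(self, costs=group)
        lo, hi = min(p.range_low, mean), max(p.range_high, mean)
        newp = replace(p, mean=mean, range_low=lo, range_high=hi)
        group = dict(self.utilities)
        group[name] = newp
        return replace(self, utilities=group)

    # -- CSV round trip -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.probabilities.values():
            rows.append(dict(
                name=p.name, kind="probability", mean=p.mean, low=p.ci_low,
                high=p.ci_high, dist="beta", shape1=p.beta_shape1,
                shape2=p.beta_shape2, cycle_length_years=p.cycle_length,
                dist_cycle_length_years=p.dist_scale,
            ))
        for c in self.costs.values():
            s1, s2 = c.printed_gamma if c.printed_gamma else (np.nan, np.nan)
            rows.append(dict(
                name=c.name, kind="cost", mean=c.mean, low=c.range_low,
                high=c.range_high, dist="gamma", shape1=s1, shape2=s2,
                cycle_length_years=np.nan, dist_cycle_length_years=np.nan,
            ))
        for u in self.utilities.values():
            rows.append(dict(
                name=u.name, kind="utility", mean=u.mean, low=u.range_low,
                high=u.range_high, dist="fixed" if u.fixed else "beta",
                shape1=np.nan if u.fixed else u.beta_shape1,
                shape2=np.nan if u.fixed else u.beta_shape2,
                cycle_length_years=np.nan, dist_cycle_length_years=np.nan,
            ))
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, constants: Mapping[str, float] | None = None) -> "ParamSet":
        df = pd.read_csv(path)
        probs: dict[str, ProbabilityParam] = {}
        costs: dict[str, CostParam] = {}
        utils: dict[str, UtilityParam] = {}
        for row in df.itertuples(index=False):
            if row.kind == "probability":
                probs[row.name] = ProbabilityParam(
                    row.name, row.mean, row.low, row.high, row.shape1,
                    row.shape2, row.cycle_length_years,
                    dist_cycle_length=row.dist_cycle_length_years,
                )
            elif row.kind == "cost":
                printed = None
                if not (pd.isna(row.shape1) or pd.isna(row.shape2)):
                    printed = (row.shape1, row.shape2)
                costs[row.name] = CostParam(row.name, row.mean, row.low, row.high, printed)
            elif row.kind == "utility":
                fixed = row.dist == "fixed"
                utils[row.name] = UtilityParam(
                    row.name, row.mean, row.low, row.high,
                    None if fixed else row.shape1, None if fixed else row.shape2,
                    fixed=fixed,
                )
            else:
                raise ValueError(f"unknown parameter kind {row.kind!r}")
        consts = dict(constants) if constants else dict(DEFAULT_CONSTANTS)
        return cls(probs, costs, utils, consts)


# ---------------------------------------------------------------------------
# base-case parameter values
# ---------------------------------------------------------------------------

#: Scalar constants of the base case: excess-mortality multipliers for the
#: lifetime phase, the discount rate, and the willingness-to-pay grid.
DEFAULT_CONSTANTS: dict[str, float] = {
    "smr_nephritis": 7.9,            # SMR for lupus death during relapse
    "rr_relapse_vs_remission_mmf": 9.3,   # lupus death, relapse vs remission on MMF
    "rr_remission_aza_vs_mmf": 0.58,      # lupus death, remission AZA vs MMF
    "hr_esrd_lupus": 1.7,            # dialysis death, lupus ESRD vs all-cause ESRD
    "discount_rate": 0.03,
    "wtp_low": 50_000.0,
    "wtp_high": 100_000.0,
}

# (mean, ci_low, ci_high, beta_a, beta_b); 6-month cycle
_PROBS_6MO = {
    # remission on AZA maintenance
    "p_death_remission_aza":     (0.0025, 0.0004, 0.0157, 24.3, 9830.3),
    "p_infection_remission_aza": (0.0138, 0.0047, 0.0430, 751.2, 53686.0),
    "p_esrd_remission_aza":      (0.0030, 0.0006, 0.0160, 35.9, 11927.1),
    "p_relapse_remission_aza":   (0.0364, 0.0234, 0.0587, 5106.0, 135192.3),
    # remission on MMF maintenance
    "p_death_remission_mmf":     (0.0043, 0.0007, 0.0285, 4.2, 963.5),
    "p_infection_remission_mmf": (0.0160, 0.0055, 0.0510, 3.9, 241.1),
    "p_esrd_remission_mmf":      (0.0012, 0.0002, 0.0063, 3.9, 3269.0),
    "p_relapse_remission_mmf":   (0.0185, 0.0122, 0.0286, 4.1, 219.5),
    # relapse treated with MMF rescue (2 or 3 g/day)
    "p_death_relapse_mmf":       (0.0410, 0.0210, 0.0790, 64.4, 1507.3),
    "p_infection_relapse_mmf":   (0.1210, 0.0810, 0.1830, 514.6, 3738.7),
    "p_esrd_relapse_mmf":        (0.0610, 0.0230, 0.1580, 139.7, 2150.5),
    "p_remission_relapse_mmf":   (0.5900, 0.4180, 0.7380, 56.5, 39.3),
    # relapse treated with IV cyclophosphamide
    "p_death_relapse_cyc":       (0.0400, 0.0200, 0.0780, 61.4, 1473.6),
    "p_infection_relapse_cyc":   (0.1090, 0.0730, 0.1650, 105.8, 864.4),
    "p_esrd_relapse_cyc":        (0.0855, 0.0320, 0.2220, 66.8, 714.1),
    "p_remission_relapse_cyc":   (0.5220, 0.3920, 0.6520, 51.6, 47.2),
    # ESRD on dialysis
    "p_death_esrd":              (0.0513, 0.0481, 0.0548, 99.8, 1845.9),
}

# annual-cycle probabilities of the posttreatment (lifetime) phase
# (mean, ci_low, ci_high, beta_a, beta_b, dist_cycle_length)
_PROBS_1Y = {
    # The AZA rows' Beta parameters are reported on the 6-month scale (they
    # are the maintenance-phase distributions); draws are converted to annual
    # probabilities through the rate scale, matching how the annual means
    # themselves were derived.
    "py_relapse_remission_aza": (0.0716, 0.0463, 0.1140, 5106.9, 135192.3, 0.5),
    "py_esrd_remission_aza":    (0.0061, 0.0012, 0.0317, 35.9, 11927.1, 0.5),
    "py_relapse_remission_mmf": (0.0367, 0.0244, 0.0564, 16.0, 419.5, None),
    "py_esrd_remission_mmf":    (0.0025, 0.0005, 0.0125, 16.6, 6771.3, None),
    # relapse state, identical in both arms
    "py_esrd_relapse":          (0.1183, 0.0455, 0.2910, 491.1, 3670.9, None),
    "py_remission_relapse":     (0.8319, 0.6613, 0.9313, 45.7, 9.2, None),
}

# (mean, range_low, range_high, printed (shape, rate)); 6-month cycle costs
_COSTS_6MO = {
    "cost_drug_aza":           (769.86, 343.98, 2626.26, (59.1, 0.08)),
    "cost_drug_mmf2":          (4833.92, 1135.68, 5773.04, (23.4, 0.005)),
    "cost_drug_mmf3":          (7250.88, 1703.52, 8659.56, (52.6, 0.007)),
    "cost_drug_cyc":           (6233.52, 4675.14, 7791.90, (42.1, 0.006)),
    "cost_direct_remission":   (1684.17, 1263.13, 2105.21, (31.5, 0.019)),
    "cost_direct_relapse":     (3243.43, 2432.57, 4054.29, (29.2, 0.009)),
    "cost_indirect_remission": (8033.19, 6024.89, 10041.49, (16.1, 0.002)),
    "cost_indirect_relapse":   (8564.07, 6423.05, 10705.09, (18.3, 0.002)),
    # range not reported; +/-25% of the mean, the convention the source
    # tables use for every cost without a published interval
    "cost_esrd":               (43304.0, 32478.0, 54130.0, (75.0, 0.002)),
    "cost_infection":          (17183.0, 16849.0, 17517.0, (32.8, 0.002)),
}

# annual costs of the lifetime phase; ranges +/-25% of the annual mean
_COSTS_1Y = {
    "costy_direct_remission":   (3368.34, 2526.255, 4210.425, (31.5, 0.019)),
    "costy_direct_relapse":     (6486.85, 4865.1375, 8108.5625, (29.2, 0.009)),
    "costy_indirect_remission": (16066.38, 12049.785, 20082.975, (16.1, 0.002)),
    "costy_indirect_relapse":   (17128.13, 12846.0975, 21410.1625, (18.3, 0.002)),
    "costy_esrd":               (86608.0, 64956.0, 108260.0, (75.0, 0.002)),
}

# (mean, range_low, range_high, beta_a, beta_b, fixed)
_UTILITIES = {
    "u_remission":   (0.70, 0.65, 0.80, 14.0, 6.0, False),
    "u_relapse_mmf": (0.60, 0.50, 0.70, 13.8, 9.2, False),
    "u_relapse_cyc": (0.50, 0.40, 0.60, 12.0, 12.0, False),
    "u_esrd":        (0.67, 0.54, 0.85, 14.1, 6.9, False),
    # transient decrement for a major infection (sepsis); not sampled
    "du_infection":  (0.31, 0.20, 0.56, None, None, True),
}


def base_case() -> ParamSet:
    """The base-case :class:`ParamSet`: every maintenance-phase (6-month
    cycle) and posttreatment-phase (annual cycle) parameter with its
    published mean, range and distribution, plus the scalar constants."""
    probs = {
        name: ProbabilityParam(name, m, lo, hi, a, b, 0.5)
        for name, (m, lo, hi, a, b) in _PROBS_6MO.items()
    }
    for name, (m, lo, hi, a, b, dl) in _PROBS_1Y.items():
        probs[name] = ProbabilityParam(name, m, lo, hi, a, b, 1.0, dist_cycle_length=dl)
    costs = {
        name: CostParam(name, m, lo, hi, printed)
        for name, (m, lo, hi, printed) in {**_COSTS_6MO, **_COSTS_1Y}.items()
    }
    utils = {
        name: UtilityParam(name, m, lo, hi, a, b, fixed)
        for name, (m, lo, hi, a, b, fixed) in _UTILITIES.items()
    }
    return ParamSet(probs, costs, utils, dict(DEFAULT_CONSTANTS))
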