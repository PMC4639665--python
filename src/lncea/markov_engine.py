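"""Discrete-time Markov cohort and microsimulation engine.

The engine is generic: a :class:`ModelSpec` declares an ordered set of health
states, a transition rule (which may depend on cycle index and attained age),
per-state per-cycle costs and utility weights, and optional within-cycle
transient events (one-time cost plus a utility decrement applied for the
cycle in which the event occurs).

Reward timing
-------------
By default rewards for cycle ``k`` accrue to the state occupied at the start
of cycle ``k``, discounted at ``(1 + r)^(-t)`` with ``t`` the time of the
cycle start measured from the discount clock origin (``time_offset`` lets a
later phase continue an earlier phase's clock).  Two switches alter this:

* ``accrue_at="end"`` discounts each cycle's reward at the cycle end instead;
* ``half_cycle_correction=True`` applies the trapezoid rule (half weight on
  the first cycle, plus half of a terminal evaluation at the final
  occupancy), the usual approximation for mid-cycle transitions.

Costs are taken as per-cycle amounts; utility weights are multiplied by the
cycle length in years, so QALY totals are in years regardless of cycle size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["EventSpec", "ModelSpec", "Trace", "MicrosimResult",
           "run_cohort", "run_microsim", "discount_factor"]

_ROW_TOL = 1e-9


def discount_factor(rate: float, t: float) -> float:
    """Present-value factor ``(1 + rate)^(-t)`` for a cash flow at ``t`` years."""
    if rate < 0.0:
        raise ValueError(f"discount rate must be nonnegative, got {rate!r}")
    if t < 0.0:
        raise ValueError(f"time must be nonnegative, got {t!r}")
    return (1.0 + rate) ** (-t)


@dataclass(frozen=True)
class EventSpec:
    """A within-cycle transient event (e.g. a major infection).

    The event does not change state: in expectation it adds
    ``probability * one_time_cost`` to the cycle's cost and removes
    ``probability * disutility * cycle_length`` from the cycle's QALY
    (the state utility is floored at zero after the decrement).
    """

    name: str
    probability: float
    one_time_cost: float = 0.0
    disutility: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"event {self.name}: probability must be in [0, 1]")
        if not 0.0 <= self.disutility <= 1.0:
            raise ValueError(f"event {self.name}: disutility must be in [0, 1]")


@dataclass
class ModelSpec:
    """States, transition rule, rewards and events of one strategy/phase.

    ``transition_rule(cycle, age)`` returns the full row-stochastic matrix in
    state order; it is re-evaluated every cycle so age- or cycle-dependent
    models need no special handling.  Absorbing states must self-loop.
    """

    states: tuple[str, ...]
    transition_rule: Callable[[int, float], np.ndarray]
    costs: Mapping[str, float]
    utilities: Mapping[str, float]
    events: Mapping[str, Sequence[EventSpec]] = field(default_factory=dict)
    absorbing: frozenset = frozenset()
    cycle_length: float = 1.0
    discount_rate: float = 0.03

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state names")
        missing = [s for s in self.states if s not in self.costs or s not in self.utilities]
        if missing:
            raise ValueError(f"states missing rewards: {missing}")
        bad_u = [s for s in self.states if not 0.0 <= self.utilities[s] <= 1.0]
        if bad_u:
            raise ValueError(f"utility weights outside [0, 1] for: {bad_u}")
        unknown = set(self.absorbing) - set(self.states)
        if unknown:
            raise ValueError(f"absorbing states not in state list: {sorted(unknown)}")
        if self.cycle_length <= 0.0:
            raise ValueError("cycle length must be positive")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)

    def matrix(self, cycle: int, age: float) -> np.ndarray:
        """Validated transition matrix for one cycle."""
        mat = np.asarray(self.transition_rule(cycle, age), dtype=float)
        if mat.shape != (self.n_states, self.n_states):
            raise ValueError(f"transition matrix has shape {mat.shape}, "
                             f"expected {(self.n_states, self.n_states)}")
        if (mat < -_ROW_TOL).any():
            s = self.states[int(np.argwhere(mat < -_ROW_TOL)[0][0])]
            raise ValueError(f"negative transition probability from state "
                             f"{s!r} at cycle {cycle}")
        rowsums = mat.sum(axis=1)
        bad = np.abs(rowsums - 1.0) > _ROW_TOL
        if bad.any():
            s = self.states[int(np.argmax(bad))]
            raise ValueError(f"transition row for state {s!r} sums to "
                             f"{rowsums[np.argmax(bad)]:.12f} at cycle {cycle}")
        for s in self.absorbing:
            i = self.index(s)
            if abs(mat[i, i] - 1.0) > _ROW_TOL:
                raise ValueError(f"absorbing state {s!r} does not self-loop "
                                 f"at cycle {cycle}")
        return np.clip(mat, 0.0, None)

    def reward_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-state expected cost per cycle and QALY per cycle, with
        transient events folded in in expectation."""
        cost = np.array([self.costs[s] for s in self.states], dtype=float)
        util = np.array([self.utilities[s] for s in self.states], dtype=float)
        for s, evs in self.events.items():
            i = self.index(s)
            for ev in evs:
                cost[i] += ev.probability * ev.one_time_cost
                util[i] -= ev.probability * ev.disutility
        util = np.clip(util, 0.0, None)
        return cost, util * self.cycle_length


@dataclass
class Trace:
    """Cohort run output: per-cycle occupancy and reward accumulators.

    ``occupancy`` has ``n_cycles + 1`` rows (initial distribution included);
    reward arrays have one entry per cycle.  The ``total_*`` properties are
    the end-of-horizon accumulator values.
    """

    states: tuple[str, ...]
    occupancy: np.ndarray
    cost_disc: np.ndarray
    qaly_disc: np.ndarray
    cost_undisc: np.ndarray
    qaly_undisc: np.ndarray
    event_expectations: pd.DataFrame
    cycle_length: float
    start_age: float
    time_offset: float

    @property
    def n_cycles(self) -> int:
        return len(self.cost_disc)

    @property
    def total_cost_disc(self) -> float:
        return float(self.cost_disc.sum())

    @property
    def total_qaly_disc(self) -> float:
        return float(self.qaly_disc.sum())

    @property
    def total_cost_undisc(self) -> float:
        return float(self.cost_undisc.sum())

    @property
    def total_qaly_undisc(self) -> float:
        return float(self.qaly_undisc.sum())

    @property
    def final_occupancy(self) -> np.ndarray:
        return self.occupancy[-1]

    @property
    def end_age(self) -> float:
        return self.start_age + self.n_cycles * self.cycle_length

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        df.insert(0, "cycle", np.arange(len(df)))
        pad = lambda a: np.concatenate([a, [np.nan]])
        df["cost_disc"] = pad(self.cost_disc)
        df["qaly_disc"] = pad(self.qaly_disc)
        df["cost_undisc"] = pad(self.cost_undisc)
        df["qaly_undisc"] = pad(self.qaly_undisc)
        df["cum_cost_disc"] = np.nancumsum(df["cost_disc"])
        df["cum_qaly_disc"] = np.nancumsum(df["qaly_disc"])
        df["cum_cost_undisc"] = np.nancumsum(df["cost_undisc"])
        df["cum_qaly_undisc"] = np.nancumsum(df["qaly_undisc"])
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run_cohort(
    spec: ModelSpec,
    init: Sequence[float],
    n_cycles: int,
    start_age: float,
    *,
    time_offset: float = 0.0,
    accrue_at: str = "start",
    half_cycle_correction: bool = False,
) -> Trace:
    """Propagate a cohort distribution through ``n_cycles`` cycles.

    Rewards accrue to the state occupied at the start of each cycle (see
    module docstring for the timing switches); transitions are applied at
    cycle end; age advances by one cycle length per cycle.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if accrue_at not in ("start", "end"):
        raise ValueError("accrue_at must be 'start' or 'end'")
    x = np.asarray(init, dtype=float)
    if x.shape != (spec.n_states,):
        raise ValueError("init has wrong length")
    if abs(x.sum() - 1.0) > _ROW_TOL or (x < 0).any():
        raise ValueError("init must be a probability vector summing to 1")

    cost_vec, qaly_vec = spec.reward_vectors()
    L, r = spec.cycle_length, spec.discount_rate
    occ = np.empty((n_cycles + 1, spec.n_states))
    occ[0] = x
    cost_d = np.empty(n_cycles)
    qaly_d = np.empty(n_cycles)
    cost_u = np.empty(n_cycles)
    qaly_u = np.empty(n_cycles)
    ev_rows = []
    ev_names = sorted({ev.name for evs in spec.events.values() for ev in evs})

    for k in range(n_cycles):
        t = time_offset + (k + (1 if accrue_at == "end" else 0)) * L
        df = discount_factor(r, t)
        w = 0.5 if (half_cycle_correction and k == 0) else 1.0
        c = float(x @ cost_vec)
        q = float(x @ qaly_vec)
        cost_u[k] = w * c
        qaly_u[k] = w * q
        cost_d[k] = w * c * df
        qaly_d[k] = w * q * df
        row = {}
        for s, evs in spec.events.items():
            xi = x[spec.index(s)]
            for ev in evs:
                row[ev.name] = row.get(ev.name, 0.0) + xi * ev.probability
        ev_rows.append([row.get(n, 0.0) for n in ev_names])
        mat = spec.matrix(k, start_age + k * L)
        x = x @ mat
        occ[k + 1] = x

    if half_cycle_correction:
        # trapezoid terminal term: half a cycle's reward at final occupancy
        t_end = time_offset + n_cycles * L
        df = discount_factor(r, t_end)
        c = 0.5 * float(x @ cost_vec)
        q = 0.5 * float(x @ qaly_vec)
        cost_u[-1] += c
        qaly_u[-1] += q
        cost_d[-1] += c * df
        qaly_d[-1] += q * df

    events = pd.DataFrame(ev_rows, columns=ev_names)
    return Trace(spec.states, occ, cost_d, qaly_d, cost_u, qaly_u,
                 events, L, start_age, time_offset)


@dataclass
class MicrosimResult:
    """Per-individual discounted outcomes from a first-order simulation."""

    costs: np.ndarray
    qalys: np.ndarray
    final_states: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return len(self.costs)

    def summary(self) -> dict[str, float]:
        n = self.n
        return {
            "n": float(n),
            "mean_cost": float(self.costs.mean()),
            "mean_qaly": float(self.qalys.mean()),
            "se_cost": float(self.costs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            "se_qaly": float(self.qalys.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        }


def run_microsim(
    spec: ModelSpec,
    n_individuals: int,
    n_cycles: int,
    start_age: float,
    seed: int,
    *,
    time_offset: float = 0.0,
    accrue_at: str = "start",
    init: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> MicrosimResult:
    """Simulate individual trajectories through the state model.

    Individuals accrue their occupied state's cost and utility each cycle;
    transient events are Bernoulli draws.  Sample means converge to the
    corresponding :func:`run_cohort` totals at the usual 1/sqrt(n) rate, and
    a fixed seed reproduces the run bit for bit.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    L, r = spec.cycle_length, spec.discount_rate

    state_cost = np.array([spec.costs[s] for s in spec.states])
    state_util = np.array([spec.utilities[s] for s in spec.states])
    ev_by_state: dict[int, list[EventSpec]] = {
        spec.index(s): list(evs) for s, evs in spec.events.items()
    }

    if init is None:
        cur = np.zeros(n_individuals, dtype=np.intp)  # everyone starts in state 0
    else:
        p = np.asarray(init, dtype=float)
        if abs(p.sum() - 1.0) > _ROW_TOL or (p < 0).any():
            raise ValueError("init must be a probability vector summing to 1")
        cur = rng.choice(spec.n_states, size=n_individuals, p=p / p.sum()).astype(np.intp)
    costs = np.zeros(n_individuals)
    qalys = np.zeros(n_individuals)

    for k in range(n_cycles):
        t = time_offset + (k + (1 if accrue_at == "end" else 0)) * L
        df = discount_factor(r, t)
        util_k = state_util[cur].copy()
        cost_k = state_cost[cur].copy()
        for i_state, evs in ev_by_state.items():
            mask = cur == i_state
            if not mask.any():
                continue
            for ev in evs:
                hits = mask & (rng.random(n_individuals) < ev.probability)
                cost_k[hits] += ev.one_time_cost
                util_k[hits] -= ev.disutility
        np.clip(util_k, 0.0, None, out=util_k)
        costs += df * cost_k
        qalys += df * util_k * L
        mat = spec.matrix(k, start_age + k * L)
        cum = mat.cumsum(axis=1)
        u = rng.random(n_individuals)
        cur = (u[:, None] > cum[cur]).sum(axis=1).astype(np.intp)

    return MicrosimResult(costs, qalys, cur, seed)
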