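"""Engine semantics: cohort propagation, rewards, events, microsimulation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncea.markov_engine import (EventSpec, ModelSpec, discount_factor,
                                 run_cohort, run_microsim)


def chain(matrix, costs, utils, *, events=None, cycle_length=1.0, rate=0.0,
          absorbing=()):
    mat = np.asarray(matrix, dtype=float)
    n = len(mat)
    states = tuple(f"s{i}" for i in range(n))
    return ModelSpec(
        states=states,
        transition_rule=lambda cycle, age: mat,
        costs={f"s{i}": costs[i] for i in range(n)},
        utilities={f"s{i}": utils[i] for i in range(n)},
        events={f"s{i}": evs for i, evs in (events or {}).items()},
        absorbing=frozenset(f"s{i}" for i in absorbing),
        cycle_length=cycle_length,
        discount_rate=rate,
    )


# a fixed 3-state test chain with nontrivial rewards and an event
ORACLE_MAT = [[0.6, 0.3, 0.1],
              [0.2, 0.5, 0.3],
              [0.0, 0.0, 1.0]]
ORACLE_COSTS = [100.0, 250.0, 0.0]
ORACLE_UTILS = [0.9, 0.5, 0.0]
ORACLE_EVENTS = {0: (EventSpec("ev", 0.2, 50.0, 0.1),)}


def enumerate_paths(mat, costs, utils, events, n_cycles, rate, cycle_length):
    """Independent oracle: expected rewards by explicit path enumeration."""
    n = len(mat)
    ev_cost = [0.0] * n
    ev_du = [0.0] * n
    for i, evs in events.items():
        for ev in evs:
            ev_cost[i] += ev.probability * ev.one_time_cost
            ev_du[i] += ev.probability * ev.disutility
    total_cost = total_qaly = 0.0
    for path in itertools.product(range(n), repeat=n_cycles):
        if path[0] != 0:
            continue
        prob = 1.0
        for a, b in zip(path, path[1:]):
            prob *= mat[a][b]
        for k, s in enumerate(path):
            df = (1.0 + rate) ** (-k * cycle_length)
            total_cost += prob * (costs[s] + ev_cost[s]) * df
            total_qaly += prob * max(utils[s] - ev_du[s], 0.0) * cycle_length * df
    return total_cost, total_qaly


class TestRunCohort:
    def test_single_absorbing_state_accrues_full_person_time(self):
        spec = chain([[1.0]], [0.0], [1.0], absorbing=(0,))
        tr = run_cohort(spec, [1.0], 10, 30.0)
        assert tr.total_qaly_disc == pytest.approx(10.0)
        assert tr.total_cost_disc == 0.0

    def test_two_state_split_after_one_cycle(self):
        spec = chain([[0.5, 0.5], [0.0, 1.0]], [0, 0], [1, 0], absorbing=(1,))
        tr = run_cohort(spec, [1.0, 0.0], 1, 30.0)
        assert tr.final_occupancy == pytest.approx([0.5, 0.5])

    @pytest.mark.parametrize("rate, cycle_length", [(0.0, 1.0), (0.03, 0.5)])
    def test_three_state_chain_matches_path_enumeration(self, rate, cycle_length):
        spec = chain(ORACLE_MAT, ORACLE_COSTS, ORACLE_UTILS,
                     events=ORACLE_EVENTS, cycle_length=cycle_length,
                     rate=rate, absorbing=(2,))
        tr = run_cohort(spec, [1.0, 0.0, 0.0], 3, 30.0)
        cost, qaly = enumerate_paths(ORACLE_MAT, ORACLE_COSTS, ORACLE_UTILS,
                                     ORACLE_EVENTS, 3, rate, cycle_length)
        assert tr.total_cost_disc == pytest.approx(cost, rel=1e-12)
        assert tr.total_qaly_disc == pytest.approx(qaly, rel=1e-12)

    def test_geometric_closed_form_for_discounted_person_time(self):
        # alive/dead chain with utility 1: discounted QALY is a geometric sum
        p_die, r, n = 0.2, 0.05, 25
        spec = chain([[1 - p_die, p_die], [0.0, 1.0]], [0, 0], [1, 0],
                     rate=r, absorbing=(1,))
        tr = run_cohort(spec, [1.0, 0.0], n, 30.0)
        x = (1 - p_die) / (1 + r)
        assert tr.total_qaly_disc == pytest.approx((1 - x ** n) / (1 - x), rel=1e-12)

    def test_probability_conservation_and_monotone_accumulators(self):
        spec = chain(ORACLE_MAT, ORACLE_COSTS, ORACLE_UTILS,
                     events=ORACLE_EVENTS, rate=0.03, absorbing=(2,))
        tr = run_cohort(spec, [1.0, 0.0, 0.0], 50, 30.0)
        assert np.allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert (tr.cost_disc >= 0).all() and (tr.qaly_disc >= 0).all()
        assert tr.total_cost_disc <= tr.total_cost_undisc
        assert tr.total_qaly_disc <= tr.total_qaly_undisc

    def test_row_sum_violation_names_state_and_cycle(self):
        spec = chain([[0.7, 0.2], [0.0, 1.0]], [0, 0], [1, 0])
        with pytest.raises(ValueError, match=r"'s0'.*cycle 0"):
            run_cohort(spec, [1.0, 0.0], 3, 30.0)

    def test_worse_state_transition_never_raises_qaly(self):
        # shifting mass toward the lower-utility state cannot help
        def total(p):
            spec = chain([[1 - p, p], [0.0, 1.0]], [0, 0], [1.0, 0.2],
                         absorbing=(1,))
            return run_cohort(spec, [1.0, 0.0], 10, 30.0).total_qaly_disc
        qalys = [total(p) for p in np.linspace(0.0, 1.0, 11)]
        assert all(a >= b - 1e-12 for a, b in zip(qalys, qalys[1:]))

    def test_half_cycle_correction_trapezoid(self):
        # static cohort: trapezoid equals the plain sum (half first cycle
        # plus half terminal evaluation of the same state)
        spec = chain([[1.0]], [10.0], [1.0], absorbing=(0,))
        plain = run_cohort(spec, [1.0], 4, 30.0)
        hcc = run_cohort(spec, [1.0], 4, 30.0, half_cycle_correction=True)
        assert hcc.total_cost_undisc == pytest.approx(plain.total_cost_undisc)
        # with mortality the trapezoid must lie below the start-state sum
        spec2 = chain([[0.8, 0.2], [0.0, 1.0]], [10.0, 0.0], [1, 0], absorbing=(1,))
        plain2 = run_cohort(spec2, [1.0, 0.0], 4, 30.0)
        hcc2 = run_cohort(spec2, [1.0, 0.0], 4, 30.0, half_cycle_correction=True)
        assert hcc2.total_cost_undisc < plain2.total_cost_undisc

    def test_event_disutility_floors_at_zero(self):
        ev = (EventSpec("bad", 1.0, 0.0, 0.9),)
        spec = chain([[1.0]], [0.0], [0.5], events={0: ev}, absorbing=(0,))
        tr = run_cohort(spec, [1.0], 2, 30.0)
        assert tr.total_qaly_disc == 0.0

    def test_time_offset_continues_discount_clock(self):
        spec = chain([[1.0]], [100.0], [1.0], rate=0.03, absorbing=(0,))
        late = run_cohort(spec, [1.0], 5, 33.0, time_offset=3.0)
        early = run_cohort(spec, [1.0], 5, 30.0)
        assert late.total_cost_disc == pytest.approx(
            early.total_cost_disc * 1.03 ** -3.0)


class TestDiscountFactor:
    @pytest.mark.parametrize("rate, t, expected", [
        (0.03, 0.0, 1.0),
        (0.0, 17.0, 1.0),
        (0.03, 1.0, 0.970874),
    ])
    def test_values(self, rate, t, expected):
        assert discount_factor(rate, t) == pytest.approx(expected, abs=5e-7)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1.0)


class TestMicrosim:
    def test_deterministic_chain_matches_cohort_exactly(self):
        spec = chain([[0.0, 1.0], [0.0, 1.0]], [50.0, 0.0], [1.0, 0.0],
                     rate=0.03, absorbing=(1,))
        cohort = run_cohort(spec, [1.0, 0.0], 4, 30.0)
        micro = run_microsim(spec, 100, 4, 30.0, seed=1)
        assert np.allclose(micro.costs, cohort.total_cost_disc)
        assert np.allclose(micro.qalys, cohort.total_qaly_disc)

    def test_converges_to_cohort_within_three_se(self):
        spec = chain(ORACLE_MAT, ORACLE_COSTS, ORACLE_UTILS,
                     events=ORACLE_EVENTS, rate=0.03, absorbing=(2,))
        cohort = run_cohort(spec, [1.0, 0.0, 0.0], 10, 30.0)
        micro = run_microsim(spec, 10_000, 10, 30.0, seed=11)
        s = micro.summary()
        assert abs(s["mean_cost"] - cohort.total_cost_disc) < 3 * s["se_cost"]
        assert abs(s["mean_qaly"] - cohort.total_qaly_disc) < 3 * s["se_qaly"]

    def test_same_seed_bit_identical(self):
        spec = chain(ORACLE_MAT, ORACLE_COSTS, ORACLE_UTILS,
                     events=ORACLE_EVENTS, rate=0.03, absorbing=(2,))
        a = run_microsim(spec, 500, 6, 30.0, seed=3)
        b = run_microsim(spec, 500, 6, 30.0, seed=3)
        assert (a.costs == b.costs).all() and (a.qalys == b.qalys).all()


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_probability_conserved_on_random_chains(seed):
    r = np.random.default_rng(seed)
    n = int(r.integers(2, 5))
    mat = r.dirichlet(np.ones(n), size=n)
    spec = chain(mat, r.uniform(0, 100, n), r.uniform(0, 1, n),
                 rate=float(r.uniform(0, 0.07)))
    tr = run_cohort(spec, np.eye(n)[0], 20, 30.0)
    assert np.allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-9)
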