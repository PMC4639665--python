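"""The lupus-nephritis maintenance-therapy decision model.

Two phases are built on top of the generic Markov engine:

* **Maintenance phase** (3 years, six 6-month cycles).  Patients enter in
  remission on maintenance therapy (MMF 2 g/day or AZA 150 mg/day).  Relapse
  triggers sequential rescue therapy — MMF rescue first (dose escalation to
  3 g/day for patients maintained on MMF), then IV cyclophosphamide if MMF
  rescue fails.  Remitters from rescue resume maintenance (by default on
  MMF 2 g/day regardless of arm; configurable).  ESRD and death are tracked
  throughout; a major infection is a within-cycle transient event.
* **Posttreatment (lifetime) phase** (annual cycles, default 40).  Patients
  are off immunosuppression; states collapse to remission / relapse / ESRD /
  death.  Lupus-related mortality is built from an age-specific general-
  population life table scaled by an SMR of 7.9 during relapse, divided by
  9.3 in remission (relapse-vs-remission relative risk on MMF) and further
  multiplied by 0.58 for remission after AZA; ESRD mortality is age-specific
  dialysis mortality scaled by a hazard ratio of 1.7 on the rate scale.

The arm evaluators at the bottom wrap phase construction, cohort (or
microsimulation) evaluation and phase chaining into the cost/QALY outcomes
the economic layer consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markov_engine import EventSpec, ModelSpec, Trace, run_cohort, run_microsim
from .param_model import ParamSet, prob_to_rate, rate_to_prob

__all__ = [
    "MAINTENANCE_STATES", "LIFETIME_STATES", "Arm", "RescuePolicy",
    "PhaseLink", "LifeTable",
    "build_maintenance_model", "build_lifetime_model",
    "lupus_mortality", "esrd_mortality", "link_phases", "apply_extrapolation",
    "ThreeYearEvaluator", "LifetimeEvaluator",
]

log = logging.getLogger(__name__)

MAINTENANCE_STATES = (
    "remission_maintenance",   # on the arm's maintenance drug
    "remission_post_mmf",      # back in remission after MMF rescue
    "remission_post_cyc",      # back in remission after CYC rescue
    "relapse_mmf",             # relapse on MMF rescue therapy
    "relapse_cyc",             # relapse on IV cyclophosphamide
    "esrd",
    "death",
)

LIFETIME_STATES = ("remission", "relapse", "esrd", "death")

EXTRAPOLATION_SCENARIOS = ("persist", "no_effect", "decay_1pct", "decay_2pct")


# ---------------------------------------------------------------------------
# life tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeTable:
    """Annual death probability by integer age.

    Lookup uses the floor of the attained age; ages outside the covered span
    raise.  Reads/writes a plain 2-column CSV (age, annual death
    probability).
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if ages.shape != qx.shape or ages.ndim != 1 or len(ages) == 0:
            raise ValueError("ages and qx must be equal-length 1-D arrays")
        if np.any(np.diff(ages) != 1):
            raise ValueError("ages must be consecutive integers")
        if np.any((qx <= 0.0) | (qx >= 1.0)):
            raise ValueError("annual death probabilities must be in (0, 1)")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def q(self, age: float) -> float:
        """Annual death probability at (the floor of) ``age``."""
        i = int(np.floor(age)) - self.min_age
        if not 0 <= i < len(self.ages):
            raise ValueError(f"age {age} outside life-table span "
                             f"[{self.min_age}, {self.max_age}]")
        return float(self.qx[i])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "q": self.qx}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("life-table CSV needs two columns (age, q)")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


# ---------------------------------------------------------------------------
# arms and policies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RescuePolicy:
    """Drug assignments around rescue therapy, switchable for scenario runs.

    ``aza_rescue_drug`` is the MMF dose used as first rescue in the AZA arm
    (base case 2 g/day); patients maintained on MMF always escalate to
    3 g/day.  ``post_mmf_maintenance`` / ``post_cyc_maintenance`` are the
    maintenance drugs resumed after remitting from each rescue state (base
    case MMF 2 g/day in both arms).
    """

    aza_rescue_drug: str = "mmf2"        # "mmf2" | "mmf3"
    post_mmf_maintenance: str = "mmf2"   # "mmf2" | "aza"
    post_cyc_maintenance: str = "mmf2"   # "mmf2" | "aza"

    def __post_init__(self) -> None:
        if self.aza_rescue_drug not in ("mmf2", "mmf3"):
            raise ValueError("aza_rescue_drug must be 'mmf2' or 'mmf3'")
        for f in (self.post_mmf_maintenance, self.post_cyc_maintenance):
            if f not in ("mmf2", "aza"):
                raise ValueError("post-rescue maintenance must be 'mmf2' or 'aza'")


@dataclass(frozen=True)
class Arm:
    """One treatment strategy (maintenance drug) plus its rescue policy."""

    label: str                      # "MMF" | "AZA"
    policy: RescuePolicy = field(default_factory=RescuePolicy)

    def __post_init__(self) -> None:
        if self.label not in ("MMF", "AZA"):
            raise ValueError("arm label must be 'MMF' or 'AZA'")

    @property
    def maintenance_drug(self) -> str:
        return "mmf2" if self.label == "MMF" else "aza"

    @property
    def rescue_drug(self) -> str:
        """MMF dose used in the first rescue state."""
        return "mmf3" if self.label == "MMF" else self.policy.aza_rescue_drug


def _drug_suffix(drug: str) -> str:
    """Map a maintenance drug to the remission-row parameter suffix."""
    return "mmf" if drug in ("mmf2", "mmf3") else "aza"


# ---------------------------------------------------------------------------
# maintenance (3-year) phase
# ---------------------------------------------------------------------------


def build_maintenance_model(
    arm: Arm,
    params: ParamSet,
    values: Mapping[str, float] | None = None,
    *,
    discount_rate: float | None = None,
) -> ModelSpec:
    """Build one arm's 6-month-cycle maintenance-phase model.

    ``values`` supplies point values by parameter name (defaults to the
    parameter means); passing a sampled dict turns this into one PSA inner
    evaluation.  Raises ``KeyError`` naming any missing parameter.
    """
    v = dict(params.means()) if values is None else dict(values)
    if discount_rate is None:
        discount_rate = params.constant("discount_rate")

    def p(name: str) -> float:
        if name not in v:
            raise KeyError(f"maintenance model needs parameter {name!r}")
        return v[name]

    drug_cost = {"aza": p("cost_drug_aza"), "mmf2": p("cost_drug_mmf2"),
                 "mmf3": p("cost_drug_mmf3")}

    def remission_row(drug: str) -> dict[str, float]:
        sfx = _drug_suffix(drug)
        return {
            "death": p(f"p_death_remission_{sfx}"),
            "esrd": p(f"p_esrd_remission_{sfx}"),
            "relapse": p(f"p_relapse_remission_{sfx}"),
            "infection": p(f"p_infection_remission_{sfx}"),
        }

    # drug on board in each remission state
    remission_drug = {
        "remission_maintenance": arm.maintenance_drug,
        "remission_post_mmf": arm.policy.post_mmf_maintenance,
        "remission_post_cyc": arm.policy.post_cyc_maintenance,
    }

    n = len(MAINTENANCE_STATES)
    idx = {s: i for i, s in enumerate(MAINTENANCE_STATES)}
    mat = np.zeros((n, n))
    for state, drug in remission_drug.items():
        row = remission_row(drug)
        i = idx[state]
        mat[i, idx["death"]] = row["death"]
        mat[i, idx["esrd"]] = row["esrd"]
        mat[i, idx["relapse_mmf"]] = row["relapse"]
        mat[i, i] = 1.0 - row["death"] - row["esrd"] - row["relapse"]
    # MMF rescue: competing remission/death/ESRD, residual escalates to CYC
    i = idx["relapse_mmf"]
    rem, dth, esr = p("p_remission_relapse_mmf"), p("p_death_relapse_mmf"), p("p_esrd_relapse_mmf")
    mat[i, idx["remission_post_mmf"]] = rem
    mat[i, idx["death"]] = dth
    mat[i, idx["esrd"]] = esr
    mat[i, idx["relapse_cyc"]] = 1.0 - rem - dth - esr
    # CYC: residual self-loops (retreatment continues until phase end)
    i = idx["relapse_cyc"]
    rem, dth, esr = p("p_remission_relapse_cyc"), p("p_death_relapse_cyc"), p("p_esrd_relapse_cyc")
    mat[i, idx["remission_post_cyc"]] = rem
    mat[i, idx["death"]] = dth
    mat[i, idx["esrd"]] = esr
    mat[i, i] = 1.0 - rem - dth - esr
    # ESRD: no background mortality in this phase beyond dialysis death
    i = idx["esrd"]
    mat[i, idx["death"]] = p("p_death_esrd")
    mat[i, i] = 1.0 - p("p_death_esrd")
    mat[idx["death"], idx["death"]] = 1.0
    mat = _renormalize_rows(mat, MAINTENANCE_STATES, context=f"{arm.label} maintenance")

    care_remission = p("cost_direct_remission") + p("cost_indirect_remission")
    care_relapse = p("cost_direct_relapse") + p("cost_indirect_relapse")
    costs = {
        "relapse_mmf": drug_cost[arm.rescue_drug] + care_relapse,
        "relapse_cyc": p("cost_drug_cyc") + care_relapse,
        "esrd": p("cost_esrd"),
        "death": 0.0,
    }
    for state, drug in remission_drug.items():
        costs[state] = drug_cost[drug] + care_remission

    utilities = {
        "relapse_mmf": p("u_relapse_mmf"),
        "relapse_cyc": p("u_relapse_cyc"),
        "esrd": p("u_esrd"),
        "death": 0.0,
    }
    for state in remission_drug:
        utilities[state] = p("u_remission")

    infection = lambda prob: (EventSpec("major_infection", prob,
                                        p("cost_infection"), p("du_infection")),)
    events = {
        "relapse_mmf": infection(p("p_infection_relapse_mmf")),
        "relapse_cyc": infection(p("p_infection_relapse_cyc")),
    }
    for state, drug in remission_drug.items():
        events[state] = infection(remission_row(drug)["infection"])

    return ModelSpec(
        states=MAINTENANCE_STATES,
        transition_rule=lambda cycle, age: mat,
        costs=costs,
        utilities=utilities,
        events=events,
        absorbing=frozenset({"death"}),
        cycle_length=0.5,
        discount_rate=discount_rate,
    )


def _renormalize_rows(mat: np.ndarray, states: Sequence[str], context: str) -> np.ndarray:
    """Proportionally renormalize rows whose competing probabilities exceed 1.

    Builders fill each row's self-loop with the residual ``1 - sum(exits)``;
    when the competing exit probabilities themselves sum above 1 (extreme
    scenario edits, tail parameter draws, or SMR-scaled mortality at old
    ages) the residual is negative.  Such rows are repaired by zeroing the
    residual and scaling the exits back onto the simplex.  Every repaired
    row is counted on ``_renormalize_rows.count`` (reported by PSA runs) and
    logged — at WARNING the first time a given state needs repair, at DEBUG
    thereafter to keep long age-dependent runs readable.
    """
    neg = mat < -1e-12
    over = mat.sum(axis=1) > 1.0 + 1e-9
    bad = neg.any(axis=1) | over
    if bad.any():
        mat = mat.copy()
        for i in np.where(bad)[0]:
            row = np.clip(mat[i], 0.0, None)
            total = row.sum()
            key = (context.split(" cycle")[0], states[i])
            level = logging.DEBUG if key in _renormalize_rows.seen else logging.WARNING
            _renormalize_rows.seen.add(key)
            log.log(level, "%s: transition row %r exceeds 1 by %.6f; renormalizing",
                    context, states[i], total - 1.0)
            mat[i] = row / total
            _renormalize_rows.count += 1
    return np.clip(mat, 0.0, None)


_renormalize_rows.count = 0
_renormalize_rows.seen = set()


# ---------------------------------------------------------------------------
# age-dependent mortality
# ---------------------------------------------------------------------------


def lupus_mortality(
    age: float,
    state: str,
    arm_label: str,
    life_table: LifeTable,
    *,
    smr: float = 7.9,
    rr_relapse_vs_remission: float = 9.3,
    rr_remission_aza_vs_mmf: float = 0.58,
) -> float:
    """Annual lupus-related death probability in the posttreatment phase.

    During relapse the general-population annual death probability is scaled
    by the SMR on the rate scale.  During remission on MMF the relapse value
    is divided by the relapse-vs-remission relative risk (probability
    scale, as the source derivation states); remission after AZA multiplies
    that by 0.58.
    """
    if state not in ("relapse", "remission"):
        raise ValueError("state must be 'relapse' or 'remission'")
    q = life_table.q(age)
    relapse_q = rate_to_prob(smr * prob_to_rate(q, 1.0), 1.0)
    if state == "relapse":
        return relapse_q
    remission_mmf = relapse_q / rr_relapse_vs_remission
    if arm_label == "MMF":
        return remission_mmf
    if arm_label == "AZA":
        return remission_mmf * rr_remission_aza_vs_mmf
    raise ValueError("arm_label must be 'MMF' or 'AZA'")


def esrd_mortality(age: float, dialysis_table: LifeTable, *, hr: float = 1.7) -> float:
    """Annual death probability on dialysis for lupus-related ESRD: the
    age-specific dialysis-population probability scaled by the hazard ratio
    on the rate scale."""
    q = dialysis_table.q(age)
    return rate_to_prob(hr * prob_to_rate(q, 1.0), 1.0)


# ---------------------------------------------------------------------------
# posttreatment (lifetime) phase
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LifetimeScenario:
    """Extrapolation assumptions for the posttreatment phase.

    ``extrapolation`` controls the remission->relapse probability after the
    maintenance phase: ``persist`` keeps trial-phase effects; ``no_effect``
    assumes certain relapse (probability 1) in both arms; ``decay_kpct``
    compounds the relapse probability by (1 + k/100) per year since the end
    of maintenance.  ``esrd_increment_per_year`` adds that many probability
    points per year to the relapse-state ESRD probability (0.005 per year
    for the "+0.5%/yr" sensitivity row).
    """

    extrapolation: str = "persist"
    esrd_increment_per_year: float = 0.0

    def __post_init__(self) -> None:
        if self.extrapolation not in EXTRAPOLATION_SCENARIOS:
            raise ValueError(f"unknown extrapolation scenario "
                             f"{self.extrapolation!r}; expected one of "
                             f"{EXTRAPOLATION_SCENARIOS}")

    @property
    def decay_factor(self) -> float:
        if self.extrapolation == "decay_1pct":
            return 1.01
        if self.extrapolation == "decay_2pct":
            return 1.02
        return 1.0


def build_lifetime_model(
    arm: Arm,
    params: ParamSet,
    life_table: LifeTable,
    dialysis_table: LifeTable,
    values: Mapping[str, float] | None = None,
    *,
    scenario: LifetimeScenario | str = "persist",
    discount_rate: float | None = None,
) -> ModelSpec:
    """Build one arm's annual-cycle posttreatment model.

    Transition probabilities depend on the attained age (mortality) and on
    the cycle index (extrapolation scenarios); the transition rule is
    therefore a closure re-evaluated each cycle.
    """
    if isinstance(scenario, str):
        scenario = LifetimeScenario(extrapolation=scenario)
    v = dict(params.means()) if values is None else dict(values)
    if discount_rate is None:
        discount_rate = params.constant("discount_rate")
    c = params.constants
    sfx = "mmf" if arm.label == "MMF" else "aza"
    base_relapse = v[f"py_relapse_remission_{sfx}"]
    base_esrd_rem = v[f"py_esrd_remission_{sfx}"]
    base_rem = v["py_remission_relapse"]
    base_esrd_rel = v["py_esrd_relapse"]

    idx = {s: i for i, s in enumerate(LIFETIME_STATES)}

    def rule(cycle: int, age: float) -> np.ndarray:
        years_post = cycle  # cycle 0 starts the year maintenance ends
        if scenario.extrapolation == "no_effect":
            p_rel = 1.0
        else:
            p_rel = min(1.0, base_relapse * scenario.decay_factor ** years_post)
        p_esrd_rel = min(1.0, base_esrd_rel + scenario.esrd_increment_per_year * years_post)
        q_rem = lupus_mortality(
            age, "remission", arm.label, life_table,
            smr=c["smr_nephritis"],
            rr_relapse_vs_remission=c["rr_relapse_vs_remission_mmf"],
            rr_remission_aza_vs_mmf=c["rr_remission_aza_vs_mmf"])
        q_rel = lupus_mortality(
            age, "relapse", arm.label, life_table,
            smr=c["smr_nephritis"],
            rr_relapse_vs_remission=c["rr_relapse_vs_remission_mmf"],
            rr_remission_aza_vs_mmf=c["rr_remission_aza_vs_mmf"])
        q_esrd = esrd_mortality(age, dialysis_table, hr=c["hr_esrd_lupus"])
        mat = np.zeros((4, 4))
        i = idx["remission"]
        mat[i, idx["death"]] = q_rem
        mat[i, idx["esrd"]] = base_esrd_rem
        mat[i, idx["relapse"]] = p_rel
        mat[i, i] = 1.0 - q_rem - base_esrd_rem - p_rel
        i = idx["relapse"]
        mat[i, idx["death"]] = q_rel
        mat[i, idx["esrd"]] = p_esrd_rel
        mat[i, idx["remission"]] = base_rem
        mat[i, i] = 1.0 - q_rel - p_esrd_rel - base_rem
        i = idx["esrd"]
        mat[i, idx["death"]] = q_esrd
        mat[i, i] = 1.0 - q_esrd
        mat[idx["death"], idx["death"]] = 1.0
        return _renormalize_rows(mat, LIFETIME_STATES,
                                 context=f"{arm.label} lifetime cycle {cycle}")

    # off immunosuppression: no drug costs, no infection events
    costs = {
        "remission": v["costy_direct_remission"] + v["costy_indirect_remission"],
        "relapse": v["costy_direct_relapse"] + v["costy_indirect_relapse"],
        "esrd": v["costy_esrd"],
        "death": 0.0,
    }
    utilities = {
        "remission": v["u_remission"],
        "relapse": v["u_relapse_mmf"],
        "esrd": v["u_esrd"],
        "death": 0.0,
    }
    return ModelSpec(
        states=LIFETIME_STATES,
        transition_rule=rule,
        costs=costs,
        utilities=utilities,
        events={},
        absorbing=frozenset({"death"}),
        cycle_length=1.0,
        discount_rate=discount_rate,
    )


def apply_extrapolation(scenario: str, spec_scenario: LifetimeScenario | None = None) -> LifetimeScenario:
    """Return the :class:`LifetimeScenario` for a named extrapolation rule,
    preserving any ESRD-risk increment already configured."""
    base = spec_scenario or LifetimeScenario()
    return replace(base, extrapolation=scenario)


# ---------------------------------------------------------------------------
# phase linkage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseLink:
    """End-of-maintenance hand-off into the posttreatment phase."""

    occupancy: np.ndarray        # over LIFETIME_STATES
    age: float
    time_offset: float           # discount-clock position in years
    cost_disc: float
    qaly_disc: float
    cost_undisc: float
    qaly_undisc: float

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.shape != (len(LIFETIME_STATES),):
            raise ValueError("occupancy must cover the four lifetime states")
        if abs(occ.sum() - 1.0) > 1e-9 or (occ < 0).any():
            raise ValueError("occupancy must be a probability vector")
        object.__setattr__(self, "occupancy", occ)


#: maintenance state -> lifetime state
_LINK_MAP = {
    "remission_maintenance": "remission",
    "remission_post_mmf": "remission",
    "remission_post_cyc": "remission",
    "relapse_mmf": "relapse",
    "relapse_cyc": "relapse",
    "esrd": "esrd",
    "death": "death",
}


def link_phases(maintenance_trace: Trace) -> PhaseLink:
    """Map the final maintenance occupancy onto the lifetime state space and
    carry the accumulators and discount clock forward (age advances by the
    phase duration)."""
    if maintenance_trace.states != MAINTENANCE_STATES:
        raise ValueError("trace does not come from the maintenance model")
    occ = np.zeros(len(LIFETIME_STATES))
    final = maintenance_trace.final_occupancy
    for i, s in enumerate(MAINTENANCE_STATES):
        occ[LIFETIME_STATES.index(_LINK_MAP[s])] += final[i]
    duration = maintenance_trace.n_cycles * maintenance_trace.cycle_length
    return PhaseLink(
        occupancy=occ,
        age=maintenance_trace.start_age + duration,
        time_offset=maintenance_trace.time_offset + duration,
        cost_disc=maintenance_trace.total_cost_disc,
        qaly_disc=maintenance_trace.total_qaly_disc,
        cost_undisc=maintenance_trace.total_cost_undisc,
        qaly_undisc=maintenance_trace.total_qaly_undisc,
    )


# ---------------------------------------------------------------------------
# evaluators
# ---------------------------------------------------------------------------


def _arm_values(params: ParamSet,
                overrides: Mapping[str, float] | None,
                arm_overrides: Mapping[str, float] | None) -> dict[str, float]:
    v = params.means(overrides)
    if arm_overrides:
        unknown = set(arm_overrides) - set(v)
        if unknown:
            raise KeyError(f"unknown parameter override(s): {sorted(unknown)}")
        v.update(arm_overrides)
    return v


@dataclass
class ThreeYearEvaluator:
    """Cohort evaluation of both arms over the 3-year maintenance phase.

    ``overrides`` replace parameter point values in both arms;
    ``arm_overrides`` (keyed by arm label) apply to a single arm — e.g. the
    biased-against-AZA scenario raises the remission indirect cost only in
    the AZA arm.
    """

    params: ParamSet
    arms: tuple[Arm, Arm] = (Arm("AZA"), Arm("MMF"))
    start_age: float = 30.0
    n_cycles: int = 6
    discount_rate: float | None = None
    accrue_at: str = "start"
    half_cycle_correction: bool = False

    def _init_vector(self) -> np.ndarray:
        init = np.zeros(len(MAINTENANCE_STATES))
        init[0] = 1.0  # everyone enters in remission on maintenance
        return init

    def trace(self, arm: Arm,
              values: Mapping[str, float] | None = None) -> Trace:
        spec = build_maintenance_model(arm, self.params, values,
                                       discount_rate=self.discount_rate)
        return run_cohort(spec, self._init_vector(), self.n_cycles,
                          self.start_age, accrue_at=self.accrue_at,
                          half_cycle_correction=self.half_cycle_correction)

    def outcomes(self, overrides: Mapping[str, float] | None = None,
                 arm_overrides: Mapping[str, Mapping[str, float]] | None = None,
                 ) -> dict[str, tuple[float, float]]:
        """``{label: (discounted cost, discounted QALY)}`` for both arms."""
        out = {}
        for arm in self.arms:
            per_arm = (arm_overrides or {}).get(arm.label)
            v = _arm_values(self.params, overrides, per_arm)
            tr = self.trace(arm, v)
            out[arm.label] = (tr.total_cost_disc, tr.total_qaly_disc)
        return out

    def outcomes_from_values(self, values: Mapping[str, float]) -> dict[str, tuple[float, float]]:
        """Evaluate both arms on one shared (e.g. sampled) value dict."""
        out = {}
        for arm in self.arms:
            tr = self.trace(arm, values)
            out[arm.label] = (tr.total_cost_disc, tr.total_qaly_disc)
        return out

    def microsim_outcomes(self, values: Mapping[str, float], n_inner: int,
                          seed: int) -> dict[str, tuple[float, float]]:
        """First-order (microsimulation) evaluation of both arms."""
        out = {}
        for j, arm in enumerate(self.arms):
            spec = build_maintenance_model(arm, self.params, values,
                                           discount_rate=self.discount_rate)
            res = run_microsim(spec, n_inner, self.n_cycles, self.start_age,
                               seed=seed + j, accrue_at=self.accrue_at,
                               init=self._init_vector())
            out[arm.label] = (float(res.costs.mean()), float(res.qalys.mean()))
        return out


@dataclass
class LifetimeEvaluator:
    """Cohort evaluation of both arms over maintenance + posttreatment.

    Totals include the 3-year maintenance phase; the posttreatment phase
    continues the discount clock at year 3 and runs ``horizon_years`` annual
    cycles (40 in the base case).
    """

    params: ParamSet
    life_table: LifeTable
    dialysis_table: LifeTable
    arms: tuple[Arm, Arm] = (Arm("AZA"), Arm("MMF"))
    start_age: float = 30.0
    horizon_years: int = 40
    scenario: LifetimeScenario = field(default_factory=LifetimeScenario)
    discount_rate: float | None = None
    accrue_at: str = "start"
    half_cycle_correction: bool = False

    def _maintenance(self) -> ThreeYearEvaluator:
        return ThreeYearEvaluator(
            self.params, self.arms, self.start_age,
            discount_rate=self.discount_rate, accrue_at=self.accrue_at,
            half_cycle_correction=self.half_cycle_correction)

    def traces(self, arm: Arm,
               values: Mapping[str, float] | None = None) -> tuple[Trace, Trace]:
        """(maintenance trace, posttreatment trace) for one arm."""
        m_trace = self._maintenance().trace(arm, values)
        link = link_phases(m_trace)
        spec = build_lifetime_model(
            arm, self.params, self.life_table, self.dialysis_table, values,
            scenario=self.scenario, discount_rate=self.discount_rate)
        l_trace = run_cohort(spec, link.occupancy, self.horizon_years,
                             link.age, time_offset=link.time_offset,
                             accrue_at=self.accrue_at,
                             half_cycle_correction=self.half_cycle_correction)
        return m_trace, l_trace

    def outcomes(self, overrides: Mapping[str, float] | None = None,
                 arm_overrides: Mapping[str, Mapping[str, float]] | None = None,
                 ) -> dict[str, tuple[float, float]]:
        out = {}
        for arm in self.arms:
            per_arm = (arm_overrides or {}).get(arm.label)
            v = _arm_values(self.params, overrides, per_arm)
            m_trace, l_trace = self.traces(arm, v)
            out[arm.label] = (m_trace.total_cost_disc + l_trace.total_cost_disc,
                              m_trace.total_qaly_disc + l_trace.total_qaly_disc)
        return out

    def outcomes_from_values(self, values: Mapping[str, float]) -> dict[str, tuple[float, float]]:
        out = {}
        for arm in self.arms:
            m_trace, l_trace = self.traces(arm, values)
            out[arm.label] = (m_trace.total_cost_disc + l_trace.total_cost_disc,
                              m_trace.total_qaly_disc + l_trace.total_qaly_disc)
        return out
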