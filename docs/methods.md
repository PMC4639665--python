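# Methods

This note documents the model structure, the parameter machinery, the
numerical conventions and the deliberate design choices behind `lncea`.
Nothing here reports an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Decision problem and model structure

The package compares two maintenance strategies for proliferative lupus
nephritis in patients who responded to induction therapy: MMF 2 g/day
versus AZA 150 mg/day, taken for 3 years, followed by lifelong follow-up
off immunosuppression. Costs are 2013 US dollars from a societal
perspective (direct medical plus indirect productivity/caregiver costs);
effectiveness is in QALYs; both are discounted at 3%/year by default.

### Maintenance phase (six 6-month cycles)

Seven states: remission on maintenance, remission after MMF rescue,
remission after CYC rescue, relapse on MMF rescue, relapse on IV
cyclophosphamide, ESRD, death. The three remission states exist because
the drug a remitter resumes is a policy choice, not an anatomy of disease:
in the base case remitters from either rescue state resume MMF 2 g/day in
*both* arms, and scenario switches can instead escalate the AZA arm's
first rescue to MMF 3 g/day or return AZA-arm CYC remitters to AZA. Each
remission state inherits the transition probabilities and drug cost of the
drug actually on board. For the MMF arm under the default policy the three
remission states are behaviourally identical, so the structure reduces to
the canonical five-state diagram.

Each remission state carries competing 6-month probabilities of
lupus-related death, ESRD, and relapse (arm-specific), with the residual
remaining in remission. The MMF-rescue state resolves to remission
(0.59), death (0.041) or ESRD (0.061), with the residual escalating to
CYC; the CYC state resolves analogously (0.522 / 0.040 / 0.0855) with the
residual repeating CYC until the phase ends. ESRD carries a 0.0513
6-month death probability and is otherwise absorbing-except-death. No
background (non-lupus) mortality is applied in this phase; the sources
list no other death pathway over 3 years.

Major infection is a *transient event*, not a state: in each cycle, state
occupancy × event probability adds the expected one-time inpatient cost
($17,183) and subtracts the fixed disutility (0.31) × cycle length from
that cycle's QALY, floored at utility 0. Events attach to all three
remission states (drug-specific probability) and both relapse states.

### Posttreatment phase (annual cycles, 40 by default)

Four states: remission, relapse, ESRD, death. The end-of-maintenance
occupancy is collapsed onto these states (both relapse states → relapse),
age advances by 3 years, and the discount clock continues at year 3. No
drug costs and no infection events apply; annual direct + indirect care
costs and the same utility weights carry the rewards.

Mortality is age-dependent, rebuilt each cycle from two annual tables:

* relapse: general-population q(age) scaled by SMR 7.9 **on the rate
  scale** (q → 1 − (1−q)^7.9);
* remission on MMF: the relapse value ÷ 9.3, applied on the probability
  scale exactly as the source derivation states; remission after AZA:
  that × 0.58 (so the AZA:MMF remission-mortality ratio is 0.58 at every
  age and the relapse:remission ratio is 9.3);
* ESRD: dialysis-population q(age) scaled by HR 1.7 on the rate scale.

The probability-scale division in the remission branch is a faithful
transcription of the published derivation; at these magnitudes it differs
from rate-scale division by well under 1e-4.

At ages ≳47 the relapse row's competing exits (remission 0.8319 + ESRD
0.1183 + SMR-scaled death) sum above 1. Such rows are repaired by
proportional renormalization onto the simplex; each repair is counted
(PSA reports the total) and logged, at WARNING the first time a state
needs repair and DEBUG thereafter. This is a property of the published
parameter combination, not of sampling.

## Parameters and uncertainty

Probabilities and utilities are Beta-distributed; costs are
Gamma-distributed; the infection disutility is fixed (not sampled). The
published Beta pairs are count-like and internally consistent with the
published means (verified to ±0.002) and are used as printed. The
published Gamma (shape, rate) pairs do **not** reproduce the published
means (e.g. the dialysis cost pair implies $37,500 against the published
$43,304), so sampling uses moment-matched pairs derived from the mean and
the range read as a central 95% interval (sd = range/3.92); the printed
pairs are retained as metadata. Where a cost row publishes no range, ±25%
of the mean is assumed — the same convention the source tables state for
their other cost rows. New Beta parameters, when needed, are fit by
matching mean and variance from a 95% interval.

Two annual-cycle probabilities of the posttreatment phase (AZA relapse
0.0716 and AZA ESRD 0.0061) are published with Beta parameters that live
on the 6-month scale (their means are the 6-month values 0.0364 and
0.0030, and the annual point values are exactly those converted through
the rate scale). These parameters therefore record the distribution's own
time scale and convert each draw: p6 → r = −2 ln(1−p6) → p12 = 1−e^(−r).
The same constant-rate identities (r = −(1/t) ln(1−P), P = 1−e^(−rt))
power all cycle-length conversions and are exact round-trips to 1e-12.

## Engine semantics and numerical conventions

Rewards for cycle k accrue to the state occupied at the *start* of cycle
k, discounted at (1+r)^(−t) with t the cycle-start time on a clock that
phase chaining continues across phases; transitions apply at cycle end;
age advances by one cycle length per cycle. Costs are per-cycle amounts;
utilities are weighted by cycle length so QALYs are in years. Two
switches exist for structural sensitivity: `accrue_at="end"` (discount at
cycle end) and `half_cycle_correction=True` (trapezoid: half weight on
the first cycle plus half of a terminal evaluation), since the original
analysis's cycle-level reward timing is not recoverable from its published
description. Transition rows are validated to sum to 1 within 1e-9 every
cycle, absorbing states must self-loop, and occupancy conservation is
property-tested.

The microsimulation engine draws individual trajectories and Bernoulli
transient events with a seeded generator; identical seeds reproduce runs
bit for bit, and sample means converge to the cohort expectation at the
usual 1/√n rate (checked at n = 10⁴ against the cohort run).

## Economic layer

ICERs are computed with explicit dominance verdicts: "dominant" (cheaper
and more effective), "dominated" (costlier and less effective), and
"cost difference only" when ΔE = 0; numeric ratios are reported only when
meaningful. Only the two published strategies are compared, so no
extended-dominance frontier is needed. CEAC acceptance probabilities are
plain fractions of iterations won on NMB, with exact ties split equally,
so curves sum to 1 at every willingness-to-pay.

## Deterministic sensitivity analyses

All deterministic analyses run in cohort mode (noise-free). Two
expected-value metrics are available: the *decision-node expected value*
(NMB of the optimal strategy at the working WTP — the convention tornado
diagrams in decision-analysis software use, and this package's tornado
default) and the *incremental NMB* (MMF − AZA), which the break-even
search root-finds. With the decision metric the tornado ranks the
remission indirect cost, the remission utility weight and the AZA drug
price on top; with the incremental metric, parameters common to both arms
nearly cancel and drug prices dominate — the decision metric is the
default precisely because between-arm-common parameters *should* show
their uncertainty in a tornado of the decision's value. Uncertainty
shares are reported under both the squared-width convention
(width²/Σwidth², the default) and the linear-width alternative.

The break-even price search brackets the MMF 2 g/day 6-month price and
bisects the incremental NMB to ±$0.01 (scipy brentq); monotonicity of the
incremental NMB in the price is validated by a test, not assumed. Named
scenario objects reproduce every published sensitivity row: excluding
indirect costs, utility overrides, the biased-against-AZA stack (the
remission indirect cost raised to $10,041.49 — applied in both arms, the
reading consistent with the published intermediate ICERs of that stack —
plus remission utility 0.8 and AZA priced at $2,626), rescue-policy
variants, ESRD-risk increments (+0.5/1/2 percentage points per year on
the relapse→ESRD probability), treatment-effect extrapolations, horizon
truncations and discount-rate variants. Treatment-effect decay compounds
the remission→relapse probability by (1 + k/100) per year since
maintenance ended, capped at 1; the no-effect scenario sets it to 1.

## Probabilistic analysis and value of information

The outer loop draws every parameter independently once per iteration
(no correlation structure is published) and evaluates both arms on the
same draw; the inner evaluation is cohort expectation by default, with a
first-order microsimulation inner loop (configurable n, default 1,000)
available for full two-dimensional simulation. Cohort inner mode is the
default because it removes first-order noise from second-order
quantities. The ICE cloud's 95% ellipse comes from the sample mean and
covariance under a bivariate-normal model (χ²₂ radius); degenerate
covariances yield zero-length axes. Per-person EVPI is
E[max_s NMB_s] − max_s E[NMB_s] ≥ 0; population EVPI multiplies by a
discounted stream of the annual decision population over a horizon — the
population size is a required explicit input, as no defensible national
default exists.

## Synthetic mortality tables

The posttreatment phase needs a general-population life table and a
dialysis mortality table; the package generates synthetic stand-ins so
everything runs offline. The general table is Gompertz
(q(a) = 1 − exp(−A e^{B a}), defaults A = 1e-4, B = 0.09), giving adult
mortality of realistic order (q(30) ≈ 0.0015, q(70) ≈ 0.05) with no claim
of demographic fidelity. The dialysis table grows exponentially in the
rate from a base annual probability at age 25 (default slope 0.03/year);
`calibrate_dialysis_table` tunes it so the implied 6-month death
probability at the age a base-case entrant reaches dialysis (~31) equals
the maintenance phase's 0.0513, keeping the phases mutually consistent.
Real tables supplied as 2-column CSV (age, annual death probability) drop
in with no code change.

Because the synthetic tables are stand-ins, absolute lifetime results are
indicative, not registry-grade: passing tests demonstrate the pipeline's
correctness and the robustness of the *orderings* (MMF cost-effective
over a lifetime, ICER improving with horizon, cost-effectiveness lost if
the treatment effect vanishes), not agreement with any specific national
life table. Maintenance-phase results use only published parameters and
are exactly reproducible.

The trial-count simulator exists for parameter recovery testing: binomial
event counts at known per-cycle probabilities (re-expressed over the
follow-up duration), with Beta(events+1, n−events+1) posteriors rebuilt
into parameters. At n = 10⁵ per arm, a model rebuilt from posteriors
reproduces truth-based cohort totals within 1%.

## Base-case settings

| Setting | Value | Rationale |
|---|---|---|
| Start age | 30 years | midpoint of the 20–40 target population |
| Maintenance cycles | 6 × 0.5 y | published design |
| Posttreatment cycles | 40 × 1 y | published base-case horizon |
| Discount rate | 3%/year, costs and QALYs | published base case (0–7% explored) |
| Initial state | 100% remission on maintenance | induction responders |
| WTP grid | $50,000 and $100,000/QALY | conventional US thresholds |
| Reward timing | cycle-start accrual, no half-cycle correction | switches provided |
| Infection disutility duration | one cycle | duration unpublished; explicit choice |

## Known limitations

* The original analysis's cycle-tree internals are unpublished; its exact
  3-year totals imply a reward-accrual weighting (~5 discounted half-year
  accruals) that no 6-cycle reading of the published design reproduces,
  and its small incremental QALY (0.0067) is likewise not recoverable
  from the published state structure — this package's 3-year incremental
  QALY is smaller (~0.0015), though its sensitivity to the remission
  utility matches the published pattern closely. Conclusions (MMF far
  from cost-effective at 3 years; break-even price ≈ $1,000) are robust
  to this.
* Parameters are sampled independently; any real correlation between,
  e.g., relapse probabilities across arms is ignored.
* Side effects other than major infection (cytopenias, GI intolerance,
  infertility) are not modeled; induction therapy is out of scope.
* Subgroup parameter sets from the individual trials are not included —
  only the pooled (meta-analytic) base case is shipped.
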