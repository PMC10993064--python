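# Methods

## The optimisation model

The package models diet change as a projection: among all diets satisfying a
set of linear adequacy, acceptability and emission constraints, it selects
the one minimising the sum of squared *relative* deviations from the
observed group-average diet,

    f(x) = sum_i ((x_i - xbar_i) / xbar_i)^2 .

Relative deviations make the objective scale-free: cutting coffee from 430
to 215 g is as costly as cutting beef from 23 to 11.5 g.  The anchor `xbar`
is the group mean, so the model operates on average diets, not individuals;
all derived quantities (energy, nutrient intakes, emissions) are linear in
`x` given fixed per-gram coefficients.

Assumptions worth keeping in mind:

* **Isoenergetic simulation.** Energy intake is fixed at its observed level;
  the model changes diet *composition* only, deliberately abstracting from
  the separate question of optimal energy intake.
* **Fixed composition and coefficients.** Nutrient densities and emission
  coefficients per gram of each food category do not respond to the
  simulated demand shifts (no price, supply or reformulation feedback).
* **Acceptability via centile boxes.** Each food is confined to the
  [P10, P90] interval of the group's observed consumption distribution, so
  the solution never prescribes consumption levels unobserved in the group.
  The box bounds come from the data; a food with P10 = P90 (or a zero
  observed mean, where the relative deviation is undefined) is removed from
  the decision vector and held fixed at that level.
* **Beef-dairy co-production.** With most beef originating from the dairy
  chain, raw-milk demand implies beef supply: rho * (beef carcass in diet)
  >= (raw-milk equivalents in diet), rho = 33.9 g milk per g carcass
  (default, configurable).  Beef-carcass fractions default to 100 % (beef),
  88 % (offals), 50 % (mixed meat dishes) and 7.5 % (sausages and cold
  cuts); both are data, not code.

## Parameters that matter

| parameter | default | units | role |
| --- | --- | --- | --- |
| `ghge_reduction` r | none / 1/3 / 1/2 | – | emission cap as a fraction of the group baseline |
| `ghge_variant` | `lca` | – | `lca` excludes land-use CO2; `eeio_landuse` includes it |
| `fe_policy` | `observed` | – | female iron floor: 10 mg/d (observed intake) vs 15 mg/d (recommended) |
| `milk_per_beef` rho | 33.9 | g milk / g carcass | beef-dairy jointness |
| energy factors k_j | 17 (protein, carbohydrate), 37 (fat, SFA), 29 (alcohol) | kJ/g | convert intakes to E% shares; configurable per nutrient in `nutrients.csv` |
| solver `tol` | 1e-9 | – | working-set dual/primal tolerance; KKT report tolerance 1e-8 |

E%-form constraints are linearised against the *observed* energy E0, which
is exact here because every simulation is isoenergetic.

## Solver

In scaled variables z_i = x_i / xbar_i the objective is ||z - 1||^2, so the
problem is a strictly convex QP with identity Hessian and a unique global
minimiser.  `solve()`:

1. certifies feasibility with a phase-1 linear programme (HiGHS); infeasible
   instances are reported with an interval-arithmetic diagnosis naming any
   constraint unreachable over the habit boxes;
2. runs a warm-start working-set iteration from the unconstrained optimum
   z = 1, re-solving the working set's equality-restricted KKT system
   exactly at each step (constraint rows are max-norm normalised for
   conditioning) — fast and exact on almost all instances;
3. if that iteration stalls (it can cycle on degenerate geometry), switches
   to a textbook primal active-set method started from the phase-1 feasible
   point, with step-length control against blocking constraints; a final
   fallback through scipy's trust-constr plus KKT polish backs both;
4. always verifies stationarity, primal feasibility, dual signs and
   complementary slackness before reporting `optimal` — a solution that
   fails verification is returned as `numerical_failure` with residuals,
   never silently.

Duals follow the convention `grad f + A_eq' nu + A_ub' lambda = 0`,
`lambda >= 0` for inequalities written `a.x <= b`: a positive dual is the
marginal objective cost of tightening that constraint.  Reported objective
values use the *sum* form above; a mean-normalised objective would have the
same minimiser and rescaled duals.

The test oracle (`brute_force_oracle`) is deliberately independent: it
enumerates every subset of at most n inequality/bound rows, computes each
restricted minimiser in closed form as a minimum-norm least-squares solution
in the relative deviations, discards infeasible candidates and keeps the
best survivor.  It shares no working-set, gradient or dual logic with the
solver and agrees with it to ~1e-15 on hundreds of random instances.

Degenerate inputs: rank-deficient working sets fall back to least-squares
KKT solves (duals then minimal-norm); foods fixed by their boxes are folded
into constraint right-hand sides; an all-fixed problem reduces to a
feasibility check.  Tie-breaking is unnecessary — strict convexity rules
out multiple optima.

## Synthetic survey generator

Group-level dietary surveys of this kind are not public, so
`dietshift.synthetic` generates a self-consistent stand-in used by the test
suite and the acceptance script.

What it emulates:

* **Population structure.** 14 groups per dataset: two sexes x (whole
  population, three education tertiles, income quintiles 1/3/5).
* **Consumption distributions.** Per (group, food), individual intake is
  zero-inflated log-normal; the group's mean, P10 and P90 are the empirical
  statistics of n = 200 simulated individuals (centiles over *all*
  individuals, non-consumers included, with linear interpolation — the
  estimator is a documented choice).  Mean/P10/P90 are therefore mutually
  consistent by construction, and occasional foods (offals, shellfish,
  spirits, legumes) get P10 = 0, exercising the degenerate-bound path.
* **Composition closure.** 74 food categories in 12 main groups with
  per-gram densities for 17 nutrients; energy density is exactly
  17(protein + carbohydrate) + 37 fat + 29 alcohol kJ/g, so E% shares over
  the {protein, fat, carbohydrate, alcohol} partition sum to 100.
* **Emission coefficients.** The LCA set ranks ruminant meat >> cheese >
  pork/poultry > farmed fish/eggs > plant staples; the land-use set
  multiplies domestic foods by class-specific uplifts and leaves wild
  berries, wild fish and imports untouched.
* **Baseline inadequacies.** Both sexes fall short on fibre (about 21/19 g
  vs 35/25 g minima), folate and carbohydrate energy (about 40/44 E% vs a
  45 E% floor), and exceed the SFA (about 16/15 E% vs 10) and sodium
  (about 3.4/2.5 g vs 2.4 g) limits, while protein, amino-acid and most
  micronutrient bounds hold — so the nutrition-only optimisation has real
  work to do, and doing that work (less cheese, butter and processed meat,
  more cereals and plants) also cuts emissions: the synergy mechanism is
  built into the coupling between violations and high-emission foods.

Calibration: the template means and coefficients are fixed so that the
noise-free template reproduces published average-adult conditions — male
~9.4 MJ/cap/day and 5.3 kg CO2e/cap/day, female ~7.4 MJ and 3.8 kg, a
land-use coefficient uplift of ~22 % for the average male diet, and a female
iron intake sitting at its observed-level bound of 10 mg/d.  The calibration
constants are frozen in `synthetic.py`; during design the minimum attainable
emission level of every group was verified (by LP) to lie below half its
baseline, so the −50 % scenario is strictly feasible for all 14 groups, as
in the emulated study, with the tightest margins among low-education female
groups.

What it does **not** emulate, hence what green tests do not show about real
data: recall-day correlation and survey weighting; recipe-level
disaggregation; the real (unknown) skewness of consumption distributions
(log-normality is an assumption isolated behind the generator config); the
full ~61-nutrient recommendation list (the shipped table carries the
published headline bounds plus plausible placeholders); and the exact
published emission-coefficient values, which are only emulated in ranking
and aggregate level.  One structural limit of the land-use emulation:
with a class-uplift model, the female uplift ratio
cannot exceed the male one given the female diet's smaller share of
uplifted animal foods, so the generator matches the male +22 % and the
female ratio lands near +21 %.

## Scenario and sensitivity machinery

`run_scenario` assembles, solves, verifies and summarises one
(group, scenario) pair; stored summaries are recomputed from the optimised
diet at construction, so tables and diets can never drift apart.
`run_all` maps over the grid and collects failures as flagged results.
Reports are pure functions of results; CSV output uses fixed float
formatting, fixed ordering and no timestamps, making full runs
byte-reproducible.  Percent changes for categories with zero baseline are
reported as missing ("n/a" in formatted output), not infinity.

Sensitivity variants are ScenarioSpec transformations (coefficient set,
beef-dairy removal, female iron floor) and compose, although the study
design applies them singly; the cap baseline is recomputed under the
variant's own coefficient set, so relative caps compare like with like, and
uniformly scaling all coefficients leaves relative-cap solutions unchanged.

## Problem sizes and runtime

Default problem sizes: 74 foods (~70 decision variables after fixing
degenerate boxes), ~40 linear constraints plus boxes; the full grid of
42 runs plus sensitivity variants solves in ~2 s on one CPU.  The test
suite's statistical checks use n = 200 individuals per group (the survey
default) and n = 10 000 for the law-of-large-numbers test; the solver
battery checks 100+ random instances against the enumeration oracle.

## Known limitations

* Group-average modelling: nothing is said about intra-group distributions
  of intakes or adequacy.
* No cost/affordability dimension and no environmental indicators beyond
  GHGE.
* The acceptability box and quadratic deviation are proxies for behaviour,
  not a behavioural model; duals measure objective cost, not willingness to
  change.
* Synthetic-data conclusions transfer to the real survey only insofar as
  the emulated structure (violations coupled to high-emission foods,
  centile widths, coefficient rankings) matches it.
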