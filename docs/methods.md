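# Methods

## The linear programs

All analyses reduce to FBA linear programs: optimize one reaction flux
subject to steady state (S·v = 0) and flux bounds, plus equality constraints
pinning measured fluxes. Internally exchange fluxes are export-positive
(uptake negative), the convention of published model files; every
user-facing table reports uptake as a positive number and the conversion
happens only at that boundary. Solving is delegated to cobrapy/optlang with
GLPK; a scipy `linprog` (HiGHS) formulation of the same problems serves as
an independent cross-check in the test-suite and powers the relaxation
diagnostics.

Numerical conventions: feasibility and optimality tolerances 1e-9; fluxes
below 1e-6 mmol/gDW/h are treated as zero everywhere downstream (essentiality
classification, "consumed" tests, correction logging). Equality constraints
are implemented as collapsed bound pairs. Objective coefficients stored in
model files are ignored — the whole point of the tool is swapping
objectives per solve.

**Alternate optima.** Only optimal objective *values* are reported (they are
unique); flux vectors are not unique and are exposed solely through
flux-variability ranges. No secondary parsimony objective is imposed.

## ENM

The essential minimum of nutrient *i* at growth μ and productivity q_P:
open every nutrient uptake (exchanges whose model lower bound permits
uptake — the medium definition; secretion-only boundaries such as lactate
or CO2 are never opened, otherwise by-products would act as nutrients) to
−1000 mmol/gDW/h (effectively infinite at physiological scales while
keeping the LP bounded), pin biomass and product, and maximize the
export-positive exchange flux of *i*; the minimum uptake is max(0, −v*).
Nutrients with any synthesis route fed by unconstrained inputs come out at
0; on a mammalian-like network the non-zero set is the essential amino
acids plus a limited glucose requirement (the obligatory energy source).
When the essential set of "amino acids" specifically is wanted, sweep those
exchanges or use the explicit essential flags carried by profiles.

Properties that follow from LP homogeneity and are enforced by tests:
linearity of each minimum in μ (at q_P = 0), monotonicity in μ and q_P, and
the round trip that capping every *essential* nutrient at its minimum and
maximizing growth returns exactly μ. The round trip deliberately leaves
non-essential nutrients at their medium availability: the essential minimum
is defined with all other uptakes unconstrained, so capping non-essentials
at their (zero) minima would under-supply the energy budget and is not the
inverse operation.

Infeasible growth demands are diagnosed by adding non-negative artificial
supplies on every biomass-substrate metabolite and minimizing their sum
(scipy LP): substrates still needing artificial supply are reported as the
blocked precursors.

## Constraint correction and UOF

Essential uptake measurements below their ENM minima are physically
inconsistent with the observed growth rate; `correct_essential_constraints`
replaces them with the minima (max semantics), logging every replacement
with its magnitude and imputing essentials missing from the profile.
Sub-tolerance deficits (< 1e-6) are raised too but logged as "kept" — they
are rounding, not underestimation.

`uof_minimize` pins growth, productivity and every measured exchange except
the target (equalities; measured secretions are pinned exactly like
uptakes), opens the target's uptake bound, and minimizes its uptake. The
target's own measurement is excluded from the constraint set — tested by
showing the result is invariant to distorting it. "Consumed" means measured
uptake above the zero threshold; other targets require an explicit
`forced=True`. Infeasible constraint sets are never silently relaxed: the
error carries the minimal L1 relaxation (which pinned fluxes must move, by
how much), which is exactly the diagnosis needed when an underestimated
essential measurement poisons the problem.

Whether measured exchanges should be strict equalities or narrow bands is a
modeling choice; equalities are the default here, and a tolerance band can
be emulated through `bound_overrides` on the underlying `LPSpec`.

**BOF asymmetry.** Growth maximization (`predict_growth_bof`) treats
measured rates as availability *limits* (lower bound −rate, upper bound from
the model; a measured secretion becomes a forced minimum secretion), not
equalities. The asymmetry is deliberate: growth maximization asks what the
cell could do with what it had; uptake minimization asks what it must have
consumed given how fast it grew.

## Dual prices

The definition of record is a finite-difference re-solve: inject ε units of
free supply into the exchanged metabolite's mass-balance row (RHS −ε) and
divide the objective change by ε. This single definition covers bounded
exchanges, equality-pinned exchanges and the objective nutrient itself, and
it remains meaningful at degenerate optima where LP duals are non-unique.
Solver shadow prices, mapped to the same availability sign convention
(λ = −shadow price), are exposed as a fast path and agree with the
finite difference to 1e-4 on non-degenerate problems (tested). Default
ε = 1e-4 mmol/gDW/h; the value is insensitive across ε ∈ [1e-5, 1e-3]
away from degeneracy because the optimal value function is piecewise
linear. If the upward injection is infeasible the downward difference is
used and flagged `one_sided`; if both directions are infeasible the matrix
entry is NaN and flagged `failed` — in a fully pinned desk-scale scenario
some perturbations genuinely have no absorbing route, and aborting the
whole matrix for one such entry would be wrong.

The UOF dual matrix evaluates each row at that row's own optimum
(scenario-specific); rows are not normalized against each other and
cross-row quantitative comparison is intentionally unsupported. At a
degenerate biomass optimum with several simultaneously binding nutrients,
reported positive duals may credit only a subset of the binding pair — the
operational check (withdrawing any of them lowers growth) is what the tests
assert.

## Rate calculations

Exponential growth is fitted by ordinary least squares on ln(VCD) vs time —
deterministic, and the slope's standard error is the usual OLS error. The
specific exchange rate over a window is the IVCD quotient
r = μ·V·ΔC/(N_x0·(e^{μt}−1)) (production positive), with the analytic
linear limit substituted below |μt| < 1e-8. Separate growth and rate
windows are supported (growth is typically fitted over the full growth
phase, rates over a later sub-window). Per-cell rates convert to model
units by dividing by the cell dry weight, default 216.1 pg/cell; literature
values for mammalian cells span roughly 200–800 pg/cell, so the parameter
is always explicit. Batch operation at constant volume is assumed —
sampling losses and feed additions are out of scope.

## Synthetic data

`toy_mammalian(n_essential, n_nonessential, seed)` builds the miniature
mammalian-like network used throughout: glucose as the only energy source
with three oxidation routes (glycolysis → 2 lactate + 2 ATP, respiration →
6 CO2 + 10 ATP, and an uncoupled oxidation capturing nothing), essential
nutrients consumed only by biomass/product (each also has a degradation
sink), non-essential nutrients synthesizable from glucose at 2 per glucose
+ 1 ATP — except tyrosine, sourced solely by 1:1 conversion from
phenylalanine — and methionine, whose catabolism consumes serine and
2 ATP instead of having a free degradation route. Biomass coefficients are
drawn once per seed from U(0.05, 0.35) (ATP coefficient U(2, 5)); carbon-
and phosphate-like token counts ride on metabolite notes so internal
reactions can be audited for balance. Default medium availability is
10 mmol/gDW/h per nutrient. The network realizes, at desk scale, the
qualitative structure that matters for the method: Liebig-style essential
limitation, substitution (phe→tyr), burden (met), decoupled by-product
secretion and an unmeasured gas exchange (CO2).

`forward_profile` generates measured profiles by minimizing a seeded,
strictly positive random weighting of all nutrient uptakes with growth and
productivity pinned (nutrient re-export forbidden; optional secretion
floors emulate overflow metabolism). Any optimum of such a weighting is
provably self-consistent for the UOF sweep: with all other exchanges
pinned at the vertex, no single uptake can be reduced further, so the sweep
recovers the generating rates exactly. This is the key property the
recovery tests rely on; it also means generated profiles describe a
minimal-waste cell. Scenarios with measurement slack (e.g. glucose above
its minimum) are constructed from these profiles explicitly where a test
needs absorbing capacity. The generator solves on a fresh solver instance
so that seeded outputs are bit-for-bit reproducible regardless of prior
solves.

Replicate sets apply mean-one lognormal noise (σ² = ln(1+cv²)) per nutrient
per replicate — lognormal so rates stay positive, independent across
nutrients since no covariance structure is claimed — then scale designated
nutrients in designated replicates by an underestimation factor. The
defaults used in tests (cv = 0.05, n = 7, factor 0.5 on lysine in
replicates 1/2/7 and histidine in 4/5/6, base uptakes 20% above minimal
requirement) realize the scenario where only the planted underestimates
limit growth; what passing those tests shows is the mechanism — averaging
the limiting inputs raises predictions and shrinks the deviation metric —
not the numeric deviation values of any real dataset, which depend on real
measurement error structure, biomass composition accuracy and dry-weight
assumptions that the generator does not emulate.

Time-course simulation inverts the rate formulas exactly (noise applied
last), so noiseless round trips are exact by algebra; the Monte-Carlo
checks run 500 seeds at 8 time points, cv = 0.05.

## Deviation metric

`mean_relative_deviation` is the mean over replicates of
|μ_rep − μ_avg| / μ_avg, with μ_avg predicted from the all-averaged inputs
(denominator choice documented, not configurable). Ranking ties in
`limiting_nutrients` break by exchange id.

## Limitations

* Genome-scale CHO analyses are supported (SBML/JSON loading, the same
  sweeps) but not validated here numerically: the published literature
  datasets and model files are not bundled, so headline numbers tied to
  them (aggregate prediction errors, replicate deviation percentages,
  per-cell-line uptake values) are outside what the tests establish.
* ENM aggregate prediction error against measured uptakes is reported as
  mean absolute relative error vs measured when computed; other aggregation
  choices exist and published aggregate figures may not be comparable.
* No thermodynamic/loopless constraints, no MILP/QP objectives, no
  gap-filling or biomass-composition editing; gene–reaction rules are
  carried as opaque annotations and never evaluated.
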