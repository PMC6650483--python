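# uofba — uptake-rate objective functions for mammalian metabolic models

Constraint-based growth prediction for mammalian cells is fragile: flux
balance analysis (FBA) with the conventional biomass objective treats every
measured nutrient uptake as an availability limit, so a single underestimated
essential amino-acid measurement caps the whole growth prediction (Liebig's
law of the minimum, in linear-programming form). `uofba` implements an
inverted workflow built for this situation:

* **ENM (essential nutrient minimization).** For a measured growth rate μ
  (and product formation rate q_P), solve

      min v_uptake,i   s.t.  S·v = 0,  v_biomass = μ,  v_product = q_P,

  with every other nutrient uptake unbounded. The optimum is the *essential
  minimum* of nutrient *i* — positive exactly for nutrients the network
  cannot synthesize (the essential amino acids, plus a limited glucose
  requirement). These minima double as constraint corrections: any measured
  essential uptake below its minimum is replaced.

* **UOF (uptake-rate objective functions).** Pin growth, productivity and
  all measured exchange rates except one, and minimize the remaining
  nutrient's uptake — once per consumed non-essential nutrient. Unlike
  growth maximization, the per-nutrient minima are sensitive to network
  differences (e.g. between cell-line variant models) and come with an
  actionable infeasibility diagnosis (the minimal L1 relaxation of the
  measured constraints) instead of silently biased predictions.

* **Dual (shadow) prices.** λ_i = ∂Z/∂r_i, the marginal change of an
  objective per unit of nutrient availability, computed by finite-difference
  re-solves (supply injection into the metabolite's mass balance; LP duals
  are used as a cross-checked fast path). Against the biomass objective this
  ranks rate-limiting nutrients; against each UOF it yields a matrix of
  nutrient coupling — substitutions (−1 entries) and burdens (positive
  entries, e.g. methionine catabolism consuming serine and ATP).

* **Rate calculations.** Batch-culture time courses (VCD + concentrations)
  to specific rates via exponential growth N_x = N_x0·e^{μt} and the IVCD
  quotient r = μ·V·ΔC / (N_x0·(e^{μt}−1)), with per-cell → per-gram-dry-
  weight conversion (216.1 pg/cell by default, overridable).

Model IO (SBML, BiGG-style JSON) and LP solving run on
[cobrapy](https://opencobra.github.io/cobrapy/) (GLPK backend). Built-in
fixtures include the two four-component hypothetical assembly networks and a
seeded mammalian-like toy network with 12 essential amino-acid analogues,
6 non-essential nutrients, overflow metabolism and an IgG-like product.

## Worked example

Build the toy network, forward-simulate a self-consistent measured profile
at μ = 0.03 h⁻¹, and run the full pipeline (ENM → constraint correction →
UOF sweep → dual matrix):

```bash
uofba fixtures model --variant toy_mammalian --seed 1 --out toy.json
uofba fixtures profile --model toy.json --growth 0.03 --productivity 0.001 \
      --seed 7 --lactate-floor 0.02 --out profile.tsv
uofba pipeline --model toy.json --profile profile.tsv --outdir bundle
cat bundle/uof_minimized.tsv
```

```
exchange_id	minimized_uptake	measured_uptake	status
EX_asp	0.00558	0.00558	optimal
EX_glc	0.0258135	0.0258135	optimal
EX_glu	0.0027	0.0027	optimal
```

Each consumed non-essential nutrient's minimized uptake reproduces the
profile's true rate — the profile is self-consistent by construction, and
the UOF sweep recovers it exactly. The dual-price matrix for selected
availabilities:

```bash
uofba dual-matrix --model toy.json --profile profile.tsv \
      --perturb EX_glc,EX_met,EX_phe,EX_trp --out dm.tsv
```

```
objective\perturbed	EX_glc	EX_met	EX_phe	EX_trp
EX_asp	-1.81818182	nan	7.80625564e-14	7.80625564e-14
EX_glc	-1	0.75	-3.46944695e-14	-3.46944695e-14
EX_glu	-1.81818182	nan	-2.60208521e-14	-2.60208521e-14
```

Reading: one extra unit of glucose lowers the aspartate requirement by 1.82
(synthesis yields 2 per glucose, minus the ATP overhead); extra methionine
*raises* the glucose requirement by 0.75 because its catabolism consumes
serine and ATP (0.5 glucose for the serine + 0.25 for 2.5 ATP); tryptophan
couples to nothing (zeros); `nan` marks perturbations this fully pinned
scenario cannot absorb in either direction (flagged, not fatal). Every
value is a finite-difference re-solve at that row's own optimum.

The library API mirrors the CLI: `enm_sweep`, `correct_essential_constraints`,
`uof_sweep`, `uof_dual_matrix`, `predict_growth_bof`, `limiting_nutrients`,
`mean_relative_deviation`, `estimate_rates`, plus the generators in
`uofba.synthetic_fixtures`.

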