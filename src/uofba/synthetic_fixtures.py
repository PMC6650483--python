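"""Generators for self-consistent synthetic test inputs.

Three generators cover the package's input surface:

* :func:`forward_profile` solves a seeded nutrient-uptake-minimization LP on
  a model and reads off the exchange fluxes — by construction the profile is
  feasible for, and exactly recoverable by, the UOF sweep (a vertex optimal
  for a strictly positive weighting of all nutrient uptakes cannot admit a
  lower single uptake once the others are pinned).
* :func:`generate_replicates` adds multiplicative lognormal measurement
  noise per nutrient per replicate and then scales designated nutrients in
  designated replicates by an underestimation factor — the scenario in which
  a few low essential-amino-acid measurements cap every growth prediction.
* :func:`simulate_timecourse` inverts the exponential-growth rate formulas
  to produce concentration time courses with optional lognormal noise.

All generators are reproducible from their (spec, seed) arguments.  Noise is
lognormal rather than Gaussian so that simulated densities, concentrations
and rates stay positive; nutrients are perturbed independently (no
covariance structure is claimed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .model_core import MetabolicModel
from .enm import nutrient_exchanges
from .lp_engine import SolverFailure
from .rates import TimeCourse
from .uof import ExchangeProfile
from .bof_analysis import ReplicateSet

__all__ = [
    "forward_profile",
    "ReplicateGenSpec",
    "generate_replicates",
    "simulate_timecourse",
]


def forward_profile(
    model: MetabolicModel,
    growth_rate: float,
    productivity: float = 0.0,
    seed: int = 0,
    secretion_floors: Optional[Dict[str, float]] = None,
    unmeasured: Sequence[str] = ("EX_co2", "EX_X", "EX_P"),
) -> ExchangeProfile:
    """A measured-exchange profile consistent with the model by construction.

    Growth (and productivity) are pinned and a seeded, strictly positive
    random weighting of all nutrient uptakes is minimized; the optimal
    vertex's exchange fluxes become the "measured" rates.  Different seeds
    land on different uptake-vs-synthesis allocations.  ``secretion_floors``
    force minimum by-product secretion (e.g. lactate), emulating overflow
    metabolism; ``unmeasured`` exchanges are omitted from the profile, the
    role CO2 or other gas exchanges play in real datasets.
    """
    rng = np.random.default_rng(seed)
    nutrients = nutrient_exchanges(model)
    weights = {rid: float(rng.uniform(0.5, 1.5)) for rid in nutrients}

    # fresh solver instance: warm-start state from earlier solves on the
    # shared model must not perturb the generated vertex bit-for-bit
    cm = model.to_cobra().copy()
    undo = []
    try:
        rxn = cm.reactions.get_by_id(model.biomass_reaction_id)
        undo.append((rxn, rxn.bounds))
        rxn.bounds = (growth_rate, growth_rate)
        if model.product_reaction_id is not None:
            rxn = cm.reactions.get_by_id(model.product_reaction_id)
            undo.append((rxn, rxn.bounds))
            rxn.bounds = (productivity, productivity)
        for rid, floor in (secretion_floors or {}).items():
            rxn = cm.reactions.get_by_id(rid)
            undo.append((rxn, rxn.bounds))
            rxn.bounds = (floor, rxn.upper_bound)
        for rid in nutrients:
            # a nutrient is consumed or untouched in the forward scenario;
            # without this, the weighted objective would reward re-exporting
            # synthesized nutrients
            rxn = cm.reactions.get_by_id(rid)
            undo.append((rxn, rxn.bounds))
            rxn.bounds = (rxn.lower_bound, 0.0)
        old_obj, old_dir = cm.objective, cm.objective_direction
        try:
            # uptake is negative flux, so minimizing weighted uptake is
            # maximizing the weighted exchange fluxes
            cm.objective = {
                cm.reactions.get_by_id(rid): w for rid, w in weights.items()
            }
            cm.objective_direction = "max"
            sol = cm.optimize()
        finally:
            cm.objective, cm.objective_direction = old_obj, old_dir
        if sol.status != "optimal":
            raise SolverFailure(
                f"forward simulation at growth {growth_rate} is {sol.status}"
            )
        rates = {}
        for r in model.reactions:
            if r.is_exchange and r.id not in unmeasured:
                v = float(sol.fluxes[r.id])
                rates[r.id] = -v if abs(v) > 1e-12 else 0.0
    finally:
        for rxn, bounds in reversed(undo):
            rxn.bounds = bounds

    ess_names = model.notes.get("essential_nutrients", [])
    essential_ids = {f"EX_{n}" for n in ess_names if f"EX_{n}" in rates}
    return ExchangeProfile(
        growth_rate=growth_rate,
        productivity=productivity,
        measured_rates=rates,
        essential_ids=essential_ids,
    )


@dataclass
class ReplicateGenSpec:
    """Parameters for a noisy replicate set with planted underestimation.

    ``underestimate`` maps a nutrient exchange id to a multiplicative factor
    in (0, 1]; ``underestimate_replicates`` selects which replicates (0-based
    indices) receive it — default all.
    """

    base_profile: ExchangeProfile
    cv: float = 0.05
    n: int = 7
    underestimate: Dict[str, float] = field(default_factory=dict)
    underestimate_replicates: Dict[str, List[int]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.n < 2:
            raise ValueError("need at least 2 replicates")
        for k, f in self.underestimate.items():
            if not (0 < f <= 1):
                raise ValueError(f"underestimation factor for {k!r} must be in (0, 1]")


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative noise with the requested coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_replicates(spec: ReplicateGenSpec) -> ReplicateSet:
    """Noisy replicates of a base profile with planted underestimation."""
    rng = np.random.default_rng(spec.seed)
    keys = sorted(spec.base_profile.measured_rates)
    replicates = []
    for i in range(spec.n):
        factors = _lognormal_factors(rng, spec.cv, len(keys))
        rates = {
            k: spec.base_profile.measured_rates[k] * f for k, f in zip(keys, factors)
        }
        for k, factor in spec.underestimate.items():
            which = spec.underestimate_replicates.get(k)
            if which is None or i in which:
                rates[k] = rates[k] * factor
        replicates.append(replace(spec.base_profile, measured_rates=rates))
    return ReplicateSet(replicates, labels=[f"rep{i + 1}" for i in range(spec.n)])


def simulate_timecourse(
    mu: float,
    rates: Dict[str, float],
    initial_concentrations: Dict[str, float],
    n0: float,
    volume: float,
    times: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> TimeCourse:
    """Exponential-growth time course implied by constant cell-specific rates.

    ``rates`` are in mmol per 10^6 cells per hour, production positive
    (uptake negative); ``n0`` is the initial cell count in 10^6 cells and
    ``volume`` the culture volume in mL.  Concentrations follow

        C_i(t) = C_i(0) + r_i * N0 * (exp(mu*t) - 1) / (mu * V)

    Simulated (noise-free) concentrations must stay non-negative over the
    horizon; measurement noise, when requested, is applied last.
    """
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    vcd = n0 * np.exp(mu * times) / volume
    if abs(mu) * max(abs(times[-1]), 1.0) < 1e-12:
        growth_factor = n0 * times
    else:
        growth_factor = n0 * (np.exp(mu * times) - 1.0) / mu
    concentrations: Dict[str, np.ndarray] = {}
    for met in sorted(rates):
        c0 = initial_concentrations.get(met, 0.0)
        curve = c0 + rates[met] * growth_factor / volume
        if np.any(curve < -1e-9):
            t_cross = float(times[np.argmax(curve < -1e-9)])
            raise ValueError(
                f"metabolite {met!r} is depleted below zero at t={t_cross:g} h; "
                "shorten the horizon or raise the initial concentration"
            )
        concentrations[met] = np.clip(curve, 0.0, None)
    if noise_cv > 0:
        vcd = vcd * _lognormal_factors(rng, noise_cv, len(times))
        concentrations = {
            k: v * _lognormal_factors(rng, noise_cv, len(times))
            for k, v in concentrations.items()
        }
    return TimeCourse(times=times, vcd=vcd, concentrations=concentrations, volume=volume)
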