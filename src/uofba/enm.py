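"""Essential nutrient minimization (ENM).

For a fixed growth rate (and, when measured, product formation rate) the
*essential minimum* of a nutrient is the smallest uptake of that nutrient
that can sustain the growth when every other nutrient may be consumed
without limit.  Nutrients whose essential minimum is positive cannot be
synthesized by the network — for a mammalian model these are the essential
amino acids (plus a limited glucose requirement as the obligatory energy
source).  Nutrients with an internal synthesis route fed by unconstrained
inputs always come out at zero.

The essential minima double as constraint corrections: a measured uptake
below the essential minimum is physically impossible at the stated growth
rate and would silently cap any growth-maximization, so downstream analyses
replace such measurements with the ENM value (see :mod:`uofba.uof`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np

from .model_core import MetabolicModel, stoichiometric_matrix
from .lp_engine import (
    LPSpec,
    InfeasibleProblem,
    ZERO_FLUX_TOL,
    solve,
)

__all__ = [
    "ENMResult",
    "essential_minimum",
    "enm_sweep",
    "predict_concentration_timecourse",
    "nutrient_exchanges",
    "UNBOUNDED_UPTAKE",
]

#: uptake bound used to emulate unlimited consumption (mmol/gDW/h);
#: effectively infinite at physiological flux scales while keeping LPs bounded
UNBOUNDED_UPTAKE = 1e3


@dataclass
class ENMResult:
    growth_rate: float
    productivity: float
    minimal_uptake: Dict[str, float]  # exchange id -> uptake >= 0 (mmol/gDW/h)
    essential_ids: Set[str]
    tolerance: float = ZERO_FLUX_TOL
    errors: Dict[str, str] = field(default_factory=dict)


def nutrient_exchanges(model: MetabolicModel) -> List[str]:
    """Exchanges that permit uptake in the model file (the medium definition).

    Secretion-only boundaries (by-products, biomass and product sinks) are
    not nutrients and are never opened by ENM.
    """
    return sorted(
        r.id for r in model.reactions if r.is_exchange and r.lower_bound < 0
    )


def _enm_spec(model: MetabolicModel, growth_rate: float, productivity: float,
              objective: str, sense: str = "maximize") -> LPSpec:
    if model.biomass_reaction_id is None:
        raise ValueError("model has no biomass reaction; cannot constrain growth")
    overrides = {
        rid: (-UNBOUNDED_UPTAKE, model.reaction(rid).upper_bound)
        for rid in nutrient_exchanges(model)
    }
    equalities = {model.biomass_reaction_id: growth_rate}
    if productivity != 0.0:
        if model.product_reaction_id is None:
            raise ValueError("model has no product reaction; productivity must be 0")
        equalities[model.product_reaction_id] = productivity
    elif model.product_reaction_id is not None:
        equalities[model.product_reaction_id] = 0.0
    return LPSpec(model, objective, sense, equalities, overrides)


def essential_minimum(
    model: MetabolicModel,
    growth_rate: float,
    productivity: float,
    nutrient: str,
) -> float:
    """Minimal uptake of one nutrient sustaining the given growth/productivity.

    All nutrient uptakes are opened to effectively unlimited consumption,
    growth and productivity are pinned, and the named nutrient's uptake is
    minimized (equivalently its exchange flux, export-positive, maximized).
    The result is clipped at zero: if the network can grow while *secreting*
    the nutrient, its requirement is zero.
    """
    if growth_rate < 0:
        raise ValueError("growth rate must be non-negative")
    rxn = model.reaction(nutrient)
    if not rxn.is_exchange:
        raise ValueError(f"{nutrient!r} is not an exchange reaction")
    spec = _enm_spec(model, growth_rate, productivity, nutrient, "maximize")
    sol = solve(spec)
    if not sol.optimal:
        raise InfeasibleProblem(
            f"growth rate {growth_rate} infeasible even with unlimited uptake; "
            f"blocked biomass precursors: {blocked_precursors(model, growth_rate, productivity)}",
        )
    return max(0.0, -sol.objective_value)


def enm_sweep(
    model: MetabolicModel,
    growth_rate: float,
    productivity: float = 0.0,
    nutrients: Optional[Iterable[str]] = None,
    tolerance: float = ZERO_FLUX_TOL,
) -> ENMResult:
    """One ENM solve per nutrient; classify essential vs non-essential.

    Per-nutrient failures are collected in ``result.errors`` rather than
    aborting the sweep.  Output ordering is deterministic (sorted by
    exchange id), and each minimum is independent of the order of queries.
    """
    ids = sorted(nutrients) if nutrients is not None else nutrient_exchanges(model)
    minimal: Dict[str, float] = {}
    errors: Dict[str, str] = {}
    for rid in ids:
        try:
            minimal[rid] = essential_minimum(model, growth_rate, productivity, rid)
        except Exception as exc:
            errors[rid] = str(exc)
    essential = {rid for rid, v in minimal.items() if v > tolerance}
    return ENMResult(
        growth_rate=growth_rate,
        productivity=productivity,
        minimal_uptake=minimal,
        essential_ids=essential,
        tolerance=tolerance,
        errors=errors,
    )


def blocked_precursors(
    model: MetabolicModel, growth_rate: float, productivity: float = 0.0
) -> List[Tuple[str, float]]:
    """Which biomass substrates block an infeasible growth demand, and by how much.

    Solves the ENM problem with non-negative artificial supplies on every
    biomass-substrate metabolite and minimizes their total: metabolites that
    still need artificial supply are the blocked precursors.
    """
    from scipy.optimize import linprog

    if model.biomass_reaction_id is None:
        raise ValueError("model has no biomass reaction")
    biomass = model.reaction(model.biomass_reaction_id)
    substrates = sorted(m for m, c in biomass.stoichiometry.items() if c < 0)
    S = stoichiometric_matrix(model)
    midx = {mid: i for i, mid in enumerate(S.index)}
    ridx = {rid: j for j, rid in enumerate(S.columns)}
    n = S.shape[1]
    k = len(substrates)

    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    for rid in nutrient_exchanges(model):
        lb[ridx[rid]] = -UNBOUNDED_UPTAKE
    j = ridx[model.biomass_reaction_id]
    lb[j] = ub[j] = growth_rate
    if model.product_reaction_id is not None:
        j = ridx[model.product_reaction_id]
        lb[j] = ub[j] = productivity

    # S.v + inj = 0 with inj >= 0 only on biomass substrate rows
    A = np.hstack([S.to_numpy(), np.zeros((S.shape[0], k))])
    for c, mid in enumerate(substrates):
        A[midx[mid], n + c] = 1.0
    cvec = np.concatenate([np.zeros(n), np.ones(k)])
    bounds = [(float(l), float(u)) for l, u in zip(lb, ub)] + [(0, None)] * k
    res = linprog(cvec, A_eq=A, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if not res.success:
        return [(mid, float("nan")) for mid in substrates]
    blocked = [
        (mid, float(res.x[n + c]))
        for c, mid in enumerate(substrates)
        if res.x[n + c] > ZERO_FLUX_TOL
    ]
    blocked.sort(key=lambda t: -t[1])
    return blocked


def predict_concentration_timecourse(
    enm: ENMResult,
    initial_concentrations: Dict[str, float],
    n0: float,
    volume: float,
    times: np.ndarray,
    dry_weight: float,
) -> Dict[str, np.ndarray]:
    """Concentration curves implied by constant cell-specific uptake rates.

    Integrating uptake * biomass over exponential growth gives

        C_i(t) = C_i(0) - r_i * DW * N0 * (exp(mu*t) - 1) / (mu * V)

    with ``r_i`` the dry-weight-specific minimal uptake, ``DW`` the per-cell
    dry weight, ``N0`` the initial cell count (10^6 cells) and ``V`` the
    volume (mL).  For mu = 0 the analytic limit is linear depletion
    ``C_i(t) = C_i(0) - r_i * DW * N0 * t / V``.  Keys of
    ``initial_concentrations`` are metabolite names matched against the
    exchange ids ``EX_<name>`` in the ENM result.
    """
    times = np.asarray(times, dtype=float)
    mu = enm.growth_rate
    grams_per_1e6_cells = dry_weight * 1e6 * 1e-12
    if abs(mu) * max(abs(times[-1]), 1.0) < 1e-12:
        growth_factor = n0 * times
    else:
        growth_factor = n0 * (np.exp(mu * times) - 1.0) / mu
    curves: Dict[str, np.ndarray] = {}
    for met, c0 in initial_concentrations.items():
        rid = f"EX_{met}" if f"EX_{met}" in enm.minimal_uptake else met
        uptake_dw = enm.minimal_uptake.get(rid, 0.0)
        r_cell = uptake_dw * grams_per_1e6_cells  # mmol/10^6 cells/h
        curves[met] = c0 - r_cell * growth_factor / volume
    return curves
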