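"""Formulate and solve FBA linear programs; compute dual (shadow) prices.

Every analysis in this package reduces to the same primitive: optimize one
reaction flux subject to steady state (S.v = 0), flux bounds and a set of
equality constraints pinning measured fluxes.  Solving is delegated to
cobrapy's optlang layer (GLPK by default); this module owns the problem
formulation, status handling, the availability sign convention for dual
prices, flux-variability sweeps and the infeasibility diagnostic.

Dual prices
-----------
The dual price of a nutrient is the marginal change of the optimal objective
per unit increase of that nutrient's availability.  The definition of record
is a finite-difference re-solve: one extra unit of the nutrient is injected
into its mass balance (equivalent to one more unit of supply, regardless of
whether the exchange flux itself is fixed) and the objective change is
divided by the injection size.  LP solver duals are exposed as a fast path
(`dual_price_lp`) but at degenerate optima they are non-unique, so the
finite-difference value is authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .model_core import MetabolicModel, stoichiometric_matrix

__all__ = [
    "LPSpec",
    "FluxSolution",
    "DualPrice",
    "SolverFailure",
    "InfeasibleProblem",
    "solve",
    "dual_price_fd",
    "dual_price_lp",
    "flux_variability",
    "relaxation_diagnosis",
    "FEASIBILITY_TOL",
    "ZERO_FLUX_TOL",
    "DEFAULT_FD_EPSILON",
]

#: mass-balance residual accepted as zero (mmol/gDW/h)
FEASIBILITY_TOL = 1e-9
#: flux magnitude treated as zero everywhere downstream (mmol/gDW/h)
ZERO_FLUX_TOL = 1e-6
#: default perturbation for finite-difference dual prices (mmol/gDW/h)
DEFAULT_FD_EPSILON = 1e-4


class SolverFailure(RuntimeError):
    """The backend failed numerically (distinct from a proven infeasibility)."""


class InfeasibleProblem(RuntimeError):
    """Raised by helpers that require an optimal base solution."""

    def __init__(self, message: str, diagnosis: Optional[List[Tuple[str, float]]] = None):
        super().__init__(message)
        self.diagnosis = diagnosis or []


@dataclass
class LPSpec:
    """One FBA linear program.

    ``equality_constraints`` pin reaction fluxes (internal sign convention:
    exchange uptake is negative).  ``bound_overrides`` replace a reaction's
    (lower, upper) bounds; equalities win over overrides for the same id.
    """

    model: MetabolicModel
    objective_reaction: str
    sense: str = "maximize"
    equality_constraints: Dict[str, float] = field(default_factory=dict)
    bound_overrides: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sense not in ("maximize", "minimize"):
            raise ValueError(f"unknown sense {self.sense!r}")
        self.model.reaction(self.objective_reaction)  # raises KeyError if absent
        for rid in list(self.equality_constraints) + list(self.bound_overrides):
            self.model.reaction(rid)


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: Dict[str, float]
    duals: Dict[str, float]  # metabolite id -> availability dual price
    reduced_costs: Dict[str, float]
    solver_name: str = "glpk"
    objective_reaction: str = ""
    sense: str = "maximize"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class DualPrice:
    """A finite-difference dual price; ``one_sided`` flags a boundary case."""

    value: float
    epsilon: float
    one_sided: bool = False


def _set_constraint_bounds(constraint, lb, ub) -> None:
    # optlang rejects transient lb > ub states; widen first, then narrow.
    constraint.lb = None
    constraint.ub = ub
    constraint.lb = lb


def _apply_spec(cm, spec: LPSpec):
    """Apply overrides/equalities/objective to the cobra model; return undo list."""
    undo = []
    for rid, (lb, ub) in spec.bound_overrides.items():
        r = cm.reactions.get_by_id(rid)
        undo.append((r, r.bounds))
        r.bounds = (lb, ub)
    for rid, value in spec.equality_constraints.items():
        r = cm.reactions.get_by_id(rid)
        undo.append((r, r.bounds))
        r.bounds = (value, value)
    return undo


def solve(spec: LPSpec) -> FluxSolution:
    """Solve one FBA LP and return the full solution with duals.

    The returned ``duals`` map each metabolite to its availability dual price
    (sign convention: positive means the objective increases when one more
    unit of the metabolite is supplied), derived from the LP shadow prices.
    """
    model = spec.model
    cm = model.to_cobra()
    undo = _apply_spec(cm, spec)
    old_objective = cm.objective
    old_direction = cm.objective_direction
    try:
        cm.objective = spec.objective_reaction
        cm.objective_direction = "max" if spec.sense == "maximize" else "min"
        from cobra.exceptions import OptimizationError

        try:
            import warnings

            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message="Solver status is.*")
                sol = cm.optimize()
            status = sol.status
        except OptimizationError:
            status = cm.solver.status
        except Exception as exc:  # pragma: no cover - backend crash
            raise SolverFailure(f"LP backend failed: {exc}") from exc
        if status not in ("optimal", "infeasible", "unbounded"):
            raise SolverFailure(f"LP backend returned status {status!r}")
        if status != "optimal":
            return FluxSolution(
                status=status,
                objective_value=float("nan"),
                fluxes={},
                duals={},
                reduced_costs={},
                objective_reaction=spec.objective_reaction,
                sense=spec.sense,
            )
        fluxes = {rid: float(v) for rid, v in sol.fluxes.items()}
        # availability dual = -d(objective)/d(mass-balance rhs): supplying one
        # unit of metabolite i shifts its row's rhs by -1.
        duals = {mid: -float(v) for mid, v in sol.shadow_prices.items()}
        rc = {rid: float(v) for rid, v in sol.reduced_costs.items()}
        return FluxSolution(
            status="optimal",
            objective_value=float(sol.objective_value),
            fluxes=fluxes,
            duals=duals,
            reduced_costs=rc,
            objective_reaction=spec.objective_reaction,
            sense=spec.sense,
        )
    finally:
        cm.objective = old_objective
        cm.objective_direction = old_direction
        for r, bounds in reversed(undo):
            r.bounds = bounds


def _objective_with_injection(spec: LPSpec, metabolite_id: str, amount: float) -> Optional[float]:
    """Optimal objective with ``amount`` units of free supply of a metabolite.

    Returns None when the perturbed problem is infeasible.
    """
    cm = spec.model.to_cobra()
    constraint = cm.constraints[metabolite_id]
    old = (constraint.lb, constraint.ub)
    try:
        _set_constraint_bounds(constraint, -amount, -amount)
        sol = solve(spec)
    finally:
        _set_constraint_bounds(constraint, *old)
    return sol.objective_value if sol.optimal else None


def dual_price_fd(
    spec: LPSpec,
    perturbed_reaction: str,
    epsilon: float = DEFAULT_FD_EPSILON,
    base_objective: Optional[float] = None,
) -> DualPrice:
    """Finite-difference dual price of an exchanged nutrient's availability.

    ``perturbed_reaction`` names an exchange reaction; its single metabolite
    receives an injection of ``epsilon`` units and the problem is re-solved.
    If the upward perturbation is infeasible, the downward (withdrawal)
    direction is used instead and the result is flagged ``one_sided``.
    """
    rxn = spec.model.reaction(perturbed_reaction)
    met = rxn.exchanged_metabolite
    if base_objective is None:
        base = solve(spec)
        if not base.optimal:
            raise InfeasibleProblem(
                f"base problem is {base.status}; dual prices undefined"
            )
        base_objective = base.objective_value
    up = _objective_with_injection(spec, met, epsilon)
    if up is not None:
        return DualPrice(value=(up - base_objective) / epsilon, epsilon=epsilon)
    down = _objective_with_injection(spec, met, -epsilon)
    if down is None:
        raise InfeasibleProblem(
            f"both perturbation directions infeasible for {perturbed_reaction!r}"
        )
    return DualPrice(value=(base_objective - down) / epsilon, epsilon=epsilon, one_sided=True)


def dual_price_lp(solution: FluxSolution, reaction_id: str, model: MetabolicModel) -> float:
    """Solver dual price for an exchange's metabolite, availability convention.

    Requires duals on ``solution``; falls back is the caller's responsibility
    (use :func:`dual_price_fd`, the definition of record, near degeneracy).
    """
    if not solution.optimal:
        raise InfeasibleProblem("dual prices require an optimal solution")
    if not solution.duals:
        raise NotImplementedError("solver did not expose dual values")
    met = model.reaction(reaction_id).exchanged_metabolite
    return solution.duals[met]


def flux_variability(
    spec: LPSpec,
    reactions: Iterable[str],
    fix_objective_at: Optional[float] = None,
) -> Dict[str, Tuple[float, float]]:
    """Min/max flux per reaction with the objective pinned at its optimum."""
    if fix_objective_at is None:
        base = solve(spec)
        if not base.optimal:
            raise InfeasibleProblem(
                f"cannot run FVA: base problem is {base.status}",
                diagnosis=relaxation_diagnosis(spec),
            )
        fix_objective_at = base.objective_value
    pinned = dict(spec.equality_constraints)
    pinned[spec.objective_reaction] = fix_objective_at
    ranges: Dict[str, Tuple[float, float]] = {}
    for rid in reactions:
        lo_spec = LPSpec(spec.model, rid, "minimize", pinned, dict(spec.bound_overrides))
        hi_spec = LPSpec(spec.model, rid, "maximize", pinned, dict(spec.bound_overrides))
        lo = solve(lo_spec)
        hi = solve(hi_spec)
        if not (lo.optimal and hi.optimal):
            raise InfeasibleProblem(
                f"FVA subproblem for {rid!r} is {lo.status}/{hi.status} with the "
                f"objective fixed at {fix_objective_at}",
                diagnosis=relaxation_diagnosis(lo_spec),
            )
        ranges[rid] = (lo.objective_value, hi.objective_value)
    return ranges


def relaxation_diagnosis(spec: LPSpec, tol: float = ZERO_FLUX_TOL) -> List[Tuple[str, float]]:
    """Minimal L1 relaxation of the equality constraints restoring feasibility.

    Returns ``(reaction_id, required_shift)`` pairs for every pinned flux that
    must move, sorted by decreasing |shift|.  This surfaces the classic
    pathology of growth predictions dictated by a single underestimated
    essential-nutrient measurement: the diagnosis names the offending fluxes
    instead of silently relaxing them.
    """
    from scipy.optimize import linprog

    model = spec.model
    S = stoichiometric_matrix(model).to_numpy()
    rids = [r.id for r in model.reactions]
    ridx = {rid: i for i, rid in enumerate(rids)}
    n = len(rids)
    pinned = list(spec.equality_constraints.items())
    k = len(pinned)

    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    for rid, (lo, hi) in spec.bound_overrides.items():
        lb[ridx[rid]], ub[ridx[rid]] = lo, hi

    # variables: v (n), s+ (k), s- (k); minimize sum of slacks
    A_eq = np.zeros((S.shape[0] + k, n + 2 * k))
    b_eq = np.zeros(S.shape[0] + k)
    A_eq[: S.shape[0], :n] = S
    for j, (rid, value) in enumerate(pinned):
        row = S.shape[0] + j
        A_eq[row, ridx[rid]] = 1.0
        A_eq[row, n + j] = 1.0       # s+ shifts the pinned value down
        A_eq[row, n + k + j] = -1.0  # s- shifts it up
        b_eq[row] = value
    c = np.concatenate([np.zeros(n), np.ones(2 * k)])
    bounds = [(float(l), float(u)) for l, u in zip(lb, ub)] + [(0, None)] * (2 * k)
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        return [(rid, float("nan")) for rid, _ in pinned]
    shifts = []
    for j, (rid, _) in enumerate(pinned):
        shift = res.x[n + k + j] - res.x[n + j]  # positive: must move up
        if abs(shift) > tol:
            shifts.append((rid, float(shift)))
    shifts.sort(key=lambda t: -abs(t[1]))
    return shifts


def check_mass_balance(model: MetabolicModel, fluxes: Dict[str, float],
                       tol: float = 1e-6) -> float:
    """Max |S.v| residual — an audit independent of the LP backend."""
    S = stoichiometric_matrix(model)
    v = np.array([fluxes.get(rid, 0.0) for rid in S.columns])
    residual = S.to_numpy() @ v
    worst = float(np.max(np.abs(residual))) if len(residual) else 0.0
    if worst > tol:
        worst_met = S.index[int(np.argmax(np.abs(residual)))]
        raise AssertionError(f"mass balance violated at {worst_met!r}: residual {worst:g}")
    return worst
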