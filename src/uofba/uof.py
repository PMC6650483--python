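"""Uptake-rate objective functions (UOFs) and the dual-price matrix.

Where conventional FBA maximizes growth under measured uptake limits, the
UOF approach inverts the question: growth, productivity and every measured
exchange flux *except one* are pinned as constraints, and the remaining
nutrient's uptake is minimized.  Run over each consumed non-essential
nutrient in turn this yields a per-nutrient minimal requirement profile that
is far more sensitive to network differences (e.g. between cell-line
variant models) than growth maximization, which collapses to the single
rate-limiting nutrient.

Before the sweep, essential amino-acid constraints are corrected with the
ENM-predicted minima whenever the measured value is smaller — an
underestimated essential uptake is inconsistent with the observed growth
rate and would otherwise make the constraint set infeasible.

The dual-price matrix extends the analysis: entry (i, j) is the marginal
change of nutrient i's minimized uptake per unit increase of nutrient j's
availability, computed at nutrient i's own optimum.  A -1 entry reads
"one unit of j substitutes one unit of i"; positive entries flag nutrients
whose surplus *burdens* the network (e.g. methionine, whose catabolism
consumes serine and ATP).  Each row is scenario-specific — it is evaluated
at that row's own optimal solution — so rows are not normalized against
each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple

import pandas as pd

from .model_core import MetabolicModel
from .lp_engine import (
    LPSpec,
    FluxSolution,
    InfeasibleProblem,
    ZERO_FLUX_TOL,
    DEFAULT_FD_EPSILON,
    dual_price_fd,
    flux_variability,
    relaxation_diagnosis,
    solve,
)
from .enm import ENMResult, UNBOUNDED_UPTAKE
from .rates import DEFAULT_DRY_WEIGHT_PG

__all__ = [
    "ExchangeProfile",
    "CorrectionEntry",
    "UOFResult",
    "correct_essential_constraints",
    "uof_minimize",
    "uof_sweep",
    "uof_dual_matrix",
    "uof_fva",
    "read_profile",
    "write_profile",
]


@dataclass
class ExchangeProfile:
    """Measured specific exchange rates for one culture condition.

    ``measured_rates`` live in user space: uptake positive, secretion
    negative, mmol/gDW/h.  ``essential_ids`` names the exchanges treated as
    essential nutrients (corrected against ENM, excluded from the UOF sweep).
    """

    growth_rate: float
    productivity: float = 0.0
    measured_rates: Dict[str, float] = field(default_factory=dict)
    essential_ids: Set[str] = field(default_factory=set)
    dry_weight: float = DEFAULT_DRY_WEIGHT_PG

    def __post_init__(self) -> None:
        if self.growth_rate < 0:
            raise ValueError("growth rate must be non-negative")

    def consumed(self, tolerance: float = ZERO_FLUX_TOL) -> List[str]:
        """Exchanges with positive measured uptake."""
        return sorted(r for r, v in self.measured_rates.items() if v > tolerance)


@dataclass
class CorrectionEntry:
    exchange_id: str
    measured: Optional[float]  # None when the profile had no measurement
    corrected: float
    action: str  # "replaced" | "imputed" | "kept"

    @property
    def magnitude(self) -> float:
        return self.corrected - (self.measured or 0.0)


@dataclass
class UOFResult:
    minimized_uptake: Dict[str, float]
    corrected_profile: ExchangeProfile
    correction_log: List[CorrectionEntry]
    statuses: Dict[str, str]
    dual_matrix: Dict[Tuple[str, str], float] = field(default_factory=dict)
    one_sided_duals: Set[Tuple[str, str]] = field(default_factory=set)
    failed_duals: Set[Tuple[str, str]] = field(default_factory=set)
    flux_ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    solutions: Dict[str, FluxSolution] = field(default_factory=dict)


def correct_essential_constraints(
    profile: ExchangeProfile, enm: ENMResult
) -> Tuple[ExchangeProfile, List[CorrectionEntry]]:
    """Raise essential uptakes to their ENM minima where measured smaller.

    Non-essential rates are untouched.  Essential exchanges missing from the
    profile are imputed at the ENM value and flagged.
    """
    rates = dict(profile.measured_rates)
    log: List[CorrectionEntry] = []
    for rid in sorted(profile.essential_ids):
        if rid not in enm.minimal_uptake:
            continue
        target = enm.minimal_uptake[rid]
        if rid not in rates:
            rates[rid] = target
            log.append(CorrectionEntry(rid, None, target, "imputed"))
        elif rates[rid] < target - ZERO_FLUX_TOL:
            log.append(CorrectionEntry(rid, rates[rid], target, "replaced"))
            rates[rid] = target
        else:
            # below-tolerance deficits are still raised (max semantics) but
            # logged as kept: they are rounding, not underestimation
            rates[rid] = max(rates[rid], target)
            log.append(CorrectionEntry(rid, rates[rid], rates[rid], "kept"))
    corrected = replace(profile, measured_rates=rates)
    return corrected, log


def _uof_spec(model: MetabolicModel, profile: ExchangeProfile, target: str) -> LPSpec:
    """The UOF linear program for one target nutrient.

    Growth and productivity are pinned, every measured exchange except the
    target is pinned at its (internal-sign) value, and the target's uptake
    bound is opened so only the objective limits it.
    """
    if model.biomass_reaction_id is None:
        raise ValueError("model has no biomass reaction; cannot constrain growth")
    equalities = {model.biomass_reaction_id: profile.growth_rate}
    if model.product_reaction_id is not None:
        equalities[model.product_reaction_id] = profile.productivity
    elif profile.productivity != 0.0:
        raise ValueError("profile has productivity but model has no product reaction")
    for rid, rate in profile.measured_rates.items():
        if rid == target:
            continue  # the solved-for flux is never part of the constraint set
        equalities[rid] = -rate  # user space uptake-positive -> internal export-positive
    overrides = {target: (-UNBOUNDED_UPTAKE, model.reaction(target).upper_bound)}
    return LPSpec(model, target, "maximize", equalities, overrides)


def uof_minimize(
    model: MetabolicModel,
    profile: ExchangeProfile,
    target: str,
    forced: bool = False,
) -> Tuple[float, FluxSolution]:
    """Minimize one nutrient's uptake under the full measured constraint set.

    ``profile`` should already be ENM-corrected.  The target must be consumed
    in the profile (measured uptake > 0) unless ``forced``.  On infeasibility
    the error carries a minimal-relaxation diagnosis naming the measured
    fluxes that conflict — constraints are never silently relaxed.
    """
    measured = profile.measured_rates.get(target)
    if not forced and (measured is None or measured <= ZERO_FLUX_TOL):
        raise ValueError(
            f"target {target!r} is not consumed in the profile "
            f"(measured rate {measured}); pass forced=True to solve anyway"
        )
    spec = _uof_spec(model, profile, target)
    sol = solve(spec)
    if not sol.optimal:
        diagnosis = relaxation_diagnosis(spec)
        raise InfeasibleProblem(
            f"UOF constraint set infeasible for target {target!r}; measured fluxes "
            f"needing relaxation (reaction, required shift): {diagnosis}",
            diagnosis=diagnosis,
        )
    return max(0.0, -sol.objective_value), sol


def uof_sweep(
    model: MetabolicModel,
    profile: ExchangeProfile,
    enm: ENMResult,
    targets: Optional[Iterable[str]] = None,
) -> UOFResult:
    """ENM correction followed by one UOF solve per consumed non-essential nutrient.

    Per-target failures are logged in ``statuses`` and the sweep continues.
    """
    corrected, log = correct_essential_constraints(profile, enm)
    forced = targets is not None  # explicitly requested targets are always solved
    if targets is None:
        targets = [
            rid for rid in corrected.consumed() if rid not in corrected.essential_ids
        ]
    minimized: Dict[str, float] = {}
    statuses: Dict[str, str] = {}
    solutions: Dict[str, FluxSolution] = {}
    for rid in sorted(targets):
        try:
            minimized[rid], solutions[rid] = uof_minimize(model, corrected, rid, forced=forced)
            statuses[rid] = "optimal"
        except Exception as exc:
            statuses[rid] = f"error: {exc}"
    return UOFResult(
        minimized_uptake=minimized,
        corrected_profile=corrected,
        correction_log=log,
        statuses=statuses,
        solutions=solutions,
    )


def uof_dual_matrix(
    model: MetabolicModel,
    profile: ExchangeProfile,
    enm: ENMResult,
    perturb_ids: Iterable[str],
    objective_ids: Optional[Iterable[str]] = None,
    epsilon: float = DEFAULT_FD_EPSILON,
) -> UOFResult:
    """Dual-price matrix of minimized uptakes vs nutrient availabilities.

    Entry (i, j) answers: if one more unit of nutrient j were available, how
    would the minimal uptake requirement of nutrient i change?  Computed by
    finite differences at nutrient i's own UOF optimum (the definition of
    record; solver duals are non-unique at degenerate optima).  Positive
    means an increased requirement, negative a decreased one; the diagonal
    is -1 whenever a nutrient's own availability substitutes its uptake 1:1.
    One-sided (boundary) evaluations are flagged in ``one_sided_duals``.
    """
    result = uof_sweep(model, profile, enm, targets=objective_ids)
    corrected = result.corrected_profile
    perturb_ids = sorted(perturb_ids)
    for i in sorted(result.minimized_uptake):
        spec = _uof_spec(model, corrected, i)
        base_v = result.solutions[i].objective_value  # internal-sign LP optimum
        for j in perturb_ids:
            try:
                dp = dual_price_fd(spec, j, epsilon=epsilon, base_objective=base_v)
            except InfeasibleProblem:
                # the scenario's other pinned fluxes leave no route to absorb
                # or supply the perturbation; the entry is undefined here
                result.dual_matrix[(i, j)] = float("nan")
                result.failed_duals.add((i, j))
                continue
            # LP objective is export-positive flux; reported objective is uptake
            result.dual_matrix[(i, j)] = -dp.value
            if dp.one_sided:
                result.one_sided_duals.add((i, j))
    return result


def uof_fva(
    model: MetabolicModel,
    profile: ExchangeProfile,
    target: str,
    reactions: Iterable[str],
    enm: Optional[ENMResult] = None,
) -> Dict[str, Tuple[float, float]]:
    """Flux-variability ranges with the UOF objective fixed at its minimum.

    With growth and all measured exchanges pinned in addition to the
    objective, the viable ranges are generally narrower than those of a
    growth-maximization solution constrained only by uptake limits.
    """
    if enm is not None:
        profile, _ = correct_essential_constraints(profile, enm)
    minimized, sol = uof_minimize(model, profile, target, forced=True)
    spec = _uof_spec(model, profile, target)
    return flux_variability(spec, reactions, fix_objective_at=sol.objective_value)


# ---------------------------------------------------------------------------
# profile TSV IO
# ---------------------------------------------------------------------------

def write_profile(profile: ExchangeProfile, path) -> None:
    """Tidy TSV with metadata header lines (# key<TAB>value)."""
    lines = [
        f"# growth_rate\t{profile.growth_rate:.9g}",
        f"# productivity\t{profile.productivity:.9g}",
        f"# dry_weight\t{profile.dry_weight:.9g}",
        "exchange_id\trate\tunit\tdirection\tessential",
    ]
    for rid in sorted(profile.measured_rates):
        rate = profile.measured_rates[rid]
        direction = "uptake" if rate >= 0 else "secretion"
        lines.append(
            f"{rid}\t{abs(rate):.9g}\tmmol/gDW/h\t{direction}\t"
            f"{int(rid in profile.essential_ids)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path) -> ExchangeProfile:
    meta = {"growth_rate": 0.0, "productivity": 0.0, "dry_weight": DEFAULT_DRY_WEIGHT_PG}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("\t")
                meta[key.strip()] = float(value)
            else:
                rows.append(line.split("\t"))
    header, data = rows[0], rows[1:]
    df = pd.DataFrame(data, columns=header)
    rates: Dict[str, float] = {}
    essential: Set[str] = set()
    for _, row in df.iterrows():
        rate = float(row["rate"])
        if str(row.get("direction", "uptake")) == "secretion":
            rate = -rate
        rates[row["exchange_id"]] = rate
        if int(row.get("essential", 0)):
            essential.add(row["exchange_id"])
    return ExchangeProfile(
        growth_rate=meta["growth_rate"],
        productivity=meta["productivity"],
        measured_rates=rates,
        essential_ids=essential,
        dry_weight=meta["dry_weight"],
    )
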