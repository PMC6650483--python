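"""Independent LP oracle built on scipy.optimize.linprog (HiGHS).

Used to cross-check the cobra/GLPK solving path: same mathematical problem,
entirely different code path (dense matrices, different solver).  Supports
metabolite injections so that finite-difference dual prices can also be
verified independently.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

from uofba.model_core import MetabolicModel, stoichiometric_matrix


def oracle_fba(
    model: MetabolicModel,
    objective: str,
    sense: str = "maximize",
    equalities: Optional[Dict[str, float]] = None,
    overrides: Optional[Dict[str, Tuple[float, float]]] = None,
    injections: Optional[Dict[str, float]] = None,
) -> Tuple[str, float, Dict[str, float]]:
    """Solve one FBA LP with scipy; returns (status, objective, fluxes)."""
    S = stoichiometric_matrix(model)
    rids = list(S.columns)
    ridx = {rid: j for j, rid in enumerate(rids)}
    lb = np.array([model.reaction(rid).lower_bound for rid in rids])
    ub = np.array([model.reaction(rid).upper_bound for rid in rids])
    for rid, (lo, hi) in (overrides or {}).items():
        lb[ridx[rid]], ub[ridx[rid]] = lo, hi
    for rid, val in (equalities or {}).items():
        lb[ridx[rid]] = ub[ridx[rid]] = val
    b_eq = np.zeros(S.shape[0])
    for mid, amount in (injections or {}).items():
        b_eq[list(S.index).index(mid)] = -amount
    c = np.zeros(len(rids))
    c[ridx[objective]] = -1.0 if sense == "maximize" else 1.0
    res = linprog(c, A_eq=S.to_numpy(), b_eq=b_eq,
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status == 2:
        return "infeasible", float("nan"), {}
    if res.status == 3:
        return "unbounded", float("nan"), {}
    if not res.success:
        raise RuntimeError(f"oracle solve failed: {res.message}")
    value = float(res.x[ridx[objective]])
    return "optimal", value, dict(zip(rids, map(float, res.x)))


def oracle_dual_fd(
    model: MetabolicModel,
    objective: str,
    metabolite: str,
    sense: str = "maximize",
    equalities: Optional[Dict[str, float]] = None,
    overrides: Optional[Dict[str, Tuple[float, float]]] = None,
    epsilon: float = 1e-4,
) -> float:
    """Finite-difference availability dual price, oracle edition."""
    s0, z0, _ = oracle_fba(model, objective, sense, equalities, overrides)
    assert s0 == "optimal"
    s1, z1, _ = oracle_fba(model, objective, sense, equalities, overrides,
                           injections={metabolite: epsilon})
    assert s1 == "optimal"
    return (z1 - z0) / epsilon
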