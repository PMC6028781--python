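"""Independent LP oracle built on scipy.optimize.linprog (HiGHS).

Assembles the steady-state LP directly from the raw network specs --
a second code path sharing nothing with the package's cobra/optlang
compilation -- with each flux split into nonnegative forward/backward
parts so total |flux| is linear. Used to cross-check FBA, parsimonious
minimization and day-level optima.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

from dielfba.network import MetabolicNetwork


def _assemble(net: MetabolicNetwork,
              bound_overrides: Optional[Dict[str, Tuple[float, float]]] = None):
    bound_overrides = bound_overrides or {}
    rxns = net.reactions
    rids = [r.id for r in rxns]
    index = {rid: i for i, rid in enumerate(rids)}
    internal = [m.id for m in net.metabolites if not m.is_external]
    met_index = {mid: i for i, mid in enumerate(internal)}
    n = len(rxns)
    stoich = np.zeros((len(internal), 2 * n))
    for j, rxn in enumerate(rxns):
        for mid, coef in rxn.stoichiometry.items():
            if mid in met_index:
                stoich[met_index[mid], j] = coef
                stoich[met_index[mid], n + j] = -coef
    bounds = []
    for rxn in rxns:  # forward parts
        lb, ub = bound_overrides.get(rxn.id, (rxn.lower_bound, rxn.upper_bound))
        bounds.append((max(0.0, lb), max(0.0, ub)))
    for rxn in rxns:  # backward parts
        lb, ub = bound_overrides.get(rxn.id, (rxn.lower_bound, rxn.upper_bound))
        bounds.append((max(0.0, -ub), max(0.0, -lb)))
    ratio_rows = np.zeros((len(net.ratio_constraints), 2 * n))
    for i, rc in enumerate(net.ratio_constraints):
        jn = index[rc.numerator_reaction]
        jd = index[rc.denominator_reaction]
        ratio_rows[i, jn] += 1.0
        ratio_rows[i, n + jn] -= 1.0
        ratio_rows[i, jd] -= rc.ratio
        ratio_rows[i, n + jd] += rc.ratio
    obj = np.zeros(2 * n)
    for j, rxn in enumerate(rxns):
        obj[j] = rxn.objective_coefficient
        obj[n + j] = -rxn.objective_coefficient
    return rids, index, stoich, ratio_rows, bounds, obj


def _net_flux_row(index: Dict[str, int], n: int,
                  coeffs: Dict[str, float]) -> np.ndarray:
    row = np.zeros(2 * n)
    for rid, c in coeffs.items():
        row[index[rid]] += c
        row[n + index[rid]] -= c
    return row


def oracle_solve(
    net: MetabolicNetwork,
    minimize_total: bool = False,
    objective_floor: Optional[float] = None,
    extra_eq: Iterable[Tuple[Dict[str, float], float]] = (),
    extra_ub: Iterable[Tuple[Dict[str, float], float]] = (),
    bound_overrides: Optional[Dict[str, Tuple[float, float]]] = None,
):
    """Solve the network LP independently.

    Returns ``(status, objective_value, fluxes, total_abs_flux)``. With
    ``minimize_total`` the total |flux| is minimized subject to the
    primary objective staying at or above ``objective_floor``. ``extra_eq``
    / ``extra_ub`` add rows given as (net-flux coefficient map, rhs).
    """
    rids, index, stoich, ratio_rows, bounds, obj = _assemble(net, bound_overrides)
    n = len(rids)
    a_eq = [stoich, ratio_rows] if len(ratio_rows) else [stoich]
    b_eq = [np.zeros(stoich.shape[0]), np.zeros(ratio_rows.shape[0])] \
        if len(ratio_rows) else [np.zeros(stoich.shape[0])]
    for coeffs, rhs in extra_eq:
        a_eq.append(_net_flux_row(index, n, coeffs)[None, :])
        b_eq.append(np.array([rhs]))
    a_ub_rows: List[np.ndarray] = []
    b_ub_rows: List[float] = []
    for coeffs, rhs in extra_ub:
        a_ub_rows.append(_net_flux_row(index, n, coeffs))
        b_ub_rows.append(rhs)
    if minimize_total:
        if objective_floor is not None:
            a_ub_rows.append(-obj)
            b_ub_rows.append(-objective_floor)
        cost = np.ones(2 * n)
    else:
        cost = -obj
    result = linprog(
        cost,
        A_eq=np.vstack(a_eq), b_eq=np.concatenate(b_eq),
        A_ub=np.vstack(a_ub_rows) if a_ub_rows else None,
        b_ub=np.array(b_ub_rows) if b_ub_rows else None,
        bounds=bounds, method="highs",
    )
    if result.status != 0:
        return ("infeasible" if result.status == 2 else "failed",
                float("nan"), {}, float("nan"))
    x = result.x
    fluxes = {rid: float(x[index[rid]] - x[n + index[rid]]) for rid in rids}
    objective_value = float(obj @ x)
    return "optimal", objective_value, fluxes, float(np.sum(x))
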