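"""FBA and parsimonious (taxicab) flux solutions via linear programming.

The first stage maximizes the objective c.v subject to S v = 0 and
lb <= v <= ub (scipy's HiGHS backend, deterministic). The second stage
fixes the attained objective as an equality constraint and minimizes the
taxicab norm sum(|v|) using the split-variable formulation v = v+ - v-,
v+, v- >= 0, minimizing sum(v+ + v-); at the optimum at most one of each
pair is nonzero, so the objective equals the L1 norm and futile cycles are
driven to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel

#: Feasibility tolerances handed to HiGHS; chosen so that optimal solutions
#: satisfy max|S v| <= 1e-9 * max(1, max|v|) on the model scales used here.
_HIGHS_OPTIONS = {
    "presolve": True,
}

MASS_BALANCE_RTOL = 1e-9


class SolverStatus(str, Enum):
    OPTIMAL = "OPTIMAL"
    INFEASIBLE = "INFEASIBLE"
    UNBOUNDED = "UNBOUNDED"


class SolverError(RuntimeError):
    pass


@dataclass
class FluxResult:
    status: SolverStatus
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == SolverStatus.OPTIMAL


def _matrices(model: MetabolicModel):
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    rxn_ids = list(model.reactions)
    rows, cols, vals = [], [], []
    for j, rid in enumerate(rxn_ids):
        for met, coef in model.reactions[rid].stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(coef)
    S = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(len(met_index), len(rxn_ids))
    ).tocsr()
    bounds = [
        (model.reactions[rid].lower_bound, model.reactions[rid].upper_bound)
        for rid in rxn_ids
    ]
    c = np.zeros(len(rxn_ids))
    for rid, coef in model.objective.items():
        c[rxn_ids.index(rid)] = coef
    return S, bounds, c, rxn_ids


def _clip_to_bounds(v: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(v, lo, hi)


def solve_fba(model: MetabolicModel) -> FluxResult:
    """Maximize the model objective at steady state.

    Returns an OPTIMAL result carrying a feasible flux vector attaining the
    optimum, or INFEASIBLE / UNBOUNDED with empty fluxes.
    """
    model.validate()
    S, bounds, c, rxn_ids = _matrices(model)
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options=_HIGHS_OPTIONS,
    )
    if res.status == 2:
        return FluxResult(SolverStatus.INFEASIBLE, 0.0)
    if res.status == 3:
        return FluxResult(SolverStatus.UNBOUNDED, float("inf"))
    if res.status != 0:
        raise SolverError(f"LP solve failed: {res.message}")
    v = _polish(res.x, S.toarray(), np.zeros(S.shape[0]), bounds)
    return FluxResult(
        SolverStatus.OPTIMAL,
        objective_value=float(c @ v),
        fluxes=dict(zip(rxn_ids, map(float, v))),
    )


def _polish(
    v: np.ndarray, A: np.ndarray, b: np.ndarray, bounds
) -> np.ndarray:
    """Tighten a solver solution onto the equality system A v = b.

    HiGHS guarantees feasibility only to its own tolerance (~1e-7); a
    minimum-norm least-squares correction removes the residual without
    moving the vector appreciably. Bounds are re-clipped afterwards; if the
    correction does not improve the residual the original vector is kept.
    """
    resid = A @ v - b
    scale = max(1.0, float(np.max(np.abs(v))) if v.size else 1.0)
    if float(np.max(np.abs(resid)) if resid.size else 0.0) <= MASS_BALANCE_RTOL * scale:
        return v
    correction, *_ = np.linalg.lstsq(A, resid, rcond=None)
    candidate = _clip_to_bounds(v - correction, bounds)
    new_resid = A @ candidate - b
    if np.max(np.abs(new_resid)) < np.max(np.abs(resid)):
        return candidate
    return v


def minimize_taxicab(
    model: MetabolicModel,
    attained_objective: float,
    objective_tolerance: float = 1e-9,
) -> dict[str, float]:
    """Minimize sum(|v|) among flux vectors attaining the FBA optimum.

    The first-stage objective is fixed as an equality constraint (to
    ``objective_tolerance``, absolute). Raises :class:`SolverError` if the
    fixed system is numerically infeasible — relax the tolerance in that
    case.
    """
    model.validate()
    S, bounds, c, rxn_ids = _matrices(model)
    n = len(rxn_ids)
    # v = p - m with p, m >= 0; bounds split so p - m always lies in [lb, ub]
    split_bounds = []
    for lb, ub in bounds:
        split_bounds.append((max(lb, 0.0), max(ub, 0.0)))  # p
    for lb, ub in bounds:
        split_bounds.append((max(-ub, 0.0), max(-lb, 0.0)))  # m
    A_parts = sparse.hstack([S, -S]).tocsr()
    c_obj = np.concatenate([c, -c])
    A_eq = sparse.vstack([A_parts, sparse.csr_matrix(c_obj)]).tocsr()
    b_eq = np.concatenate([np.zeros(S.shape[0]), [attained_objective]])
    cost = np.ones(2 * n)
    res = linprog(
        cost,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=split_bounds,
        method="highs",
        options=_HIGHS_OPTIONS,
    )
    if res.status != 0:
        raise SolverError(
            "taxicab stage infeasible at the fixed objective "
            f"{attained_objective!r}; consider relaxing objective_tolerance "
            f"(solver: {res.message})"
        )
    v = res.x[:n] - res.x[n:]
    # polish against mass balance AND the fixed-objective row together
    A_full = np.vstack([S.toarray(), c])
    b_full = np.concatenate([np.zeros(S.shape[0]), [attained_objective]])
    v = _polish(v, A_full, b_full, bounds)
    achieved = float(c @ v)
    if abs(achieved - attained_objective) > max(
        objective_tolerance, 1e-7 * max(1.0, abs(attained_objective))
    ):
        raise SolverError(
            f"taxicab stage drifted the objective: {achieved} vs "
            f"{attained_objective}"
        )
    return dict(zip(rxn_ids, map(float, v)))
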