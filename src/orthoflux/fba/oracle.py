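"""Brute-force reference solver for small flux polytopes.

Enumerates candidate vertices of {v : S v = 0, lb <= v <= ub} by fixing
every subset of n - rank(S) variables at a bound (all sign combinations),
solving the reduced equality system, and keeping feasible solutions. The
optimum of a bounded feasible LP is attained at a vertex, so the maximum
objective over the enumerated set equals the LP optimum. Exponential in
the reaction count — intended only for models with at most ~8 reactions,
as an independent check of the simplex route.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from .model import MetabolicModel


def enumerate_vertices(
    model: MetabolicModel, tol: float = 1e-9
) -> tuple[list[np.ndarray], list[str]]:
    rxn_ids = list(model.reactions)
    n = len(rxn_ids)
    met_ids = list(model.metabolites)
    S = np.zeros((len(met_ids), n))
    for j, rid in enumerate(rxn_ids):
        for met, coef in model.reactions[rid].stoichiometry.items():
            S[met_ids.index(met), j] = coef
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    rank = int(np.linalg.matrix_rank(S)) if S.size else 0
    n_fixed = n - rank

    vertices: list[np.ndarray] = []
    for fixed_tuple in combinations(range(n), n_fixed):
        fixed = list(fixed_tuple)
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        if free and np.linalg.matrix_rank(A) < len(free):
            continue  # free block underdetermined; vertex found elsewhere
        for signs in product((0, 1), repeat=n_fixed):
            v = np.zeros(n)
            for j, s in zip(fixed, signs):
                v[j] = lb[j] if s == 0 else ub[j]
            rhs = -S[:, fixed] @ v[fixed] if n_fixed else np.zeros(S.shape[0])
            if free:
                sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
                if np.max(np.abs(A @ sol - rhs)) > tol * 100:
                    continue  # inconsistent: no point on this face
                v[free] = sol
            elif np.max(np.abs(rhs)) > tol * 100:
                continue
            if np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7):
                vertices.append(np.clip(v, lb, ub))
    return vertices, rxn_ids


def max_objective_by_enumeration(model: MetabolicModel) -> float:
    """LP optimum by exhaustive vertex enumeration (bounded models only)."""
    vertices, rxn_ids = enumerate_vertices(model)
    if not vertices:
        raise ValueError("no feasible vertex found (empty polytope?)")
    c = np.zeros(len(rxn_ids))
    for rid, coef in model.objective.items():
        c[rxn_ids.index(rid)] = coef
    return float(max(c @ v for v in vertices))
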