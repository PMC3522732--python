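"""Independent oracles used to certify the implementation.

Deliberately naive: exhaustive vertex enumeration for small LPs, the
two-pass textbook Pearson formula, and a double-loop stoichiometric matrix
assembler.  None of them share code paths with the package.
"""

from itertools import combinations, product

import numpy as np


def vertex_optimum(S, lower, upper, obj_idx, sense="maximize"):
    """LP optimum by exhaustive enumeration of basic feasible solutions.

    Valid whenever the polytope {S v = 0, lb <= v <= ub} is bounded (all
    bounds finite) and non-empty: the optimum of a linear objective is then
    attained at a vertex, and every vertex fixes (n - rank S) variables at
    bounds with the rest solved from the equalities.
    """
    S = np.asarray(S, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    n = len(lower)
    rank = np.linalg.matrix_rank(S) if S.size else 0

    better = max if sense == "maximize" else min
    best = None

    if rank == 0:
        # no effective mass-balance constraints: the box itself
        return upper[obj_idx] if sense == "maximize" else lower[obj_idx]

    for basic in combinations(range(n), rank):
        B = S[:, basic]
        if np.linalg.matrix_rank(B) < rank:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        for assignment in product(*[(lower[j], upper[j]) for j in nonbasic]):
            v = np.zeros(n)
            v[nonbasic] = assignment
            rhs = -S[:, nonbasic] @ np.asarray(assignment)
            sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            v[list(basic)] = sol
            if S.size and np.max(np.abs(S @ v)) > 1e-7:
                continue  # inconsistent subsystem, not a vertex
            if np.any(v < lower - 1e-7) or np.any(v > upper + 1e-7):
                continue
            value = v[obj_idx]
            best = value if best is None else better(best, value)
    return best


def vertex_optimum_for_model(model, objective, sense="maximize", overrides=None):
    """Run the vertex oracle directly off a model's declared data."""
    rxn_ids = [r.id for r in model.reactions]
    internal = [m.id for m in model.metabolites if not m.external]
    index = {mid: i for i, mid in enumerate(internal)}
    S = np.zeros((len(internal), len(rxn_ids)))
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            if met_id in index:
                S[index[met_id], j] = coeff
    lower = np.array([r.lower_bound for r in model.reactions])
    upper = np.array([r.upper_bound for r in model.reactions])
    if overrides:
        for rid, lo, hi in overrides:
            j = rxn_ids.index(rid)
            lower[j], upper[j] = lo, hi
    return vertex_optimum(S, lower, upper, rxn_ids.index(objective), sense)


def naive_pearson_r2(x, y):
    """Textbook two-pass Pearson correlation, squared.  Returns None when
    either variance vanishes."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((v - mx) ** 2 for v in x)
    syy = sum((v - my) ** 2 for v in y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    if sxx == 0 or syy == 0:
        return None
    r = sxy / (sxx ** 0.5 * syy ** 0.5)
    return r * r


def naive_stoichiometric_matrix(model):
    """Coefficient-by-coefficient assembly, metabolite-major."""
    internal = [m.id for m in model.metabolites if not m.external]
    rows = []
    for met_id in internal:
        row = []
        for rxn in model.reactions:
            row.append(float(rxn.stoichiometry.get(met_id, 0.0)))
        rows.append(row)
    return np.array(rows).reshape(len(internal), len(model.reactions))


def naive_orphans(model):
    """Exhaustive per-metabolite producer/consumer scan."""
    orphan_mets = []
    for met in model.metabolites:
        if met.external:
            continue
        has_producer = False
        has_consumer = False
        for rxn in model.reactions:
            coeff = rxn.stoichiometry.get(met.id)
            if coeff is None:
                continue
            if rxn.lower_bound < 0:  # reversible: either role
                has_producer = True
                has_consumer = True
            elif coeff > 0:
                has_producer = True
            elif coeff < 0:
                has_consumer = True
        if not (has_producer and has_consumer):
            orphan_mets.append(met.id)
    orphan_set = set(orphan_mets)
    orphan_rxns = [
        r.id
        for r in model.reactions
        if any(m in orphan_set for m in r.stoichiometry)
    ]
    return orphan_mets, orphan_rxns
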