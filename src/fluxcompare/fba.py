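"""Flux balance analysis: formulate and solve the steady-state LP.

Maximize (or minimize) the flux through a single objective reaction subject
to ``S v = 0`` over the internal metabolites and per-reaction capacity
bounds ``lb <= v <= ub``.  Only the optimal objective *value* is
contractual: FBA optima are famously degenerate and the returned flux
vector is one optimal point among possibly many.

The LP backend sits behind a single solve contract (matrix, bounds,
objective -> status/value/point) so it can be swapped; the default backend
is HiGHS via :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .errors import FluxcompareError, ObjectiveNotFoundError, SolverError
from .model import MetabolicModel, build_stoichiometric_matrix

__all__ = [
    "SolverStatus",
    "FluxResult",
    "solve_fba",
    "solve_fba_with_fixed_flux",
    "FEASIBILITY_TOL",
]

#: Absolute tolerance on constraint satisfaction and objective comparisons.
FEASIBILITY_TOL = 1e-6


class SolverStatus(str, enum.Enum):
    OPTIMAL = "OPTIMAL"
    INFEASIBLE = "INFEASIBLE"
    UNBOUNDED = "UNBOUNDED"


@dataclass
class FluxResult:
    """Outcome of one FBA solve.

    ``objective_value`` and ``fluxes`` are present iff the status is
    OPTIMAL.  The flux vector satisfies mass balance and bounds to within
    :data:`FEASIBILITY_TOL` but is otherwise one arbitrary optimal point.
    """

    status: SolverStatus
    objective_reaction: str
    objective_value: Optional[float] = None
    fluxes: Optional[Dict[str, float]] = None

    @property
    def optimal(self) -> bool:
        return self.status is SolverStatus.OPTIMAL


def _scipy_highs_backend(
    S: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    objective: np.ndarray,
) -> Tuple[str, Optional[float], Optional[np.ndarray]]:
    """Default LP backend: minimize objective . v  s.t.  S v = 0, lb<=v<=ub."""
    n = len(lower)
    kwargs = {}
    if S.shape[0] > 0:
        kwargs["A_eq"] = S
        kwargs["b_eq"] = np.zeros(S.shape[0])
    res = linprog(
        objective,
        bounds=list(zip(lower, upper)),
        method="highs",
        **kwargs,
    )
    if res.status == 0:
        return ("optimal", float(res.fun), np.asarray(res.x, dtype=float))
    if res.status == 2:
        return ("infeasible", None, None)
    if res.status == 3:
        return ("unbounded", None, None)
    return (f"error:{res.status}:{res.message}", None, None)


#: Pluggable backend honouring the solve contract above.
LP_BACKEND: Callable[
    [np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    Tuple[str, Optional[float], Optional[np.ndarray]],
] = _scipy_highs_backend


def _solve(
    model: MetabolicModel,
    objective: str,
    sense: str,
    overrides: Optional[Dict[str, Tuple[float, float]]] = None,
) -> FluxResult:
    if sense not in ("maximize", "minimize"):
        raise ValueError(f"sense must be 'maximize' or 'minimize', got {sense!r}")
    rxn_ids = model.reaction_ids()
    try:
        obj_idx = rxn_ids.index(objective)
    except ValueError:
        raise ObjectiveNotFoundError(
            f"objective reaction {objective!r} not in model {model.id!r}"
        ) from None

    S = build_stoichiometric_matrix(model)
    lower = np.array([r.lower_bound for r in model.reactions], dtype=float)
    upper = np.array([r.upper_bound for r in model.reactions], dtype=float)
    if overrides:
        for rid, (lo, hi) in overrides.items():
            if rid not in rxn_ids:
                raise ObjectiveNotFoundError(
                    f"override reaction {rid!r} not in model {model.id!r}"
                )
            if lo > hi:
                raise ValueError(
                    f"override for {rid!r}: lower {lo} exceeds upper {hi}"
                )
            j = rxn_ids.index(rid)
            lower[j], upper[j] = lo, hi

    c = np.zeros(len(rxn_ids))
    c[obj_idx] = -1.0 if sense == "maximize" else 1.0

    status_text, _, point = LP_BACKEND(S, lower, upper, c)
    if status_text == "optimal":
        fluxes = {rid: float(point[j]) for j, rid in enumerate(rxn_ids)}
        return FluxResult(
            status=SolverStatus.OPTIMAL,
            objective_reaction=objective,
            objective_value=float(point[obj_idx]),
            fluxes=fluxes,
        )
    if status_text == "infeasible":
        return FluxResult(SolverStatus.INFEASIBLE, objective)
    if status_text == "unbounded":
        return FluxResult(SolverStatus.UNBOUNDED, objective)
    raise SolverError(f"LP backend failed: {status_text}")


def solve_fba(
    model: MetabolicModel, objective: str, sense: str = "maximize"
) -> FluxResult:
    """Optimize the flux through ``objective`` at steady state.

    The zero flux vector is feasible whenever every bound admits zero, so a
    model with no route from the medium to the objective yields an OPTIMAL
    result with value 0 rather than infeasibility.
    """
    return _solve(model, objective, sense)


def solve_fba_with_fixed_flux(
    model: MetabolicModel,
    objective: str,
    fixed: Sequence[Tuple[str, float, float]],
    sense: str = "maximize",
) -> FluxResult:
    """As :func:`solve_fba` with per-reaction bound overrides applied
    non-destructively (the model is left unchanged)."""
    overrides: Dict[str, Tuple[float, float]] = {}
    for rid, lo, hi in fixed:
        if lo > hi:
            raise ValueError(f"override for {rid!r}: lower {lo} exceeds upper {hi}")
        overrides[rid] = (lo, hi)
    return _solve(model, objective, sense, overrides=overrides)
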