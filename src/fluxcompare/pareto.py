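"""Two-objective trade-off analysis by constraint sweeping.

The Pareto front between two reaction fluxes (classically: biomass
production versus product biosynthesis) is computed with an
epsilon-constraint sweep: first maximize objective 1 alone; then, for a
grid of fractions of that maximum, re-maximize objective 2 with objective
1's *lower* bound raised to the fractional floor.  A lower-bound floor (not
an equality fix) yields the true upper boundary of the feasible region
projected onto the two objective fluxes.

The sweep runs from fraction 1 (objective 1 at its maximum) down to
fraction 0 (objective 2 unconstrained), producing ``n + 1`` points
inclusive of both endpoints.

Diagnostics: :func:`binding_medium_constraints` names the medium nutrients
whose influx is at its cap at a given optimum (the limiting nutrients), and
:func:`transition_points` locates slope changes of the front — the
"metabolic switches" where the active constraint set changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import pandas as pd

from .collection import Medium, apply_medium, exchange_influx
from .errors import FrontError, StateError
from .fba import (
    FEASIBILITY_TOL,
    FluxResult,
    SolverStatus,
    solve_fba,
    solve_fba_with_fixed_flux,
)
from .model import MetabolicModel

__all__ = [
    "ParetoSettings",
    "ParetoPoint",
    "ParetoFront",
    "pareto_front",
    "binding_medium_constraints",
    "transition_points",
]


@dataclass(frozen=True)
class ParetoSettings:
    """Sweep configuration: the two objective reaction ids and the number of
    sweep intervals ``n`` (the resolution; the front has ``n + 1`` points)."""

    objective1: str
    objective2: str
    n: int = 10

    def validate(self, model: MetabolicModel) -> None:
        if self.n < 1:
            raise ValueError("resolution n must be >= 1")
        if self.objective1 == self.objective2:
            raise ValueError("the two objectives must be distinct reactions")
        for rid in (self.objective1, self.objective2):
            if not model.has_reaction(rid):
                raise ValueError(
                    f"objective reaction {rid!r} not in model {model.id!r}"
                )


@dataclass
class ParetoPoint:
    """One sweep point: objective 1 floored at ``fraction · f1_max``."""

    fraction: float
    objective1_floor: float
    objective1_percent: float
    objective2_value: Optional[float]
    status: SolverStatus
    result: FluxResult = field(repr=False)


@dataclass
class ParetoFront:
    """Ordered trade-off points, fraction 1 down to fraction 0."""

    objective1: str
    objective2: str
    f1_max: float
    points: List[ParetoPoint]
    model: MetabolicModel = field(repr=False)
    medium: Optional[Medium] = field(default=None, repr=False)

    @property
    def f2_max(self) -> Optional[float]:
        """Unconstrained maximum of objective 2 (the fraction-0 point)."""
        last = self.points[-1]
        return last.objective2_value

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pt in self.points:
            binding = ""
            if (
                pt.status is SolverStatus.OPTIMAL
                and self.medium is not None
            ):
                binding = ";".join(
                    binding_medium_constraints(pt.result, self.model, self.medium)
                )
            rows.append(
                {
                    "fraction": pt.fraction,
                    "obj1_floor": pt.objective1_floor,
                    "obj1_percent": pt.objective1_percent,
                    "obj2_flux": pt.objective2_value,
                    "status": pt.status.value,
                    "binding_nutrients": binding,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def pareto_front(
    model: MetabolicModel,
    settings: ParetoSettings,
    medium: Optional[Medium] = None,
) -> ParetoFront:
    """Compute the two-objective trade-off curve.

    For i = 0..n the floor on objective 1 at fraction ``f = 1 - i/n`` is
    ``f · f1_max`` (when the objective's own lower bound is the usual 0;
    in general the floor interpolates from that lower bound to ``f1_max``);
    each point maximizes objective 2 with the floor as objective 1's lower
    bound (upper bound untouched).  Raises :class:`FrontError` if the base model
    is infeasible; per-point failures are recorded in the point status.
    """
    settings.validate(model)
    prepared = apply_medium(model, medium) if medium is not None else model

    base = solve_fba(prepared, settings.objective1, sense="maximize")
    if base.status is SolverStatus.INFEASIBLE:
        raise FrontError(
            f"model {model.id!r} is infeasible; no Pareto front exists"
        )
    if base.status is SolverStatus.UNBOUNDED:
        raise FrontError(
            f"objective {settings.objective1!r} is unbounded in model "
            f"{model.id!r}"
        )
    f1_max = base.objective_value
    obj1 = prepared.get_reaction(settings.objective1)
    obj1_lb, obj1_ub = obj1.lower_bound, obj1.upper_bound

    points: List[ParetoPoint] = []
    n = settings.n
    for i in range(n + 1):
        fraction = 1.0 - i / n
        # interpolate between the reaction's own lower bound (fraction 0:
        # the plain objective-2 optimum) and f1_max (fraction 1); for the
        # usual lb = 0 this is exactly fraction * f1_max
        floor = obj1_lb + fraction * (f1_max - obj1_lb)
        result = solve_fba_with_fixed_flux(
            prepared,
            settings.objective2,
            fixed=[(settings.objective1, floor, obj1_ub)],
            sense="maximize",
        )
        points.append(
            ParetoPoint(
                fraction=fraction,
                objective1_floor=floor,
                objective1_percent=100.0 * fraction,
                objective2_value=result.objective_value,
                status=result.status,
                result=result,
            )
        )
    return ParetoFront(
        objective1=settings.objective1,
        objective2=settings.objective2,
        f1_max=f1_max,
        points=points,
        model=prepared,
        medium=medium,
    )


def binding_medium_constraints(
    result: FluxResult,
    model: MetabolicModel,
    medium: Medium,
    tol: float = FEASIBILITY_TOL,
) -> List[str]:
    """External metabolite ids whose influx sits at its medium cap.

    A nutrient is *binding* (limiting) when its net import flux equals its
    finite, positive medium bound within ``tol``.  ``model`` must be the
    medium-applied model the result was solved on.  Sorted by id.
    """
    if result.status is not SolverStatus.OPTIMAL:
        raise StateError(
            "binding constraints are only defined for an OPTIMAL result"
        )
    binding = []
    for met_id in sorted(medium.entries):
        bound = medium.entries[met_id]
        if not (bound > 0) or bound == float("inf"):
            continue
        influx = exchange_influx(result, model, met_id)
        if abs(influx - bound) <= tol:
            binding.append(met_id)
    return binding


def transition_points(
    front: ParetoFront, tol_scale: float = 1e-6
) -> List[float]:
    """Fractions where the front's slope changes (active-constraint switches).

    Uses the discrete second difference of objective 2 over the equally
    spaced fraction grid; a point fires when |Δ²| exceeds
    ``tol_scale · f2_max`` (scale-free; absolute ``tol_scale`` if the
    objective-2 maximum is zero).  Reported in sweep order.  A kink lying
    strictly between grid fractions fires at the two bracketing points.
    """
    if len(front.points) < 3:
        return []
    values = [
        pt.objective2_value if pt.objective2_value is not None else 0.0
        for pt in front.points
    ]
    f2_max = front.f2_max or 0.0
    tol = tol_scale * abs(f2_max) if f2_max else tol_scale
    out = []
    for i in range(1, len(values) - 1):
        second = values[i - 1] - 2 * values[i] + values[i + 1]
        if abs(second) > tol:
            out.append(front.points[i].fraction)
    return out
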