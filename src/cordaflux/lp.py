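"""Flux balance analysis: the one LP contract every other module calls.

The problem is always  optimize c·v  subject to  S·v = 0,  lb <= v <= ub.
The backend is scipy's HiGHS interface; ``LPSettings.backend`` is kept so
an alternative solver can be plugged in behind the same signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, ModelError

__all__ = ["LPSettings", "FluxVector", "solve_fba", "can_carry_flux"]


@dataclass
class LPSettings:
    feasibility_tol: float = 1e-9
    optimality_tol: float = 1e-9
    backend: str = "highs"

    def __post_init__(self) -> None:
        if self.feasibility_tol <= 0 or self.optimality_tol <= 0:
            raise ValueError("tolerances must be strictly positive")


@dataclass
class FluxVector:
    values: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rxn_id: str) -> float:
        return self.values[rxn_id]


class SolverError(Exception):
    """Backend failure that is neither infeasibility nor unboundedness."""


def _resolve_objective(model: MetabolicModel, objective) -> np.ndarray:
    n = len(model.reactions)
    if isinstance(objective, str):
        c = np.zeros(n)
        idx = {r.id: i for i, r in enumerate(model.reactions)}
        if objective not in idx:
            raise ModelError(f"unknown objective reaction {objective!r}")
        c[idx[objective]] = 1.0
        return c
    c = np.asarray(objective, dtype=float)
    if c.shape != (n,):
        raise ValueError(f"objective length {c.shape} != {n} reactions")
    return c


def solve_fba(
    model: MetabolicModel,
    objective,
    sense: str = "maximize",
    settings: LPSettings | None = None,
) -> FluxVector:
    """Optimize a linear objective over the steady-state flux polytope.

    ``objective`` is a length-n coefficient vector or a reaction id.
    Status is propagated verbatim: ``optimal``, ``infeasible`` or
    ``unbounded``; any other backend condition raises :class:`SolverError`.
    """
    settings = settings or LPSettings()
    if sense not in ("maximize", "minimize"):
        raise ValueError(f"bad sense {sense!r}")
    c = _resolve_objective(model, objective)
    sign = -1.0 if sense == "maximize" else 1.0
    S = model.S
    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(model.lb, model.ub)),
        method="highs",
        options={
            "primal_feasibility_tolerance": settings.feasibility_tol,
            "dual_feasibility_tolerance": settings.optimality_tol,
        },
    )
    if res.status == 0:
        values = dict(zip(model.reaction_ids, map(float, res.x)))
        return FluxVector(values, float(sign * res.fun), "optimal")
    if res.status == 2:
        return FluxVector({}, float("nan"), "infeasible")
    if res.status == 3:
        return FluxVector({}, float("nan"), "unbounded")
    raise SolverError(f"LP backend failure (status {res.status}): {res.message}")


def can_carry_flux(
    model: MetabolicModel,
    rxn_id: str,
    direction: str = "forward",
    epsilon: float = 1.0,
    settings: LPSettings | None = None,
) -> bool:
    """True iff the reaction can carry flux >= epsilon (or <= -epsilon).

    A feasibility LP with a zero objective and the single extra bound
    ``v >= epsilon`` (forward) or ``v <= -epsilon`` (backward).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if direction not in ("forward", "backward"):
        raise ValueError(f"bad direction {direction!r}")
    probe = model.copy()
    r = probe.reaction(rxn_id)
    if direction == "forward":
        if r.ub < epsilon:
            return False
        r.lb = max(r.lb, epsilon)
    else:
        if r.lb > -epsilon:
            return False
        r.ub = min(r.ub, -epsilon)
    sol = solve_fba(probe, np.zeros(len(probe.reactions)), "minimize", settings)
    return sol.status == "optimal"
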