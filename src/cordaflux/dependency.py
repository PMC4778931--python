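"""Cost-optimization dependency assessment.

To test whether a reaction *j* depends on a set *Y* of undesirable
reactions to carry flux, the model is augmented with a cost
pseudo-metabolite: every column produces cost (gamma + noise for members
of *Y*, noise alone otherwise), one extra column consumes it, reversible
reactions are split so cost is produced in either direction, *j* is
forced to carry flux +/- epsilon, and FBA minimises cost consumption.
Members of *Y* carrying flux in the optimum are *associated* with *j* —
the set of undesirable reactions whose combined flux is minimal among
all flux distributions supporting the forced flux.

Noise draws are keyed by (seed, tested reaction, direction, repeat,
cost-bearing column), so results are independent of the order in which
queries are issued and of the ordering of reactions in the model.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .lp import LPSettings, solve_fba
from .model import MetabolicModel, ModelError, Reaction, SplitMapping

__all__ = [
    "CordaParams",
    "DependencyQuery",
    "DependencyResult",
    "build_cost_model",
    "assess_dependency",
    "assess_dependency_repeated",
]

COST_MET = "__cost"
COST_CONSUMER = "__cost_consumer"


@dataclass(frozen=True)
class CordaParams:
    """Algorithm knobs; the defaults are the reference configuration
    gamma=1e5, kappa=1e-2, epsilon=1, n=5, p=2."""

    gamma: float = 1e5  # cost of undesirable reactions
    kappa: float = 1e-2  # noise magnitude, uniform on [0, kappa]
    epsilon: float = 1.0  # forced flux through the tested reaction
    n: int = 5  # dependency-assessment repeats
    p: int = 2  # NC inclusion threshold (step 2)
    gamma_mc: float = 1e3  # step-1 cost for MC reactions (< gamma)
    tau: float | None = None  # association flux tolerance; default 1e-6*epsilon
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.gamma > self.kappa > 0):
            raise ValueError("require gamma >> kappa > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.n < 1 or self.p < 1:
            raise ValueError("n and p must be >= 1")
        if not (0 < self.gamma_mc <= self.gamma):
            raise ValueError("require 0 < gamma_mc <= gamma")

    @property
    def flux_tol(self) -> float:
        return self.tau if self.tau is not None else 1e-6 * self.epsilon


@dataclass(frozen=True)
class DependencyQuery:
    rxn_id: str
    direction: str = "forward"  # forward | backward
    cost_map: tuple = ()  # tuple of (reaction-id, base cost) pairs

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"bad direction {self.direction!r}")
        cm = tuple(sorted(dict(self.cost_map).items()))
        object.__setattr__(self, "cost_map", cm)
        if self.rxn_id in dict(cm):
            raise ValueError("tested reaction cannot be in the cost set Y")

    @property
    def Y(self) -> set[str]:
        return {rid for rid, _ in self.cost_map}

    def cost(self, rid: str) -> float:
        return dict(self.cost_map).get(rid, 0.0)


@dataclass
class DependencyResult:
    query: DependencyQuery
    feasible: bool
    associated: set[str] = field(default_factory=set)
    flux: dict[str, float] = field(default_factory=dict)  # net, original ids
    cost_objective: float = float("nan")


class InfeasibleForcedFlux(Exception):
    """The tested reaction's bounds exclude the forced flux entirely."""


def _u32(text: str) -> int:
    return zlib.crc32(text.encode())


def _noise_rng(params: CordaParams, query: DependencyQuery, repeat: int, col: str):
    """Generator keyed by (seed, tested reaction, direction, repeat, column)."""
    key = [
        params.seed,
        _u32(query.rxn_id),
        0 if query.direction == "forward" else 1,
        repeat,
        _u32(col),
    ]
    return np.random.default_rng(np.random.SeedSequence(key))


def draw_noise(
    model: MetabolicModel, query: DependencyQuery, params: CordaParams, repeat: int
) -> dict[str, float]:
    """Per-column noise in [0, kappa], one independent keyed stream each.

    Split backward columns (``<id>__rev``) get their own draw; keying by
    column id rather than column position makes the draw invariant to
    reaction ordering in the model.
    """
    cols: list[str] = []
    for r in model.reactions:
        cols.append(r.id)
        if r.id != query.rxn_id and r.lb < 0:
            cols.append(r.id + "__rev")
    return {
        c: float(_noise_rng(params, query, repeat, c).uniform(0.0, params.kappa))
        for c in cols
    }


def build_cost_model(
    model: MetabolicModel,
    query: DependencyQuery,
    params: CordaParams,
    noise: dict[str, float],
) -> tuple[MetabolicModel, SplitMapping]:
    """Augment the model with the cost pseudo-metabolite LP.

    Reversible reactions other than the tested one are split; every
    column produces ``cost(i) + noise_i`` units of the cost metabolite; a
    single consuming column is appended; the tested reaction is forced to
    carry flux epsilon (forward: lb_j = eps) or -epsilon (backward:
    ub_j = -eps).
    """
    from .model import split_reversible

    r_j = model.reaction(query.rxn_id)  # raises on unknown id
    if query.direction == "backward" and r_j.lb >= 0:
        raise ModelError(
            f"backward assessment requested on irreversible reaction {r_j.id!r}"
        )
    split, mapping = split_reversible(model, exempt=query.rxn_id)
    cost_of = dict(query.cost_map)

    def base_cost(col_id: str) -> float:
        orig = col_id[: -len("__rev")] if col_id.endswith("__rev") else col_id
        return cost_of.get(orig, 0.0)

    rxns = []
    for r in split.reactions:
        rr = r.copy()
        coef = base_cost(r.id) + noise.get(r.id, 0.0)
        if coef != 0.0:  # a zero coefficient is simply absent
            rr.stoich[COST_MET] = coef
        rxns.append(rr)
    consumer = Reaction(COST_CONSUMER, {COST_MET: -1.0}, lb=0.0, ub=np.inf)
    rxns.append(consumer)

    # force the tested flux
    for rr in rxns:
        if rr.id == query.rxn_id:
            if query.direction == "forward":
                if rr.ub < params.epsilon:
                    raise InfeasibleForcedFlux(rr.id)
                rr.lb = max(rr.lb, params.epsilon)
            else:
                if rr.lb > -params.epsilon:
                    raise InfeasibleForcedFlux(rr.id)
                rr.ub = min(rr.ub, -params.epsilon)

    from dataclasses import replace

    mets = [replace(m) for m in split.metabolites]
    mets.append(_cost_metabolite())
    return MetabolicModel(mets, rxns, id=model.id), mapping


def _cost_metabolite():
    from .model import Metabolite

    return Metabolite(COST_MET, compartment="pseudo")


def assess_dependency(
    model: MetabolicModel,
    query: DependencyQuery,
    params: CordaParams,
    noise: dict[str, float] | None = None,
    repeat: int = 0,
    settings: LPSettings | None = None,
) -> DependencyResult:
    """One dependency assessment: minimal-cost support of the forced flux."""
    if noise is None:
        noise = draw_noise(model, query, params, repeat)
    try:
        augmented, mapping = build_cost_model(model, query, params, noise)
    except InfeasibleForcedFlux:
        return DependencyResult(query, feasible=False)
    sol = solve_fba(augmented, COST_CONSUMER, "minimize", settings)
    if sol.status != "optimal":
        return DependencyResult(query, feasible=False)
    net = mapping.net_flux(sol.values)
    net.pop(COST_CONSUMER, None)
    associated = {
        rid for rid in query.Y if abs(net.get(rid, 0.0)) > params.flux_tol
    }
    return DependencyResult(
        query,
        feasible=True,
        associated=associated,
        flux=net,
        cost_objective=sol.objective_value,
    )


def assess_dependency_repeated(
    model: MetabolicModel,
    query: DependencyQuery,
    params: CordaParams,
    n: int | None = None,
    settings: LPSettings | None = None,
) -> set[str]:
    """Union of associated sets over n independent keyed noise draws."""
    n = params.n if n is None else n
    if n < 1:
        raise ValueError("n must be >= 1")
    out: set[str] = set()
    for k in range(n):
        res = assess_dependency(model, query, params, repeat=k, settings=settings)
        out |= res.associated
    return out
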