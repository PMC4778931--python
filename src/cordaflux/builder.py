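"""Three-step tissue-model extraction on top of the dependency assessment.

Reactions arrive partitioned into a non-flexible high-confidence core
(HC), a flexible medium/negative-confidence core (MC, NC) and the
remainder (OT).  Metabolic-task sinks are treated as HC members that are
added to the model one at a time while tested and removed afterwards.

Step 1  HC (and task) support: MC and NC reactions associated with any
        HC-seeded query join the reconstruction RE.
Step 2  Flexible core: NC reactions associated with >= p MC reactions
        join RE; the remaining NC are blocked and every MC reaction
        still able to carry flux in either direction joins RE.  MC
        reactions lost here are reported with their NC associations.
Step 3  OT support: with all excluded MC/NC blocked, OT reactions
        associated with any RE reaction join RE.

All queries within a step run against the same step-start state (batch
semantics), which together with keyed noise makes the outcome
independent of reaction ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dependency import (
    CordaParams,
    DependencyQuery,
    assess_dependency_repeated,
)
from .lp import LPSettings, can_carry_flux
from .model import MetabolicModel, Metabolite, ModelError, Reaction, subset_model

__all__ = ["ReactionGroups", "CordaResult", "corda_build", "extract_tissue_model"]


@dataclass(frozen=True)
class TaskSink:
    """Sink consuming one metabolite, forced positive while under test."""

    metabolite: str
    lb: float = 1.0

    def __post_init__(self) -> None:
        if self.lb <= 0:
            raise ValueError("task sink lower bound must be strictly positive")

    @property
    def rxn_id(self) -> str:
        return f"__task_sink__{self.metabolite}"


@dataclass
class ReactionGroups:
    hc: set[str] = field(default_factory=set)
    mc: set[str] = field(default_factory=set)
    nc: set[str] = field(default_factory=set)
    ot: set[str] = field(default_factory=set)
    tasks: list[TaskSink] = field(default_factory=list)

    def validate(self, model: MetabolicModel) -> None:
        sets = [self.hc, self.mc, self.nc, self.ot]
        names = ["HC", "MC", "NC", "OT"]
        for i in range(4):
            for j in range(i + 1, 4):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ModelError(
                        f"groups {names[i]}/{names[j]} overlap: {sorted(overlap)}"
                    )
        union = set().union(*sets)
        model_ids = set(model.reaction_ids)
        if union != model_ids:
            missing = model_ids - union
            extra = union - model_ids
            raise ModelError(
                f"groups must partition the model; missing={sorted(missing)}, "
                f"unknown={sorted(extra)}"
            )
        for t in self.tasks:
            if model.has_reaction(t.rxn_id):
                raise ModelError(f"task sink id {t.rxn_id!r} collides with a reaction")


@dataclass
class CordaResult:
    re: set[str]
    ledger: dict[str, set[tuple[str, int]]]
    excluded_mc: dict[str, set[str]]
    params_used: CordaParams
    step_log: dict[str, int]


def _query_directions(model: MetabolicModel, rid: str) -> list[str]:
    r = model.reaction(rid)
    dirs = []
    if r.ub > 0:
        dirs.append("forward")
    if r.lb < 0:
        dirs.append("backward")
    return dirs


def _with_sink(model: MetabolicModel, sink: TaskSink) -> MetabolicModel:
    """Copy of the model with one task-sink reaction appended."""
    if not model.has_metabolite(sink.metabolite):
        raise ModelError(f"task metabolite {sink.metabolite!r} not in model")
    mets = list(model.metabolites)
    rxns = [r.copy() for r in model.reactions]
    rxns.append(Reaction(sink.rxn_id, {sink.metabolite: -1.0}, lb=0.0, ub=np.inf))
    return MetabolicModel([Metabolite(m.id, m.compartment, m.name) for m in mets],
                          rxns, id=model.id)


def _assess_seed(
    model: MetabolicModel,
    rid: str,
    cost_map: dict[str, float],
    params: CordaParams,
    settings: LPSettings | None,
) -> set[str]:
    """Union of associations over both feasible directions and n repeats."""
    out: set[str] = set()
    for direction in _query_directions(model, rid):
        q = DependencyQuery(rid, direction, tuple(cost_map.items()))
        out |= assess_dependency_repeated(model, q, params, settings=settings)
    return out


def corda_build(
    model: MetabolicModel,
    groups: ReactionGroups,
    params: CordaParams | None = None,
    settings: LPSettings | None = None,
) -> CordaResult:
    """Run the three-step extraction and return RE plus the curation ledger.

    The ledger maps each admitted non-HC reaction to the (seed reaction,
    step) pairs that brought it in; an MC reaction admitted in step 2 by
    the flux-capability check is recorded as supported by itself.
    """
    params = params or CordaParams()
    groups.validate(model)
    re: set[str] = set(groups.hc)
    ledger: dict[str, set[tuple[str, int]]] = {}
    step_log: dict[str, int] = {"step0_hc": len(re)}

    def admit(member: str, supporter: str, step: int) -> None:
        re.add(member)
        ledger.setdefault(member, set()).add((supporter, step))

    # ---- step 1: MC/NC support of the HC core and metabolic tasks
    cost1 = {rid: params.gamma for rid in groups.nc}
    cost1.update({rid: params.gamma_mc for rid in groups.mc})
    for rid in sorted(groups.hc):
        for member in _assess_seed(model, rid, cost1, params, settings):
            admit(member, rid, 1)
    for sink in groups.tasks:
        try:
            sink_model = _with_sink(model, sink)
        except ModelError:
            continue  # metabolite absent: the task can contribute nothing
        q_cost = dict(cost1)
        q = DependencyQuery(sink.rxn_id, "forward", tuple(q_cost.items()))
        for member in assess_dependency_repeated(sink_model, q, params, settings=settings):
            admit(member, sink.rxn_id, 1)
    step_log["step1_added"] = len(re) - step_log["step0_hc"]

    # ---- step 2: flexible MC/NC core
    mc_left = sorted(groups.mc - re)
    nc_left = groups.nc - re
    cost2 = {rid: params.gamma for rid in nc_left}
    nc_supporters: dict[str, set[str]] = {rid: set() for rid in nc_left}
    mc_assoc: dict[str, set[str]] = {}
    for rid in mc_left:
        assoc = _assess_seed(model, rid, cost2, params, settings)
        mc_assoc[rid] = assoc
        for nc in assoc:
            nc_supporters[nc].add(rid)
    for nc in sorted(nc_left):
        if len(nc_supporters[nc]) >= params.p:
            for supporter in nc_supporters[nc]:
                admit(nc, supporter, 2)
    from .model import block_reactions

    blocked_nc = block_reactions(model, groups.nc - re)
    excluded_mc: dict[str, set[str]] = {}
    for rid in mc_left:
        capable = any(
            can_carry_flux(blocked_nc, rid, d, params.epsilon, settings)
            for d in _query_directions(model, rid)
        )
        if capable:
            admit(rid, rid, 2)  # self-supported: independent of blocked NC
        else:
            excluded_mc[rid] = set(mc_assoc[rid])
    step_log["step2_added"] = (
        len(re) - step_log["step0_hc"] - step_log["step1_added"]
    )

    # ---- step 3: OT support of the reconstruction
    model3 = block_reactions(model, (groups.mc | groups.nc) - re)
    cost3 = {rid: params.gamma for rid in groups.ot}
    for rid in sorted(re):
        for member in _assess_seed(model3, rid, cost3, params, settings):
            admit(member, rid, 3)
    for sink in groups.tasks:
        try:
            sink_model = _with_sink(model3, sink)
        except ModelError:
            continue
        q = DependencyQuery(sink.rxn_id, "forward", tuple(cost3.items()))
        for member in assess_dependency_repeated(sink_model, q, params, settings=settings):
            admit(member, sink.rxn_id, 3)
    step_log["step3_added"] = len(re) - sum(
        step_log[k] for k in ("step0_hc", "step1_added", "step2_added")
    )
    step_log["re_total"] = len(re)

    return CordaResult(
        re=re,
        ledger=ledger,
        excluded_mc=excluded_mc,
        params_used=params,
        step_log=step_log,
    )


def extract_tissue_model(model: MetabolicModel, result: CordaResult) -> MetabolicModel:
    """Materialise the final RE set as a stand-alone model."""
    unknown = result.re - set(model.reaction_ids)
    if unknown:
        raise ModelError(f"RE references reactions absent from the model: {sorted(unknown)}")
    return subset_model(model, result.re)
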