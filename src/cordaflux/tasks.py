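"""Metabolic-task battery and metabolite essentiality.

Tasks run in a controlled exchange environment: the basal inputs (CO2,
water, protons, O2, phosphate, H2O2, superoxide, bicarbonate, CO) are
freely exchanged while every other uptake is blocked; test-specific
substrates are then opened up to a fixed rate.  Three task kinds are
supported:

recycling   uptake of one amino acid (the sole nitrogen source) plus
            glucose; urea export is forced positive and maximised.
glucogenic  uptake of one substrate; glucose export forced and maximised.
nucleotide  a cytosolic sink for the nucleotide is added and maximised,
            with glucose and ammonium available.

A missing test-specific exchange makes a recycling/glucogenic result
*inconsistent*; nucleotide tests need no exchanges and simply fail when
the sink cannot carry flux.  All operations leave the input model
untouched.

Metabolite knockout blocks every consuming direction of the metabolite
(and reverse production through reversible consumers); a metabolite is
*essential* when a task that passed on the intact model fails after its
knockout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lp import LPSettings, solve_fba
from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    classify_reaction,
    parse_compartment,
)

__all__ = [
    "BASAL_INPUTS",
    "TaskEnvironment",
    "TaskSpec",
    "TaskResult",
    "apply_basal_environment",
    "run_recycling_test",
    "run_glucogenic_test",
    "run_nucleotide_test",
    "run_task",
    "knockout_metabolite",
    "is_essential_metabolite",
    "read_task_table",
]

BASAL_INPUTS = (
    "co2[e]",
    "h2o[e]",
    "h[e]",
    "o2[e]",
    "pi[e]",
    "h2o2[e]",
    "o2s[e]",
    "hco3[e]",
    "co[e]",
)


@dataclass(frozen=True)
class TaskEnvironment:
    basal_inputs: tuple = BASAL_INPUTS
    uptake_value: float = 1.0  # rate allowed for test-specific uptakes
    epsilon: float = 1.0  # strictly-positive forcing for products
    glucose: str = "glc_D[e]"
    urea: str = "urea[e]"
    ammonium: str = "nh4[e]"

    def __post_init__(self) -> None:
        if self.uptake_value <= 0 or self.epsilon <= 0:
            raise ValueError("uptake value and epsilon must be positive")


@dataclass(frozen=True)
class TaskSpec:
    task_id: str
    kind: str  # recycling | glucogenic | nucleotide
    metabolite: str

    def __post_init__(self) -> None:
        if self.kind not in ("recycling", "glucogenic", "nucleotide"):
            raise ValueError(f"unknown task kind {self.kind!r}")


@dataclass
class TaskResult:
    task_id: str
    outcome: str  # passed | failed | inconsistent
    objective: float | None = None


def _met_key(met_id: str) -> tuple[str, str]:
    return parse_compartment(met_id)


def _exchange_of(model: MetabolicModel, met_id: str):
    """Exchange reaction of a metabolite, matched across suffix dialects."""
    target = _met_key(met_id)
    for r in model.reactions:
        if len(r.stoich) == 1:
            (met,) = r.stoich
            if _met_key(met) == target:
                return r
    return None


def _uptake_sign(reaction: Reaction) -> float:
    """+1 if positive flux imports the metabolite, -1 if it exports."""
    (coef,) = reaction.stoich.values()
    return 1.0 if coef > 0 else -1.0


def _block_uptake(r: Reaction) -> None:
    if _uptake_sign(r) > 0:
        r.ub = min(r.ub, 0.0)
        r.lb = min(r.lb, r.ub)
    else:
        r.lb = max(r.lb, 0.0)
        r.ub = max(r.ub, r.lb)


def _allow_uptake(r: Reaction, rate: float) -> None:
    if _uptake_sign(r) > 0:
        r.ub = rate
    else:
        r.lb = -rate


def _force_export(r: Reaction, eps: float) -> None:
    """Constrain the exchange to export at least eps; an exchange whose
    bounds exclude any export becomes an infeasible LP, which the caller
    reports as a failed task."""
    if _uptake_sign(r) > 0:
        r.ub = min(r.ub, -eps)
    else:
        r.lb = max(r.lb, eps)


def _export_objective(model: MetabolicModel, r: Reaction) -> np.ndarray:
    c = np.zeros(len(model.reactions))
    idx = model.reaction_ids.index(r.id)
    c[idx] = -_uptake_sign(r)  # export direction is positive objective
    return c


def apply_basal_environment(
    model: MetabolicModel, env: TaskEnvironment | None = None
) -> MetabolicModel:
    """Open the basal exchanges fully; block uptake through all others.

    Export directions of non-basal exchanges stay open.  Missing basal
    exchanges are simply absent.
    """
    env = env or TaskEnvironment()
    basal = {_met_key(m) for m in env.basal_inputs}
    out = model.copy()
    for r in out.reactions:
        if classify_reaction(out, r.id) != "exchange":
            continue
        (met,) = r.stoich
        if _met_key(met) in basal:
            r.lb = -DEFAULT_BOUND
            r.ub = DEFAULT_BOUND
        else:
            _block_uptake(r)
    return out


def _production_test(
    model: MetabolicModel,
    uptakes: list[str],
    required_exchanges: list[str],
    product: str,
    env: TaskEnvironment,
    task_id: str,
    settings: LPSettings | None,
) -> TaskResult:
    for met in required_exchanges:
        if _exchange_of(model, met) is None:
            return TaskResult(task_id, "inconsistent")
    probe = apply_basal_environment(model, env)
    for met in uptakes:
        ex = _exchange_of(probe, met)
        if ex is not None:
            _allow_uptake(ex, env.uptake_value)
    ex_prod = _exchange_of(probe, product)
    _force_export(ex_prod, env.epsilon)
    sol = solve_fba(probe, _export_objective(probe, ex_prod), "maximize", settings)
    if sol.status == "optimal":
        return TaskResult(task_id, "passed", abs(sol.objective_value))
    return TaskResult(task_id, "failed")


def run_recycling_test(
    model: MetabolicModel,
    amino_acid: str,
    env: TaskEnvironment | None = None,
    settings: LPSettings | None = None,
    task_id: str | None = None,
) -> TaskResult:
    """Urea production from one amino acid as the sole nitrogen source."""
    env = env or TaskEnvironment()
    return _production_test(
        model,
        uptakes=[amino_acid, env.glucose],
        required_exchanges=[amino_acid, env.urea],
        product=env.urea,
        env=env,
        task_id=task_id or f"recycling:{amino_acid}",
        settings=settings,
    )


def run_glucogenic_test(
    model: MetabolicModel,
    substrate: str,
    env: TaskEnvironment | None = None,
    settings: LPSettings | None = None,
    task_id: str | None = None,
) -> TaskResult:
    """Glucose production from one substrate."""
    env = env or TaskEnvironment()
    return _production_test(
        model,
        uptakes=[substrate],
        required_exchanges=[substrate, env.glucose],
        product=env.glucose,
        env=env,
        task_id=task_id or f"glucogenic:{substrate}",
        settings=settings,
    )


def run_nucleotide_test(
    model: MetabolicModel,
    nucleotide: str,
    env: TaskEnvironment | None = None,
    settings: LPSettings | None = None,
    task_id: str | None = None,
) -> TaskResult:
    """Production of a cytosolic nucleotide through a temporary sink.

    Glucose and ammonium uptake are allowed; the sink flux is maximised.
    No exchange is required, so the outcome is never inconsistent: a
    nucleotide absent from the model simply fails.
    """
    env = env or TaskEnvironment()
    tid = task_id or f"nucleotide:{nucleotide}"
    if not any(_met_key(m.id) == _met_key(nucleotide) for m in model.metabolites):
        return TaskResult(tid, "failed")
    probe = apply_basal_environment(model, env)
    for met in (env.glucose, env.ammonium):
        ex = _exchange_of(probe, met)
        if ex is not None:
            _allow_uptake(ex, env.uptake_value)
    met_id = next(
        m.id for m in probe.metabolites if _met_key(m.id) == _met_key(nucleotide)
    )
    sink_id = f"__sink__{met_id}"
    probe.reactions.append(
        Reaction(sink_id, {met_id: -1.0}, lb=env.epsilon, ub=np.inf)
    )
    sol = solve_fba(probe, sink_id, "maximize", settings)
    if sol.status in ("optimal", "unbounded"):
        obj = sol.objective_value if sol.status == "optimal" else float("inf")
        return TaskResult(tid, "passed", obj)
    return TaskResult(tid, "failed")


def run_task(
    model: MetabolicModel,
    spec: TaskSpec,
    env: TaskEnvironment | None = None,
    settings: LPSettings | None = None,
) -> TaskResult:
    runner = {
        "recycling": run_recycling_test,
        "glucogenic": run_glucogenic_test,
        "nucleotide": run_nucleotide_test,
    }[spec.kind]
    return runner(model, spec.metabolite, env, settings, task_id=spec.task_id)


# ---------------------------------------------------------------------------
# metabolite knockout / essentiality


def knockout_metabolite(model: MetabolicModel, met_id: str) -> MetabolicModel:
    """Block all consumption of a metabolite (and reverse production).

    For every reaction touching the metabolite: a negative coefficient
    (forward consumption) has its forward direction blocked and, being a
    producer in reverse, its backward direction too; a positive
    coefficient (backward consumption / forward production) has only its
    backward direction blocked, so forward production stays possible.
    No bound is ever relaxed except to keep lb <= ub on already-forced
    reactions.
    """
    if not model.has_metabolite(met_id):
        raise ModelError(f"unknown metabolite {met_id!r}")
    out = model.copy()
    for r in out.reactions:
        coef = r.stoich.get(met_id)
        if coef is None:
            continue
        if coef < 0:
            r.ub = min(r.ub, 0.0)
            r.lb = max(r.lb, 0.0)
            if r.lb > r.ub:  # reaction was forced; it simply cannot run
                r.lb = r.ub = 0.0
        else:
            r.lb = max(r.lb, 0.0)
            if r.lb > r.ub:
                r.lb = r.ub = 0.0
    return out


def is_essential_metabolite(
    model: MetabolicModel,
    met_id: str,
    tasks: list[TaskSpec],
    env: TaskEnvironment | None = None,
    settings: LPSettings | None = None,
) -> bool:
    """True iff a task passing on the intact model fails after knockout."""
    if not tasks:
        raise ValueError("task list must be non-empty")
    ko = knockout_metabolite(model, met_id)
    for spec in tasks:
        before = run_task(model, spec, env, settings)
        if before.outcome != "passed":
            continue
        after = run_task(ko, spec, env, settings)
        if after.outcome == "failed":
            return True
    return False


def read_task_table(path: str) -> list[TaskSpec]:
    """TSV task definitions: (task_id, kind, metabolite)."""
    out: list[TaskSpec] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if parts[0].lower() == "task_id":
                continue
            if len(parts) < 3:
                raise ValueError(f"bad task row: {line!r}")
            out.append(TaskSpec(parts[0], parts[1], parts[2]))
    return out
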