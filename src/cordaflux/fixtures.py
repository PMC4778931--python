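"""Synthetic toy networks with planted structure, and brute-force oracles.

Every planted network carries expectations computed by exhaustive
enumeration at construction time, never hand-asserted, so the dependency
assessment and the builder can be checked end to end without any
external data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .builder import ReactionGroups
from .dependency import CordaParams, DependencyQuery
from .lp import LPSettings, can_carry_flux, solve_fba
from .model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    block_reactions,
    split_reversible,
)

__all__ = [
    "PlantedNetwork",
    "make_linear_chain",
    "make_detox_motif",
    "make_flexible_core_fixture",
    "brute_force_dependency_oracle",
    "minimal_y_flux",
    "make_synthetic_evidence",
]

MAX_ORACLE_Y = 14  # exhaustive enumeration cap (2^|Y| subsets)


@dataclass
class PlantedNetwork:
    model: MetabolicModel
    groups: ReactionGroups
    expected_re: set[str]
    expected_associations: dict[DependencyQuery, set[frozenset]] = field(
        default_factory=dict
    )


def _mets(*ids: str) -> list[Metabolite]:
    return [Metabolite(i) for i in ids]


def make_linear_chain(k: int, cap: float = 10.0) -> MetabolicModel:
    """Irreversible chain 0 -> M1 -> ... -> Mk -> 0 with k+1 reactions."""
    if k < 1:
        raise ValueError("k must be >= 1")
    mets = _mets(*[f"M{i}[c]" for i in range(1, k + 1)])
    rxns = [Reaction("R_in", {"M1[c]": 1.0}, 0.0, cap)]
    for i in range(1, k):
        rxns.append(
            Reaction(f"R{i}", {f"M{i}[c]": -1.0, f"M{i+1}[c]": 1.0}, 0.0, cap)
        )
    rxns.append(Reaction("R_out", {f"M{k}[c]": -1.0}, 0.0, cap))
    return MetabolicModel(mets, rxns, id=f"chain{k}")


def minimal_y_flux(
    model: MetabolicModel,
    query: DependencyQuery,
    epsilon: float,
    settings: LPSettings | None = None,
) -> tuple[bool, float, frozenset]:
    """LP for the minimal summed |flux| over Y under the forced flux.

    Splits reversible reactions (tested reaction exempt), forces the
    tested flux, minimises the sum of all Y columns, and returns
    (feasible, minimal total Y flux, Y-support of that optimum).
    """
    split, mapping = split_reversible(model, exempt=query.rxn_id)
    r_j = split.reaction(query.rxn_id)
    if query.direction == "forward":
        if r_j.ub < epsilon:
            return False, float("inf"), frozenset()
        r_j.lb = max(r_j.lb, epsilon)
    else:
        if r_j.lb > -epsilon:
            return False, float("inf"), frozenset()
        r_j.ub = min(r_j.ub, -epsilon)
    y = query.Y
    c = np.zeros(len(split.reactions))
    for i, r in enumerate(split.reactions):
        base = r.id[: -len("__rev")] if r.id.endswith("__rev") else r.id
        if base in y:
            c[i] = 1.0
    sol = solve_fba(split, c, "minimize", settings)
    if sol.status != "optimal":
        return False, float("inf"), frozenset()
    net = mapping.net_flux(sol.values)
    tol = 1e-6 * epsilon
    support = frozenset(r for r in y if abs(net.get(r, 0.0)) > tol)
    return True, float(sol.objective_value), support


def brute_force_dependency_oracle(
    model: MetabolicModel,
    query: DependencyQuery,
    epsilon: float = 1.0,
    settings: LPSettings | None = None,
) -> set[frozenset]:
    """All minimal-total-Y-flux supports, by exhaustive subset enumeration.

    For every subset T of Y the complement is blocked, feasibility of the
    forced flux is tested, and the minimal summed Y flux on T is
    computed; the Y-supports of all subsets attaining the global minimum
    are returned.  An infeasible query yields the empty set.
    """
    y = sorted(query.Y)
    if len(y) > MAX_ORACLE_Y:
        raise ValueError(f"oracle capped at |Y| <= {MAX_ORACLE_Y}, got {len(y)}")
    best = float("inf")
    supports: set[frozenset] = set()
    tol = 1e-6 * max(epsilon, 1.0)
    for r in range(len(y) + 1):
        for keep in itertools.combinations(y, r):
            restricted = block_reactions(model, set(y) - set(keep))
            feasible, total, support = minimal_y_flux(
                restricted, query, epsilon, settings
            )
            if not feasible:
                continue
            if total < best - tol:
                best = total
                supports = {support}
            elif abs(total - best) <= tol:
                supports.add(support)
    return supports


def make_detox_motif() -> PlantedNetwork:
    """Demanded metabolite reachable via a direct import or a 2-step
    route through a toxic intermediate.

    The demand DM_X is high confidence; the direct exchange E_direct is
    an ordinary (OT) reaction; the toxic route E_tox + R_tox is negative
    confidence.  Expected associations are computed by the oracle.
    """
    mets = _mets("X[c]", "T[c]")
    rxns = [
        Reaction("DM_X", {"X[c]": -1.0}, 0.0, 10.0),
        Reaction("E_direct", {"X[c]": 1.0}, 0.0, 10.0),
        Reaction("E_tox", {"T[c]": 1.0}, 0.0, 10.0),
        Reaction("R_tox", {"T[c]": -1.0, "X[c]": 1.0}, 0.0, 10.0),
    ]
    model = MetabolicModel(mets, rxns, id="detox")
    groups = ReactionGroups(
        hc={"DM_X"}, nc={"E_tox", "R_tox"}, ot={"E_direct"}
    )
    q = DependencyQuery(
        "DM_X",
        "forward",
        (("E_direct", 1e5), ("E_tox", 1e5), ("R_tox", 1e5)),
    )
    expectations = {q: brute_force_dependency_oracle(model, q)}
    # direct route wins; toxic route stays out of the reconstruction
    expected_re = {"DM_X", "E_direct"}
    return PlantedNetwork(model, groups, expected_re, expectations)


def make_flexible_core_fixture(p: int = 2) -> PlantedNetwork:
    """One NC source feeding p MC consumers (admitted at threshold p) and
    a second NC source feeding p-1 (excluded, dragging its MC consumers
    into the excluded report)."""
    if p < 1:
        raise ValueError("p must be >= 1")
    mets = _mets("H[c]", "A[c]", "C[c]")
    rxns = [
        Reaction("E_H", {"H[c]": 1.0}, 0.0, 10.0),
        Reaction("DM_H", {"H[c]": -1.0}, 0.0, 10.0),
        Reaction("NC1", {"A[c]": 1.0}, 0.0, 10.0),
        Reaction("NC2", {"C[c]": 1.0}, 0.0, 10.0),
    ]
    mc: set[str] = set()
    for i in range(1, p + 1):
        rxns.append(Reaction(f"MCa{i}", {"A[c]": -1.0}, 0.0, 10.0))
        mc.add(f"MCa{i}")
    for j in range(1, p):
        rxns.append(Reaction(f"MCc{j}", {"C[c]": -1.0}, 0.0, 10.0))
        mc.add(f"MCc{j}")
    model = MetabolicModel(mets, rxns, id=f"flexcore_p{p}")
    groups = ReactionGroups(
        hc={"E_H", "DM_H"}, mc=mc, nc={"NC1", "NC2"}
    )
    expected_re = {"E_H", "DM_H", "NC1"} | {f"MCa{i}" for i in range(1, p + 1)}
    if p == 1:
        # NC2 has no consumers at p=1; nothing admits it
        expected_re = {"E_H", "DM_H", "NC1", "MCa1"}
    return PlantedNetwork(model, groups, expected_re)


HEALTHY_LEVELS = ("NotDetected", "Low", "Medium", "High")


def make_synthetic_evidence(model: MetabolicModel, rng: np.random.Generator, mode: str):
    """Random evidence over the model's GPR genes, healthy or cancer mode.

    Healthy draws one level per gene uniformly; cancer draws sample
    counts from a multinomial over the four levels with Dirichlet
    weights, with 8-15 samples per gene.
    """
    from .scoring import EvidenceTable, parse_gpr

    genes: set[str] = set()
    for r in model.reactions:
        tree = parse_gpr(r.gpr)
        stack = [tree] if tree else []
        while stack:
            node = stack.pop()
            if node[0] == "gene":
                genes.add(node[1])
            else:
                stack.extend(node[1])
    if mode == "healthy":
        table = {g: HEALTHY_LEVELS[rng.integers(4)] for g in sorted(genes)}
        return EvidenceTable(mode="healthy", healthy=table)
    counts = {}
    for g in sorted(genes):
        total = int(rng.integers(8, 16))
        probs = rng.dirichlet(np.ones(4))
        draw = rng.multinomial(total, probs)
        # order (n_high, n_medium, n_low, n_notdetected)
        counts[g] = (int(draw[0]), int(draw[1]), int(draw[2]), int(draw[3]))
    return EvidenceTable(mode="cancer", cancer=counts)


def cancer_counts_for_score(target: float, total: int = 10) -> tuple[int, int, int, int]:
    """Search sample counts whose weighted average is closest to target."""
    best, best_err = (0, 0, 0, total), float("inf")
    for nh in range(total + 1):
        for nm in range(total + 1 - nh):
            for nl in range(total + 1 - nh - nm):
                nd = total - nh - nm - nl
                score = (3 * nh + 2 * nm + nl - nd) / total
                err = abs(score - target)
                if err < best_err:
                    best, best_err = (nh, nm, nl, nd), err
    return best
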