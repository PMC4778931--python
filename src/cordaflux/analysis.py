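"""Post-reconstruction comparison utilities.

Presence matrices and subsystem-fraction scores are the inputs the
clustering of model libraries consumes (the clustering itself is left to
standard routines); the remaining helpers cover evidence composition,
knockout dependency sets, differential inclusion between model groups,
cross-validation enrichment of the reaction cores, and summed flux
distributions over sampled points.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .builder import ReactionGroups, corda_build
from .dependency import CordaParams
from .lp import LPSettings, can_carry_flux
from .model import MetabolicModel, ModelError, block_reactions
from .sampler import SampleSet
from .scoring import ConfidenceAssignment

__all__ = [
    "presence_matrix",
    "subsystem_fraction",
    "confidence_composition",
    "knockout_dependency",
    "differential_inclusion",
    "hypergeometric_pvalue",
    "fisher_combine",
    "cross_validation_enrichment",
    "combined_flux_distribution",
]


def presence_matrix(models: dict[str, set[str]]) -> pd.DataFrame:
    """Presence (1) / absence (-1) of reactions across models.

    Columns are restricted to reactions present in at least one but not
    all models; universally present or absent reactions carry no
    clustering signal and are dropped.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    all_rxns = set().union(*models.values())
    keep = sorted(
        r for r in all_rxns if 0 < sum(r in s for s in models.values()) < len(models)
    )
    data = {
        name: [1 if r in rxns else -1 for r in keep] for name, rxns in models.items()
    }
    return pd.DataFrame(data, index=keep).T


def subsystem_fraction(
    models: dict[str, set[str]],
    categories: dict[str, str],
    subsystems: dict[str, str],
) -> pd.DataFrame:
    """Category x subsystem matrix of inclusion fractions in [0, 1].

    Entry = (mean number of the subsystem's reactions included in the
    category's models) / (number of the subsystem's reactions included in
    any model).  Reactions without a subsystem label fall under
    'uncategorized'.
    """
    missing = set(models) - set(categories)
    if missing:
        raise ValueError(f"models without a category: {sorted(missing)}")
    union = set().union(*models.values())
    sub_of = {r: subsystems.get(r) or "uncategorized" for r in union}
    subs = sorted(set(sub_of.values()))
    totals = {s: sum(1 for r in union if sub_of[r] == s) for s in subs}
    cats = sorted(set(categories.values()))
    out = pd.DataFrame(0.0, index=cats, columns=subs)
    for cat in cats:
        members = [m for m in models if categories[m] == cat]
        for s in subs:
            counts = [
                sum(1 for r in models[m] if sub_of[r] == s) for m in members
            ]
            out.loc[cat, s] = (sum(counts) / len(counts)) / totals[s]
    return out


_LEVEL_BINS = (
    ("NotDetected", lambda s: s <= -0.5),
    ("High", lambda s: s >= 2.5),
    ("Medium", lambda s: 1.5 <= s < 2.5),
    ("Low", lambda s: 0.5 <= s < 1.5),
)


def confidence_composition(
    reactions: set[str], assignment: ConfidenceAssignment
) -> dict[str, int]:
    """Count included reactions by underlying evidence level.

    Scores are binned to the nearest canonical level (Not Detected, Low,
    Medium, High); scores without evidence (near zero) are reported as
    'NoEvidence'.  Counts always sum to the number of reactions given.
    """
    counts = {name: 0 for name, _ in _LEVEL_BINS}
    counts["NoEvidence"] = 0
    for rid in reactions:
        s = assignment.score.get(rid, 0.0)
        for name, pred in _LEVEL_BINS:
            if pred(s):
                counts[name] += 1
                break
        else:
            counts["NoEvidence"] += 1
    return counts


def knockout_dependency(
    model: MetabolicModel,
    rxn_id: str,
    epsilon: float = 1.0,
    settings: LPSettings | None = None,
) -> set[str]:
    """Reactions that lose all flux capability when one reaction is blocked."""
    if not model.has_reaction(rxn_id):
        raise ModelError(f"unknown reaction {rxn_id!r}")

    def capable(m: MetabolicModel, rid: str) -> bool:
        r = m.reaction(rid)
        if r.ub > 0 and can_carry_flux(m, rid, "forward", epsilon, settings):
            return True
        return r.lb < 0 and can_carry_flux(m, rid, "backward", epsilon, settings)

    blocked = block_reactions(model, {rxn_id})
    out = set()
    for rid in model.reaction_ids:
        if rid == rxn_id:
            continue
        if capable(model, rid) and not capable(blocked, rid):
            out.add(rid)
    return out


def differential_inclusion(
    models: dict[str, set[str]], labels: dict[str, str]
) -> pd.DataFrame:
    """Per-reaction inclusion frequencies in two model groups.

    Returns a frame with columns freq_<groupA>, freq_<groupB> and diff,
    sorted by decreasing |diff|.
    """
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two group labels, got {groups}")
    ga, gb = groups
    members = {g: [m for m in models if labels[m] == g] for g in groups}
    if not members[ga] or not members[gb]:
        raise ValueError("both groups must be non-empty")
    all_rxns = sorted(set().union(*models.values()))
    fa = [np.mean([r in models[m] for m in members[ga]]) for r in all_rxns]
    fb = [np.mean([r in models[m] for m in members[gb]]) for r in all_rxns]
    out = pd.DataFrame(
        {f"freq_{ga}": fa, f"freq_{gb}": fb}, index=all_rxns
    )
    out["diff"] = out[f"freq_{ga}"] - out[f"freq_{gb}"]
    return out.reindex(out["diff"].abs().sort_values(ascending=False).index)


def hypergeometric_pvalue(population: int, successes: int, draws: int, observed: int) -> float:
    """Upper-tail hypergeometric probability P[X >= observed]."""
    if observed <= 0:
        return 1.0
    return float(stats.hypergeom.sf(observed - 1, population, successes, draws))


def fisher_combine(pvalues) -> float:
    """Fisher's method: -2 sum(ln p) ~ chi2 with 2k degrees of freedom."""
    ps = [p for p in pvalues if p is not None and not math.isnan(p)]
    if not ps:
        return float("nan")
    statistic = -2.0 * sum(math.log(max(p, 1e-300)) for p in ps)
    return float(stats.chi2.sf(statistic, 2 * len(ps)))


def cross_validation_enrichment(
    model: MetabolicModel,
    groups: ReactionGroups,
    params: CordaParams | None = None,
    holdout: float = 0.2,
    reps: int = 10,
    rng: np.random.Generator | None = None,
    settings: LPSettings | None = None,
) -> dict[str, float]:
    """Enrichment of held-out core reactions among the rebuilt models.

    Each repetition keeps a random (1 - holdout) share of every core
    group (HC, MC, NC), demotes the held-out reactions to OT, rebuilds,
    and scores each group with an upper-tail hypergeometric p-value on
    (pool size, held-out of the group, pool members included, held-out
    included).  Per-group p-values across repetitions are combined with
    Fisher's method.  A group empty after subsampling contributes NaN for
    that repetition.
    """
    params = params or CordaParams()
    if not (0 < holdout < 1) or reps < 1:
        raise ValueError("need 0 < holdout < 1 and reps >= 1")
    rng = rng or np.random.default_rng(params.seed)
    per_group: dict[str, list[float]] = {"HC": [], "MC": [], "NC": []}
    originals = {"HC": groups.hc, "MC": groups.mc, "NC": groups.nc}
    for _rep in range(reps):
        retained: dict[str, set[str]] = {}
        held: dict[str, set[str]] = {}
        for g, ids in originals.items():
            ids = sorted(ids)
            n_keep = int(round((1 - holdout) * len(ids)))
            keep = set(rng.choice(ids, size=n_keep, replace=False)) if ids else set()
            retained[g] = keep
            held[g] = set(ids) - keep
        sub = ReactionGroups(
            hc=retained["HC"],
            mc=retained["MC"],
            nc=retained["NC"],
            ot=groups.ot | held["HC"] | held["MC"] | held["NC"],
            tasks=list(groups.tasks),
        )
        result = corda_build(model, sub, params, settings)
        pool = sub.ot
        included_pool = result.re & pool
        for g in per_group:
            if not held[g]:
                per_group[g].append(float("nan"))
                continue
            observed = len(held[g] & result.re)
            per_group[g].append(
                hypergeometric_pvalue(
                    len(pool), len(held[g]), len(included_pool), observed
                )
            )
    return {g: fisher_combine(ps) for g, ps in per_group.items()}


def combined_flux_distribution(samples: SampleSet, rxn_ids) -> np.ndarray:
    """Element-wise sum of the named reaction columns across sample points."""
    missing = [r for r in rxn_ids if r not in samples.reaction_ids]
    if missing:
        raise ModelError(f"reactions not in sample set: {missing}")
    cols = [samples.reaction_ids.index(r) for r in rxn_ids]
    return samples.points[:, cols].sum(axis=1)
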