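"""Metabolic network container, readers/writers and structural edits.

The in-memory representation is deliberately minimal: an ordered list of
metabolites (rows), an ordered list of reactions (columns), each reaction
holding a sparse stoichiometry map, flux bounds, a gene-protein-reaction
(GPR) boolean rule string and a subsystem label.  The stoichiometric matrix
``S`` is materialised on demand.

Two compartment-suffix dialects are accepted for metabolite ids,
``h2o[e]`` (bracketed) and ``h2o_e`` (underscore); ids are kept verbatim
and the compartment is parsed out for classification purposes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "SplitMapping",
    "parse_compartment",
    "read_model",
    "write_model",
    "split_reversible",
    "block_reactions",
    "subset_model",
    "classify_reaction",
]

DEFAULT_BOUND = 1000.0

_BRACKET_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[^\[\]]+)\]$")
_UNDERSCORE_RE = re.compile(r"^(?P<base>.+)_(?P<comp>[a-zA-Z][a-zA-Z0-9]?)$")


def parse_compartment(met_id: str) -> tuple[str, str]:
    """Split a metabolite id into (base, compartment).

    Accepts ``glc[c]`` and ``glc_c``; an id with neither suffix is placed
    in the default compartment ``c``.
    """
    m = _BRACKET_RE.match(met_id)
    if m:
        return m.group("base"), m.group("comp")
    m = _UNDERSCORE_RE.match(met_id)
    if m:
        return m.group("base"), m.group("comp")
    return met_id, "c"


@dataclass
class Metabolite:
    id: str
    compartment: str = ""
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.compartment:
            self.compartment = parse_compartment(self.id)[1]

    @property
    def base_id(self) -> str:
        return parse_compartment(self.id)[0]


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lb: float = 0.0
    ub: float = DEFAULT_BOUND
    gpr: str = ""
    subsystem: str = ""

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ValueError(
                f"reaction {self.id!r}: lb={self.lb} exceeds ub={self.ub}"
            )
        for met, coef in self.stoich.items():
            if not np.isfinite(coef) or coef == 0:
                raise ValueError(
                    f"reaction {self.id!r}: bad coefficient {coef} for {met!r}"
                )

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    def copy(self) -> "Reaction":
        return replace(self, stoich=dict(self.stoich))


class ModelError(Exception):
    """Structural problem in a model or a failed id lookup."""


class MetabolicModel:
    """Ordered metabolite/reaction collection with a derived S matrix."""

    def __init__(
        self,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        id: str = "model",
    ):
        self.id = id
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self._check()

    def _check(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelError("duplicate reaction ids")
        known = set(met_ids)
        for r in self.reactions:
            for met in r.stoich:
                if met not in known:
                    raise ModelError(
                        f"reaction {r.id!r} references undeclared metabolite {met!r}"
                    )

    # -- indexing ---------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise ModelError(f"unknown reaction id {rxn_id!r}")

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise ModelError(f"unknown metabolite id {met_id!r}")

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    def has_metabolite(self, met_id: str) -> bool:
        return any(m.id == met_id for m in self.metabolites)

    # -- matrix view ------------------------------------------------------

    @property
    def S(self) -> sparse.csc_matrix:
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoich.items():
                rows.append(met_index[met])
                cols.append(j)
                vals.append(coef)
        return sparse.csc_matrix(
            (vals, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)),
        )

    @property
    def lb(self) -> np.ndarray:
        return np.array([r.lb for r in self.reactions], dtype=float)

    @property
    def ub(self) -> np.ndarray:
        return np.array([r.ub for r in self.reactions], dtype=float)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            [replace(m) for m in self.metabolites],
            [r.copy() for r in self.reactions],
            id=self.id,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        if self.metabolite_ids != other.metabolite_ids:
            return False
        if len(self.reactions) != len(other.reactions):
            return False
        for a, b in zip(self.reactions, other.reactions):
            if (a.id, a.lb, a.ub, a.gpr, a.subsystem) != (
                b.id,
                b.lb,
                b.ub,
                b.gpr,
                b.subsystem,
            ):
                return False
            if a.stoich != b.stoich:
                return False
        return True

    def __repr__(self) -> str:
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


@dataclass
class SplitMapping:
    """Forward/backward column ids for each split reversible reaction.

    ``pairs`` maps an original reaction id to its (forward, backward)
    column ids in the split model; untouched reactions are absent and map
    to themselves.
    """

    pairs: dict[str, tuple[str, str]] = field(default_factory=dict)

    def net_flux(self, split_values: dict[str, float]) -> dict[str, float]:
        """Reconstruct net fluxes on the original reaction set."""
        net: dict[str, float] = {}
        backward_ids = {b for _, b in self.pairs.values()}
        for rid, v in split_values.items():
            if rid in backward_ids:
                continue
            if rid in self.pairs:
                fwd, bwd = self.pairs[rid]
                net[rid] = split_values.get(fwd, 0.0) - split_values.get(bwd, 0.0)
            else:
                net[rid] = v
        return net


# ---------------------------------------------------------------------------
# readers / writers


def _from_cobra(cmodel) -> MetabolicModel:
    mets = [
        Metabolite(m.id, compartment=m.compartment or "", name=m.name or None)
        for m in cmodel.metabolites
    ]
    rxns = []
    for r in cmodel.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        rxns.append(
            Reaction(
                r.id,
                stoich,
                lb=float(r.lower_bound),
                ub=float(r.upper_bound),
                gpr=r.gene_reaction_rule or "",
                subsystem=r.subsystem or "",
            )
        )
    return MetabolicModel(mets, rxns, id=cmodel.id or "model")


def _to_cobra(model: MetabolicModel):
    import cobra

    cmodel = cobra.Model(model.id)
    cmets = {}
    for m in model.metabolites:
        cm = cobra.Metabolite(m.id, name=m.name or m.id, compartment=m.compartment)
        cmets[m.id] = cm
    cmodel.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
        cr.subsystem = r.subsystem
        crxns.append(cr)
    cmodel.add_reactions(crxns)
    for r in model.reactions:
        cr = cmodel.reactions.get_by_id(r.id)
        cr.add_metabolites({cmets[k]: v for k, v in r.stoich.items()})
        if r.gpr:
            cr.gene_reaction_rule = r.gpr
    return cmodel


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt:
        return fmt
    p = str(path).lower()
    if p.endswith(".json"):
        return "json"
    if p.endswith((".xml", ".sbml")):
        return "sbml"
    raise ValueError(f"cannot infer model format from {path!r}; pass format=")


def read_model(path: str, format: str | None = None) -> MetabolicModel:
    """Read a model from COBRA-style JSON or SBML Level 3 + FBC."""
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path) as fh:
            doc = json.load(fh)
        return model_from_dict(doc)
    if fmt == "sbml":
        import cobra.io

        try:
            cmodel = cobra.io.read_sbml_model(path)
        except Exception as exc:  # cobra raises several types here
            raise ModelError(f"failed to parse SBML file {path!r}: {exc}") from exc
        return _from_cobra(cmodel)
    raise ValueError(f"unsupported model format {fmt!r}")


def write_model(model: MetabolicModel, path: str, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1)
    elif fmt == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(_to_cobra(model), path)
    else:
        raise ValueError(f"unsupported model format {fmt!r}")


def model_to_dict(model: MetabolicModel) -> dict:
    """COBRA JSON dialect (readable by cobrapy)."""
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name or m.id, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.id,
                "metabolites": dict(r.stoich),
                "lower_bound": r.lb,
                "upper_bound": r.ub,
                "gene_reaction_rule": r.gpr,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "genes": [],
        "compartments": sorted({m.compartment for m in model.metabolites}),
        "version": "1",
    }


def model_from_dict(doc: dict) -> MetabolicModel:
    try:
        mets = [
            Metabolite(
                d["id"],
                compartment=d.get("compartment", ""),
                name=d.get("name"),
            )
            for d in doc["metabolites"]
        ]
        rxns = [
            Reaction(
                d["id"],
                {k: float(v) for k, v in d["metabolites"].items()},
                lb=float(d.get("lower_bound", 0.0)),
                ub=float(d.get("upper_bound", DEFAULT_BOUND)),
                gpr=d.get("gene_reaction_rule", ""),
                subsystem=d.get("subsystem", "") or "",
            )
            for d in doc["reactions"]
        ]
    except KeyError as exc:
        raise ModelError(f"malformed model document: missing key {exc}") from exc
    return MetabolicModel(mets, rxns, id=doc.get("id", "model"))


# ---------------------------------------------------------------------------
# structural edits (all return new models; inputs are never mutated)


def split_reversible(
    model: MetabolicModel, exempt: str | None = None
) -> tuple[MetabolicModel, SplitMapping]:
    """Split every reversible reaction into a forward/backward pair.

    A reaction with ``lb < 0`` keeps its forward column (lb reset to 0) and
    gains a mirrored column with negated stoichiometry and bounds
    ``[0, -lb]``.  ``exempt`` names one reaction to leave untouched (the
    reaction under test in a dependency assessment keeps its signed flux).
    """
    if exempt is not None and not model.has_reaction(exempt):
        raise ModelError(f"unknown exempt reaction {exempt!r}")
    mapping = SplitMapping()
    new_rxns: list[Reaction] = []
    appended: list[Reaction] = []
    for r in model.reactions:
        if r.id != exempt and r.lb < 0:
            fwd = r.copy()
            fwd.lb = 0.0
            bwd = Reaction(
                r.id + "__rev",
                {k: -v for k, v in r.stoich.items()},
                lb=0.0,
                ub=-r.lb,
                gpr=r.gpr,
                subsystem=r.subsystem,
            )
            mapping.pairs[r.id] = (r.id, bwd.id)
            new_rxns.append(fwd)
            appended.append(bwd)
        else:
            new_rxns.append(r.copy())
    split = MetabolicModel(
        [replace(m) for m in model.metabolites], new_rxns + appended, id=model.id
    )
    return split, mapping


def block_reactions(model: MetabolicModel, ids) -> MetabolicModel:
    """Return a copy with lb = ub = 0 for every named reaction."""
    ids = set(ids)
    unknown = ids - set(model.reaction_ids)
    if unknown:
        raise ModelError(f"unknown reaction ids {sorted(unknown)}")
    out = model.copy()
    for r in out.reactions:
        if r.id in ids:
            r.lb = 0.0
            r.ub = 0.0
    return out


def subset_model(model: MetabolicModel, keep) -> MetabolicModel:
    """Restrict the model to the kept reactions and their metabolites."""
    keep = set(keep)
    unknown = keep - set(model.reaction_ids)
    if unknown:
        raise ModelError(f"unknown reaction ids {sorted(unknown)}")
    rxns = [r.copy() for r in model.reactions if r.id in keep]
    used = {met for r in rxns for met in r.stoich}
    mets = [replace(m) for m in model.metabolites if m.id in used]
    return MetabolicModel(mets, rxns, id=model.id)


def classify_reaction(model: MetabolicModel, rxn_id: str) -> str:
    """Classify a reaction as ``exchange``, ``transport`` or ``internal``.

    A single-metabolite stoichiometry marks a system boundary (exchange);
    a reaction moving one base metabolite between compartments is a
    transport; everything else is internal.
    """
    r = model.reaction(rxn_id)
    if len(r.stoich) == 1:
        return "exchange"
    by_base: dict[str, set[str]] = {}
    for met in r.stoich:
        base, comp = parse_compartment(met)
        by_base.setdefault(base, set()).add(comp)
    if any(len(comps) >= 2 for comps in by_base.values()):
        return "transport"
    return "internal"
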