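"""Protein-evidence scoring of reactions through GPR boolean rules.

Evidence comes in two modes.  *Healthy* tables give each gene one
categorical level (Not Detected / Low / Medium / High) which maps to the
weights -1 / 1 / 2 / 3.  *Cancer* tables give per-level sample counts and
the gene score is the sample-weighted average of the same weights.  Genes
absent from the table score 0.

A reaction score is obtained by evaluating its gene-protein-reaction
(GPR) boolean rule with AND replaced by MIN and OR by MAX over the gene
scores, and reactions are then partitioned into confidence groups:

healthy:  HC = {3},  MC = {1, 2},  NC = {-1},  else OT
cancer:   HC iff score >= 2.5,  MC iff 1 < score < 2.5,
          NC iff score <= -0.5,  else OT
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import MetabolicModel

__all__ = [
    "LEVEL_WEIGHTS",
    "EvidenceTable",
    "ScoringScheme",
    "ConfidenceAssignment",
    "gene_score",
    "parse_gpr",
    "evaluate_gpr",
    "assign_confidence",
    "read_evidence_table",
    "write_confidence_table",
    "GPRParseError",
]

LEVEL_WEIGHTS = {"High": 3.0, "Medium": 2.0, "Low": 1.0, "NotDetected": -1.0}

_LEVEL_ALIASES = {
    "high": "High",
    "medium": "Medium",
    "low": "Low",
    "notdetected": "NotDetected",
    "not detected": "NotDetected",
    "not_detected": "NotDetected",
    "nd": "NotDetected",
}


@dataclass
class EvidenceTable:
    """Gene-level protein evidence, healthy or cancer mode."""

    mode: str  # healthy | cancer
    healthy: dict[str, str] = field(default_factory=dict)
    cancer: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)
    # cancer counts ordered (n_high, n_medium, n_low, n_notdetected)

    def __post_init__(self) -> None:
        if self.mode not in ("healthy", "cancer"):
            raise ValueError(f"bad evidence mode {self.mode!r}")
        for g, lvl in self.healthy.items():
            key = _LEVEL_ALIASES.get(str(lvl).strip().lower())
            if key is None:
                raise ValueError(f"gene {g!r}: unknown level {lvl!r}")
            self.healthy[g] = key
        for g, counts in self.cancer.items():
            if len(counts) != 4 or any(c < 0 for c in counts):
                raise ValueError(f"gene {g!r}: bad sample counts {counts}")
            if sum(counts) < 1:
                raise ValueError(f"gene {g!r}: zero total samples")


@dataclass(frozen=True)
class ScoringScheme:
    """Level weights and group thresholds; defaults are the standard scheme."""

    weights: tuple = tuple(sorted(LEVEL_WEIGHTS.items()))
    hc_min_cancer: float = 2.5
    mc_min_cancer: float = 1.0  # strict lower bound
    nc_max_cancer: float = -0.5

    def weight(self, level: str) -> float:
        return dict(self.weights)[level]

    def group_healthy(self, score: float) -> str:
        if score == 3:
            return "HC"
        if score in (1, 2):
            return "MC"
        if score == -1:
            return "NC"
        return "OT"

    def group_cancer(self, score: float) -> str:
        if score >= self.hc_min_cancer:
            return "HC"
        if self.mc_min_cancer < score < self.hc_min_cancer:
            return "MC"
        if score <= self.nc_max_cancer:
            return "NC"
        return "OT"

    def group(self, score: float, mode: str) -> str:
        return self.group_healthy(score) if mode == "healthy" else self.group_cancer(score)


@dataclass
class ConfidenceAssignment:
    group: dict[str, str]
    score: dict[str, float]

    def members(self, grp: str) -> set[str]:
        return {r for r, g in self.group.items() if g == grp}


def gene_score(
    gene: str, evidence: EvidenceTable, scheme: ScoringScheme | None = None
) -> float:
    """Numeric score of one gene; 0 when the gene is not in the table.

    Healthy mode returns the level weight.  Cancer mode returns the
    sample-count weighted average
    (3*n_high + 2*n_medium + 1*n_low - n_notdetected) / total, unrounded.
    """
    scheme = scheme or ScoringScheme()
    if evidence.mode == "healthy":
        lvl = evidence.healthy.get(gene)
        return scheme.weight(lvl) if lvl is not None else 0.0
    counts = evidence.cancer.get(gene)
    if counts is None:
        return 0.0
    n_high, n_med, n_low, n_nd = counts
    total = n_high + n_med + n_low + n_nd
    if total == 0:
        raise ValueError(f"gene {gene!r}: zero total samples")
    return (3.0 * n_high + 2.0 * n_med + 1.0 * n_low - 1.0 * n_nd) / total


# ---------------------------------------------------------------------------
# GPR rule grammar:  expr := term (OR term)* ; term := factor (AND factor)* ;
# factor := GENE | '(' expr ')'.  AND binds tighter than OR.


class GPRParseError(ValueError):
    pass


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(rule: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(rule)]


class _Parser:
    def __init__(self, rule: str):
        self.rule = rule
        self.tokens = _tokenize(rule)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def fail(self, msg: str):
        at = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.rule)
        raise GPRParseError(f"{msg} at position {at} in {self.rule!r}")

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            self.fail(f"unexpected token {self.peek()!r}")
        return node

    def expr(self):
        terms = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def term(self):
        factors = [self.factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def factor(self):
        tok = self.peek()
        if tok is None:
            self.fail("unexpected end of rule")
        if tok == "(":
            self.next()
            node = self.expr()
            if self.peek() != ")":
                self.fail("unbalanced parentheses: expected ')'")
            self.next()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            self.fail(f"unexpected token {tok!r}")
        self.next()
        return ("gene", tok.strip())


def parse_gpr(rule: str):
    """Parse a GPR rule into an ('and'|'or', children) / ('gene', id) tree."""
    if not rule or not rule.strip():
        return None
    return _Parser(rule).parse()


def _eval_node(node, scores: dict[str, float]) -> float:
    kind = node[0]
    if kind == "gene":
        return scores.get(node[1], 0.0)
    vals = [_eval_node(child, scores) for child in node[1]]
    return min(vals) if kind == "and" else max(vals)


def evaluate_gpr(rule: str, gene_scores: dict[str, float]) -> float:
    """MIN/MAX evaluation of a GPR rule; empty rule scores 0."""
    tree = parse_gpr(rule)
    if tree is None:
        return 0.0
    return _eval_node(tree, gene_scores)


def assign_confidence(
    model: MetabolicModel,
    evidence: EvidenceTable,
    scheme: ScoringScheme | None = None,
) -> ConfidenceAssignment:
    """Score every reaction through its GPR and partition into HC/MC/NC/OT."""
    scheme = scheme or ScoringScheme()
    genes = set()
    for r in model.reactions:
        tree = _try_parse(r)
        genes |= _genes_in(tree)
    scores = {g: gene_score(g, evidence, scheme) for g in genes}
    group: dict[str, str] = {}
    score: dict[str, float] = {}
    for r in model.reactions:
        s = evaluate_gpr(r.gpr, scores) if r.gpr.strip() else 0.0
        score[r.id] = s
        group[r.id] = scheme.group(s, evidence.mode) if r.gpr.strip() else "OT"
    return ConfidenceAssignment(group, score)


def _try_parse(reaction):
    try:
        return parse_gpr(reaction.gpr)
    except GPRParseError as exc:
        raise GPRParseError(f"reaction {reaction.id!r}: {exc}") from exc


def _genes_in(node) -> set[str]:
    if node is None:
        return set()
    if node[0] == "gene":
        return {node[1]}
    out: set[str] = set()
    for child in node[1]:
        out |= _genes_in(child)
    return out


# ---------------------------------------------------------------------------
# delimited-text interfaces


def read_evidence_table(path: str, mode: str) -> EvidenceTable:
    """Read a TSV evidence table.

    healthy: two columns (gene, level); cancer: five columns
    (gene, n_high, n_medium, n_low, n_notdetected).  A header line whose
    first field is 'gene' is skipped.
    """
    healthy: dict[str, str] = {}
    cancer: dict[str, tuple[int, int, int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if parts[0].lower() == "gene":
                continue
            if mode == "healthy":
                if len(parts) != 2:
                    raise ValueError(f"bad healthy evidence row: {line!r}")
                healthy[parts[0]] = parts[1]
            else:
                if len(parts) != 5:
                    raise ValueError(f"bad cancer evidence row: {line!r}")
                cancer[parts[0]] = tuple(int(x) for x in parts[1:])
    return EvidenceTable(mode=mode, healthy=healthy, cancer=cancer)


def write_confidence_table(assignment: ConfidenceAssignment, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("reaction\tscore\tgroup\n")
        for rid in sorted(assignment.group):
            fh.write(f"{rid}\t{assignment.score[rid]:.6g}\t{assignment.group[rid]}\n")
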