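# Methods

## Model representation

A model is an ordered metabolite list (rows) and reaction list (columns);
each reaction stores a sparse stoichiometry map, bounds, a GPR string and a
subsystem label. The stoichiometric matrix is materialised on demand (the
sampler is the only consumer of dense arrays). Both compartment-suffix
dialects, `met[c]` and `met_c`, are accepted; ids are kept verbatim and
compartments parsed for classification. A reaction is an *exchange* iff its
stoichiometry names exactly one metabolite; it is a *transport* iff it
moves one base metabolite between two or more compartments. This
single-metabolite boundary heuristic is a design choice — it matches the
common convention for human reconstructions without relying on SBML
annotations. SBML Level 3 + FBC I/O is delegated to cobrapy; the
COBRA-style JSON dialect is read and written directly and is
schema-compatible with cobrapy. Default bounds when a file omits them are
±1000 (reversible) or [0, 1000].

## The LP core

Every optimisation in the package is the one FBA contract: optimise c·v
over {v : S·v = 0, lb ≤ v ≤ ub}. The backend is the HiGHS solver through
scipy; its simplex path returns vertex solutions, which the sampler's
warmup generation relies on. Feasibility and optimality tolerances default
to 1e-9. Solver status is propagated verbatim (`optimal` / `infeasible` /
`unbounded`); any other backend condition raises.

## Dependency assessment

Parameters (defaults are the reference configuration): γ = 1e5 cost of
undesirable reactions, κ = 1e-2 noise magnitude, ε = 1 forced flux, n = 5
repeats, p = 2 NC-inclusion threshold. Two implementation parameters are
added:

* **τ (association tolerance), default 1e-6·ε.** The mathematical rule is
  "v_i ≠ 0"; a floating-point LP needs a cutoff. τ is configurable.
* **γ_MC (step-1 MC cost), default γ/100.** Step 1 penalises both MC and NC
  reactions while the intent is to favour MC inclusion over NC; with equal
  costs the preference cannot be expressed, so MC carries a separate,
  lower cost. Setting `gamma_mc = gamma` recovers the equal-cost variant.

Noise κ̈ for column *c* of repeat *k* of a query on reaction *j* is drawn
from a generator seeded by the tuple (seed, crc32(j), direction, k,
crc32(c)). Keying by column *id* (the split backward column has its own id)
rather than position makes every result invariant both to the order in
which queries are issued and to the ordering of reactions inside the model
— order-independence holds exactly, not just statistically.

Forcing the tested flux uses `lb_j = max(lb_j, ε)` (forward) or
`ub_j = min(ub_j, −ε)` (backward); a reaction whose bounds exclude the
forced flux is reported as an infeasible query with no associations, not an
error, since generic models contain blocked reactions. Reversible tested
reactions are assessed in both feasible directions and the associations
unioned when no direction is specified.

## The builder

Step semantics are *batch*: all queries of a step run against the state at
the step's start, and admissions take effect between steps. This is what
makes the result independent of iteration order. Task sinks (one reaction
consuming one metabolite, forced positive while tested) are added singly
and removed immediately; they are queried in steps 1 and 3 like HC members
but never appear in the final model. The step-2 capability check runs with
the not-admitted NC blocked and uses the same ε as the dependency
assessment, in either direction. The curation ledger records, per admitted
reaction, the seed reactions and step that brought it in; an MC reaction
admitted by the step-2 capability check is recorded as supported by itself.
Excluded MC reactions are reported with the NC reactions they were
associated with. No post-hoc pruning is applied to the final model; HC
reactions that can never carry flux in the source model simply remain (the
extraction honours the non-flexible core).

## Task battery

The basal environment opens the nine basal inputs (CO2, water, protons,
O2, phosphate, H2O2, superoxide, bicarbonate, CO) in both directions and
closes the *uptake* direction of every other exchange, leaving export open.
"Uptake set to an arbitrary value" is implemented as *allowing* uptake up
to the value (default 1 flux unit) rather than forcing it; feasibility
questions are scale-invariant and unaffected, while a forced uptake could
spuriously fail a model that cannot dissipate the substrate. Strictly
positive production forcing uses the global ε. Recycling and glucogenic
tests report `inconsistent` when a required exchange is missing; nucleotide
tests need no exchange (the sink is temporary) and report only
passed/failed. All task runners operate on copies; the input model compares
equal before and after.

Metabolite knockout blocks, for each reaction touching the metabolite, the
consuming forward direction (negative coefficient) together with its
reverse-producing direction, and the backward direction of producers
(positive coefficient) — so after knockout the metabolite can still be
produced forward but never consumed. The only bound "relaxation" is the
degenerate clamp of an already-forced reaction (lb > 0 consumer) to [0, 0].
A metabolite is essential when at least one task that passed on the intact
model fails after knockout.

## ACHR sampler

Warmup points are vertices obtained by maximising random ±1 objectives
(default count min(2n, 5000): both signs per axis). A move picks a point,
takes the direction to a randomly chosen point minus the cloud centre,
computes the feasible step interval from the bounds alone (directions
between feasible points lie in the null space of S, so mass balance needs
no projection) and jumps uniformly. The mixed fraction uses per-reaction
medians of the phase-start points — a single global median is ill-defined
for vector-valued chains — averaged into one scalar over all
(point, reaction) pairs still on their starting side; zero-width dimensions
(lb = ub) can never cross and are excluded to avoid biasing the statistic
upward. Convergence is checked once per sweep over all points (default).
Sampling runs three phases to the same threshold (default 0.52), the later
phases restarting the median bookkeeping from the previous phase's final
points. A fixed-point polytope returns immediately; a threshold of 1.0 is
vacuously satisfied at phase start.

## Analysis utilities

Presence matrices keep only reactions present in at least one but not all
models. Subsystem fractions divide the category's mean per-subsystem
inclusion count by the subsystem's inclusion count across all models.
Confidence composition bins scores to the nearest canonical evidence level
(≤ −0.5 Not Detected, [0.5, 1.5) Low, [1.5, 2.5) Medium, ≥ 2.5 High, else
no evidence) so healthy integer scores map exactly and tumour-mode
continuous scores bin consistently. Cross-validation retains a random
(1 − holdout) share of each core group, demotes held-out reactions to OT
(they stay in the model — only their group membership changes), rebuilds,
and scores each group with an upper-tail hypergeometric p-value (observed
count included in the tail) over the OT pool; repetition p-values combine
with Fisher's method (−2·Σ ln p ~ χ² with 2k df). Hierarchical clustering
itself is left to standard routines; this package computes exactly its
input matrices.

## Fixtures and oracles

The fixture module plants small networks (≤ ~30 reactions) whose expected
behaviour is computed by exhaustive enumeration, never hand-asserted: the
brute-force oracle enumerates subsets of the penalised set Y, blocks each
complement, and minimises the summed Y flux under the forced test flux
(matching the method's minimal-combined-flux semantics, not minimal
cardinality). Enumerating subsets of Y rather than of all reactions is
equivalent for the minimal supports — blocking a non-Y reaction only
shrinks the feasible set — and keeps the oracle at 2^|Y| LPs. Synthetic
evidence draws uniform healthy levels or multinomial tumour sample counts
(8–15 samples per gene, Dirichlet level weights) from a seeded generator.

What the fixtures emulate: planted dependency structure, flexible-core
admit/exclude splits at the threshold, detoxification-style route choices,
and task pass/fail/inconsistent triples. What they do not emulate:
Recon-scale network size, realistic GPR complexity, mass-imbalanced
legacy reactions, or proteome-wide evidence tables — passing tests
demonstrate algorithmic correctness at desk scale, not biological fidelity
of any particular reconstruction.

## Problem sizes and numerical choices

Test fixtures stay below ~30 reactions so the exhaustive oracles run in
seconds; the sampler's acceptance-level check uses a 4-reaction box
polytope with 60 points, where closed-form centroids exist. LP degeneracy
between equal-cost pathways is resolved by the κ noise exactly as the
algorithm intends; ε = 1 with τ = 1e-6 keeps forced fluxes far above both
solver tolerances. Degenerate ACHR directions (below 1e-10) are resampled
with a bounded retry count, and a step whose feasible interval collapses
returns the point unmoved.

## Known limitations

* One LP backend (HiGHS via scipy) is wired in; the settings object keeps
  a backend key for extension.
* The healthy-mode grouping is defined on exact integer scores, so GPR
  rules mixing evidence levels always produce one of {−1, 0, 1, 2, 3};
  tumour-mode thresholds leave scores in (−0.5, 1] ungrouped by design —
  they fall to OT as the only consistent remainder.
* Very small ε interacts with τ and solver tolerances; the defaults keep
  ε = 1 and τ six orders of magnitude below it.
* No flux-variability analysis, MILP reformulation, gap-filling or
  loopless sampling; these are outside the method's scope.
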