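"""Metabolic-task battery, knockout semantics and essentiality."""

import pytest

from cordaflux.model import MetabolicModel, Metabolite, ModelError, Reaction, block_reactions
from cordaflux.tasks import (
    BASAL_INPUTS,
    TaskEnvironment,
    TaskSpec,
    apply_basal_environment,
    is_essential_metabolite,
    knockout_metabolite,
    run_glucogenic_test,
    run_nucleotide_test,
    run_recycling_test,
    run_task,
)


def urea_toy():
    """Amino acid imported, nitrogen transferred to a urea analog."""
    mets = [
        Metabolite(m)
        for m in ("aa[e]", "aa[c]", "urea[c]", "urea[e]", "glc_D[e]", "o2[e]")
    ]
    rxns = [
        Reaction("EX_aa", {"aa[e]": -1.0}, -10.0, 10.0),
        Reaction("T_aa", {"aa[e]": -1.0, "aa[c]": 1.0}, 0.0, 10.0),
        Reaction("R_deam", {"aa[c]": -1.0, "urea[c]": 1.0}, 0.0, 10.0),
        Reaction("T_urea", {"urea[c]": -1.0, "urea[e]": 1.0}, 0.0, 10.0),
        Reaction("EX_urea", {"urea[e]": -1.0}, 0.0, 10.0),
        Reaction("EX_glc", {"glc_D[e]": -1.0}, -10.0, 10.0),
        Reaction("EX_o2", {"o2[e]": -1.0}, -10.0, 10.0),
    ]
    return MetabolicModel(mets, rxns, id="urea_toy")


def gluco_toy():
    """Substrate convertible to glucose, exportable."""
    mets = [Metabolite(m) for m in ("sub[e]", "sub[c]", "glc_D[c]", "glc_D[e]")]
    rxns = [
        Reaction("EX_sub", {"sub[e]": -1.0}, -10.0, 10.0),
        Reaction("T_sub", {"sub[e]": -1.0, "sub[c]": 1.0}, 0.0, 10.0),
        Reaction("R_g", {"sub[c]": -1.0, "glc_D[c]": 1.0}, 0.0, 10.0),
        Reaction("T_glc", {"glc_D[c]": -1.0, "glc_D[e]": 1.0}, 0.0, 10.0),
        Reaction("EX_glc", {"glc_D[e]": -1.0}, -10.0, 10.0),
    ]
    return MetabolicModel(mets, rxns, id="gluco_toy")


def nucleotide_toy():
    """Nucleotide N built from glucose-derived carbon and ammonium."""
    mets = [
        Metabolite(m)
        for m in ("glc_D[e]", "glc_D[c]", "nh4[e]", "nh4[c]", "N[c]")
    ]
    rxns = [
        Reaction("EX_glc", {"glc_D[e]": -1.0}, -10.0, 10.0),
        Reaction("T_glc", {"glc_D[e]": -1.0, "glc_D[c]": 1.0}, 0.0, 10.0),
        Reaction("EX_nh4", {"nh4[e]": -1.0}, -10.0, 10.0),
        Reaction("T_nh4", {"nh4[e]": -1.0, "nh4[c]": 1.0}, 0.0, 10.0),
        Reaction("R_N", {"glc_D[c]": -1.0, "nh4[c]": -1.0, "N[c]": 1.0}, 0.0, 10.0),
    ]
    return MetabolicModel(mets, rxns, id="nt_toy")


class TestBasalEnvironment:
    def test_basal_open_others_uptake_blocked(self):
        mets = [Metabolite("o2[e]"), Metabolite("glc_D[e]")]
        rxns = [
            Reaction("EX_o2", {"o2[e]": -1.0}, -10.0, 10.0),
            Reaction("EX_glc", {"glc_D[e]": -1.0}, -10.0, 10.0),
        ]
        model = MetabolicModel(mets, rxns)
        out = apply_basal_environment(model)
        assert out.reaction("EX_o2").lb == -1000.0
        assert out.reaction("EX_glc").lb == 0.0  # uptake closed
        assert out.reaction("EX_glc").ub == 10.0  # export still open

    def test_no_exchanges_unchanged(self, chain3):
        # the chain's boundary reactions are its in/out columns, which do
        # not match any basal metabolite: only uptake closure can apply
        out = apply_basal_environment(chain3)
        assert out.reaction("R1").lb == chain3.reaction("R1").lb

    def test_basal_list_content(self):
        assert "h2o[e]" in BASAL_INPUTS and len(BASAL_INPUTS) == 9

    def test_demand_needing_glucose_fails_under_basal(self):
        model = gluco_toy()
        basal = apply_basal_environment(model)
        from cordaflux.lp import solve_fba

        probe = basal.copy()
        probe.reaction("EX_glc").lb = 1.0  # force export with no uptake
        assert solve_fba(probe, "EX_glc", "maximize").status == "infeasible"


class TestRecyclingTest:
    def test_intact_route_passes(self):
        res = run_recycling_test(urea_toy(), "aa[e]")
        assert res.outcome == "passed" and res.objective > 0

    def test_cut_route_fails(self):
        model = block_reactions(urea_toy(), {"R_deam"})
        assert run_recycling_test(model, "aa[e]").outcome == "failed"

    def test_missing_amino_acid_exchange_inconsistent(self):
        model = urea_toy()
        model = MetabolicModel(
            list(model.metabolites),
            [r.copy() for r in model.reactions if r.id != "EX_aa"],
        )
        assert run_recycling_test(model, "aa[e]").outcome == "inconsistent"

    def test_missing_urea_exchange_inconsistent(self):
        model = urea_toy()
        model = MetabolicModel(
            list(model.metabolites),
            [r.copy() for r in model.reactions if r.id != "EX_urea"],
        )
        assert run_recycling_test(model, "aa[e]").outcome == "inconsistent"

    def test_model_unchanged_after_test(self):
        model = urea_toy()
        before = model.copy()
        run_recycling_test(model, "aa[e]")
        assert model == before


class TestGlucogenicTest:
    def test_pass_fail_inconsistent_triple(self):
        model = gluco_toy()
        assert run_glucogenic_test(model, "sub[e]").outcome == "passed"
        cut = block_reactions(model, {"R_g"})
        assert run_glucogenic_test(cut, "sub[e]").outcome == "failed"
        missing = MetabolicModel(
            list(model.metabolites),
            [r.copy() for r in model.reactions if r.id != "EX_sub"],
        )
        assert run_glucogenic_test(missing, "sub[e]").outcome == "inconsistent"


class TestNucleotideTest:
    def test_intact_passes_cut_fails(self):
        model = nucleotide_toy()
        assert run_nucleotide_test(model, "N[c]").outcome == "passed"
        cut = block_reactions(model, {"R_N"})
        assert run_nucleotide_test(cut, "N[c]").outcome == "failed"

    def test_model_unchanged_after_sink(self):
        model = nucleotide_toy()
        before = model.copy()
        run_nucleotide_test(model, "N[c]")
        assert model == before

    def test_absent_metabolite_fails_not_errors(self):
        res = run_nucleotide_test(nucleotide_toy(), "ghost[c]")
        assert res.outcome == "failed"


class TestKnockoutMetabolite:
    def test_irreversible_consumer_forward_blocked(self):
        mets = [Metabolite("A[c]"), Metabolite("B[c]")]
        model = MetabolicModel(
            mets, [Reaction("R", {"A[c]": -1.0, "B[c]": 1.0}, 0.0, 10.0)]
        )
        ko = knockout_metabolite(model, "A[c]")
        assert (ko.reaction("R").lb, ko.reaction("R").ub) == (0.0, 0.0)

    def test_reversible_consumer_fully_blocked(self):
        """A <=> B consumes A forward and produces it backward: both go."""
        mets = [Metabolite("A[c]"), Metabolite("B[c]")]
        model = MetabolicModel(
            mets, [Reaction("R", {"A[c]": -1.0, "B[c]": 1.0}, -10.0, 10.0)]
        )
        ko = knockout_metabolite(model, "A[c]")
        assert (ko.reaction("R").lb, ko.reaction("R").ub) == (0.0, 0.0)

    def test_producer_keeps_forward_direction(self):
        mets = [Metabolite("A[c]"), Metabolite("B[c]")]
        model = MetabolicModel(
            mets, [Reaction("R", {"B[c]": -1.0, "A[c]": 1.0}, -10.0, 10.0)]
        )
        ko = knockout_metabolite(model, "A[c]")
        assert (ko.reaction("R").lb, ko.reaction("R").ub) == (0.0, 10.0)

    def test_untouched_reactions_unchanged(self):
        model = urea_toy()
        ko = knockout_metabolite(model, "aa[c]")
        assert ko.reaction("EX_glc").lb == model.reaction("EX_glc").lb

    def test_never_relaxes_bounds(self):
        model = urea_toy()
        ko = knockout_metabolite(model, "urea[c]")
        for rid in model.reaction_ids:
            assert ko.reaction(rid).lb >= model.reaction(rid).lb
            assert ko.reaction(rid).ub <= model.reaction(rid).ub

    def test_unknown_metabolite_raises(self):
        with pytest.raises(ModelError):
            knockout_metabolite(urea_toy(), "ghost[c]")


class TestEssentiality:
    tasks = [TaskSpec("t_urea", "recycling", "aa[e]")]

    def test_sole_precursor_is_essential(self):
        assert is_essential_metabolite(urea_toy(), "aa[c]", self.tasks)

    def test_bypassed_metabolite_not_essential(self):
        """A redundant parallel route keeps the task alive after knockout."""
        model = urea_toy()
        model.metabolites.append(Metabolite("aa2[c]"))
        model.reactions.extend(
            [
                Reaction("T_aa2", {"aa[e]": -1.0, "aa2[c]": 1.0}, 0.0, 10.0),
                Reaction("R_deam2", {"aa2[c]": -1.0, "urea[c]": 1.0}, 0.0, 10.0),
            ]
        )
        assert not is_essential_metabolite(model, "aa[c]", self.tasks)

    def test_task_irrelevant_metabolite_not_essential(self):
        assert not is_essential_metabolite(urea_toy(), "glc_D[e]", self.tasks)

    def test_monotone_under_task_inclusion(self):
        """Adding tasks can only turn non-essential into essential."""
        model = gluco_toy()
        few = [TaskSpec("none", "nucleotide", "ghost[c]")]
        more = few + [TaskSpec("g", "glucogenic", "sub[e]")]
        assert not is_essential_metabolite(model, "sub[c]", few)
        assert is_essential_metabolite(model, "sub[c]", more)

    def test_empty_task_list_rejected(self):
        with pytest.raises(ValueError):
            is_essential_metabolite(urea_toy(), "aa[c]", [])


def test_run_task_dispatch():
    res = run_task(urea_toy(), TaskSpec("t1", "recycling", "aa[e]"))
    assert res.task_id == "t1" and res.outcome == "passed"
    with pytest.raises(ValueError):
        TaskSpec("t2", "mystery", "aa[e]")
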