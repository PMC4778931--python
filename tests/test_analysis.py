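"""Comparison utilities: presence, composition, enrichment, flux sums."""

import itertools
import math

import numpy as np
import pytest

from cordaflux.analysis import (
    combined_flux_distribution,
    confidence_composition,
    cross_validation_enrichment,
    differential_inclusion,
    fisher_combine,
    hypergeometric_pvalue,
    knockout_dependency,
    presence_matrix,
    subsystem_fraction,
)
from cordaflux.fixtures import make_flexible_core_fixture, make_linear_chain
from cordaflux.model import MetabolicModel, Metabolite, Reaction
from cordaflux.sampler import SampleSet
from cordaflux.scoring import ConfidenceAssignment


class TestPresenceMatrix:
    def test_identical_models_empty_columns(self):
        mat = presence_matrix({"m1": {"A", "B"}, "m2": {"A", "B"}})
        assert mat.shape[1] == 0

    def test_two_model_example(self):
        mat = presence_matrix({"m1": {"A", "B"}, "m2": {"A", "C"}})
        assert sorted(mat.columns) == ["B", "C"]
        assert mat.loc["m1", "B"] == 1 and mat.loc["m1", "C"] == -1
        assert mat.loc["m2", "B"] == -1 and mat.loc["m2", "C"] == 1

    def test_column_count_matches_brute_force(self, rng):
        universe = [f"R{i}" for i in range(12)]
        models = {
            f"m{k}": {r for r in universe if rng.random() < 0.5} for k in range(5)
        }
        mat = presence_matrix(models)
        expected = sum(
            1
            for r in universe
            if 0 < sum(r in s for s in models.values()) < len(models)
        )
        assert mat.shape[1] == expected


class TestSubsystemFraction:
    subsystems = {"R1": "glycolysis", "R2": "glycolysis", "R3": "tca", "R4": ""}

    def test_full_inclusion_scores_one(self):
        models = {"m1": {"R1", "R2"}, "m2": {"R1", "R2"}}
        cats = {"m1": "c1", "m2": "c1"}
        out = subsystem_fraction(models, cats, self.subsystems)
        assert out.loc["c1", "glycolysis"] == 1.0

    def test_absent_subsystem_scores_zero(self):
        models = {"m1": {"R1"}, "m2": {"R3"}}
        cats = {"m1": "a", "m2": "b"}
        out = subsystem_fraction(models, cats, self.subsystems)
        assert out.loc["a", "tca"] == 0.0

    def test_hand_computed_two_category_fixture(self):
        # glycolysis universe = {R1, R2}; category a has models with 2 and 1
        models = {"m1": {"R1", "R2"}, "m2": {"R1"}, "m3": {"R2", "R3"}}
        cats = {"m1": "a", "m2": "a", "m3": "b"}
        out = subsystem_fraction(models, cats, self.subsystems)
        assert out.loc["a", "glycolysis"] == pytest.approx(1.5 / 2)
        assert out.loc["b", "glycolysis"] == pytest.approx(0.5)
        assert ((out.values >= 0) & (out.values <= 1)).all()

    def test_unlabeled_reaction_goes_uncategorized(self):
        models = {"m1": {"R4"}, "m2": {"R4"}}
        cats = {"m1": "a", "m2": "a"}
        out = subsystem_fraction(models, cats, self.subsystems)
        assert out.loc["a", "uncategorized"] == 1.0


class TestConfidenceComposition:
    def test_all_high_model(self):
        asg = ConfidenceAssignment(
            group={"R1": "HC", "R2": "HC"}, score={"R1": 3.0, "R2": 3.0}
        )
        counts = confidence_composition({"R1", "R2"}, asg)
        assert counts["High"] == 2 and sum(counts.values()) == 2

    def test_mixed_tally(self):
        score = {"R1": 3.0, "R2": 2.0, "R3": 1.0, "R4": -1.0, "R5": 0.0, "R6": 1.1}
        asg = ConfidenceAssignment(group={}, score=score)
        counts = confidence_composition(set(score), asg)
        assert counts == {
            "High": 1, "Medium": 1, "Low": 2, "NotDetected": 1, "NoEvidence": 1
        }

    def test_empty_model_zero_counts(self):
        asg = ConfidenceAssignment(group={}, score={})
        assert sum(confidence_composition(set(), asg).values()) == 0


class TestKnockoutDependency:
    def test_chain_entry_kills_downstream(self):
        chain = make_linear_chain(4)
        deps = knockout_dependency(chain, "R_in")
        assert deps == {"R1", "R2", "R3", "R_out"}

    def test_bypassed_reaction_no_dependents(self):
        mets = [Metabolite("A[c]")]
        rxns = [
            Reaction("E1", {"A[c]": 1.0}, 0.0, 10.0),
            Reaction("E2", {"A[c]": 1.0}, 0.0, 10.0),
            Reaction("DM", {"A[c]": -1.0}, 0.0, 10.0),
        ]
        model = MetabolicModel(mets, rxns)
        assert knockout_dependency(model, "E1") == set()

    def test_already_blocked_reaction(self):
        from cordaflux.model import block_reactions

        chain = block_reactions(make_linear_chain(3), {"R1"})
        assert knockout_dependency(chain, "R1") == set()


class TestDifferentialInclusion:
    def test_fully_differential_reaction(self):
        models = {"a1": {"R"}, "a2": {"R"}, "b1": set(), "b2": {"Q"}}
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        out = differential_inclusion(models, labels)
        assert out.loc["R", "freq_A"] == 1.0 and out.loc["R", "freq_B"] == 0.0

    def test_manual_frequencies(self):
        models = {"a1": {"R", "Q"}, "a2": {"R"}, "b1": {"Q"}}
        labels = {"a1": "A", "a2": "A", "b1": "B"}
        out = differential_inclusion(models, labels)
        assert out.loc["Q", "freq_A"] == 0.5 and out.loc["Q", "freq_B"] == 1.0

    def test_single_model_groups_binary(self):
        models = {"a": {"R"}, "b": {"Q"}}
        labels = {"a": "A", "b": "B"}
        out = differential_inclusion(models, labels)
        assert set(np.unique(out[["freq_A", "freq_B"]].values)) <= {0.0, 1.0}


class TestHypergeometric:
    @staticmethod
    def enumerate_pvalue(population, successes, draws, observed):
        """Exhaustive upper-tail enumeration over all C(population, draws)."""
        total = 0
        hits = 0
        items = list(range(population))
        good = set(range(successes))
        for combo in itertools.combinations(items, draws):
            total += 1
            if len(good.intersection(combo)) >= observed:
                hits += 1
        return hits / total

    @pytest.mark.parametrize(
        "population,successes,draws,observed",
        [(20, 10, 5, 5), (20, 10, 5, 3), (12, 4, 6, 2), (15, 7, 4, 0)],
    )
    def test_matches_exhaustive_enumeration(
        self, population, successes, draws, observed
    ):
        expected = self.enumerate_pvalue(population, successes, draws, observed)
        got = hypergeometric_pvalue(population, successes, draws, observed)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_fisher_single_p_identity(self):
        for p in (0.01, 0.3, 0.9):
            assert fisher_combine([p]) == pytest.approx(p, rel=1e-9)

    def test_fisher_combines_downward(self):
        assert fisher_combine([0.01, 0.01, 0.01]) < 0.01


class TestCrossValidation:
    @staticmethod
    def enrichment_fixture():
        """Four mutually supporting HC reactions plus ten dead-end OT
        decoys that can never join the reconstruction."""
        from cordaflux.builder import ReactionGroups

        mets = [Metabolite("H[c]"), Metabolite("G[c]")]
        mets += [Metabolite(f"D{i}[c]") for i in range(10)]
        rxns = [
            Reaction("E_H", {"H[c]": 1.0}, 0.0, 10.0),
            Reaction("DM_H", {"H[c]": -1.0}, 0.0, 10.0),
            Reaction("E_G", {"G[c]": 1.0}, 0.0, 10.0),
            Reaction("DM_G", {"G[c]": -1.0}, 0.0, 10.0),
        ]
        rxns += [
            Reaction(f"dec{i}", {f"D{i}[c]": 1.0, "H[c]": 1.0, "G[c]": 1.0}, 0.0, 10.0)
            for i in range(10)
        ]
        model = MetabolicModel(mets, rxns)
        groups = ReactionGroups(
            hc={"E_H", "DM_H", "E_G", "DM_G"},
            ot={f"dec{i}" for i in range(10)},
        )
        return model, groups

    def test_recovered_holdouts_give_small_p(self, params):
        model, groups = self.enrichment_fixture()
        out = cross_validation_enrichment(
            model, groups, params, holdout=0.25, reps=5,
            rng=np.random.default_rng(0),
        )
        assert set(out) == {"HC", "MC", "NC"}
        # a held-out HC reaction is always recovered through its partner,
        # while the dead-end decoys never are: strong enrichment
        assert out["HC"] < 0.05

    def test_nan_for_empty_holdout(self, params, detox):
        # MC group is empty: its p-value is undefined, not an exception
        out = cross_validation_enrichment(
            detox.model, detox.groups, params, reps=2,
            rng=np.random.default_rng(1),
        )
        assert math.isnan(out["MC"])


class TestCombinedFlux:
    def make_samples(self):
        pts = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        return SampleSet(pts, ["R1", "R2", "R3"], 3, [[1.0]])

    def test_single_id_identity(self):
        s = self.make_samples()
        assert np.array_equal(combined_flux_distribution(s, ["R2"]), [2.0, 5.0])

    def test_two_constant_columns_sum(self):
        s = self.make_samples()
        assert np.array_equal(
            combined_flux_distribution(s, ["R1", "R3"]), [4.0, 10.0]
        )

    def test_missing_id_raises(self):
        from cordaflux.model import ModelError

        with pytest.raises(ModelError):
            combined_flux_distribution(self.make_samples(), ["ghost"])
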