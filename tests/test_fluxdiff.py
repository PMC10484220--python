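"""The 10% flux-change rule, KO/OE verdicts, and subsystem summaries."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxshift.exceptions import ContractError
from fluxshift.fluxdiff import (
    DOWN,
    FLUX_DECREASING,
    FLUX_INCREASING,
    INCONSISTENT,
    NO_CHANGE,
    UNCHANGED,
    UNIDENTIFIED,
    UP,
    KoOeClassification,
    classify_flux_change,
    classify_ko_oe,
    summarize_subsystems,
)
from fluxshift.metnet import MetabolicModel, Metabolite, Reaction
from fluxshift.solvers import FluxDistribution

finite = st.floats(
    min_value=-1e4, max_value=1e4, allow_nan=False, allow_infinity=False
)


def dist(fluxes: dict, status="optimal") -> FluxDistribution:
    return FluxDistribution("m", fluxes, status)


class TestClassifyFluxChange:
    @pytest.mark.parametrize(
        "v_orig, v_pert, expected",
        [
            (1.0, 1.2, UP),           # delta 0.2 > 0.1
            (1.0, 1.05, NO_CHANGE),   # below threshold
            (1.0, 0.8, DOWN),
            (1.0, 1.1, NO_CHANGE),    # tie at exactly 10%: strict rule
            (1.0, 0.9, NO_CHANGE),
            (-2.0, -2.3, DOWN),       # threshold on |v_orig| for reversible flux
            (-2.0, -1.7, UP),
            (0.0, 0.5, UP),           # zero original: absolute floor governs
            (0.0, 0.0, NO_CHANGE),
            (0.0, 5e-7, NO_CHANGE),   # solver noise below the floor
        ],
    )
    def test_rule_on_constructed_pairs(self, v_orig, v_pert, expected):
        assert classify_flux_change(v_orig, v_pert) == expected

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ContractError):
            classify_flux_change(math.nan, 1.0)
        with pytest.raises(ContractError):
            classify_flux_change(1.0, math.inf)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ContractError):
            classify_flux_change(1.0, 2.0, rel_threshold=0.0)
        with pytest.raises(ContractError):
            classify_flux_change(1.0, 2.0, abs_floor=-1.0)

    @given(v=finite)
    def test_unchanged_flux_is_no_change(self, v):
        assert classify_flux_change(v, v) == NO_CHANGE

    @given(v_orig=finite, v_pert=finite)
    @settings(max_examples=200)
    def test_threshold_monotonicity(self, v_orig, v_pert):
        """Raising the relative threshold never turns no_change into a call."""
        loose = classify_flux_change(v_orig, v_pert, rel_threshold=0.10)
        tight = classify_flux_change(v_orig, v_pert, rel_threshold=0.25)
        if loose == NO_CHANGE:
            assert tight == NO_CHANGE


class TestClassifyKoOe:
    def test_verdicts_on_constructed_triples(self):
        orig = dist({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0})
        ko = dist({"a": 0.8, "b": 1.2, "c": 1.2, "d": 1.0})
        oe = dist({"a": 1.3, "b": 0.7, "c": 1.3, "d": 1.0})
        by_id = {c.reaction_id: c for c in classify_ko_oe(orig, ko, oe)}
        assert by_id["a"].verdict == FLUX_DECREASING
        assert by_id["b"].verdict == FLUX_INCREASING
        assert by_id["c"].verdict == INCONSISTENT
        assert by_id["d"].verdict == UNCHANGED

    def test_missing_reactions_labelled_unidentified(self):
        orig = dist({"a": 1.0})
        out = classify_ko_oe(orig, orig, orig, missing=["HMR0030"])
        missing = [c for c in out if c.reaction_id == "HMR0030"]
        assert len(missing) == 1
        assert missing[0].verdict == UNIDENTIFIED
        assert missing[0].ko_label == UNIDENTIFIED

    def test_single_arm_change_is_inconsistent(self):
        orig = dist({"a": 1.0})
        ko = dist({"a": 0.5})
        oe = dist({"a": 1.0})
        (c,) = classify_ko_oe(orig, ko, oe)
        assert c.verdict == INCONSISTENT

    def test_non_optimal_distribution_rejected(self):
        orig = dist({"a": 1.0})
        bad = dist({}, status="infeasible")
        with pytest.raises(ContractError):
            classify_ko_oe(orig, bad, orig)

    def test_universe_mismatch_rejected(self):
        orig = dist({"a": 1.0})
        extra = dist({"a": 1.0, "b": 2.0})
        with pytest.raises(ContractError):
            classify_ko_oe(orig, extra, orig)

    @given(
        st.lists(
            st.tuples(finite, finite, finite), min_size=1, max_size=8
        )
    )
    @settings(max_examples=100)
    def test_antisymmetry_under_arm_swap(self, triples):
        """Swapping KO and OE swaps flux_decreasing ↔ flux_increasing and
        fixes unchanged/inconsistent."""
        ids = [f"r{i}" for i in range(len(triples))]
        orig = dist({i: t[0] for i, t in zip(ids, triples)})
        ko = dist({i: t[1] for i, t in zip(ids, triples)})
        oe = dist({i: t[2] for i, t in zip(ids, triples)})
        fwd = {c.reaction_id: c.verdict for c in classify_ko_oe(orig, ko, oe)}
        rev = {c.reaction_id: c.verdict for c in classify_ko_oe(orig, oe, ko)}
        swap = {
            FLUX_DECREASING: FLUX_INCREASING,
            FLUX_INCREASING: FLUX_DECREASING,
            UNCHANGED: UNCHANGED,
            INCONSISTENT: INCONSISTENT,
        }
        assert rev == {rid: swap[v] for rid, v in fwd.items()}


class TestSummarizeSubsystems:
    @staticmethod
    def model_with_subsystems(spec: dict[str, int]) -> MetabolicModel:
        rxns = []
        for subsystem, n in spec.items():
            for i in range(n):
                rxns.append(
                    Reaction(
                        f"{subsystem}_{i}", {"X": 1}, 0, 10,
                        subsystem=subsystem, exchange=True,
                    )
                )
        return MetabolicModel(
            id="m", metabolites=(Metabolite("X"),), reactions=tuple(rxns)
        )

    def test_counts_and_fractions(self):
        model = self.model_with_subsystems({"S": 4})
        cls = [
            KoOeClassification("S_0", UP, DOWN, FLUX_INCREASING),
            KoOeClassification("S_1", UP, DOWN, FLUX_INCREASING),
            KoOeClassification("S_2", DOWN, UP, FLUX_DECREASING),
            KoOeClassification("S_3", NO_CHANGE, NO_CHANGE, UNCHANGED),
        ]
        (s,) = summarize_subsystems(cls, model)
        assert (s.n_total, s.n_increasing, s.n_decreasing) == (4, 2, 1)
        assert s.frac_increasing == 0.5 and s.frac_decreasing == 0.25

    def test_no_changes_gives_zero_fractions(self):
        model = self.model_with_subsystems({"A": 2, "B": 3})
        cls = [
            KoOeClassification(r.id, NO_CHANGE, NO_CHANGE, UNCHANGED)
            for r in model.reactions
        ]
        for s in summarize_subsystems(cls, model):
            assert s.frac_increasing == 0.0 and s.frac_decreasing == 0.0

    def test_totals_partition_the_model(self):
        model = self.model_with_subsystems({"A": 2, "B": 3, "C": 1})
        cls = [
            KoOeClassification(r.id, NO_CHANGE, NO_CHANGE, UNCHANGED)
            for r in model.reactions
        ]
        summaries = summarize_subsystems(cls, model)
        assert sum(s.n_total for s in summaries) == len(model.reactions)
        assert {s.subsystem for s in summaries} == {"A", "B", "C"}

    def test_sorted_by_decreasing_then_increasing_fraction(self):
        model = self.model_with_subsystems({"A": 2, "B": 2, "C": 2})
        cls = [
            KoOeClassification("A_0", DOWN, UP, FLUX_DECREASING),
            KoOeClassification("A_1", DOWN, UP, FLUX_DECREASING),
            KoOeClassification("B_0", DOWN, UP, FLUX_DECREASING),
            KoOeClassification("B_1", NO_CHANGE, NO_CHANGE, UNCHANGED),
            KoOeClassification("C_0", UP, DOWN, FLUX_INCREASING),
            KoOeClassification("C_1", NO_CHANGE, NO_CHANGE, UNCHANGED),
        ]
        order = [s.subsystem for s in summarize_subsystems(cls, model)]
        assert order == ["A", "B", "C"]

    def test_classified_reaction_must_exist(self):
        model = self.model_with_subsystems({"A": 1})
        cls = [KoOeClassification("ghost", UP, DOWN, FLUX_INCREASING)]
        with pytest.raises(ContractError):
            summarize_subsystems(cls, model)
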