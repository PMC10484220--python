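"""FBA and MOMA: analytic examples, solver contracts, and oracle checks."""

import numpy as np
import pytest

from fluxshift.exceptions import ConfigurationError, ContractError
from fluxshift.metnet import set_bounds, stoichiometric_matrix
from fluxshift.solvers import (
    FluxDistribution,
    mass_balance_residual,
    solve_fba,
    solve_moma,
)
from fluxshift.synthdata import random_feasible_model

from oracles import admm_moma, fba_lp_cobra


class TestFba:
    def test_chain_optimum_forced_by_uptake(self, chain_model):
        sol = solve_fba(chain_model)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0, abs=1e-6)
        for rid in ("R_up", "R_conv", "R_out"):
            assert sol[rid] == pytest.approx(10.0, abs=1e-6)

    def test_blocked_pathway_gives_zero(self, chain_model):
        blocked = set_bounds(chain_model, "R_conv", 0, 0)
        sol = solve_fba(blocked)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
        assert all(abs(v) <= 1e-9 for v in sol.fluxes.values())

    def test_contradictory_bounds_infeasible(self, chain_model):
        bad = set_bounds(chain_model, "R_out", 20, 1000)
        sol = solve_fba(bad)
        assert sol.status == "infeasible"
        assert sol.fluxes == {}

    def test_empty_objective_is_configuration_error(self, chain_model):
        from dataclasses import replace

        with pytest.raises(ConfigurationError):
            solve_fba(replace(chain_model, objective={}))
        with pytest.raises(ConfigurationError):
            solve_fba(replace(chain_model, objective={"R_out": 0.0}))

    def test_solution_respects_bounds_and_mass_balance(self, toy_model, toy_wild_type):
        tol = toy_wild_type.tolerances
        for r in toy_model.reactions:
            v = toy_wild_type[r.id]
            assert r.lower_bound - tol.bound <= v <= r.upper_bound + tol.bound
        assert mass_balance_residual(toy_model, toy_wild_type) <= tol.mass_balance

    def test_agrees_with_independent_lp_formulation(self, toy_model, chain_model):
        """Cross-check the scipy LP against cobrapy/GLPK."""
        for model in (toy_model, chain_model):
            status, obj = fba_lp_cobra(model)
            ours = solve_fba(model)
            assert status == "optimal" and ours.status == "optimal"
            assert ours.objective_value == pytest.approx(obj, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_optimum_dominates_feasibility_witness(self, seed):
        model, witness = random_feasible_model(4, 9, seed)
        sol = solve_fba(model)
        assert sol.status == "optimal"
        assert sol.objective_value >= witness.objective_value - 1e-7


class TestMoma:
    def test_identity_perturbation_distance_zero(self, diamond_model, diamond_reference):
        sol = solve_moma(diamond_model, diamond_reference)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-8)
        for rid, w in diamond_reference.fluxes.items():
            assert sol[rid] == pytest.approx(w, abs=1e-6)

    def test_diamond_knockout_reroutes(self, diamond_model, diamond_reference):
        """Closed form: with R1 blocked, v = t on the surviving route
        minimizes (t−10)² + 25 + (t−5)² + (t−10)², so t = 25/3."""
        ko = set_bounds(diamond_model, "R1", 0, 0)
        sol = solve_moma(ko, diamond_reference)
        assert sol.status == "optimal"
        assert sol["R2"] == pytest.approx(25 / 3, abs=1e-4)
        assert sol["R_in"] == pytest.approx(25 / 3, abs=1e-4)
        assert sol["R_out"] == pytest.approx(25 / 3, abs=1e-4)
        assert sol.objective_value == pytest.approx(125 / 3, abs=1e-4)

    def test_toy_ketone_knockout_zeroes_branch(self, toy_model, toy_wild_type):
        ko = set_bounds(toy_model, "HMGCS2x", 0, 0)
        sol = solve_moma(ko, toy_wild_type)
        assert sol.status == "optimal"
        assert sol["HMGCS2x"] == 0.0
        branch = sum(abs(sol[r]) for r in ("ACAT", "HMGCS2x", "HMGL"))
        assert branch == pytest.approx(0.0, abs=1e-6)
        assert mass_balance_residual(ko, sol) <= 1e-6

    def test_infeasible_perturbation_reported(self, diamond_model, diamond_reference):
        # R_in forced to 15 but both routes blocked
        broken = set_bounds(diamond_model, "R_in", 15, 20)
        broken = set_bounds(broken, "R1", 0, 0)
        broken = set_bounds(broken, "R2", 0, 0)
        sol = solve_moma(broken, diamond_reference)
        assert sol.status == "infeasible"
        assert sol.fluxes == {}

    def test_non_optimal_reference_rejected(self, diamond_model):
        bad_ref = FluxDistribution("diamond", {}, "infeasible", None)
        with pytest.raises(ContractError):
            solve_moma(diamond_model, bad_ref)

    def test_reference_missing_reactions_treated_as_zero(
        self, diamond_model, diamond_reference
    ):
        """Dropping a reaction from the reference is equivalent to w_j = 0."""
        partial = FluxDistribution(
            "diamond",
            {k: v for k, v in diamond_reference.fluxes.items() if k != "R1"},
            "optimal",
            10.0,
        )
        full = FluxDistribution(
            "diamond",
            {**diamond_reference.fluxes, "R1": 0.0},
            "optimal",
            10.0,
        )
        a = solve_moma(diamond_model, partial)
        b = solve_moma(diamond_model, full)
        for rid in diamond_model.reaction_ids:
            assert a[rid] == pytest.approx(b[rid], abs=1e-6)

    def test_distance_zero_iff_reference_feasible(self):
        model, witness = random_feasible_model(3, 7, seed=11)
        # witness is feasible in the unperturbed model -> distance 0
        same = solve_moma(model, witness)
        assert same.objective_value == pytest.approx(0.0, abs=1e-8)
        # shrink one bound interval away from the witness -> distance > 0
        rid = model.reactions[0].id
        wv = witness[rid]
        shifted = set_bounds(model, rid, wv + 0.1, model.reaction(rid).upper_bound + 1)
        moved = solve_moma(shifted, witness)
        assert moved.status == "optimal"
        assert moved.objective_value > 1e-4

    def test_monotonicity_under_tighter_perturbation(
        self, diamond_model, diamond_reference
    ):
        """Shrinking a bound interval that already excludes the reference
        value never decreases the optimal distance."""
        distances = []
        for ub in (4.0, 3.0, 1.0, 0.0):
            pert = set_bounds(diamond_model, "R1", 0, ub)
            sol = solve_moma(pert, diamond_reference)
            distances.append(sol.objective_value)
        assert distances == sorted(distances)

    @pytest.mark.parametrize("c", [0.1, 1.0, 7.5])
    def test_scale_invariance(self, diamond_model, diamond_reference, c):
        """Scaling bounds and reference by c scales fluxes by c and the
        squared distance by c²."""
        base_ko = set_bounds(diamond_model, "R1", 0, 0)
        base = solve_moma(base_ko, diamond_reference)

        from dataclasses import replace

        scaled_rxns = tuple(
            replace(r, lower_bound=r.lower_bound * c, upper_bound=r.upper_bound * c)
            for r in base_ko.reactions
        )
        scaled_model = replace(base_ko, reactions=scaled_rxns)
        scaled_ref = FluxDistribution(
            diamond_reference.model_id,
            {k: v * c for k, v in diamond_reference.fluxes.items()},
            "optimal",
        )
        scaled = solve_moma(scaled_model, scaled_ref)
        for rid in base.fluxes:
            assert scaled[rid] == pytest.approx(c * base[rid], abs=1e-6 * max(c, 1))
        assert scaled.objective_value == pytest.approx(
            c**2 * base.objective_value, rel=1e-6
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_admm_oracle(self, seed):
        """Spot check against the independent ADMM projection oracle
        (the full 50-seed sweep runs in the acceptance suite)."""
        rng = np.random.default_rng(1000 + seed)
        model, witness = random_feasible_model(4, 10, seed)
        S = stoichiometric_matrix(model)
        lb = np.array([r.lower_bound for r in model.reactions])
        ub = np.array([r.upper_bound for r in model.reactions])
        w = witness.as_vector(model) + rng.normal(0, 2.0, size=len(lb))
        ref = FluxDistribution(
            model.id,
            {r.id: float(x) for r, x in zip(model.reactions, w)},
            "feasible",
        )
        ours = solve_moma(model, ref)
        expected = admm_moma(S, lb, ub, w)
        assert ours.status == "optimal"
        assert np.max(np.abs(ours.as_vector(model) - expected)) <= 1e-4
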