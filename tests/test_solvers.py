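"""FBA, reference selection, MOMA projection, FVA and flux-sum LPs."""

import math

import numpy as np
import pytest

from fluxdesigner.solvers import (
    Infeasible,
    Unbounded,
    apply_state,
    flux_variability,
    min_flux_sum,
    reference_fba,
    solve_fba,
    solve_moma,
)
from fluxdesigner.stoichmodel import (
    Metabolite,
    ModelValidationError,
    MutantDesign,
    Reaction,
    StoichiometricModel,
    apply_design,
)
from fluxdesigner.toynet import make_state_spec

from .conftest import chain_model, two_branch_model
from .oracle import cobra_max


class TestFba:
    def test_chain_throughput_is_forced_by_bounds(self):
        sol = solve_fba(chain_model())
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
        assert sol.residual <= 1e-9

    @pytest.mark.parametrize("mode", ["respiratory", "respiro_fermentative",
                                      "measured_vg0", "measured_vg2", "measured_vg4"])
    def test_growth_optimum_matches_independent_glpk_oracle(self, vg_model, mode):
        constrained = apply_state(vg_model, make_state_spec(mode))
        ours = solve_fba(constrained).objective_value
        theirs = cobra_max(constrained, "BIOMASS")
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_zero_glucose_means_zero_growth(self, vg_model):
        model = vg_model.copy()
        model.reaction("glucose_uptake").upper_bound = 0.0
        try:
            mu = solve_fba(model).objective_value
        except Infeasible:
            mu = 0.0  # starved: not even maintenance is satisfiable
        assert mu <= 1e-9

    def test_optimum_dominates_random_feasible_points(self, vg_model):
        """The FBA optimum is an upper bound for any feasible distribution."""
        best = solve_fba(vg_model).objective_value
        rng = np.random.default_rng(7)
        for _ in range(5):
            probe = vg_model.copy()
            # random extra restrictions keep the point feasible but arbitrary
            for rxn in rng.choice(probe.reactions, size=4, replace=False):
                if rxn.id == "BIOMASS" or rxn.lower_bound != 0.0:
                    continue
                rxn.upper_bound = float(rng.uniform(0, rxn.upper_bound))
            try:
                sub = solve_fba(probe).objective_value
            except Infeasible:
                continue
            assert sub <= best + 1e-9

    def test_infeasible_reports_bounds(self, vg_model):
        model = vg_model.copy()
        model.reaction("glucose_uptake").upper_bound = 0.0
        model.reaction("ethanol_exchange").lower_bound = 1.0
        with pytest.raises(Infeasible) as err:
            solve_fba(model)
        assert any("ethanol_exchange" in line for line in err.value.details)

    def test_unbounded_names_a_witness(self):
        m = StoichiometricModel(
            metabolites=[Metabolite("a_e", is_external=True),
                         Metabolite("b_e", is_external=True)],
            reactions=[Reaction("free", {"a_e": -1, "b_e": 1},
                                lower_bound=-math.inf, upper_bound=math.inf)],
            objective={"free": 1.0},
        )
        with pytest.raises(Unbounded, match="free"):
            solve_fba(m)

    def test_invalid_model_is_rejected(self, vg_model):
        model = vg_model.copy()
        model.reaction("PDC").lower_bound = 5.0
        model.reaction("PDC").upper_bound = 1.0
        with pytest.raises(ModelValidationError):
            solve_fba(model)


class TestReferenceFba:
    def test_respiratory_reference_has_no_ethanol(self, respiratory_reference):
        assert abs(respiratory_reference["ethanol_exchange"]) <= 1e-9

    def test_measured_reference_grows_at_dilution_rate(self, vg0_reference):
        assert vg0_reference.objective_value == pytest.approx(0.1, abs=1e-6)
        assert vg0_reference["BIOMASS"] == pytest.approx(0.1, abs=1e-6)

    def test_reference_is_deterministic(self, vg_model, vg0_state):
        a = reference_fba(vg_model, vg0_state)
        b = reference_fba(vg_model, vg0_state)
        assert a.fluxes == b.fluxes

    def test_parsimonious_tiebreak_shrinks_total_flux(self, vg_model, rf_state):
        ref = reference_fba(vg_model, rf_state)
        plain = solve_fba(apply_state(vg_model, rf_state))
        assert sum(abs(v) for v in ref.fluxes.values()) <= \
            sum(abs(v) for v in plain.fluxes.values()) + 1e-6


class TestMoma:
    def test_projection_identity_when_reference_feasible(self, rf_model, rf_reference):
        sol, ma = solve_moma(rf_model, rf_reference)
        assert ma <= 1e-6
        for rxn_id, w in rf_reference.fluxes.items():
            assert sol[rxn_id] == pytest.approx(w, abs=1e-5)

    def test_two_branch_closed_form(self):
        """Knocking out the loaded branch reroutes all flux: MA = sqrt(200)."""
        model = two_branch_model()
        from fluxdesigner.stoichmodel import FluxDistribution

        reference = FluxDistribution(fluxes={"source": 10.0, "P": 10.0, "Q": 0.0})
        mutant = apply_design(model, MutantDesign(knockouts={"P"}))
        sol, ma = solve_moma(mutant, reference)
        assert sol["Q"] == pytest.approx(10.0, abs=1e-8)
        assert ma == pytest.approx(math.sqrt(200.0), abs=1e-6)

    def test_matches_slsqp_on_fixture_knockouts(self, rf_model, rf_reference):
        """The active-set QP agrees with an independent SLSQP solve."""
        from scipy.optimize import Bounds, LinearConstraint, minimize

        for ko in ("GDH1", "ADH", "TCA"):
            mutant = apply_design(rf_model, MutantDesign(knockouts={ko}))
            sol, ma = solve_moma(mutant, rf_reference)
            S, _, rxns = mutant.stoichiometric_matrix()
            w = np.array([rf_reference.get(r, 0.0) for r in rxns])
            lb = np.array([r.lower_bound for r in mutant.reactions])
            ub = np.array([r.upper_bound for r in mutant.reactions])
            x0 = np.array([sol[r] for r in rxns])
            res = minimize(
                lambda x: float(np.sum((x - w) ** 2)), x0,
                jac=lambda x: 2.0 * (x - w),
                bounds=Bounds(lb, ub),
                constraints=[LinearConstraint(S, 0.0, 0.0)],
                method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14},
            )
            assert ma ** 2 <= res.fun + 1e-6

    def test_infeasible_mutant_raises(self, vg_model):
        model = vg_model.copy()
        model.reaction("glucose_uptake").lower_bound = 5.0
        mutant = apply_design(model, MutantDesign(knockouts={"HXK"}))
        from fluxdesigner.stoichmodel import FluxDistribution

        with pytest.raises(Infeasible):
            solve_moma(mutant, FluxDistribution(fluxes={}))

    def test_ma_monotone_under_tightening(self, respiratory_model,
                                          respiratory_reference):
        """Shrinking a bound interval can never decrease the adjustment."""
        mas = []
        for fraction in (1.0, 0.8, 0.5, 0.2):
            mutant = respiratory_model.copy()
            rxn = mutant.reaction("PDC")
            rxn.upper_bound = fraction * abs(respiratory_reference["PDC"])
            _, ma = solve_moma(mutant, respiratory_reference)
            mas.append(ma)
        assert all(a <= b + 1e-8 for a, b in zip(mas, mas[1:]))


class TestFluxVariability:
    def test_pinned_reaction_has_point_range(self, vg_model):
        model = vg_model.copy()
        model.reaction("GPD").lower_bound = 0.0
        model.reaction("GPD").upper_bound = 0.0
        ranges = flux_variability(model, reactions=["GPD"])
        assert ranges["GPD"].lo == pytest.approx(0.0, abs=1e-9)
        assert ranges["GPD"].hi == pytest.approx(0.0, abs=1e-9)

    def test_chain_with_fixed_throughput_is_unique(self):
        ranges = flux_variability(chain_model(throughput=(4.0, 4.0)))
        for rxn_id in ("uptake", "r_ab", "r_bx", "export"):
            assert ranges[rxn_id].lo == pytest.approx(4.0, abs=1e-9)
            assert ranges[rxn_id].hi == pytest.approx(4.0, abs=1e-9)

    def test_ranges_contain_reference_solution(self, vg_model, vg0_state,
                                               vg0_reference):
        ranges = flux_variability(vg_model, vg0_state, fix_growth=True)
        for rxn_id, fr in ranges.items():
            assert fr.lo <= fr.hi + 1e-9
            v = vg0_reference[rxn_id]
            assert fr.lo - 1e-6 <= v <= fr.hi + 1e-6

    def test_moma_solution_lies_within_ranges(self, vg0_model, vg0_reference):
        mutant = apply_design(vg0_model, MutantDesign(knockouts={"GDH1"}))
        sol, _ = solve_moma(mutant, vg0_reference)
        ranges = flux_variability(mutant)
        for rxn_id, fr in ranges.items():
            assert fr.lo - 1e-5 <= sol[rxn_id] <= fr.hi + 1e-5


class TestMinFluxSum:
    def test_chain_turnover_equals_throughput(self):
        from fluxdesigner.toynet import PhysiologicalState

        state = PhysiologicalState(mode="measured",
                                   fixed_rates={"export": (4.0, 4.0)})
        result = min_flux_sum(chain_model(), "b", state)
        assert result.phi_min == pytest.approx(4.0, abs=1e-8)

    def test_futile_cycle_is_suppressed(self):
        """A reversible self-loop around B does not inflate the turnover."""
        from fluxdesigner.toynet import PhysiologicalState

        model = chain_model()
        model.metabolites.append(Metabolite("b2"))
        model.reactions.append(
            Reaction("loop_fwd", {"b": -1, "b2": 1}, lower_bound=0.0, upper_bound=50.0))
        model.reactions.append(
            Reaction("loop_back", {"b2": -1, "b": 1}, lower_bound=0.0, upper_bound=50.0))
        state = PhysiologicalState(mode="measured",
                                   fixed_rates={"export": (4.0, 4.0)})
        result = min_flux_sum(model, "b", state)
        assert result.phi_min == pytest.approx(4.0, abs=1e-8)
        assert abs(result.support["loop_fwd"]) <= 1e-8

    def test_demand_without_producer_is_infeasible(self):
        from fluxdesigner.toynet import PhysiologicalState

        model = chain_model()
        model.reaction("r_ab").upper_bound = 0.0
        state = PhysiologicalState(mode="measured",
                                   fixed_rates={"export": (4.0, 4.0)})
        with pytest.raises(Infeasible):
            min_flux_sum(model, "b", state)

    def test_external_metabolite_is_rejected(self, vg_model, vg0_state):
        with pytest.raises(ValueError, match="external"):
            min_flux_sum(vg_model, "glc_e", vg0_state)

    def test_definition_lower_bounds_any_feasible_vector(self, vg_model, vg0_state):
        """Phi evaluated on an arbitrary feasible vector >= the LP minimum."""
        result = min_flux_sum(vg_model, "pyr", vg0_state)
        arbitrary = reference_fba(vg_model, vg0_state)
        S, mets, rxns = vg_model.stoichiometric_matrix()
        i = mets.index("pyr")
        v = np.array([arbitrary[r] for r in rxns])
        phi_arbitrary = 0.5 * float(np.sum(np.abs(S[i, :] * v)))
        assert result.phi_min <= phi_arbitrary + 1e-6
        # and the support satisfies the definition
        vs = np.array([result.support[r] for r in rxns])
        assert result.phi_min == pytest.approx(
            0.5 * float(np.sum(np.abs(S[i, :] * vs))), abs=1e-6)
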