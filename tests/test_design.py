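"""Design scoring (yield, BPCY, MA, R^3) and knockout searches."""

import dataclasses

import pytest

from fluxdesigner.design import (
    DesignEvaluation,
    GAParams,
    default_candidates,
    evaluate_design,
    exhaustive_search,
    normalize_r3,
    optgene_search,
)
from fluxdesigner.stoichmodel import (
    FluxDistribution,
    Metabolite,
    MutantDesign,
    Reaction,
    StoichiometricModel,
)


def production_model():
    """Substrate uptake 10 feeding product export (2) and growth (0.2)."""
    m = StoichiometricModel()
    m.metabolites = [
        Metabolite("s_e", is_external=True),
        Metabolite("s"),
        Metabolite("p_e", is_external=True),
        Metabolite("x_e", is_external=True),
    ]
    m.reactions = [
        Reaction("uptake", {"s_e": -1, "s": 1}, lower_bound=10.0, upper_bound=10.0),
        Reaction("export_p", {"s": -1, "p_e": 1}, lower_bound=2.0, upper_bound=2.0),
        Reaction("growth", {"s": -40, "x_e": 1}, lower_bound=0.0, upper_bound=10.0),
    ]
    m.objective = {"growth": 1.0}
    return m


class TestEvaluateDesign:
    def test_yield_and_bpcy_arithmetic(self):
        model = production_model()
        reference = FluxDistribution(
            fluxes={"uptake": 10.0, "export_p": 2.0, "growth": 0.2})
        ev = evaluate_design(model, MutantDesign(), reference, "export_p", "uptake")
        assert ev.viable
        assert ev.growth == pytest.approx(0.2, abs=1e-8)
        assert ev.yield_ == pytest.approx(0.2, abs=1e-8)
        assert ev.bpcy == pytest.approx(0.04, abs=1e-8)
        assert ev.ma <= 1e-6 and ev.r3 is None

    def test_empty_design_reproduces_reference(self, vg0_model, vg0_reference):
        ev = evaluate_design(vg0_model, MutantDesign(), vg0_reference,
                             "VG_secretion", "glucose_uptake")
        assert ev.ma <= 1e-6
        assert ev.r3 is None
        assert ev.bpcy == pytest.approx(
            vg0_reference["VG_secretion"] / vg0_reference["glucose_uptake"]
            * vg0_reference["BIOMASS"], rel=1e-4)

    def test_r3_is_bpcy_over_ma(self, vg0_model, vg0_reference):
        ev = evaluate_design(vg0_model, MutantDesign(knockouts={"GDH1"}),
                             vg0_reference, "VG_secretion", "glucose_uptake")
        assert ev.ma > 1e-6
        assert ev.r3 == pytest.approx(ev.bpcy / ev.ma, rel=1e-9)

    def test_lethal_design_is_nonviable_not_an_exception(self, vg0_model,
                                                         vg0_reference):
        ev = evaluate_design(vg0_model, MutantDesign(knockouts={"HXK"}),
                             vg0_reference, "VG_secretion", "glucose_uptake")
        assert not ev.viable
        assert ev.bpcy == 0.0

    def test_reevaluation_is_bit_reproducible(self, vg0_model, vg0_reference):
        first = evaluate_design(vg0_model, MutantDesign(knockouts={"GDH1"}),
                                vg0_reference, "VG_secretion", "glucose_uptake")
        second = evaluate_design(vg0_model, first.design, vg0_reference,
                                 "VG_secretion", "glucose_uptake")
        assert dataclasses.asdict(first) == dataclasses.asdict(second)


class TestNormalizeR3:
    def _evals(self, r3s):
        return [DesignEvaluation(design=MutantDesign(), r3=r) for r in r3s]

    def test_simple_panel(self):
        out = normalize_r3(self._evals([0.02, 0.01]))
        assert [e.r3_normalized for e in out] == [100.0, 50.0]

    def test_single_defined_entry(self):
        out = normalize_r3(self._evals([0.005, None]))
        assert out[0].r3_normalized == 100.0
        assert out[1].r3_normalized is None

    def test_scale_invariance(self):
        a = normalize_r3(self._evals([0.02, 0.01, 0.004]))
        b = normalize_r3(self._evals([0.14, 0.07, 0.028]))
        assert [e.r3_normalized for e in a] == pytest.approx(
            [e.r3_normalized for e in b])

    def test_all_undefined_raises(self):
        with pytest.raises(ValueError):
            normalize_r3(self._evals([None, None]))


class TestExhaustiveSearch:
    def test_k0_returns_only_the_reference(self, vg0_model, vg0_reference):
        out = exhaustive_search(vg0_model, vg0_reference, "VG_secretion",
                                "glucose_uptake", k=0)
        assert len(out) == 1 and out[0].design.is_empty

    def test_matches_independent_reenumeration(self, vg0_model, vg0_reference):
        candidates = ["GDH1", "GDH2", "GPD", "PPP_OX", "ALD", "hsOMT_a"]
        ranked = exhaustive_search(vg0_model, vg0_reference, "VG_secretion",
                                   "glucose_uptake", k=1, candidates=candidates,
                                   rank_by="bpcy")
        # oracle: plain loop over the same subsets, no ranking machinery
        best_bpcy, best_ko = -1.0, None
        for ko in [frozenset()] + [frozenset({c}) for c in candidates]:
            ev = evaluate_design(vg0_model, MutantDesign(knockouts=ko),
                                 vg0_reference, "VG_secretion", "glucose_uptake")
            if ev.bpcy > best_bpcy:
                best_bpcy, best_ko = ev.bpcy, ko
        assert ranked[0].bpcy == pytest.approx(best_bpcy, abs=1e-12)

    def test_rankings_are_sorted(self, vg0_model, vg0_reference):
        candidates = ["GDH1", "GDH2", "GPD", "PPP_OX"]
        for key in ("bpcy", "r3"):
            out = exhaustive_search(vg0_model, vg0_reference, "VG_secretion",
                                    "glucose_uptake", k=1,
                                    candidates=candidates, rank_by=key)
            if key == "bpcy":
                values = [e.bpcy for e in out]
            else:
                values = [e.r3 for e in out if e.r3 is not None]
            assert values == sorted(values, reverse=True)

    def test_bilevel_interval_brackets_moma_product(self, vg0_model, vg0_reference):
        out = exhaustive_search(vg0_model, vg0_reference, "VG_secretion",
                                "glucose_uptake", k=1, candidates=["GDH1"])
        for ev in out:
            if ev.viable and ev.fba_product_range is not None:
                lo, hi = ev.fba_product_range
                assert lo <= hi + 1e-9

    def test_unknown_candidate_raises(self, vg0_model, vg0_reference):
        with pytest.raises(ValueError, match="NOPE"):
            exhaustive_search(vg0_model, vg0_reference, "VG_secretion",
                              "glucose_uptake", k=1, candidates=["NOPE"])


class TestCandidateSet:
    def test_excludes_exchanges_biomass_and_maintenance(self, vg_model):
        cand = default_candidates(vg_model)
        assert "glucose_uptake" not in cand
        assert "VG_secretion" not in cand
        assert "BIOMASS" not in cand
        assert "ATPM" not in cand
        assert "PDC" in cand and "GDH1" in cand


class TestOptgeneSearch:
    CAND = ["GDH1", "GDH2", "GPD", "PPP_OX", "ALD", "hsOMT_a", "E4P_TKT", "SHIK"]

    def test_same_seed_same_output(self, vg0_model, vg0_reference):
        params = GAParams(seed=11, population_size=10, generations=4)
        runs = [
            optgene_search(vg0_model, vg0_reference, "VG_secretion",
                           "glucose_uptake", params, candidates=self.CAND)
            for _ in range(2)
        ]
        assert [dataclasses.asdict(e) for e in runs[0]] == \
            [dataclasses.asdict(e) for e in runs[1]]

    def test_degenerate_ga_keeps_empty_population(self, vg0_model, vg0_reference):
        params = GAParams(seed=3, population_size=6, generations=3,
                          per_bit_mutation=0.0, crossover=0.0, init_bit_prob=0.0)
        out = optgene_search(vg0_model, vg0_reference, "VG_secretion",
                             "glucose_uptake", params, candidates=self.CAND)
        assert len(out) == 1 and out[0].design.is_empty

    def test_recovers_single_knockout_optimum(self, vg0_model, vg0_reference):
        exhaustive = exhaustive_search(vg0_model, vg0_reference, "VG_secretion",
                                       "glucose_uptake", k=1,
                                       candidates=self.CAND, rank_by="bpcy")
        params = GAParams(seed=5, population_size=16, generations=12,
                          max_knockouts=1, per_bit_mutation=0.2)
        ga = optgene_search(vg0_model, vg0_reference, "VG_secretion",
                            "glucose_uptake", params, candidates=self.CAND)
        assert ga[0].bpcy == pytest.approx(exhaustive[0].bpcy, abs=1e-10)

    def test_more_generations_never_hurt(self, vg0_model, vg0_reference):
        """Elitism makes the best fitness non-decreasing in generations."""
        best = []
        for gens in (0, 4, 10):
            params = GAParams(seed=9, population_size=8, generations=gens,
                              max_knockouts=2)
            out = optgene_search(vg0_model, vg0_reference, "VG_secretion",
                                 "glucose_uptake", params, candidates=self.CAND)
            best.append(out[0].bpcy)
        assert best[0] <= best[1] + 1e-12 <= best[2] + 2e-12

    def test_empty_candidates_raise(self, vg0_model, vg0_reference):
        with pytest.raises(ValueError):
            optgene_search(vg0_model, vg0_reference, "VG_secretion",
                           "glucose_uptake", GAParams(seed=1), candidates=[])
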