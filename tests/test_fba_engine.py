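import numpy as np
import pytest

from crossfeed.fba_engine import (
    GROWTH_THRESHOLD,
    SECRETION_CUTOFF,
    costless_secretions,
    secretion_cost,
    solve_alternative_objective,
    solve_growth,
    verify_secretion_uniqueness,
)
from crossfeed.media import apply_medium, build_medium
from crossfeed.model_core import MetaboliteRef, MetabolicModel, Reaction
from crossfeed.toyforge import make_motif_pair, make_organism, make_suite, FERM_SPEC

from conftest import cobra_growth, dense_lp_growth


class TestSolveGrowth:
    def test_ferm_anoxic(self, ferm, glc_medium_anoxic):
        # glc split v+f <= 10 with ATP balance 2f = 2v forces v = 5
        sol = solve_growth(ferm, glc_medium_anoxic)
        assert sol.status == "optimal"
        assert sol.growth_rate == pytest.approx(5.0, rel=1e-9)

    def test_ferm_oxic(self, ferm, glc_medium_oxic):
        # respiration at 10 ATP/glc: 1.2 v <= 10 so v = 25/3
        sol = solve_growth(ferm, glc_medium_oxic)
        assert sol.growth_rate == pytest.approx(25.0 / 3.0, rel=1e-9)

    def test_no_carbon_no_growth(self, ferm):
        med = build_medium(base={"nh4_e"}, carbon_sources=("xyl_e",), oxygen=False)
        sol = solve_growth(ferm, med)
        assert sol.growth_rate == pytest.approx(0.0, abs=1e-9)
        assert not sol.grows

    def test_infeasible_maintenance(self, glc_medium_anoxic):
        from dataclasses import replace

        spec = replace(FERM_SPEC, ngam_min=1.0)
        model = make_organism(spec)
        med = build_medium(base={"nh4_e"}, carbon_sources=("xyl_e",), oxygen=False)
        sol = solve_growth(model, med)  # no ATP source on this medium
        assert sol.status == "infeasible"
        assert sol.growth_rate == 0.0

    def test_steady_state_residual(self, ferm, glc_medium_anoxic):
        sol = solve_growth(ferm, glc_medium_anoxic)
        assert sol.steady_state_residual <= 1e-6


class TestCostlessSecretions:
    def test_anoxic_acetate(self, ferm, glc_medium_anoxic):
        sol, prof = costless_secretions(ferm, glc_medium_anoxic)
        assert sol.growth_rate == pytest.approx(5.0, rel=1e-6)
        assert prof.secretions["ac_e"] == pytest.approx(10.0, rel=1e-6)

    def test_oxic_no_acetate(self, ferm, glc_medium_oxic):
        sol, prof = costless_secretions(ferm, glc_medium_oxic)
        assert sol.growth_rate == pytest.approx(25.0 / 3.0, rel=1e-6)
        assert "ac_e" not in prof
        assert prof.secretions["co2_e"] == pytest.approx(10.0, rel=1e-6)

    def test_no_growth_returns_empty_profile(self, acsp, glc_medium_anoxic):
        sol, prof = costless_secretions(acsp, glc_medium_anoxic)
        assert not sol.grows
        assert len(prof) == 0

    def test_stage2_never_increases_total_flux(self, ferm, glc_medium_oxic):
        stage1 = solve_growth(ferm, glc_medium_oxic)
        stage2, _ = costless_secretions(ferm, glc_medium_oxic)
        assert stage2.total_abs_flux <= stage1.total_abs_flux + 1e-6

    def test_all_recorded_fluxes_above_cutoff(self, ferm, glc_medium_anoxic):
        _, prof = costless_secretions(ferm, glc_medium_anoxic)
        assert all(v >= SECRETION_CUTOFF for v in prof.secretions.values())

    def test_uniqueness_probe(self, ferm, glc_medium_anoxic):
        # anoxic FERM must ferment: both byproducts are non-degenerate
        unique = verify_secretion_uniqueness(ferm, glc_medium_anoxic)
        assert unique == {"ac_e": True, "co2_e": True}


class TestSecretionCost:
    def test_forced_acetate_oxic_is_costly(self, ferm, glc_medium_oxic):
        # 0.5 glc diverted to fermentation: growth 8.0, delta -1/3
        out = secretion_cost(ferm, glc_medium_oxic, "ac_e", 1.0)
        assert out["category"] == "costly"
        assert out["growth_rate"] == pytest.approx(8.0, rel=1e-9)
        assert out["delta_growth"] == pytest.approx(-1.0 / 3.0, rel=1e-6)

    def test_forced_acetate_anoxic_is_costless(self, ferm, glc_medium_anoxic):
        out = secretion_cost(ferm, glc_medium_anoxic, "ac_e", 10.0)
        assert out["category"] == "costless"
        assert out["growth_rate"] == pytest.approx(5.0, rel=1e-9)

    def test_unsynthesizable_is_infeasible(self, ferm, glc_medium_anoxic):
        # pi has an exchange but no production path
        out = secretion_cost(ferm, glc_medium_anoxic, "pi_e", 1.0)
        assert out["category"] == "infeasible"

    def test_unknown_metabolite(self, ferm, glc_medium_anoxic):
        with pytest.raises(ValueError, match="exchange"):
            secretion_cost(ferm, glc_medium_anoxic, "unobtainium_e", 1.0)

    def test_costlessness_property_on_motif_pairs(self):
        # the defining inequality: re-forcing any reported secretion at its
        # reported flux must not reduce growth
        for code in ("C1a", "N1b", "M1b"):
            m1, m2, medium, _ = make_motif_pair(code)
            for model in (m1, m2):
                sol, prof = costless_secretions(model, medium)
                if not sol.grows:
                    continue
                for met, flux in prof.secretions.items():
                    out = secretion_cost(model, medium, met, flux)
                    assert out["category"] in ("costless", "beneficial"), (
                        code,
                        model.model_id,
                        met,
                    )


class TestAlternativeObjectives:
    def test_min_biomass_pins_growth(self, ferm, glc_medium_anoxic):
        sol, prof = solve_alternative_objective(ferm, glc_medium_anoxic, "min_biomass")
        assert sol.growth_rate == pytest.approx(0.01, rel=1e-6)
        # any ATP demand forces fermentation, so acetate is still secreted
        assert "ac_e" in prof

    def test_max_growth_equivalence(self, ferm, glc_medium_anoxic):
        a_sol, a_prof = solve_alternative_objective(ferm, glc_medium_anoxic, "max_growth")
        b_sol, b_prof = costless_secretions(ferm, glc_medium_anoxic)
        assert a_sol.growth_rate == pytest.approx(b_sol.growth_rate, rel=1e-9)
        assert a_prof.secretions == b_prof.secretions

    def test_max_atp(self, ferm, glc_medium_oxic):
        sol, _ = solve_alternative_objective(ferm, glc_medium_oxic, "max_atp")
        assert sol.status == "optimal"
        assert sol.fluxes["NGAM"] > 0
        assert sol.growth_rate >= 0.01 - 1e-9

    def test_missing_atp_maintenance_errors(self, glc_medium_anoxic):
        model = MetabolicModel(
            model_id="noatp",
            metabolites=[
                MetaboliteRef("glc_e", external=True),
                MetaboliteRef("glc_c"),
            ],
            reactions=[
                Reaction("EX_glc_e", {"glc_e": -1.0}, -10, 1000, is_exchange=True),
                Reaction("t_glc", {"glc_e": -1.0, "glc_c": 1.0}, -1000, 1000),
                Reaction("BIOMASS", {"glc_c": -1.0}, 0, 1000),
            ],
            biomass_reaction_id="BIOMASS",
        )
        med = build_medium(base=set(), carbon_sources=("glc_e",), oxygen=False)
        with pytest.raises(ValueError, match="ATP maintenance"):
            solve_alternative_objective(model, med, "max_atp")

    def test_unknown_objective(self, ferm, glc_medium_anoxic):
        with pytest.raises(ValueError, match="objective"):
            solve_alternative_objective(ferm, glc_medium_anoxic, "max_entropy")


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [3, 17])
    def test_dense_lp_oracle(self, seed):
        models, medium, carbons = make_suite(4, 4, seed=seed)
        rng = np.random.default_rng(seed)
        for model in models:
            pair = tuple(rng.choice(carbons, size=2, replace=False))
            med = build_medium(base={"nh4_e"}, carbon_sources=pair, oxygen=bool(rng.integers(2)))
            bounded = apply_medium(model, med)
            ours = solve_growth(bounded).growth_rate
            assert ours == pytest.approx(dense_lp_growth(bounded), abs=1e-6)

    def test_cobra_glpk_oracle(self, ferm, glc_medium_anoxic, glc_medium_oxic):
        for med in (glc_medium_anoxic, glc_medium_oxic):
            bounded = apply_medium(ferm, med)
            assert solve_growth(bounded).growth_rate == pytest.approx(
                cobra_growth(bounded), abs=1e-6
            )

    def test_growth_threshold_config(self):
        assert GROWTH_THRESHOLD == 1e-6
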