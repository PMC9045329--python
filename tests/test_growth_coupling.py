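"""Herbert-Pirt coupling: maintenance, biomass flux, yields, balances."""

from dataclasses import replace

import pytest

from methanomod.dynamics import solve_steady_state
from methanomod.growth import (growth_rate_from_fluxes,
                               maintenance_reaction, yield_report)
from methanomod.network import BiomassStoichiometry, CellParameters

CELL = CellParameters(radius=1e-6, capacitance=1e-13, w_prot=1e-12,
                      dry_mass=2e-12, temperature=310.15,
                      maintenance_atp=3e-7)
BIO = BiomassStoichiometry(atp_per_g=0.14, fdred_per_g=1.1e-2,
                           f420h2_per_g=1.1e-2, accoa_per_g=1.4e-2,
                           y_p_ch3oh=5.0, y_p_ch4=6.0)


class TestHerbertPirt:
    def test_maintenance_is_rate_times_dry_mass(self):
        assert maintenance_reaction(CELL) == pytest.approx(3e-7 * 2e-12)
        zero = replace(CELL, maintenance_atp=0.0)
        assert maintenance_reaction(zero) == 0.0

    def test_surplus_converts_at_atp_cost(self):
        # hypothetical surplus of 0.14 mol ATP/s at 0.14 mol ATP per gram
        g = growth_rate_from_fluxes(0.14 + maintenance_reaction(CELL),
                                    maintenance_reaction(CELL), BIO, CELL)
        assert g.biomass_flux == pytest.approx(1.0)
        assert g.drains["accoa"] == pytest.approx(1.4e-2)
        assert g.mu == pytest.approx(1.0 / CELL.dry_mass)

    def test_maintenance_only_regime(self):
        m = maintenance_reaction(CELL)
        g = growth_rate_from_fluxes(m, m, BIO, CELL)
        assert g.biomass_flux == 0.0 and g.mu == 0.0
        g2 = growth_rate_from_fluxes(0.5 * m, m, BIO, CELL)
        assert g2.biomass_flux == 0.0

    def test_zero_atp_cost_is_error(self):
        bad = replace(BIO, atp_per_g=0.0)
        with pytest.raises(ValueError):
            growth_rate_from_fluxes(1.0, 0.0, bad, CELL)


class TestYields:
    def test_catabolic_stoichiometry_without_biosynthesis(self, model):
        # no maintenance, no biomass demands: 4/3 methanol ->
        # 2/3 H2O + 1/3 CO2 + CH4, so 0.25 CO2 and 0.75 CH4 per methanol
        pure = model.copy()
        pure.cell = replace(pure.cell, maintenance_atp=0.0)
        pure.biomass = replace(pure.biomass, fdred_per_g=0.0,
                               f420h2_per_g=0.0, accoa_per_g=0.0)
        for rxn in pure.reactions:
            if rxn.kind == "biomass":
                rxn.stoich = {"atp": -0.14, "adp": 0.14, "pi": 0.14,
                              "biomass": 1.0}
        ss = solve_steady_state(pure, polish=True)
        assert ss.converged
        y = yield_report(ss)
        assert y["co2_per_methanol"] == pytest.approx(0.25, abs=1e-4)
        assert y["ch4_per_methanol"] == pytest.approx(0.75, abs=1e-4)

    def test_yields_below_catabolic_with_drains(self, ss100):
        y = yield_report(ss100)
        assert 0 < y["co2_per_methanol"] < 0.25
        assert 0 < y["ch4_per_methanol"] < 0.75

    def test_zero_influx_is_error(self, ss100):
        broken = replace(ss100, fluxes={"ch3oh_c": 0.0})
        with pytest.raises(ValueError):
            yield_report(broken)

    def test_carbon_balance(self, model, ss100):
        influx = ss100.fluxes["ch3oh_c"]
        effluxes = -ss100.fluxes["co2_c"] - ss100.fluxes["ch4_c"]
        drained = 2 * model.biomass.accoa_per_g \
            * ss100.velocities["biomass"]
        assert influx == pytest.approx(effluxes + drained, rel=1e-6)

    def test_net_rate_decomposition(self, model, ss100):
        maint_equiv = model.cell.maintenance_atp / model.biomass.atp_per_g
        assert ss100.mu_net == pytest.approx(ss100.mu - maint_equiv,
                                             rel=1e-9)
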