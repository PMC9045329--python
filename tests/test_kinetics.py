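"""Thermodynamic rate law: free energies, velocities, diffusive fluxes."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from methanomod.dynamics import MetabolicState
from methanomod.kinetics import (diffusive_flux, reaction_gibbs,
                                 reaction_velocity, saturation_factor)
from methanomod.network import CellParameters, DiffusionProcess, \
    EnzymeReaction

CELL = CellParameters(radius=1e-6, capacitance=1e-13, w_prot=1.0,
                      dry_mass=1.0, temperature=310.15,
                      maintenance_atp=0.0)


def _rxn(**kw):
    base = dict(id="R", stoich={"s": -1, "p": 1},
                km={"s": 1e-3, "p": 1e-3}, kcat=1.0, phi=1.0, keq=10.0,
                chi=1)
    base.update(kw)
    return EnzymeReaction(**base)


def _state(s, p, psi=0.0):
    return MetabolicState({"s": s, "p": p}, psi)


class TestGibbs:
    def test_equilibrium_is_zero(self):
        rxn = _rxn(keq=10.0)
        th = reaction_gibbs(rxn, _state(1e-3, 1e-2), CELL)  # Q = 10 = K
        assert th.delta_g == pytest.approx(0.0, abs=1e-9)

    def test_rt_ln10_when_q_tenfold_above_k(self):
        # Q = 10 K at 310.15 K: dG = RT ln 10 = +5.938 kJ/mol
        rxn = _rxn(keq=1.0)
        th = reaction_gibbs(rxn, _state(1e-3, 1e-2), CELL)
        assert th.delta_g == pytest.approx(5937.6, rel=1e-4)

    def test_charge_translocation_term(self):
        # c_C = 2, dpsi = 135 mV: 2 F dpsi = 26.05 kJ/mol
        rxn = _rxn(keq=1.0, charge_out=2)
        th = reaction_gibbs(rxn, _state(1e-3, 1e-3, psi=0.135), CELL)
        assert th.charge_term == pytest.approx(2 * 96485 * 0.135)
        assert th.delta_g == pytest.approx(26051.0, rel=1e-4)

    def test_nonpositive_concentration_is_domain_error(self):
        with pytest.raises(ValueError, match="s"):
            reaction_gibbs(_rxn(), _state(0.0, 1e-3), CELL)


class TestVelocity:
    def test_half_occupancy_full_driving_force(self):
        # C_S = Km, no product, strongly downhill: v = 0.5 Vmax
        rxn = _rxn(keq=1e12)
        v = reaction_velocity(rxn, _state(1e-3, 1e-15), CELL)
        assert v.v == pytest.approx(0.5 * CELL.w_prot * rxn.kcat * rxn.phi,
                                    rel=1e-3)

    def test_zero_at_equilibrium(self):
        v = reaction_velocity(_rxn(keq=10.0), _state(1e-3, 1e-2), CELL)
        assert v.v == pytest.approx(0.0, abs=1e-15)

    def test_saturation_limit_is_vmax(self):
        rxn = _rxn(keq=1e12)
        v = reaction_velocity(rxn, _state(10.0, 1e-15), CELL)
        assert v.v == pytest.approx(CELL.w_prot * rxn.kcat * rxn.phi,
                                    rel=1e-3)

    def test_thermo_factor_linear_near_equilibrium_chi1(self):
        # for chi = 1 the factor is exactly 1 - Q/K (mass-action limit)
        rxn = _rxn(keq=10.0)
        st_ = _state(1e-3, 9.9e-3)
        v = reaction_velocity(rxn, st_, CELL)
        q = st_.conc["p"] / st_.conc["s"]
        assert v.thermo_factor == pytest.approx(1 - q / rxn.keq, rel=1e-12)

    def test_saturation_monotone_in_substrate(self):
        rxn = _rxn()
        sats = [saturation_factor(rxn, {"s": c, "p": 1e-4})
                for c in (1e-5, 1e-4, 1e-3, 1e-2)]
        assert all(a < b for a, b in zip(sats, sats[1:]))

    def test_convenience_form_factorizes(self):
        rxn = EnzymeReaction("R", {"a": -1, "b": -1, "p": 1},
                             km={"a": 1e-3, "b": 1e-4, "p": 1e-3},
                             kcat=1.0, phi=1.0, keq=1e9, chi=1,
                             rate_law="convenience")
        conc = {"a": 1e-3, "b": 1e-4, "p": 1e-9}
        sat = saturation_factor(rxn, conc)
        assert sat == pytest.approx(0.5 * 0.5 / (1 + 1e-6), rel=1e-6)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(s=st.floats(1e-9, 1.0), p=st.floats(1e-9, 1.0),
       keq=st.floats(1e-6, 1e6), psi=st.floats(-0.2, 0.2),
       cc=st.sampled_from([0.0, 1.0, -2.0]),
       chi=st.sampled_from([1, 2, 4]))
def test_sign_law(s, p, keq, psi, cc, chi):
    """v > 0 iff dG < 0, v < 0 iff dG > 0, v = 0 iff dG = 0."""
    rxn = _rxn(keq=keq, charge_out=cc, chi=chi)
    state = _state(s, p, psi)
    dg = reaction_gibbs(rxn, state, CELL).delta_g
    v = reaction_velocity(rxn, state, CELL).v
    assert v * dg <= 0
    if dg == 0:
        assert v == 0
    elif abs(dg) > 1e-6:
        assert v != 0


class TestDiffusion:
    def test_no_gradient_no_flux(self):
        proc = DiffusionProcess("s", 1e-9, 1e-3)
        assert diffusive_flux(proc, _state(1e-3, 0), CELL) == 0.0

    def test_direct_evaluation(self):
        # D = 1e-9 m2/s, r = 1e-6 m, dC = 1 mol/m3: J = 4 pi D r dC
        proc = DiffusionProcess("s", 1e-9, 2e-3)  # delta 1e-3 M = 1 mol/m3
        j = diffusive_flux(proc, _state(1e-3, 0), CELL)
        assert j == pytest.approx(1.2566e-14, rel=1e-4)

    def test_efflux_antisymmetric(self):
        proc_in = DiffusionProcess("s", 1e-9, 2e-3)
        proc_out = DiffusionProcess("s", 1e-9, 0.0)
        j_in = diffusive_flux(proc_in, _state(1e-3, 0), CELL)
        j_out = diffusive_flux(proc_out, _state(1e-3, 0), CELL)
        assert j_out < 0 < j_in
        assert j_in == pytest.approx(-j_out)  # gradients +1 vs -1 mol/m3
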