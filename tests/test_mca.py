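"""Control analysis against the closed-form chain oracle and invariants."""

import numpy as np
import pytest

from methanomod.dynamics import solve_steady_state
from methanomod.mca import (control_profile, flux_control_coefficient,
                            response_coefficient)
from methanomod.synthetic import toy_linear_chain


def test_single_enzyme_has_full_control():
    model, oracle = toy_linear_chain(1)
    eps = flux_control_coefficient(model, "E1", objective="flux:E1")
    assert eps == pytest.approx(1.0, abs=2e-3)
    assert oracle.control_coefficients[0] == 1.0


def test_chain_control_matches_closed_form():
    model, oracle = toy_linear_chain(3, a=(1e-3, 2e-3, 5e-4),
                                     q=(5.0, 2.0, 10.0))
    base = solve_steady_state(model, polish=True)
    for i in range(3):
        central = flux_control_coefficient(
            model, f"E{i + 1}", objective="flux:E2", baseline=base,
            central=True)
        assert central == pytest.approx(
            oracle.control_coefficients[i], abs=1e-3)
        forward = flux_control_coefficient(
            model, f"E{i + 1}", objective="flux:E2", baseline=base)
        assert forward == pytest.approx(
            oracle.fd_control_coefficient(i), abs=1e-4)


def test_scale_invariance_of_chain_control():
    _, o1 = toy_linear_chain(2, a=(1e-3, 5e-4), q=(4.0, 9.0))
    _, o2 = toy_linear_chain(2, a=(2e-3, 1e-3), q=(4.0, 9.0))
    assert o2.flux == pytest.approx(2 * o1.flux, rel=1e-12)
    assert np.allclose(o1.control_coefficients, o2.control_coefficients)


def test_summation_theorem_on_toy_chain():
    model, _ = toy_linear_chain(3, a=(1e-3, 2e-3, 5e-4), q=(5., 2., 10.))
    base = solve_steady_state(model, polish=True)
    total = sum(flux_control_coefficient(model, f"E{i+1}",
                                         objective="flux:E2",
                                         baseline=base)
                for i in range(3))
    assert total == pytest.approx(1.0, abs=0.02)


def test_delta_halving_robustness():
    model, _ = toy_linear_chain(2, a=(1e-3, 5e-4), q=(4.0, 9.0))
    base = solve_steady_state(model, polish=True)
    for rid in ("E1", "E2"):
        e1 = flux_control_coefficient(model, rid, delta=0.01,
                                      objective="flux:E1", baseline=base)
        e2 = flux_control_coefficient(model, rid, delta=0.005,
                                      objective="flux:E1", baseline=base)
        assert e2 == pytest.approx(e1, rel=0.05)


def test_saturated_pool_has_negligible_response(model, ss100):
    # the CoA pool saturates its consumers at 100 mM methanol
    eps = response_coefficient(model, "CoA", baseline=ss100)
    assert abs(eps) < 0.01


def test_profile_bookkeeping(model):
    prof = control_profile(model, grid=[1e-4],
                           components=["MTA", "MCR", "CoM", "ch3oh_c"])
    assert set(prof.component_kind) == {"MTA", "MCR", "CoM", "ch3oh_c"}
    assert prof.component_kind["CoM"] == "moiety"
    assert prof.component_kind["ch3oh_c"] == "diffusion"
    assert not prof.failures
    assert len(prof.series("MTA")) == 1
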