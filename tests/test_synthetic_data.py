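"""The parameter fixture and toy-network generators."""

import numpy as np
import pandas as pd
import pytest

from methanomod.synthetic import (ToyChainOracle, fixture_barkeri,
                                  perturb_fixture, toy_linear_chain)


def _value(table, rid, kind, sp=""):
    row = table[(table.reaction_id == rid) & (table.param_kind == kind)
                & (table.species_id == sp)]
    assert len(row) == 1, (rid, kind, sp)
    return float(row.value.iloc[0])


class TestFixture:
    def test_published_magnitudes_present(self):
        t = fixture_barkeri()
        assert _value(t, "MCR", "km", "cob") == pytest.approx(59e-6)
        assert _value(t, "MTA", "km", "ch3oh_c") == pytest.approx(0.05)
        assert _value(t, "CoB", "moiety_total") == pytest.approx(1.7e-3)
        assert _value(t, "atp", "met_conc_init") == pytest.approx(10e-3)
        assert _value(t, "adp", "met_conc_init") == pytest.approx(1e-3)
        assert _value(t, "pi", "met_conc_init") == pytest.approx(10e-3)
        assert _value(t, "biomass_stoich", "bio_atp_per_g") \
            == pytest.approx(0.14)
        assert _value(t, "biomass_stoich", "bio_accoa_per_g") \
            == pytest.approx(1.4e-2)
        assert _value(t, "cell", "cell_phi_membrane_total") \
            == pytest.approx(0.10)

    def test_clamped_species_flagged(self):
        t = fixture_barkeri()
        for sp in ("atp", "adp", "pi", "ch3oh_env", "co2_env", "ch4_env"):
            assert _value(t, sp, "met_fixed") == 1

    def test_provenance_flags(self):
        t = fixture_barkeri()
        assert set(t.provenance) == {"printed", "calibrated"}
        printed = t[t.provenance == "printed"]
        assert len(printed) >= 10


class TestPerturb:
    def test_zero_cv_is_identity(self):
        t = fixture_barkeri()
        out = perturb_fixture(t, seed=5, cv=0.0)
        pd.testing.assert_frame_equal(out, t)

    def test_deterministic_per_seed(self):
        t = fixture_barkeri()
        a = perturb_fixture(t, seed=11, cv=0.1)
        b = perturb_fixture(t, seed=11, cv=0.1)
        pd.testing.assert_frame_equal(a, b)
        c = perturb_fixture(t, seed=12, cv=0.1)
        assert not a.equals(c)

    def test_printed_rows_protected(self):
        t = fixture_barkeri()
        out = perturb_fixture(t, seed=3, cv=0.2, protect_printed=True)
        mask = t.provenance == "printed"
        assert (out[mask].value == t[mask].value).all()
        kinetic = (t.param_kind == "kcat") & ~mask
        assert (out[kinetic].value != t[kinetic].value).any()

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            perturb_fixture(fixture_barkeri(), seed=0, cv=-0.1)


class TestToyChain:
    def test_single_enzyme_full_control(self):
        _, oracle = toy_linear_chain(1)
        assert oracle.control_coefficients.tolist() == [1.0]

    def test_doubling_capacity_doubles_flux_not_control(self):
        _, o1 = toy_linear_chain(3, a=(1e-3, 2e-3, 5e-4), q=(5., 2., 10.))
        _, o2 = toy_linear_chain(3, a=(2e-3, 4e-3, 1e-3), q=(5., 2., 10.))
        assert o2.flux == pytest.approx(2 * o1.flux, rel=1e-12)
        assert np.allclose(o1.control_coefficients,
                           o2.control_coefficients, rtol=1e-12)

    def test_irreversible_limit_concentrates_control_upstream(self):
        _, o = toy_linear_chain(2, a=(1e-3, 1e-3), q=(1e9, 1e9))
        assert o.control_coefficients[0] == pytest.approx(1.0, abs=1e-6)

    def test_summation_exact(self):
        _, o = toy_linear_chain(4, a=(1e-3, 2e-3, 5e-4, 3e-3),
                                q=(5.0, 2.0, 7.0, 3.0))
        assert o.control_coefficients.sum() == pytest.approx(1.0,
                                                             rel=1e-12)

    def test_bad_sizes_rejected(self):
        with pytest.raises(ValueError):
            toy_linear_chain(0)
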