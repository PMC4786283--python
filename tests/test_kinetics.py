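"""Rate-law forms, Vmax solving, and the packed fast path."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from emra.ensemble import draw_parameters
from emra.errors import ConfigurationError
from emra.fixtures import get_fixture
from emra.kinetics import (
    PackedKinetics,
    ParameterSet,
    ode_rhs,
    rate,
    rate_vector,
    solve_vmax,
)
from emra.network import MetabolicNetwork, Regulator

from conftest import unit_kbar


def _gk_network(regulated):
    regs = [Regulator("GK", "G6P")] if regulated else []
    return MetabolicNetwork(
        metabolite_ids=["Glc", "ATP", "G6P", "ADP"],
        reaction_ids=["IN", "GK", "OUT", "ADK"],
        S=np.array([[1, -1, 0, 0], [0, -1, 0, 1], [0, 1, -1, 0], [0, 1, 0, -1]]),
        reversible=np.array([False] * 4),
        kind=["input_exchange", "enzymatic", "output_exchange", "enzymatic"],
        vref=np.ones(4),
        regulators=regs,
    )


class TestGlucokinaseForms:
    """The bi-substrate instance must match the published enzyme equations."""

    def test_unregulated_rate_is_vmax_over_four_at_reference(self):
        net = _gk_network(False)
        p = ParameterSet(kbar=unit_kbar(net), vmax={"GK": 1.0})
        # denominator KGlc/Glc + KATP/ATP + KATP KGlc/(ATP Glc) + 1 = 4
        assert rate(net, "GK", p, np.ones(4)) == pytest.approx(0.25, abs=1e-12)

    def test_g6p_inhibition_adds_one_denominator_unit(self):
        net = _gk_network(True)
        p = ParameterSet(
            kbar=unit_kbar(net), kibar={("GK", "G6P"): 1.0}, vmax={"GK": 1.0}
        )
        assert rate(net, "GK", p, np.ones(4)) == pytest.approx(0.2, abs=1e-12)

    def test_zero_inhibitor_recovers_unregulated_form(self):
        reg, unreg = _gk_network(True), _gk_network(False)
        x = np.array([1.7, 0.4, 0.0, 1.2])
        p_reg = ParameterSet(
            kbar=unit_kbar(reg), kibar={("GK", "G6P"): 0.3}, vmax={"GK": 2.0}
        )
        p_unreg = ParameterSet(kbar=unit_kbar(unreg), vmax={"GK": 2.0})
        assert rate(reg, "GK", p_reg, x) == pytest.approx(
            rate(unreg, "GK", p_unreg, x), rel=1e-14
        )

    def test_negative_concentration_rejected(self):
        net = _gk_network(False)
        p = ParameterSet(kbar=unit_kbar(net), vmax={"GK": 1.0})
        with pytest.raises(ValueError, match="negative"):
            rate(net, "GK", p, np.array([-0.1, 1, 1, 1]))

    def test_missing_parameter_is_configuration_error(self):
        net = _gk_network(False)
        p = ParameterSet(kbar={("GK", "Glc"): 1.0}, vmax={"GK": 1.0})
        with pytest.raises(ConfigurationError, match="kbar"):
            rate(net, "GK", p, np.ones(4))


class TestSolveVmax:
    def test_unregulated_gk_vmax_is_four(self):
        net = _gk_network(False)
        p = solve_vmax(net, ParameterSet(kbar=unit_kbar(net)))
        assert p.vmax["GK"] == pytest.approx(4.0, abs=1e-12)

    def test_reversible_uni_uni_vmax_is_six(self, rev_uni_uni):
        # D(1) = 3, N(1) = (1 - rho) = 0.5 -> Vmax = 6
        p = solve_vmax(
            rev_uni_uni,
            ParameterSet(kbar=unit_kbar(rev_uni_uni), rho={"R": 0.5}),
        )
        assert p.vmax["R"] == pytest.approx(6.0, abs=1e-12)

    @pytest.mark.parametrize(
        "name", ["mcc_mixed_1_3", "purge_valve_phb", "glucose_isoprene_gkreg"]
    )
    def test_reference_rate_equals_vref_for_any_draw(self, name):
        net = get_fixture(name)
        rng = np.random.default_rng(5)
        for _ in range(5):
            p = solve_vmax(net, draw_parameters(net, rng))
            v = rate_vector(net, p, np.ones(net.n_metabolites))
            np.testing.assert_allclose(v, net.vref, atol=1e-12)

    def test_solving_is_idempotent(self, rev_uni_uni):
        p1 = solve_vmax(
            rev_uni_uni,
            ParameterSet(kbar=unit_kbar(rev_uni_uni), rho={"R": 0.37}),
        )
        p2 = solve_vmax(rev_uni_uni, p1)
        assert p1.vmax == p2.vmax

    def test_reversible_net_reference_rate_positive(self, rev_uni_uni):
        # by the gamma construction the reverse term is rho x forward at 1
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = solve_vmax(rev_uni_uni, draw_parameters(rev_uni_uni, rng))
            assert rate(rev_uni_uni, "R", p, np.ones(2)) > 0


class TestOdeRhs:
    def test_reference_state_is_fixed_point(self, mcc_mixed):
        p = solve_vmax(
            mcc_mixed, draw_parameters(mcc_mixed, np.random.default_rng(1))
        )
        dx = ode_rhs(mcc_mixed, p, np.ones(10))
        assert np.max(np.abs(dx)) < 1e-9

    def test_batch_substrate_initially_consumed(self, mcc_mixed):
        from emra.simulate import to_batch

        p = solve_vmax(
            mcc_mixed, draw_parameters(mcc_mixed, np.random.default_rng(2))
        )
        _net, p_b, x0 = to_batch(mcc_mixed, p, "CH2O", 200.0)
        dx = ode_rhs(mcc_mixed, p_b, x0)
        assert dx[mcc_mixed.metabolite_index("CH2O")] < 0

    def test_closed_system_conserves_total(self, closed_ab):
        p = ParameterSet(
            kbar={("R", "A"): 2.0, ("R", "B"): 0.5}, rho={"R": 0.3},
            vmax={"R": 1.7},
        )
        x = np.array([1.4, 0.6])
        assert ode_rhs(closed_ab, p, x).sum() == pytest.approx(0.0, abs=1e-14)


class TestPackedKinetics:
    @pytest.mark.parametrize(
        "name", ["mcc_mixed_1_3", "chimeric_glycolysis", "glucose_isoprene_gkreg"]
    )
    def test_packed_matches_reference_implementation(self, name):
        net = get_fixture(name)
        rng = np.random.default_rng(7)
        p = solve_vmax(net, draw_parameters(net, rng))
        pk = PackedKinetics(net, p)
        for _ in range(10):
            x = rng.uniform(0.0, 5.0, net.n_metabolites)
            np.testing.assert_allclose(
                pk.rates(x), rate_vector(net, p, x), rtol=1e-12, atol=1e-14
            )

    def test_scale_vmax_is_in_place_multiplier(self, mcc_mixed):
        p = solve_vmax(
            mcc_mixed, draw_parameters(mcc_mixed, np.random.default_rng(3))
        )
        pk = PackedKinetics(mcc_mixed, p)
        before = pk.vmax.copy()
        pk.scale_vmax(["Fpk", "Xpk"], 2.0)
        i_f = mcc_mixed.reaction_index("Fpk")
        assert pk.vmax[i_f] == pytest.approx(2 * before[i_f])

    @given(
        x=st.floats(0.0, 50.0),
        k=st.floats(0.1, 10.0),
        other=st.floats(0.0, 10.0),
    )
    def test_irreversible_rate_monotone_in_substrate(self, x, k, other):
        net = _gk_network(False)
        p = ParameterSet(
            kbar={("GK", "Glc"): k, ("GK", "ATP"): 1.0, ("OUT", "G6P"): 1.0,
                  ("ADK", "ADP"): 1.0},
            vmax={"GK": 3.0},
        )
        lo = rate(net, "GK", p, np.array([x, other, 1, 1]))
        hi = rate(net, "GK", p, np.array([x + 0.5, other, 1, 1]))
        assert hi >= lo - 1e-12
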