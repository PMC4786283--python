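"""Jacobian accuracy, stability classification, steady-state location."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from emra.ensemble import draw_parameters
from emra.fixtures import make_toy_chain
from emra.kinetics import PackedKinetics, ParameterSet, solve_vmax
from emra.stability import (
    EPS_STRUCT,
    classify_stability,
    find_steady_state,
    jacobian,
    packed_find_steady_state,
    reference_stability,
)

from conftest import unit_kbar


class TestJacobian:
    def test_single_species_closed_form(self, single_species):
        net, p = single_species
        # d/dx [1 - Vmax x/(K+x)] at x=1 with solved Vmax=2, K=1 -> -1/2
        J = jacobian(net, p, np.ones(1))
        assert J[0, 0] == pytest.approx(-0.5, rel=1e-6)

    def test_matches_analytic_mm_derivative(self):
        # out-flux derivative -Vmax K / (K + x)^2 for arbitrary Vmax, K
        net = make_toy_chain(1)
        p = ParameterSet(kbar={("OUT", "M1"): 0.7}, vmax={"IN": 1.0, "OUT": 4.0})
        x = np.array([1.3])
        J = jacobian(net, p, x)
        k = 0.7
        expected = -4.0 * k / (k + x[0]) ** 2
        assert J[0, 0] == pytest.approx(expected, rel=1e-6)

    def test_near_first_order_chain_matches_rate_matrix(self):
        # with Kbar >> x the chain is linear: dMi/dt = ci-1 M(i-1) - ci Mi
        net = make_toy_chain(3)
        kbar = {("E1", "M1"): 10.0, ("E2", "M2"): 10.0, ("OUT", "M3"): 10.0}
        p = solve_vmax(net, ParameterSet(kbar=kbar))
        J = jacobian(net, p, np.ones(3))
        # first-order rate constant of each consuming step: Vmax/K/(1+1/K)^..
        # at x=1, d rate/dx = Vmax*(1/K)/(1+x/K)^2
        rates = [p.vmax["E1"], p.vmax["E2"], p.vmax["OUT"]]
        c = [v * (1 / 10.0) / (1 + 1 / 10.0) ** 2 for v in rates]
        expected = np.array(
            [[-c[0], 0, 0], [c[0], -c[1], 0], [0, c[1], -c[2]]]
        )
        assert np.allclose(J, expected, rtol=0.1)

    def test_moiety_rows_sum_to_zero(self, purge_valve):
        from emra.network import conserved_moieties

        p = solve_vmax(
            purge_valve, draw_parameters(purge_valve, np.random.default_rng(4))
        )
        J = jacobian(purge_valve, p, np.ones(8))
        basis = conserved_moieties(purge_valve)
        assert np.max(np.abs(basis.vectors @ J)) < 1e-6


class TestClassifyStability:
    def test_negative_scalar_is_stable(self):
        lead, stable = classify_stability(np.array([[-1.0]]))
        assert stable and lead == pytest.approx(-1.0)

    def test_positive_scalar_is_unstable(self):
        _lead, stable = classify_stability(np.array([[0.5]]))
        assert not stable

    def test_conservation_zero_is_excluded(self):
        # closed A<->B with unit rates: eigenvalues {0, -2}
        J = np.array([[-1.0, 1.0], [1.0, -1.0]])
        lead, stable = classify_stability(J, moieties=1)
        assert stable and lead == pytest.approx(-2.0)

    def test_zero_mode_without_moiety_is_marginal_not_stable(self):
        J = np.array([[-1.0, 1.0], [1.0, -1.0]])
        _lead, stable = classify_stability(J, moieties=0)
        assert not stable

    @given(
        arrays(
            np.float64,
            (4, 4),
            elements=st.floats(-2, 2, allow_nan=False),
        )
    )
    def test_symmetric_negative_definite_always_stable(self, A):
        J = -(A @ A.T) - 0.1 * np.eye(4)
        _lead, stable = classify_stability(J)
        assert stable


class TestFindSteadyState:
    def test_reference_point_returns_immediately(self, mcc_mixed):
        from emra.ensemble import sample_constrained

        p = sample_constrained(mcc_mixed, 1, seed=6).members[0]
        rec = find_steady_state(mcc_mixed, p, np.ones(10))
        assert rec.converged and rec.stable
        np.testing.assert_allclose(rec.xbar, 1.0, atol=1e-7)

    def test_single_species_closed_form_root(self):
        # constant input 1 vs MM output 4x/(1+x): steady state at x = 1/3
        net = make_toy_chain(1)
        p = ParameterSet(kbar={("OUT", "M1"): 1.0}, vmax={"IN": 1.0, "OUT": 4.0})
        rec = find_steady_state(net, p, np.array([0.2]))
        assert rec.converged
        assert rec.xbar[0] == pytest.approx(1.0 / 3.0, abs=1e-8)

    def test_no_steady_state_reports_nonconverged(self):
        # input above the sink's maximal capacity: no root exists
        net = make_toy_chain(1)
        p = ParameterSet(kbar={("OUT", "M1"): 1.0}, vmax={"IN": 5.0, "OUT": 4.0})
        rec = find_steady_state(net, p, np.ones(1))
        assert not rec.converged and not rec.stable

    def test_permutation_equivariance(self, purge_valve):
        # well-conditioned system with a locally unique root: the located
        # steady state must not depend on metabolite ordering
        from emra.ensemble import sample_constrained

        rng = np.random.default_rng(8)
        net = purge_valve
        p = sample_constrained(net, 1, seed=8).members[0]
        x0 = np.ones(8)
        x0[net.metabolite_index("Pyr")] = 0.8
        x0[net.metabolite_index("NADH")] = 1.2
        x0[net.metabolite_index("NAD")] = 0.8
        rec = find_steady_state(net, p, x0)

        perm = rng.permutation(8)
        doc = net.to_dict()
        doc["metabolites"] = [net.metabolite_ids[i] for i in perm]
        from emra.network import MetabolicNetwork

        net_p = MetabolicNetwork.from_dict(doc)
        x0_p = np.empty(8)
        for met in net.metabolite_ids:
            x0_p[net_p.metabolite_index(met)] = x0[net.metabolite_index(met)]
        rec_p = find_steady_state(net_p, p, x0_p)
        assert rec.converged and rec_p.converged
        for met in net.metabolite_ids:
            i, ip = net.metabolite_index(met), net_p.metabolite_index(met)
            assert rec.xbar[i] == pytest.approx(rec_p.xbar[ip], abs=1e-6)

    def test_matches_brute_force_grid_on_small_networks(self):
        # independent oracle: dense grid search + local refinement, <= 2 mets
        net = make_toy_chain(2)
        p = solve_vmax(
            net,
            ParameterSet(
                kbar={("E1", "M1"): 2.0, ("OUT", "M2"): 0.5}
            ),
        )
        pk = PackedKinetics(net, p)
        grid = np.linspace(0.0, 5.0, 201)
        best, best_norm = None, np.inf
        for a, b in itertools.product(grid, grid):
            norm = np.max(np.abs(pk.rhs(0.0, np.array([a, b]))))
            if norm < best_norm:
                best, best_norm = np.array([a, b]), norm
        from scipy.optimize import fsolve

        refined = fsolve(lambda x: pk.rhs(0.0, np.maximum(x, 0)), best)
        rec = find_steady_state(net, p, np.array([3.0, 3.0]))
        assert rec.converged
        np.testing.assert_allclose(rec.xbar, refined, atol=1e-6)

    def test_reference_stability_convenience(self, mcc_mixed):
        p = solve_vmax(
            mcc_mixed, draw_parameters(mcc_mixed, np.random.default_rng(9))
        )
        lead, stable = reference_stability(mcc_mixed, p)
        assert np.isfinite(lead)
        assert stable == (lead < -EPS_STRUCT)
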