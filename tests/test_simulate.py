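"""Batch conversion, time-domain integration, production diagnostics."""

import numpy as np
import pytest

from emra.continuation import continue_parameter
from emra.ensemble import sample_constrained, sample_unconstrained
from emra.errors import ConfigurationError
from emra.fixtures import get_fixture, make_toy_chain
from emra.kinetics import ParameterSet, PackedKinetics, solve_vmax
from emra.network import conserved_moieties
from emra.simulate import (
    batch_run,
    classify_productive,
    fed_batch,
    integrate,
    productive_member,
    to_batch,
)


@pytest.fixture(scope="module")
def mcc_member():
    net = get_fixture("mcc_mixed_1_3")
    return net, sample_constrained(net, 1, seed=40).members[0]


@pytest.fixture(scope="module")
def mcc_bifurcating_member():
    """Member whose PK branch vanishes between 1.2x and 1.6x."""
    net = get_fixture("mcc_mixed_1_3")
    ens = sample_constrained(net, 40, seed=7)
    for p in ens.members:
        prof = continue_parameter(net, p, "PK")
        if prof.bifurcation_fold_up and 1.2 <= prof.bifurcation_fold_up <= 1.6:
            return net, p, prof.bifurcation_fold_up
    pytest.fail("no suitably bifurcating member found")


class TestToBatch:
    def test_initial_state_charges_only_the_substrate(self, mcc_member):
        net, p = mcc_member
        _net, _p, x0 = to_batch(net, p, "CH2O", 200.0)
        expected = np.ones(10)
        expected[net.metabolite_index("CH2O")] = 200.0
        np.testing.assert_array_equal(x0, expected)

    def test_exchange_fluxes_vanish_after_conversion(self, mcc_member):
        net, p = mcc_member
        _net, p_b, _x0 = to_batch(net, p, "CH2O", 200.0)
        pk = PackedKinetics(net, p_b)
        rng = np.random.default_rng(0)
        for _ in range(5):
            v = pk.rates(rng.uniform(0, 3, 10))
            for j, kind in enumerate(net.kind):
                if kind != "enzymatic":
                    assert v[j] == 0.0

    def test_unit_multiplier_starts_at_reference(self, mcc_member):
        net, p = mcc_member
        _net, _p, x0 = to_batch(net, p, "CH2O", 1.0)
        np.testing.assert_array_equal(x0, np.ones(10))

    def test_unknown_substrate_rejected(self, mcc_member):
        net, p = mcc_member
        with pytest.raises(Exception):
            to_batch(net, p, "NotAMetabolite", 200.0)


class TestIntegrate:
    def test_reference_state_is_invariant_in_continuous_mode(self, mcc_member):
        net, p = mcc_member
        traj = integrate(net, p, np.ones(10), t_end=1e3)
        assert np.max(np.abs(traj.xbar_t[-1] - 1.0)) < 1e-6

    def test_stable_batch_reaches_production_plateau(self, mcc_member):
        # pseudo-steady state: batch production rate matches the continuous
        # steady-state output flux while substrate is far above its Km
        net, p = mcc_member
        traj = batch_run(net, p, "CH2O", 200.0)
        vref_out = float(net.vref[-1])
        i_mid = int(np.searchsorted(traj.t, 0.25 * traj.t[-1]))
        assert traj.production_rate[i_mid] == pytest.approx(vref_out, rel=0.05)
        from emra.simulate import detect_plateau

        res = detect_plateau(traj)
        assert res is not None
        assert res[1] == pytest.approx(vref_out, rel=0.05)
        # and the run terminates by substrate depletion
        assert traj.series("CH2O")[-1] <= 0.01 * 200.0 + 1e-6

    def test_product_amount_is_nondecreasing(self, mcc_member):
        net, p = mcc_member
        traj = batch_run(net, p, "CH2O", 200.0)
        assert np.all(np.diff(traj.product_amount) > -1e-9)

    def test_past_bifurcation_intermediates_deplete(self, mcc_bifurcating_member):
        net, p, _bif = mcc_bifurcating_member
        vmax = dict(p.vmax)
        for r in ("Fpk", "Xpk"):
            vmax[r] *= 2.0
        traj = batch_run(net, p.with_vmax(vmax), "CH2O", 200.0, t_end=300.0)
        # production rate declines from early times instead of flattening
        n = len(traj.t)
        assert traj.production_rate[n // 2] < traj.production_rate[n // 10]
        # the kinetic trap empties F6P while G3P piles up
        assert traj.series("F6P")[-1] < 0.05
        assert traj.series("G3P")[-1] > 1.0

    def test_moiety_totals_conserved_in_batch(self):
        net = get_fixture("purge_valve_phb")
        p = sample_constrained(net, 1, seed=41).members[0]
        traj = batch_run(net, p, "Pyr", 50.0, t_end=50.0)
        basis = conserved_moieties(net)
        totals = basis.totals(traj.xbar_t)
        assert basis.dim >= 2
        drift = np.max(np.abs(totals - totals[0]), axis=0)
        assert np.max(drift) < 1e-6

    def test_mcc_batch_conserves_carbon(self, mcc_member):
        net, p = mcc_member
        carbons = {"CH2O": 1, "Ru5P": 5, "H6P": 6, "F6P": 6, "E4P": 4,
                   "S7P": 7, "G3P": 3, "X5P": 5, "R5P": 5, "AcP": 2}
        c = np.array([carbons[m] for m in net.metabolite_ids])
        traj = batch_run(net, p, "CH2O", 200.0)
        total = traj.xbar_t @ c
        assert np.max(np.abs(total - total[0])) < 1e-5 * total[0]


class TestClassifyProductive:
    def test_constrained_stable_member_is_productive(self, mcc_member):
        net, p = mcc_member
        traj = integrate(net, p, np.ones(10), t_end=500.0)
        assert classify_productive(traj)

    def test_batch_trajectory_rejected(self, mcc_member):
        net, p = mcc_member
        traj = batch_run(net, p, "CH2O", 2.0, t_end=5.0)
        with pytest.raises(ConfigurationError):
            classify_productive(traj)

    def test_diverging_member_not_productive(self):
        # feed above the sink's maximal capacity: M1 grows without bound
        net = make_toy_chain(1)
        p = ParameterSet(
            kbar={("OUT", "M1"): 1.0}, vmax={"IN": 5.0, "OUT": 4.0}
        )
        assert not productive_member(net, p, t_end=200.0)

    def test_collapsed_mid_pathway_not_productive(self):
        # a mid-chain enzyme 100x below reference throttles output to ~1%
        net = make_toy_chain(3)
        p = solve_vmax(
            net,
            ParameterSet(
                kbar={("E1", "M1"): 1.0, ("E2", "M2"): 1.0, ("OUT", "M3"): 1.0}
            ),
        )
        vmax = dict(p.vmax)
        vmax["E2"] /= 100.0
        assert not productive_member(net, p.with_vmax(vmax), t_end=500.0)

    def test_unconstrained_fraction_between_zero_and_one(self):
        net = make_toy_chain(2)
        ens = sample_unconstrained(net, 20, seed=42)
        from emra.simulate import productive_fraction

        frac = productive_fraction(net, ens, t_end=500.0)
        assert 0.0 <= frac <= 1.0


@pytest.fixture(scope="module")
def feed_sensitive_member():
    # a member that loses its steady state below a 4x feed increase
    net = get_fixture("chimeric_glycolysis")
    ens = sample_constrained(net, 10, seed=21)
    for p in ens.members:
        prof = continue_parameter(net, p, "IN")
        if prof.bifurcation_fold_up and prof.bifurcation_fold_up < 4:
            return net, p
    pytest.fail("no feed-sensitive member found")


class TestFedBatch:
    def test_reference_feed_maintains_atp_and_product_grows(
        self, feed_sensitive_member
    ):
        net, p = feed_sensitive_member
        traj = fed_batch(net, p, 1.0, t_end=50.0)
        assert traj.series("ATP")[-1] > 0.5
        # lactate accumulates roughly linearly at the reference rate (2)
        assert traj.product_amount[-1] == pytest.approx(100.0, rel=0.1)

    def test_overfeeding_depletes_atp_and_halts_production(
        self, feed_sensitive_member
    ):
        net, p = feed_sensitive_member
        t1 = fed_batch(net, p, 1.0, t_end=50.0)
        t4 = fed_batch(net, p, 4.0, t_end=50.0)
        assert t4.series("ATP")[-1] < 0.05
        assert t4.product_amount[-1] < t1.product_amount[-1]
        # production has effectively stopped by the end of the 4x run
        assert t4.production_rate[-1] < 0.1 * t1.production_rate[-1]

    def test_zero_feed_equals_plain_batch_from_reference(self, mcc_member):
        net, p = mcc_member
        fb = fed_batch(net, p, 0.0, t_end=20.0)
        _net, p_b, x0 = to_batch(net, p, "CH2O", 1.0)
        plain = integrate(net, p_b, x0, t_end=20.0, mode="batch")
        np.testing.assert_allclose(
            fb.xbar_t[-1], plain.xbar_t[-1], rtol=1e-6, atol=1e-8
        )

    def test_negative_feed_rejected(self, mcc_member):
        net, p = mcc_member
        with pytest.raises(ConfigurationError, match="nonnegative"):
            fed_batch(net, p, [(0.0, -1.0)], t_end=10.0)
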