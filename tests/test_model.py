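"""Neural-mass model: transfer function, connectome, drift, integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tmapper as tm
from tmapper.model import ModelParameters, _drift_flat


class TestTransferRate:
    def test_saturates_at_maximal_firing_rate(self):
        # far beyond the knee the sigmoid must plateau at r_max = 500 Hz
        assert tm.transfer_rate(10.0, "E") == pytest.approx(500.0, rel=1e-6)
        assert tm.transfer_rate(10.0, "I") == pytest.approx(500.0, rel=1e-6)

    def test_high_precision_oracle(self):
        # independent transcription of the sigmoidal transfer function,
        # evaluated with sympy at 50 digits
        sympy = pytest.importorskip("sympy")
        a, b, d, r = (
            sympy.Rational(310),
            sympy.Rational(125),
            sympy.Rational(16, 100),
            sympy.Rational(500),
        )
        x = sympy.Rational(4, 10)
        u = a * x - b
        H = (r + (u - r) / (1 - sympy.exp(d * (u - r)))) / (1 - sympy.exp(-d * u))
        expected = float(sympy.N(H, 50))
        assert tm.transfer_rate(0.4, "E") == pytest.approx(expected, rel=1e-10)

    @given(
        x1=st.floats(-100, 100, allow_nan=False),
        x2=st.floats(-100, 100, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_nondecreasing(self, x1, x2):
        lo, hi = min(x1, x2), max(x1, x2)
        assert tm.transfer_rate(lo, "E") <= tm.transfer_rate(hi, "E") + 1e-9

    def test_bounded_on_dense_grid(self):
        x = np.linspace(-50, 50, 20001)
        for pop in ("E", "I"):
            H = tm.transfer_rate(x, pop)
            assert np.all(H >= 0.0)
            assert np.all(H <= 500.0 + 1e-9)
            assert np.all(np.diff(H) >= -1e-9)

    def test_rejects_non_finite_input(self):
        with pytest.raises(ValueError):
            tm.transfer_rate(np.nan, "E")
        with pytest.raises(ValueError):
            tm.transfer_rate(np.inf, "I")


class TestNormalizeConnectome:
    def test_unit_max_row_sum(self, rng):
        C = rng.random((66, 66)) * 3
        conn = tm.normalize_connectome(C)
        assert np.abs(conn.C).sum(axis=1).max() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diag(conn.C) == 0)

    def test_idempotent(self, rng):
        conn = tm.normalize_connectome(rng.random((8, 8)))
        again = tm.normalize_connectome(conn.C)
        np.testing.assert_allclose(again.C, conn.C, rtol=0, atol=1e-15)

    def test_scale_invariant(self, rng):
        C = rng.random((7, 7))
        a = tm.normalize_connectome(C)
        b = tm.normalize_connectome(3.0 * C)
        np.testing.assert_allclose(a.C, b.C, atol=1e-15)

    def test_rejects_degenerate_and_negative(self):
        with pytest.raises(ValueError, match="degenerate"):
            tm.normalize_connectome(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="nonnegative"):
            tm.normalize_connectome(np.array([[0.0, -1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="square"):
            tm.normalize_connectome(np.ones((2, 3)))


class TestProtocol:
    def test_single_breakpoint_is_constant(self):
        p = tm.make_protocol([(0.0, 2.0)])
        assert p(0.0) == 2.0
        assert p(57.3) == 2.0

    def test_linear_midpoint_and_anchors(self):
        p = tm.make_protocol([(0.0, 1.5), (10.0, 2.5)])
        assert p(5.0) == pytest.approx(2.0)
        assert p(0.0) == 1.5
        assert p(10.0) == 2.5
        # constant extrapolation
        assert p(-3.0) == 1.5
        assert p(99.0) == 2.5

    def test_out_of_range_warns(self):
        with pytest.warns(UserWarning, match="admissible range"):
            tm.make_protocol([(0.0, 0.5)])

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            tm.make_protocol([(0.0, 2.0), (0.0, 3.0)])


def _hand_drift_single_region(sE, sI, g_input, p: ModelParameters):
    """Independent two-variable transcription of the local model equations."""

    def H(x, a, b, d):
        u = a * x - b
        w = u - p.r_max
        inner = p.r_max + w / (1 - np.exp(d * w))
        return inner / (1 - np.exp(-d * u))

    xE = p.w_EE * sE - p.w_IE * sI + g_input
    xI = p.w_EI * sE - p.w_II * sI + p.I_I
    dE = -sE / p.tau_E + (1 - sE) * p.gamma_E * H(xE, p.a_E, p.b_E, p.d_E)
    dI = -sI / p.tau_I + (1 - sI) * p.gamma_I * H(xI, p.a_I, p.b_I, p.d_I)
    return dE, dI


class TestDriftField:
    def test_saturated_state_decays_at_rate_one_over_tau(self, two_region_connectome):
        # at S_E = 1 the growth term vanishes, leaving -S_E / tau_E = -10/s
        dE, _ = tm.drift_field(
            np.ones(2), np.array([0.3, 0.9]), 3.0, two_region_connectome
        )
        np.testing.assert_allclose(dE, -10.0, rtol=1e-12)

    def test_matches_hand_coded_two_variable_model(self, two_region_connectome):
        # with G = 0 each region follows the isolated local model exactly
        p = ModelParameters()
        for sE, sI in [(0.2, 0.1), (0.5, 0.4), (0.9, 0.7)]:
            dE, dI = tm.drift_field(
                np.array([sE, sE]), np.array([sI, sI]), 0.0, two_region_connectome, p
            )
            eE, eI = _hand_drift_single_region(sE, sI, 0.0, p)
            assert dE[0] == pytest.approx(eE, abs=1e-12)
            assert dI[0] == pytest.approx(eI, abs=1e-12)

    def test_shape_mismatch_rejected(self, two_region_connectome):
        with pytest.raises(ValueError, match="length"):
            tm.drift_field(np.ones(3), np.ones(2), 1.0, two_region_connectome)

    def test_drift_at_saturation_strictly_negative(self, two_region_connectome):
        dE, dI = tm.drift_field(np.ones(2), np.ones(2), 5.0, two_region_connectome)
        assert np.all(dE < 0)
        assert np.all(dI < 0)


class TestIntegrateSde:
    def test_seeded_determinism(self, two_region_connectome):
        proto = tm.make_protocol([(0.0, 2.0)])
        a = tm.integrate_sde(np.full(4, 0.1), proto, two_region_connectome,
                             duration=0.5, seed=3)
        b = tm.integrate_sde(np.full(4, 0.1), proto, two_region_connectome,
                             duration=0.5, seed=3)
        np.testing.assert_array_equal(a.S_E, b.S_E)
        np.testing.assert_array_equal(a.S_I, b.S_I)

    def test_zero_noise_is_seed_independent(self, two_region_connectome):
        proto = tm.make_protocol([(0.0, 2.0)])
        p = tm.ModelParameters(sigma=0.0)
        a = tm.integrate_sde(np.full(4, 0.1), proto, two_region_connectome,
                             params=p, duration=0.3, seed=1)
        b = tm.integrate_sde(np.full(4, 0.1), proto, two_region_connectome,
                             params=p, duration=0.3, seed=99)
        np.testing.assert_array_equal(a.S_E, b.S_E)

    def test_matches_fine_step_reference(self, two_region_connectome):
        # deterministic 1-s run (from a relaxed state, so the stiff
        # inhibitory transient does not dominate) against a dt = 1e-4
        # reference; also checks the second-order convergence of Heun
        p = tm.ModelParameters(sigma=0.0)
        relax = tm.integrate_sde(np.full(4, 0.2), tm.make_protocol([(0.0, 1.5)]),
                                 two_region_connectome, params=p, duration=2.0,
                                 dt=1e-4)
        x0 = np.concatenate([relax.S_E[-1], relax.S_I[-1]])
        proto = tm.make_protocol([(0.0, 1.5), (1.0, 2.5)])
        coarse = tm.integrate_sde(x0, proto, two_region_connectome,
                                  params=p, duration=1.0, dt=1e-3)
        half = tm.integrate_sde(x0, proto, two_region_connectome,
                                params=p, duration=1.0, dt=5e-4, record_every=2)
        fine = tm.integrate_sde(x0, proto, two_region_connectome,
                                params=p, duration=1.0, dt=1e-4, record_every=10)
        assert coarse.S_E.shape == fine.S_E.shape
        err = np.max(np.abs(coarse.S_E - fine.S_E))
        err_half = np.max(np.abs(half.S_E - fine.S_E))
        assert err < 1e-5
        assert 2.5 < err / err_half < 6.5  # ~4x per halving: second order

    def test_record_every_thins_output(self, two_region_connectome):
        proto = tm.make_protocol([(0.0, 2.0)])
        t = tm.integrate_sde(np.full(4, 0.1), proto, two_region_connectome,
                             duration=0.1, dt=0.001, seed=0, record_every=10)
        assert len(t.times) == 11
        assert t.times[1] == pytest.approx(0.01)

    def test_invalid_steps_rejected(self, two_region_connectome):
        proto = tm.make_protocol([(0.0, 2.0)])
        with pytest.raises(ValueError):
            tm.integrate_sde(np.full(4, 0.1), proto, two_region_connectome,
                             duration=0.5, dt=-1.0)
        with pytest.raises(ValueError):
            tm.integrate_sde(np.full(4, 0.1), proto, two_region_connectome,
                             duration=1e-5, dt=1e-3)


def test_decimate_trajectory_keeps_g_trace(two_region_connectome):
    proto = tm.make_protocol([(0.0, 1.5), (2.0, 2.5)])
    p = tm.ModelParameters(sigma=0.0)
    traj = tm.integrate_sde(np.full(4, 0.1), proto, two_region_connectome,
                            params=p, duration=2.0, dt=0.001)
    dec = tm.decimate_trajectory(traj, 0.5)
    assert len(dec.times) == 5
    np.testing.assert_allclose(dec.G_trace, [1.5, 1.75, 2.0, 2.25, 2.5], atol=1e-9)
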