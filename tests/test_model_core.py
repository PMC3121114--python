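"""Unit and property tests for the kinetic core: Hill regulation, the
D-xylose input, the CreA gate, rate functions, steady states and promoter
occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from xlnrdyn import (
    FeedbackSpec,
    InputSignal,
    SystemState,
    crea_gate,
    dxylose,
    feedback_drive,
    hill_activation,
    hill_repression,
    promoter_activity,
    steady_state,
    transcription_rates,
    translation_rates,
)
from xlnrdyn.model_core import ConvergenceError, load_config, save_config, system_rhs


class TestHill:
    @pytest.mark.parametrize(
        "z, theta, h, expected",
        [
            (0.0, 10.0, 1.0, 0.0),  # no activator, no activation
            (10.0, 10.0, 1.0, 0.5),  # half-saturation by definition of theta
            (90.0, 10.0, 1.0, 0.9),  # z/(theta+z)
            (10.0, 10.0, 2.0, 0.5),  # half-saturation holds for any h
        ],
    )
    def test_activation_values(self, z, theta, h, expected):
        assert hill_activation(z, theta, h) == pytest.approx(expected, abs=1e-12)

    def test_repression_complements_activation_at_half_saturation(self):
        assert hill_repression(0.0, 10.0) == 1.0
        assert hill_repression(10.0, 10.0) == 0.5

    @pytest.mark.parametrize("bad", [dict(theta=0.0), dict(theta=-1.0), dict(h=0.0)])
    def test_invalid_parameters_raise(self, bad):
        kwargs = dict(z=1.0, theta=1.0, h=1.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            hill_activation(**kwargs)

    @settings(deadline=None, max_examples=200)
    @given(
        z=st.floats(0.0, 1e6),
        theta=st.floats(1e-6, 1e6),
        h=st.floats(0.1, 8.0),
    )
    def test_activation_and_repression_partition_unity(self, z, theta, h):
        a = hill_activation(z, theta, h)
        r = hill_repression(z, theta, h)
        assert 0.0 <= a <= 1.0
        assert a + r == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(
        z=st.tuples(st.floats(0.0, 1e4), st.floats(0.0, 1e4)),
        theta=st.floats(1e-3, 1e3),
        h=st.floats(0.2, 6.0),
    )
    def test_activation_monotone(self, z, theta, h):
        lo, hi = sorted(z)
        assert hill_activation(lo, theta, h) <= hill_activation(hi, theta, h) + 1e-15
        assert hill_repression(lo, theta, h) >= hill_repression(hi, theta, h) - 1e-15


class TestInputSignal:
    def test_initial_value_is_stated_concentration(self):
        sig = InputSignal(u0=50.0, K=0.3, beta=1e-6)
        assert dxylose(0.0, sig) == pytest.approx(50.0, rel=1e-5)

    def test_decays_to_zero(self):
        sig = InputSignal(u0=50.0, K=0.3)
        assert dxylose(200.0, sig) < 1e-20

    def test_faster_consumption_for_larger_K(self):
        t = np.linspace(0.1, 40.0, 100)
        slow = dxylose(t, InputSignal(u0=50.0, K=0.3))
        fast = dxylose(t, InputSignal(u0=50.0, K=0.6))
        assert np.all(fast < slow)

    def test_non_increasing(self):
        sig = InputSignal(u0=50.0, K=0.3)
        u = dxylose(np.linspace(0, 50, 500), sig)
        assert np.all(np.diff(u) <= 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            dxylose(-1.0, InputSignal())


class TestCreAGate:
    def test_absent_repressor_gives_full_activity(self):
        assert crea_gate(FeedbackSpec(creA_activity=0.0)) == 1.0

    def test_binary_mode_present_silences(self):
        assert crea_gate(FeedbackSpec(creA_activity=1.0, creA_binary=True)) == 0.0

    def test_continuous_hill_form(self):
        spec = FeedbackSpec(creA_activity=1.0, k_A=1.0, creA_binary=False)
        assert crea_gate(spec) == pytest.approx(0.5)

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            FeedbackSpec(creA_activity=-1.0)


class TestRates:
    def test_basal_transcription_only(self, canonical):
        # no master protein, no input: target rate is the basal rate alone
        state = SystemState(x=np.zeros(3), z=np.zeros(3))
        dx = transcription_rates(state, 0.0, canonical.model)
        assert dx[1] == pytest.approx(2.5e-3)
        assert dx[2] == pytest.approx(1e-3)

    def test_master_gene_driven_linearly_by_input(self, canonical):
        state = SystemState(x=np.zeros(3), z=np.zeros(3))
        dx = transcription_rates(state, 50.0, canonical.model)
        assert dx[0] == pytest.approx(50.002)

    def test_rates_vanish_at_steady_state(self, canonical):
        ss = steady_state(canonical.model, u_const=7.5)
        assert np.max(np.abs(transcription_rates(ss, 7.5, canonical.model))) < 1e-8
        assert np.max(np.abs(translation_rates(ss, canonical.model))) < 1e-8

    def test_translation_balance(self, canonical):
        # r*x = eta*z  =>  dz/dt = 0 for the master gene
        state = SystemState(x=np.array([2.0, 0.0, 0.0]), z=np.array([1.0, 0.0, 0.0]))
        dz = translation_rates(state, canonical.model)
        assert dz[0] == pytest.approx(0.0)

    def test_dimension_mismatch_raises(self, canonical):
        state = SystemState(x=np.zeros(2), z=np.zeros(2))
        with pytest.raises(ValueError):
            transcription_rates(state, 0.0, canonical.model)
        with pytest.raises(ValueError):
            translation_rates(state, canonical.model)


class TestFeedbackDrive:
    def test_silenced_by_crea_or_zero_synthesis(self):
        z = np.array([1.0, 2.0, 3.0])
        present = FeedbackSpec(S1={2}, S2={3}, creA_activity=1.0)
        assert feedback_drive(z, present) == 0.0
        off = FeedbackSpec(S1={2}, S2={3}, k_ls=0.0)
        assert feedback_drive(z, off) == 0.0

    def test_repressor_limits(self):
        spec = FeedbackSpec(S1={2}, S2=frozenset(), k_ls=1.0)
        assert feedback_drive(np.array([0.0, 0.0, 0.0]), spec) == pytest.approx(1.0)
        assert feedback_drive(np.array([0.0, 1e9, 0.0]), spec) < 1e-8

    def test_activator_half_saturation(self):
        spec = FeedbackSpec(S1=frozenset(), S2={2}, k_AL=1.0, k_ls=1.0)
        assert feedback_drive(np.array([0.0, 1.0, 0.0]), spec) == pytest.approx(0.5)

    def test_out_of_range_index_rejected(self):
        spec = FeedbackSpec(S1={5}, S2=frozenset())
        with pytest.raises(ValueError):
            feedback_drive(np.zeros(3), spec)

    @settings(deadline=None, max_examples=100)
    @given(
        z=st.lists(st.floats(0.0, 1e5), min_size=3, max_size=3),
        k_ls=st.floats(0.0, 10.0),
    )
    def test_drive_bounded(self, z, k_ls):
        spec = FeedbackSpec(S1={2}, S2={3}, k_ls=k_ls)
        drive = feedback_drive(np.array(z), spec)
        assert 0.0 <= drive <= k_ls * 2 + 1e-12


class TestSteadyState:
    def test_basal_master_level(self, canonical):
        ss = steady_state(canonical.model, u_const=0.0)
        assert ss.x[0] == pytest.approx(0.004, rel=1e-9)

    def test_induced_levels(self, canonical):
        ss = steady_state(canonical.model, u_const=50.0)
        assert ss.x[0] == pytest.approx(100.004, rel=1e-10)
        assert ss.z[0] == pytest.approx(50.002, rel=1e-10)

    @pytest.mark.parametrize("u_const, with_fb", [(0.0, False), (50.0, False), (50.0, True)])
    def test_agrees_with_long_time_integration(self, canonical, canonical_fb, u_const, with_fb):
        # independent oracle: integrate the ODEs to t = 200 h at constant u
        # (feedback without delay) and compare the plateau to the fixed point
        model = canonical.model
        spec = canonical_fb.feedback.with_tau(0.0) if with_fb else None
        ss = steady_state(model, u_const=u_const, spec=spec)
        sol = solve_ivp(
            lambda t, y: system_rhs(t, y, model, None, spec, u_const=u_const),
            (0.0, 200.0),
            np.zeros(6),
            rtol=1e-10,
            atol=1e-12,
        )
        plateau = sol.y[:, -1]
        assert np.allclose(ss.as_vector(), plateau, rtol=1e-6)

    def test_translation_balance_exact(self, canonical):
        ss = steady_state(canonical.model, u_const=12.0)
        assert np.allclose(ss.z, canonical.model.r * ss.x / canonical.model.eta, rtol=0, atol=0)

    def test_nonconvergence_reports_residual(self, canonical_fb):
        with pytest.raises(ConvergenceError) as err:
            steady_state(canonical_fb.model, 50.0, canonical_fb.feedback, max_iter=2)
        assert err.value.residual > 0


class TestPromoterActivity:
    def test_limits(self):
        spec = FeedbackSpec(S1={2}, S2={3})
        ga, gr, comb = promoter_activity(np.zeros(3), spec)
        assert (ga, gr, comb) == (0.0, 1.0, 0.0)

    def test_half_saturation_product(self):
        spec = FeedbackSpec(S1={2}, S2={3}, k_AL=1.0, k_RL=1.0)
        ga, gr, comb = promoter_activity(np.array([0.0, 1.0, 1.0]), spec)
        assert ga == pytest.approx(0.5)
        assert gr == pytest.approx(0.5)
        assert comb == pytest.approx(0.25)

    def test_competitive_variant_shares_denominator(self):
        spec = FeedbackSpec(S1={2}, S2={3}, k_AL=1.0, k_RL=1.0)
        ga, gr, comb = promoter_activity(np.array([0.0, 1.0, 1.0]), spec, competitive=True)
        assert ga == pytest.approx(1.0 / 3.0)
        assert 0.0 <= comb <= 1.0

    def test_empty_role_sets_rejected(self):
        with pytest.raises(ValueError):
            promoter_activity(np.zeros(3), FeedbackSpec(S1={2}, S2=frozenset()))

    @settings(deadline=None, max_examples=100)
    @given(
        z2=st.floats(0.0, 1e4),
        z3=st.floats(0.0, 1e4),
        competitive=st.booleans(),
    )
    def test_fractions_bounded_and_monotone_roles(self, z2, z3, competitive):
        spec = FeedbackSpec(S1={2}, S2={3})
        ga, gr, comb = promoter_activity(np.array([0.0, z2, z3]), spec, competitive)
        assert 0.0 <= ga <= 1.0 and 0.0 <= gr <= 1.0 and 0.0 <= comb <= 1.0


class TestConfigRoundTrip:
    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_round_trip(self, tmp_path, canonical_fb, suffix):
        path = tmp_path / f"cfg{suffix}"
        save_config(path, canonical_fb.model, canonical_fb.input, canonical_fb.feedback)
        model, sig, spec = load_config(path)
        assert model == canonical_fb.model
        assert sig == canonical_fb.input
        assert spec == canonical_fb.feedback
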