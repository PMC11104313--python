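"""Unit tests for the dual-critic update and decision operations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from competing_critics import (
    CriticPair,
    CriticParams,
    SensitivityCoords,
    Transition,
    apply_asymmetric_update,
    compute_prediction_errors,
    draw_utilities,
    select_action,
    sensitivity_coords,
    update_neutral,
)


def pair(n_states=1, n_actions=1, neutral=False):
    return CriticPair.zeros(n_states, n_actions, neutral=neutral)


class TestPredictionErrors:
    def test_zero_tables_return_reward(self):
        critics = pair()
        t = Transition(0, 0, reward=1.0, next_state=0, next_actions=(0,))
        assert compute_prediction_errors(critics, t, gamma=0.0) == (1.0, 1.0)

    def test_direct_substitution_gamma_zero(self):
        critics = pair()
        critics.q_plus[0, 0], critics.q_minus[0, 0] = 0.5, 0.2
        t = Transition(0, 0, reward=0.5, next_state=0, next_actions=(0,))
        dp, dm = compute_prediction_errors(critics, t, gamma=0.0)
        assert dp == pytest.approx(0.0)
        assert dm == pytest.approx(0.3)

    def test_bootstrap_term_uses_next_state_max(self):
        critics = pair(n_states=2, n_actions=2)
        critics.q_plus[0, 0], critics.q_minus[0, 0] = 0.2, 0.1
        critics.q_plus[1] = [1.0, 0.3]
        critics.q_minus[1] = [0.5, 0.2]
        t = Transition(0, 0, reward=0.0, next_state=1, next_actions=(0, 1))
        dp, dm = compute_prediction_errors(critics, t, gamma=0.9)
        assert dp == pytest.approx(0.7)
        assert dm == pytest.approx(0.35)

    def test_terminal_transition_drops_bootstrap(self):
        critics = pair()
        critics.q_plus[0, 0] = critics.q_minus[0, 0] = 0.4
        t = Transition(0, 0, reward=1.0, next_state=0, next_actions=())
        dp, dm = compute_prediction_errors(critics, t, gamma=0.9)
        assert dp == dm == pytest.approx(0.6)

    def test_non_finite_error_raises(self):
        critics = pair()
        t = Transition(0, 0, reward=float("inf"), next_state=0, next_actions=(0,))
        with pytest.raises(FloatingPointError):
            compute_prediction_errors(critics, t, gamma=0.0)


class TestAsymmetricUpdate:
    def params(self, **kw):
        base = dict(alpha=0.5, epsilon=0.0, gamma=0.0, k_plus=0.9, k_minus=0.9)
        base.update(kw)
        return CriticParams(**base)

    def test_positive_error_amplified_on_optimist(self):
        critics = pair()
        t = Transition(0, 0, reward=1.0, next_state=0, next_actions=(0,))
        rec = apply_asymmetric_update(critics, t, self.params())
        assert rec.d_q_plus == pytest.approx(0.95)  # (1 + 0.9) * 0.5 * 1
        assert critics.q_plus[0, 0] == pytest.approx(0.95)

    def test_negative_error_amplified_on_pessimist(self):
        critics = pair()
        t = Transition(0, 0, reward=-1.0, next_state=0, next_actions=(0,))
        rec = apply_asymmetric_update(critics, t, self.params())
        assert rec.d_q_minus == pytest.approx(-0.95)  # (1 + 0.9) * 0.5 * (-1)

    def test_zero_k_collapses_to_risk_neutral(self):
        critics = pair(neutral=True)
        critics.q_plus[0, 0] = critics.q_minus[0, 0] = critics.q_neutral[0, 0] = 0.1
        t = Transition(0, 0, reward=0.5, next_state=0, next_actions=(0,))
        rec = apply_asymmetric_update(critics, t, self.params(k_plus=0.0, k_minus=0.0))
        d_neutral = update_neutral(critics, t, self.params())
        assert rec.d_q_plus == rec.d_q_minus == d_neutral == pytest.approx(0.2)

    def test_zero_error_means_zero_update(self):
        critics = pair()
        critics.q_plus[0, 0] = critics.q_minus[0, 0] = 0.5
        t = Transition(0, 0, reward=0.5, next_state=0, next_actions=(0,))
        rec = apply_asymmetric_update(critics, t, self.params())
        assert rec.d_q_plus == rec.d_q_minus == 0.0

    def test_update_signs_follow_errors(self):
        critics = pair()
        t = Transition(0, 0, reward=0.7, next_state=0, next_actions=(0,))
        rec = apply_asymmetric_update(critics, t, self.params())
        assert np.sign(rec.d_q_plus) == np.sign(rec.delta_plus)
        assert np.sign(rec.d_q_minus) == np.sign(rec.delta_minus)


class TestNeutralUpdate:
    def test_basic_update(self):
        critics = pair(neutral=True)
        t = Transition(0, 0, reward=1.0, next_state=0, next_actions=(0,))
        update_neutral(critics, t, CriticParams(alpha=0.5, gamma=0.0))
        assert critics.q_neutral[0, 0] == pytest.approx(0.5)

    def test_constant_reward_converges_geometrically(self):
        critics = pair(neutral=True)
        p = CriticParams(alpha=0.5, gamma=0.0)
        t = Transition(0, 0, reward=2.0, next_state=0, next_actions=(0,))
        for i in range(1, 11):
            update_neutral(critics, t, p)
            assert critics.q_neutral[0, 0] == pytest.approx(2.0 * (1 - 0.5**i))

    def test_requires_neutral_table(self):
        critics = pair(neutral=False)
        t = Transition(0, 0, reward=1.0, next_state=0, next_actions=(0,))
        with pytest.raises(ValueError, match="neutral"):
            update_neutral(critics, t, CriticParams())

    def test_fixed_point_is_absorbing_for_all_critics(self):
        """Once every table equals the constant reward, nothing moves."""
        critics = pair(neutral=True)
        p = CriticParams(alpha=0.5, gamma=0.0, k_plus=0.9, k_minus=0.9)
        t = Transition(0, 0, reward=1.5, next_state=0, next_actions=(0,))
        critics.q_plus[0, 0] = critics.q_minus[0, 0] = critics.q_neutral[0, 0] = 1.5
        rec = apply_asymmetric_update(critics, t, p)
        update_neutral(critics, t, p)
        assert rec.d_q_plus == rec.d_q_minus == 0.0
        assert critics.q_neutral[0, 0] == 1.5


class TestUtilityDraw:
    def test_degenerate_interval_returns_common_value(self, rng):
        critics = pair(n_actions=2)
        critics.q_plus[0] = critics.q_minus[0] = [0.3, 0.3]
        draw = draw_utilities(critics, 0, (0, 1), rng)
        np.testing.assert_array_equal(draw.u, [0.3, 0.3])

    def test_draws_are_uniform_on_interval(self, rng):
        critics = pair()
        critics.q_minus[0, 0], critics.q_plus[0, 0] = 0.0, 1.0
        u = np.array([draw_utilities(critics, 0, (0,), rng).u[0] for _ in range(10**5)])
        assert u.min() >= 0.0 and u.max() <= 1.0
        assert u.mean() == pytest.approx(0.5, abs=3 * np.sqrt(1 / 12 / 10**5))

    def test_inverted_endpoints_are_ordered_before_sampling(self, rng):
        critics = pair()
        critics.q_minus[0, 0], critics.q_plus[0, 0] = 0.3, 0.1
        u = np.array([draw_utilities(critics, 0, (0,), rng).u[0] for _ in range(1000)])
        assert (u >= 0.1).all() and (u <= 0.3).all()

    def test_empty_action_set_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            draw_utilities(pair(), 0, (), rng)

    def test_utility_within_critic_interval_property(self, rng):
        """Every U(a) lies in the closed interval spanned by the two critics."""
        critics = pair(n_actions=3)
        critics.q_plus[0] = rng.normal(size=3)
        critics.q_minus[0] = rng.normal(size=3)
        lo = np.minimum(critics.q_plus[0], critics.q_minus[0])
        hi = np.maximum(critics.q_plus[0], critics.q_minus[0])
        for _ in range(200):
            draw = draw_utilities(critics, 0, (0, 1, 2), rng)
            assert (draw.u >= lo).all() and (draw.u <= hi).all()


class TestSelectAction:
    def test_greedy_when_epsilon_zero(self, rng):
        critics = pair(n_actions=2)
        critics.q_plus[0] = critics.q_minus[0] = [0.9, 0.2]
        for _ in range(50):
            draw = draw_utilities(critics, 0, (0, 1), rng)
            assert select_action(draw, 0.0, rng) == 0

    def test_single_action_always_returned(self, rng):
        critics = pair()
        draw = draw_utilities(critics, 0, (0,), rng)
        assert select_action(draw, 1.0, rng) == 0

    def test_epsilon_greedy_frequency_law(self, rng):
        """P(greedy) -> 1 - eps; each non-greedy -> eps / (A - 1)."""
        critics = pair(n_actions=4)
        critics.q_plus[0] = critics.q_minus[0] = [0.9, 0.5, 0.3, 0.1]
        n = 10**5
        counts = np.zeros(4)
        for _ in range(n):
            draw = draw_utilities(critics, 0, (0, 1, 2, 3), rng)
            counts[select_action(draw, 0.3, rng)] += 1
        freqs = counts / n
        se = np.sqrt(0.7 * 0.3 / n)
        assert freqs[0] == pytest.approx(0.7, abs=3 * se)
        for a in (1, 2, 3):
            assert freqs[a] == pytest.approx(0.1, abs=3 * np.sqrt(0.1 * 0.9 / n))

    def test_all_tied_explore_is_uniform_over_actions(self, rng):
        """Fully degenerate draws with eps=1 spread choice over all actions."""
        critics = pair(n_actions=3)
        n = 30000
        counts = np.zeros(3)
        for _ in range(n):
            draw = draw_utilities(critics, 0, (0, 1, 2), rng)
            counts[select_action(draw, 1.0, rng)] += 1
        np.testing.assert_allclose(counts / n, 1 / 3, atol=3 * np.sqrt(2 / 9 / n))


class TestParamsAndCoords:
    @pytest.mark.parametrize(
        "field, value",
        [("alpha", 0.0), ("alpha", 1.1), ("gamma", 1.0), ("epsilon", -0.1),
         ("k_plus", 1.2), ("k_minus", -0.2)],
    )
    def test_out_of_bound_params_rejected(self, field, value):
        with pytest.raises(ValueError, match=field):
            CriticParams(**{field: value})

    @pytest.mark.parametrize(
        "k_plus, k_minus, s_r, s_u",
        [(0.9, 0.9, 0.0, 1.8), (0.9, 0.1, 0.8, 1.0), (0.0, 0.0, 0.0, 0.0)],
    )
    def test_sensitivity_coords_values(self, k_plus, k_minus, s_r, s_u):
        coords = sensitivity_coords(CriticParams(k_plus=k_plus, k_minus=k_minus))
        assert coords.s_r == pytest.approx(s_r)
        assert coords.s_u == pytest.approx(s_u)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(k_plus=st.floats(0.0, 1.0), k_minus=st.floats(0.0, 1.0))
    def test_coords_invert_exactly(self, k_plus, k_minus):
        coords = sensitivity_coords(CriticParams(k_plus=k_plus, k_minus=k_minus))
        assert -1.0 <= coords.s_r <= 1.0 and 0.0 <= coords.s_u <= 2.0
        kp, km = coords.to_k()
        assert kp == pytest.approx(k_plus, abs=1e-12)
        assert km == pytest.approx(k_minus, abs=1e-12)

    def test_coords_roundtrip_from_axes(self):
        assert SensitivityCoords(0.8, 1.0).to_k() == (0.9, pytest.approx(0.1))
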