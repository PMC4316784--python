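import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import primlearn as pl
from primlearn.models import LearnerParams


class TestLearnerParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(eta=0.0),
            dict(eta=-0.5),
            dict(eta=0.5, lambda1=-0.1),
            dict(eta=0.5, lambda2=-0.1),
            dict(eta=math.nan),
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            LearnerParams(**kwargs)


class TestMotorCommand:
    def test_zero_weights(self, two_primitive_basis):
        assert pl.motor_command(np.zeros(2), two_primitive_basis, 1.2) == 0.0

    def test_single_primitive_at_pd(self):
        basis = pl.PrimitiveBasis(1, math.pi / 4, np.array([0.3]))
        assert pl.motor_command([2.0], basis, 0.3) == pytest.approx(2.0)

    def test_two_primitive_hand_value(self, two_primitive_basis):
        x = pl.motor_command([1.0, 1.0], two_primitive_basis, 0.0)
        assert x == pytest.approx(1 + math.exp(-2), rel=1e-12)

    def test_length_mismatch(self, two_primitive_basis):
        with pytest.raises(ValueError):
            pl.motor_command([1.0], two_primitive_basis, 0.0)


class TestUpdateWeights:
    def test_first_trial_is_error_term_only(self, two_primitive_basis):
        p = math.pi / 4
        params = LearnerParams(eta=0.5, lambda1=0.1, lambda2=0.2)
        w = pl.update_weights(np.zeros(2), two_primitive_basis, 0.7, p, params)
        a = pl.activities(two_primitive_basis, 0.7)
        np.testing.assert_allclose(w, params.eta * p * a, rtol=1e-14)

    def test_effort_decay_in_clamp_trial(self):
        # single primitive trained at its PD: x = W, A = 1, e clamped to 0
        basis = pl.PrimitiveBasis(1, math.pi / 4, np.array([0.0]))
        params = LearnerParams(eta=0.5, lambda1=0.0, lambda2=0.06)  # eta*lambda2 = 0.03
        w = pl.update_weights(np.array([1.0]), basis, 0.0, 0.0, params)
        assert w[0] == pytest.approx(0.97, rel=1e-14)

    def test_weight_decay_in_clamp_trial_is_direction_independent(self):
        basis = pl.sample_basis(10, math.pi / 4, seed=0)
        params = LearnerParams(eta=0.5, lambda1=0.003, lambda2=0.0)
        w0 = np.linspace(-1, 1, 10)
        for theta_t in (0.0, 1.0, -2.5):
            w = pl.update_weights(w0, basis, theta_t, 0.0, params)
            np.testing.assert_array_equal(w, (1 - 0.5 * 0.003) * w0)

    def test_rejects_non_finite_error(self, two_primitive_basis):
        with pytest.raises(ValueError):
            pl.update_weights(np.zeros(2), two_primitive_basis, 0.0,
                              math.nan, LearnerParams(eta=0.5))


class TestUpdateStateSpace:
    def test_learning_from_zero(self):
        params = LearnerParams(eta=0.04, lambda2=0.0375)
        x = pl.update_state_space(0.0, math.pi / 4, params)
        assert x == pytest.approx(0.04 * math.pi / 4, rel=1e-14)

    def test_forgetting_in_clamp_trial(self):
        params = LearnerParams(eta=0.04, lambda2=0.0015 / 0.04)
        assert pl.update_state_space(1.0, 0.0, params) == pytest.approx(0.9985)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            pl.update_state_space(math.inf, 0.0, LearnerParams(eta=0.04))


class TestRecursiveCommandUpdate:
    def test_no_overlap_no_decay(self):
        # vanishing tuning width: primitives at theta_t do not overlap a
        # probe one quadrant away, so its command is untouched in a clamp
        basis = pl.sample_basis(50, 1e-3, seed=1)
        params = LearnerParams(eta=0.5, lambda2=0.06)
        cmds = {0.0: 0.8, math.pi / 2: 0.5}
        out = pl.recursive_command_update(cmds, basis, 0.0, 0.0, params)
        assert out[math.pi / 2] == pytest.approx(0.5, abs=1e-15)

    def test_clamp_decay_at_trained_direction(self, two_primitive_basis):
        params = LearnerParams(eta=0.5, lambda2=0.06)
        g = pl.generalization_empirical(two_primitive_basis, 0.0, 0.0)
        out = pl.recursive_command_update({0.0: 1.0}, two_primitive_basis,
                                          0.0, 0.0, params)
        assert out[0.0] == pytest.approx(1 - 0.5 * 0.06 * g, rel=1e-12)

    def test_missing_trained_direction_raises(self, two_primitive_basis):
        with pytest.raises(ValueError):
            pl.recursive_command_update({1.0: 0.0}, two_primitive_basis,
                                        0.0, 0.1, LearnerParams(eta=0.5))

    @pytest.mark.parametrize(
        "params",
        [
            LearnerParams(eta=0.5, lambda1=0.003),
            LearnerParams(eta=0.5, lambda2=0.06),
            LearnerParams(eta=0.5, lambda1=0.01, lambda2=0.05),
        ],
        ids=["weight-decay", "effort", "combined"],
    )
    def test_one_trial_matches_weight_space(self, params):
        basis = pl.sample_basis(40, math.pi / 4, seed=9)
        probes = [-math.pi / 2, 0.0, 0.4, math.pi / 2]
        rng = np.random.default_rng(9)
        w0 = rng.normal(size=40) * 0.1
        theta_t, e = 0.4, 0.3
        cmds = {th: pl.motor_command(w0, basis, th) for th in probes}
        out = pl.recursive_command_update(cmds, basis, theta_t, e, params)
        w1 = pl.update_weights(w0, basis, theta_t, e, params)
        for th in probes:
            assert out[th] == pytest.approx(
                pl.motor_command(w1, basis, th), abs=1e-12
            )


class TestFixedPointCommand:
    def test_no_regularization_gives_full_compensation(self, two_primitive_basis):
        params = LearnerParams(eta=0.5)
        for kind in (pl.EFFORT_PRIMITIVE, pl.STATE_SPACE_EFFORT):
            assert pl.fixed_point_command(1.3, params, None, 0.0, kind) == 1.3
        assert pl.fixed_point_command(
            1.3, params, two_primitive_basis, 0.0, pl.WEIGHT_DECAY_PRIMITIVE
        ) == pytest.approx(1.3)

    def test_effort_asymptote(self):
        params = LearnerParams(eta=0.5, lambda2=0.06)
        fp = pl.fixed_point_command(math.pi / 4, params, None, 0.0,
                                    pl.EFFORT_PRIMITIVE)
        assert fp == pytest.approx(math.pi / 4 / 1.06, rel=1e-12)
        assert fp == pytest.approx(0.74094, abs=1e-5)

    def test_weight_decay_single_primitive(self):
        basis = pl.PrimitiveBasis(1, math.pi / 4, np.array([0.0]))
        params = LearnerParams(eta=0.5, lambda1=0.003)
        fp = pl.fixed_point_command(1.0, params, basis, 0.0,
                                    pl.WEIGHT_DECAY_PRIMITIVE)
        assert fp == pytest.approx(1 / 1.003, rel=1e-12)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            pl.fixed_point_command(1.0, LearnerParams(eta=0.5), None, 0.0, "nope")


@settings(derandomize=True, max_examples=30)
@given(scale=st.floats(0.1, 5.0))
def test_update_is_linear_in_perturbation_scale(scale):
    """Scaling weights and error together scales the update: the dynamics
    are linear, which underlies perturbation-magnitude invariance."""
    basis = pl.sample_basis(20, math.pi / 3, seed=4)
    params = LearnerParams(eta=0.5, lambda1=0.01, lambda2=0.05)
    rng = np.random.default_rng(4)
    w0 = rng.normal(size=20) * 0.05
    w1 = pl.update_weights(w0, basis, 0.5, 0.2, params)
    w1s = pl.update_weights(scale * w0, basis, 0.5, scale * 0.2, params)
    np.testing.assert_allclose(w1s, scale * w1, rtol=1e-10, atol=1e-14)
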