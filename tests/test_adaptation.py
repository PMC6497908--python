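"""Epoch vectors, mirroring, cosine analysis and the structure regression."""

import numpy as np
import pytest

from splitbelt.adaptation import (
    CollinearFactorsError,
    DeltaResponse,
    EpochSpec,
    InsufficientStridesError,
    UndefinedCosineError,
    collinearity_check,
    cosine,
    delta_response,
    epoch_vector,
    fit_structure,
    mirror_transpose,
    vector_magnitude,
)
from splitbelt.vectors import DEFAULT_INDEX

IDX = DEFAULT_INDEX
N = IDX.n_components


def _delta(values, label="on(+)"):
    return DeltaResponse(np.asarray(values, float), label, IDX)


class TestEpochVector:
    def test_early_epoch_is_strides_2_to_6(self):
        strides = np.arange(50, dtype=float)[:, None] * np.ones((1, 4))
        v = epoch_vector(strides, EpochSpec("longExposure", "early", 5))
        assert v[0] == pytest.approx(np.mean([1, 2, 3, 4, 5]))

    def test_late_epoch_drops_final_stride(self):
        strides = np.arange(50, dtype=float)[:, None] * np.ones((1, 3))
        v = epoch_vector(strides, EpochSpec("baseline", "late", 40))
        assert v[0] == pytest.approx(np.mean(np.arange(9, 49)))

    def test_whole_short_exposure_uses_eight_strides(self):
        strides = np.arange(10, dtype=float)[:, None] * np.ones((1, 2))
        v = epoch_vector(strides, EpochSpec("shortExposure", "whole"))
        assert v[0] == pytest.approx(np.mean(np.arange(1, 9)))

    def test_identical_strides_return_the_vector(self):
        v0 = np.random.default_rng(0).random(6)
        v = epoch_vector(np.tile(v0, (12, 1)), EpochSpec("x", "early", 5))
        np.testing.assert_allclose(v, v0)

    def test_insufficient_strides_error_names_condition(self):
        with pytest.raises(InsufficientStridesError, match="washout"):
            epoch_vector(np.zeros((4, 3)), EpochSpec("washout", "early", 5))


class TestDeltaAndMirror:
    def test_delta_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(N), rng.random(N)
        d1 = delta_response(a, b, "x").values
        d2 = delta_response(b, a, "x").values
        np.testing.assert_allclose(d1, -d2)
        np.testing.assert_allclose(delta_response(a, a, "x").values, 0.0)

    def test_mirror_is_involution(self):
        d = _delta(np.random.default_rng(2).random(N))
        np.testing.assert_array_equal(
            mirror_transpose(mirror_transpose(d)).values, d.values)

    def test_symmetric_vector_is_fixed_point(self):
        half = np.random.default_rng(3).random(N // 2)
        d = _delta(np.concatenate([half, half]))
        np.testing.assert_array_equal(mirror_transpose(d).values, d.values)

    def test_mirror_preserves_norm_and_blocks(self):
        rng = np.random.default_rng(4)
        d = _delta(rng.random(N))
        m = mirror_transpose(d)
        assert np.linalg.norm(m.values) == pytest.approx(np.linalg.norm(d.values))
        np.testing.assert_array_equal(m.values[: N // 2], d.values[N // 2 :])
        np.testing.assert_array_equal(m.values[N // 2 :], d.values[: N // 2])

    def test_component_addressing(self):
        v = np.zeros(N)
        v[IDX.position("fast", "SOL", "DS2b")] = 1.0
        m = IDX.mirror(v)
        assert m[IDX.position("slow", "SOL", "DS2b")] == 1.0


class TestCosineAndMagnitude:
    def test_trivial_cosines(self):
        a = np.random.default_rng(5).random(N)
        assert cosine(a, a) == pytest.approx(1.0)
        assert cosine(a, -a) == pytest.approx(-1.0)
        b = np.zeros(N)
        b[0], a0 = 1.0, np.zeros(N)
        a0[1] = 1.0
        assert cosine(b, a0) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedCosineError):
            cosine(np.zeros(N), np.ones(N))

    def test_magnitude(self):
        v = np.zeros(N)
        v[0], v[1] = 3.0, 4.0
        assert vector_magnitude(v) == 5.0
        assert vector_magnitude(np.zeros(N)) == 0.0

    def test_cosine_scale_invariance(self, smooth_delta):
        a = smooth_delta
        b = np.roll(a, 3)
        assert cosine(2.7 * a, b) == pytest.approx(cosine(a, 0.4 * b))


class TestCollinearityCheck:
    def test_antisymmetric_gives_plus_one(self):
        half = np.random.default_rng(6).random(N // 2)
        d = _delta(np.concatenate([half, -half]))
        assert collinearity_check(d) == pytest.approx(1.0)

    def test_one_leg_silent_gives_zero(self):
        half = np.random.default_rng(7).random(N // 2)
        d = _delta(np.concatenate([half, np.zeros(N // 2)]))
        assert collinearity_check(d) == pytest.approx(0.0)

    def test_symmetric_gives_minus_one(self):
        half = np.random.default_rng(8).random(N // 2)
        d = _delta(np.concatenate([half, half]))
        assert collinearity_check(d) == pytest.approx(-1.0)


def _normal_equations(y, f1, f2):
    """Independent closed-form oracle for the two-factor fit."""
    X = np.column_stack([-f1, f2])
    return np.linalg.inv(X.T @ X) @ (X.T @ y)


class TestFitStructure:
    def test_environment_based_limit(self, smooth_delta):
        d_on = _delta(smooth_delta)
        res = fit_structure(_delta(-smooth_delta, "off(+)-long"), d_on)
        assert res.beta_no_adapt == pytest.approx(1.0, abs=1e-9)
        assert res.beta_adapt == pytest.approx(0.0, abs=1e-9)
        assert res.r2_uncentered == pytest.approx(1.0, abs=1e-12)

    def test_adaptive_limit(self, smooth_delta):
        d_on = _delta(smooth_delta)
        off = _delta(IDX.mirror(smooth_delta), "off(+)-long")
        res = fit_structure(off, d_on)
        assert res.beta_adapt == pytest.approx(1.0, abs=1e-9)
        assert res.beta_no_adapt == pytest.approx(0.0, abs=1e-9)
        assert res.r2_uncentered == pytest.approx(1.0, abs=1e-12)

    def test_mixture_recovery_vs_normal_equations(self, smooth_delta):
        d_on = _delta(smooth_delta)
        y = -0.2 * smooth_delta + 0.7 * IDX.mirror(smooth_delta)
        res = fit_structure(_delta(y, "off"), d_on)
        assert res.beta_adapt == pytest.approx(0.7, abs=1e-6)
        assert res.beta_no_adapt == pytest.approx(0.2, abs=1e-6)
        oracle = _normal_equations(y, smooth_delta, IDX.mirror(smooth_delta))
        assert res.beta_no_adapt == pytest.approx(oracle[0], abs=1e-10)
        assert res.beta_adapt == pytest.approx(oracle[1], abs=1e-10)

    def test_noisy_fit_matches_normal_equations(self, smooth_delta):
        rng = np.random.default_rng(9)
        y = -0.4 * smooth_delta + 0.5 * IDX.mirror(smooth_delta) + rng.normal(0, 5, N)
        res = fit_structure(_delta(y, "off"), _delta(smooth_delta))
        oracle = _normal_equations(y, smooth_delta, IDX.mirror(smooth_delta))
        assert res.beta_no_adapt == pytest.approx(oracle[0], abs=1e-10)
        assert res.beta_adapt == pytest.approx(oracle[1], abs=1e-10)
        lo, hi = res.ci_adapt
        assert lo < res.beta_adapt < hi

    def test_scale_properties(self, smooth_delta):
        d_on = _delta(smooth_delta)
        y = -0.3 * smooth_delta + 0.6 * IDX.mirror(smooth_delta)
        base = fit_structure(_delta(y, "off"), d_on)
        scaled_y = fit_structure(_delta(3.0 * y, "off"), d_on)
        assert scaled_y.beta_adapt == pytest.approx(3.0 * base.beta_adapt)
        assert scaled_y.beta_no_adapt == pytest.approx(3.0 * base.beta_no_adapt)
        scaled_x = fit_structure(
            _delta(y, "off"), _delta(2.0 * smooth_delta),
            _delta(2.0 * IDX.mirror(smooth_delta)))
        assert scaled_x.beta_adapt == pytest.approx(base.beta_adapt / 2.0)
        assert scaled_x.beta_no_adapt == pytest.approx(base.beta_no_adapt / 2.0)

    def test_collinear_design_rejected(self):
        half = np.random.default_rng(10).random(N // 2)
        anti = _delta(np.concatenate([half, -half]))
        with pytest.raises(CollinearFactorsError):
            fit_structure(_delta(-anti.values, "off"), anti)

    def test_factor_noise_shrinks_betas_monotonically(self, smooth_delta):
        # noise on the factors (not the response) biases both coefficients
        # toward zero, monotonically in the noise level
        rng = np.random.default_rng(11)
        y = -0.2 * smooth_delta + 0.7 * IDX.mirror(smooth_delta)
        means = []
        for sd in (0.0, 5.0, 10.0, 20.0):
            betas = []
            for _ in range(200):
                f = smooth_delta + rng.normal(0, sd, N)
                try:
                    res = fit_structure(_delta(y, "off"), _delta(f))
                except CollinearFactorsError:
                    continue
                betas.append([res.beta_adapt, res.beta_no_adapt])
            means.append(np.mean(betas, axis=0))
        means = np.asarray(means)
        assert np.all(np.diff(means[:, 0]) < 0)   # beta_adapt shrinks
        assert np.all(np.diff(means[:, 1]) < 0)   # beta_no_adapt shrinks
        assert means[0, 0] == pytest.approx(0.7, abs=1e-9)
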