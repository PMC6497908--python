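"""Phase segmentation, binning, normalization and kinematics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_

from splitbelt.gait_features import (
    DegenerateNormalizationError,
    EmptyBinError,
    InvalidGeometryError,
    apply_normalization,
    bin_stride_activity,
    fit_baseline_normalization,
    hip_displacement,
    segment_phases,
    step_length_asymmetry,
)
from splitbelt.signal_prep import GaitEvents, SampledSignal


def _events(n_strides=3, T=1.0, t0=0.0):
    """Regular alternating two-leg events: slow HS at stride start."""
    hs_s = t0 + T * np.arange(n_strides + 1)
    return GaitEvents(
        heel_strikes={"slow": hs_s, "fast": hs_s[:-1] + 0.5 * T},
        toe_offs={"slow": hs_s[:-1] + 0.65 * T, "fast": hs_s[:-1] + 0.15 * T},
    )


class TestSegmentPhases:
    def test_twelve_bins_per_stride(self):
        parts = segment_phases(_events(4), "slow")
        assert len(parts) == 4
        assert all(p.n_bins == 12 for p in parts)

    def test_double_support_equal_halves(self):
        # ipsi HS at 0, contra TO at 0.2 -> DS1a=[0,0.1), DS1b=[0.1,0.2)
        ev = GaitEvents(
            heel_strikes={"slow": np.array([0.0, 1.0]), "fast": np.array([0.5])},
            toe_offs={"slow": np.array([0.7]), "fast": np.array([0.2])},
        )
        p = segment_phases(ev, "slow")[0]
        np.testing.assert_allclose(p.edges[:3], [0.0, 0.1, 0.2])

    def test_bins_tile_stride_exactly(self):
        for p in segment_phases(_events(5, T=1.07), "fast"):
            assert np.all(np.diff(p.edges) > 0)
            # contiguous edges: union of bins is the stride span
            assert p.edges[0] == p.start and p.edges[-1] == p.end

    def test_incomplete_stride_skipped(self):
        ev = _events(4)
        # remove one contralateral toe-off: that stride is dropped
        ev.toe_offs["fast"] = np.delete(ev.toe_offs["fast"], 1)
        parts = segment_phases(ev, "slow")
        assert len(parts) == 3  # stride 2 lost its contralateral toe-off


class TestBinStrideActivity:
    def test_constant_channel(self):
        sig = SampledSignal(np.full((4000, 1), 3.25), 2000.0, ["m"])
        parts = segment_phases(_events(2, T=0.9, t0=0.05), "slow")
        bins = bin_stride_activity(sig, parts)
        np.testing.assert_allclose(bins, 3.25)

    def test_thirty_channels_give_360_values(self):
        sig = SampledSignal(np.random.default_rng(0).random((6000, 30)),
                            2000.0, [f"c{i}" for i in range(30)])
        parts = segment_phases(_events(3), "slow")
        bins = bin_stride_activity(sig, parts)
        assert bins.shape == (3, 30, 12)
        assert bins[0].size == 360

    def test_linear_ramp_bin_mean(self):
        # analytic integral of a*t over [t0, t1) is a*(t0+t1)/2
        a = 2.5
        t = np.arange(8000) / 2000.0
        sig = SampledSignal((a * t).reshape(-1, 1), 2000.0, ["m"])
        parts = segment_phases(_events(2), "slow")
        bins = bin_stride_activity(sig, parts)
        for p, row in zip(parts, bins[:, 0, :]):
            mid = a * 0.5 * (p.edges[:-1] + p.edges[1:])
            np.testing.assert_allclose(row, mid, atol=a / 2000.0)

    def test_empty_bin_raises_with_location(self):
        sig = SampledSignal(np.zeros((12, 1)), 5.0, ["m"])  # 5 Hz: 75 ms bins empty
        parts = segment_phases(_events(2), "slow")
        with pytest.raises(EmptyBinError, match="stride"):
            bin_stride_activity(sig, parts)


class TestNormalization:
    def _bins(self, rng, n=45):
        profile = np.linspace(1.0, 2.0, 12)[None, None, :] * np.array([[1.0], [3.0]])[None, :, :]
        return profile + 0.01 * rng.standard_normal((n, 2, 12))

    def test_baseline_profile_maps_to_0_100(self):
        bins = self._bins(np.random.default_rng(0))
        nmap = fit_baseline_normalization(bins, ["a", "b"], last_n=40)
        profile = bins[-40:].mean(axis=0)
        out = apply_normalization(profile, nmap, ["a", "b"])
        np.testing.assert_allclose(out.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.max(axis=1), 100.0, atol=1e-12)

    def test_affine_invariance(self):
        bins = self._bins(np.random.default_rng(1))
        n1 = fit_baseline_normalization(bins, ["a", "b"])
        n2 = fit_baseline_normalization(2.5 * bins + 7.0, ["a", "b"])
        x = bins[:5]
        np.testing.assert_allclose(
            apply_normalization(x, n1, ["a", "b"]),
            apply_normalization(2.5 * x + 7.0, n2, ["a", "b"]),
            atol=1e-9,
        )

    def test_flat_muscle_raises(self):
        bins = self._bins(np.random.default_rng(2))
        bins[:, 1, :] = 1.0
        with pytest.raises(DegenerateNormalizationError, match="b"):
            fit_baseline_normalization(bins, ["a", "b"])

    def test_endpoints_and_midpoint(self):
        bins = self._bins(np.random.default_rng(3))
        nmap = fit_baseline_normalization(bins, ["a", "b"])
        lo, rng_ = nmap.shift["a"], nmap.scale["a"]
        x = np.array([[[lo, lo + rng_, lo + 0.5 * rng_]]])
        out = apply_normalization(x, nmap, ["a"])
        np.testing.assert_allclose(out[0, 0], [0.0, 100.0, 50.0])

    def test_missing_channel_raises(self):
        bins = self._bins(np.random.default_rng(4))
        nmap = fit_baseline_normalization(bins, ["a", "b"])
        with pytest.raises(KeyError):
            apply_normalization(bins, nmap, ["a", "zz"])

    def test_pipeline_baseline_contract(self, noiseless_result):
        # through the full pipeline: normalized baseline mean profile of
        # every muscle attains exactly 0 and 100
        mat = noiseless_result.stride_matrices["baseline"][:-1][-40:]
        profile = mat.mean(axis=0).reshape(30, 12)
        np.testing.assert_allclose(profile.min(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(profile.max(axis=1), 100.0, atol=1e-9)


def _markers(positions: dict, times: np.ndarray) -> SampledSignal:
    names = list(positions)
    return SampledSignal(np.column_stack([positions[n] for n in names]),
                         1.0 / (times[1] - times[0]), names, float(times[0]))


class TestStepLengthAsymmetry:
    def _setup(self, sl_fast, sl_slow):
        # one fast step then one slow step with prescribed lengths
        t = np.arange(0, 3.0, 0.01)
        ank_f = np.full_like(t, sl_fast)  # fast ankle parked after landing
        # slow ankle lands sl_slow ahead of the fast ankle at its heel-strike
        ank_s = np.where(t < 1.5, 0.0, sl_fast + sl_slow)
        ev = GaitEvents(
            heel_strikes={"fast": np.array([1.0]), "slow": np.array([1.5])},
            toe_offs={"fast": np.array([2.6]), "slow": np.array([0.9])},
        )
        m = _markers({"ankle_fast_ap_m": ank_f, "ankle_slow_ap_m": ank_s}, t)
        return m, ev

    def test_worked_pair(self):
        m, ev = self._setup(0.6, 0.4)
        sla = step_length_asymmetry(m, ev)
        assert sla[0] == pytest.approx((0.6 - 0.4) / (0.6 + 0.4), abs=1e-9)

    def test_even_steps_zero(self):
        m, ev = self._setup(0.5, 0.5)
        assert step_length_asymmetry(m, ev)[0] == pytest.approx(0.0, abs=1e-9)

    def test_swap_flips_sign(self):
        a = step_length_asymmetry(*self._setup(0.6, 0.4))[0]
        b = step_length_asymmetry(*self._setup(0.4, 0.6))[0]
        assert a == pytest.approx(-b, abs=1e-9)

    @given(st_.floats(0.05, 1.5), st_.floats(0.05, 1.5))
    @settings(max_examples=40, deadline=None)
    def test_bounded_for_positive_steps(self, sl_f, sl_s):
        sla = step_length_asymmetry(*self._setup(sl_f, sl_s))[0]
        assert -1.0 < sla < 1.0

    def test_nonpositive_sum_raises(self):
        m, ev = self._setup(-0.2, 0.1)
        with pytest.raises(InvalidGeometryError):
            step_length_asymmetry(m, ev)

    def test_ground_truth_recovery(self, noiseless_trial, noiseless_result):
        per_cond = noiseless_result.kinematics["sla_by_condition"]
        gt = noiseless_trial.ground_truth
        rows = gt.condition_strides("longExposure")
        meas = per_cond["longExposure"][2:40]
        np.testing.assert_allclose(meas, gt.sla[rows][2:40], atol=0.02)


class TestHipDisplacement:
    def _case(self, hip_fun, ankle_fun):
        t = np.arange(0, 2.0, 0.01)
        ev = GaitEvents(
            heel_strikes={"slow": np.array([0.5]), "fast": np.array([1.5])},
            toe_offs={"slow": np.array([1.8]), "fast": np.array([0.4])},
        )
        m = _markers({
            "hip_left_ap_m": hip_fun(t), "hip_right_ap_m": hip_fun(t),
            "ankle_slow_ap_m": ankle_fun(t), "ankle_fast_ap_m": np.zeros_like(t),
        }, t)
        return m, ev

    def test_stationary_zero(self):
        m, ev = self._case(lambda t: np.full_like(t, 0.1), lambda t: np.zeros_like(t))
        assert hip_displacement(m, ev, "slow")[0] == pytest.approx(0.0, abs=1e-12)

    def test_linear_advance(self):
        # hip midpoint advances 0.3 m over the stance span [0.5, 1.5]
        m, ev = self._case(lambda t: 0.3 * (t - 0.5), lambda t: np.zeros_like(t))
        assert hip_displacement(m, ev, "slow")[0] == pytest.approx(0.3, abs=1e-9)

    def test_telescoping_over_subspans(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 2.0, 0.01)
        hip = np.cumsum(rng.standard_normal(t.size)) * 0.001
        m, ev = self._case(lambda tt: hip, lambda tt: np.zeros_like(tt))
        total = hip_displacement(m, ev, "slow")[0]
        # split the span [0.5, 1.5] at an arbitrary midpoint event
        ev_a = GaitEvents(heel_strikes={"slow": np.array([0.5]), "fast": np.array([0.9])},
                          toe_offs={"slow": np.array([1.8]), "fast": np.array([0.4])})
        ev_b = GaitEvents(heel_strikes={"slow": np.array([0.9]), "fast": np.array([1.5])},
                          toe_offs={"slow": np.array([1.8]), "fast": np.array([0.85])})
        part = hip_displacement(m, ev_a, "slow")[0] + hip_displacement(m, ev_b, "slow")[0]
        assert total == pytest.approx(part, abs=1e-9)
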