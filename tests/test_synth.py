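"""Synthetic-trial generator: determinism, ground truth, signal contracts."""

import numpy as np
import pytest

import splitbelt as sb
from splitbelt.synth import InvalidConfigError, transition_targets


class TestConfigAndSchedule:
    def test_default_schedule_counts(self):
        sched = sb.ProtocolSchedule.default()
        counts = {c.name: c.stride_count for c in sched.conditions}
        assert counts == {"slow": 50, "mid": 50, "shortExposure": 10,
                          "baseline": 150, "longExposure": 900, "washout": 600}

    def test_split_speeds_are_two_to_one(self):
        from splitbelt.synth import belt_speeds
        v = belt_speeds("split(+)", 1.2)
        assert v["fast"] == pytest.approx(2 * v["slow"])
        assert v["fast"] == pytest.approx(4 / 3 * 1.2)

    @pytest.mark.parametrize("bad", [
        dict(emg_rate=-1.0), dict(stride_duration_mean=0.0), dict(noise_sd=-0.1),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(InvalidConfigError):
            sb.SyntheticConfig(**bad)

    def test_decay_is_monotone_and_compact(self):
        cfg = sb.SyntheticConfig()
        g = cfg.decay(np.arange(1, 200))
        assert g[0] == 1.0
        assert np.all(np.diff(g) <= 0)
        assert np.all(g[cfg.transient_len - 1 :] == 0.0)
        assert np.all(g[: cfg.transient_plateau] == 1.0)


class TestStrideVectors:
    def test_stride_counts_match_schedule(self):
        sim = sb.simulate_stride_vectors(sb.SyntheticConfig(seed=1))
        conds = np.asarray(sim["stride_conditions"])
        assert (conds == "slow").sum() == 50
        assert (conds == "longExposure").sum() == 900

    def test_seeded_determinism_and_seed_sensitivity(self):
        cfg = sb.SyntheticConfig(seed=5)
        s1 = sb.simulate_stride_vectors(cfg, sb.ProtocolSchedule.compact())
        s2 = sb.simulate_stride_vectors(cfg, sb.ProtocolSchedule.compact())
        np.testing.assert_array_equal(s1["activity_noisy"], s2["activity_noisy"])
        s3 = sb.simulate_stride_vectors(
            sb.SyntheticConfig(seed=6), sb.ProtocolSchedule.compact())
        assert not np.array_equal(s1["activity_noisy"], s3["activity_noisy"])

    def test_stride1_off_delta_is_configured_mixture(self):
        # noiseless: the first post-off stride equals the previous
        # condition's end plus the configured mixture of the stored on(+)
        cfg = sb.SyntheticConfig(seed=2, noise_sd=0.0, b_adapt=0.7, b_no_adapt=0.2)
        sim = sb.simulate_stride_vectors(cfg)
        conds = np.asarray(sim["stride_conditions"])
        act = sim["activity"]
        d_on = sim["transition_deltas"]["on(+)"]
        idx = sim["index"]
        first_wash = np.flatnonzero(conds == "washout")[0]
        last_long = np.flatnonzero(conds == "longExposure")[-1]
        delta = act[first_wash] - act[last_long]
        expected = -0.2 * d_on + 0.7 * idx.mirror(d_on)
        np.testing.assert_allclose(delta, expected, atol=1e-9)
        np.testing.assert_array_equal(
            sim["transition_deltas"]["off(+)-long"], expected)

    def test_activity_nonnegative_in_raw_units(self, noiseless_trial):
        gt = noiseless_trial.ground_truth
        nmap = gt.normalization
        # normalized floor: raw = shift + scale*v/100 must be >= 0
        shift = np.array([nmap.shift[c] for c in noiseless_trial.emg.channels])
        scale = np.array([nmap.scale[c] for c in noiseless_trial.emg.channels])
        floor = -100.0 * shift / scale
        v = gt.activity.reshape(gt.activity.shape[0], 30, 12)
        assert np.all(v >= floor[None, :, None] - 1e-9)

    def test_noise_is_additive_iid(self):
        cfg = sb.SyntheticConfig(seed=3, noise_sd=7.0)
        sim = sb.simulate_stride_vectors(cfg, sb.ProtocolSchedule.compact())
        resid = sim["activity_noisy"] - sim["activity"]
        assert abs(resid.std() - 7.0) < 0.1
        assert abs(resid.mean()) < 0.1

    def test_collinearity_stays_moderate(self):
        for seed in range(5):
            sim = sb.simulate_stride_vectors(
                sb.SyntheticConfig(seed=seed), sb.ProtocolSchedule.compact())
            d = sim["transition_deltas"]["on(+)"]
            idx = sim["index"]
            c = np.dot(idx.mirror(d), -d) / np.dot(d, d)
            assert abs(c) < 0.9


class TestForceProfile:
    def _cfg(self):
        return sb.SyntheticConfig(seed=0)

    def test_single_stance_interval(self):
        ev = sb.GaitEvents(heel_strikes={"slow": np.array([1.0])},
                           toe_offs={"slow": np.array([1.6])})
        fz = sb.make_force_profile(ev, self._cfg())
        t = fz.times
        inside = (t >= 1.0) & (t < 1.6)
        assert np.all(fz.values[inside, 0] > 10.0)
        assert np.all(fz.values[~inside, 0] < 10.0)

    def test_empty_events_zero_force(self):
        fz = sb.make_force_profile(sb.GaitEvents(), self._cfg(), t_end=1.0)
        assert np.all(fz.values == 0.0)

    def test_overlapping_events_rejected(self):
        ev = sb.GaitEvents(heel_strikes={"slow": np.array([0.0, 0.5])},
                           toe_offs={"slow": np.array([0.7, 1.0])})
        with pytest.raises(Exception):
            sb.make_force_profile(ev, self._cfg())

    def test_round_trip_through_detector(self):
        rng = np.random.default_rng(4)
        t, hs, to = 0.5, [], []
        for _ in range(6):
            stance = round(rng.uniform(0.5, 0.8), 3)
            swing = round(rng.uniform(0.3, 0.5), 3)
            hs.append(t)
            to.append(t + stance)
            t += stance + swing
        ev = sb.GaitEvents(heel_strikes={"slow": np.array(hs)},
                           toe_offs={"slow": np.array(to)})
        fz = sb.make_force_profile(ev, self._cfg())
        det = sb.detect_gait_events(fz, leg_names={"fz_slow_N": "slow"})
        np.testing.assert_allclose(det.heel_strikes["slow"], hs, atol=1.01e-3)
        np.testing.assert_allclose(det.toe_offs["slow"], to, atol=1.01e-3)

    def test_trial_forces_respect_event_rule(self, noiseless_trial):
        gt = noiseless_trial.ground_truth.events
        fz = noiseless_trial.forces
        t = fz.times
        for leg, ch in (("slow", "fz_left_N"), ("fast", "fz_right_N")):
            f = fz.channel(ch)
            hs = gt.heel_strikes[leg]
            to = gt.toe_offs[leg]
            for k in range(min(10, len(to))):
                i0 = int(round(hs[k] * fz.sample_rate))
                i1 = int(round(to[k] * fz.sample_rate))
                assert np.all(f[i0:i1] > 10.0)
            # swing after first toe-off
            i1 = int(round(to[0] * fz.sample_rate))
            i2 = int(round(hs[1] * fz.sample_rate))
            assert np.all(f[i1:i2] < 10.0)


class TestContinuousTrial:
    def test_trial_determinism(self):
        sched = sb.ProtocolSchedule(conditions=(
            sb.Condition("baseline", 45, "tied-medium"),))
        cfg = sb.SyntheticConfig.compact(seed=9, noise_sd=5.0)
        t1 = sb.generate_trial(cfg, sched)
        t2 = sb.generate_trial(cfg, sched)
        np.testing.assert_array_equal(t1.emg.values, t2.emg.values)
        np.testing.assert_array_equal(t1.forces.values, t2.forces.values)
        np.testing.assert_array_equal(t1.markers.values, t2.markers.values)

    def test_binning_recovers_intended_values(self, noiseless_trial, noiseless_result):
        # the emitted EMG, after the full filter/rectify/bin/normalize
        # front-end, reproduces the generator's intended per-stride
        # activity to well below binning discretization
        gt = noiseless_trial.ground_truth
        worst = 0.0
        for cond, mat in noiseless_result.stride_matrices.items():
            rows = gt.condition_strides(cond)
            worst = max(worst, np.abs(mat - gt.activity[rows]).max())
        assert worst < 0.5  # % of baseline range; actual ~1e-9
        assert worst < 1e-6

    def test_stride_counts(self, noiseless_trial):
        gt = noiseless_trial.ground_truth
        for cond in noiseless_trial.schedule.conditions:
            assert gt.condition_strides(cond.name).size == cond.stride_count


def test_transition_targets_use_mirror():
    cfg = sb.SyntheticConfig(seed=1, b_adapt=0.5, b_no_adapt=0.3)
    rng = np.random.default_rng(0)
    from splitbelt.synth import _build_patterns
    pat = _build_patterns(cfg, rng)
    targets = transition_targets(cfg, pat)
    np.testing.assert_allclose(
        targets["off(+)-long"],
        -0.3 * targets["on(+)"] + 0.5 * pat.index.mirror(targets["on(+)"]))
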