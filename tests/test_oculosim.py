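import numpy as np
import pytest

from sacmod.oculosim import (
    CohortConfig,
    GroupLatencyModel,
    MainSequenceParams,
    simulate_cohort,
    simulate_latency_table,
    simulate_trial,
)
from sacmod.pipeline import extract_latencies


class TestSaccadeSegment:
    def test_zero_amplitude_is_flat(self):
        from sacmod.oculosim import simulate_saccade_segment
        _, pos, vel = simulate_saccade_segment(0.0)
        assert np.all(pos == 0) and np.all(vel == 0)

    def test_velocity_integrates_to_amplitude(self):
        from sacmod.oculosim import simulate_saccade_segment
        t, _, vel = simulate_saccade_segment(55.0, sampling_rate=2000.0)
        integral = np.trapezoid(vel, t) / 1000.0
        assert integral == pytest.approx(55.0, abs=0.1)

    def test_duration_is_physiological_at_55_deg(self):
        d = MainSequenceParams().duration_ms(55.0)
        assert 80.0 <= d <= 200.0

    @pytest.mark.parametrize("amp", [5.0, 10.0, 25.0, 55.0])
    def test_peak_velocity_exceeds_onset_threshold(self, amp):
        assert MainSequenceParams().peak_velocity_deg_s(amp) >= 60.0

    def test_position_monotone_and_velocity_unimodal(self):
        from sacmod.oculosim import simulate_saccade_segment
        _, pos, vel = simulate_saccade_segment(30.0, sampling_rate=1000.0)
        assert np.all(np.diff(pos) >= -1e-12)
        peak = vel.argmax()
        assert np.all(np.diff(vel[:peak + 1]) >= -1e-9)
        assert np.all(np.diff(vel[peak:]) <= 1e-9)

    def test_peak_velocity_saturates_with_amplitude(self):
        ms = MainSequenceParams()
        peaks = [ms.peak_velocity_deg_s(a) for a in (5, 15, 30, 55, 80)]
        assert all(b > a for a, b in zip(peaks, peaks[1:]))
        assert peaks[-1] < ms.vmax_asymptote_deg_s

    def test_rejects_negative_sampling_rate(self):
        from sacmod.oculosim import simulate_saccade_segment
        with pytest.raises(ValueError):
            simulate_saccade_segment(10.0, sampling_rate=-200.0)


class TestSimulateTrial:
    def test_noiseless_onset_is_exact(self, noiseless_trial):
        trace, event, truth = noiseless_trial
        assert truth.true_latency_ms == 200.0
        assert truth.true_saccade_onset_ms == event.second_target_onset_ms + 200.0
        before = trace.time_ms <= truth.true_saccade_onset_ms
        np.testing.assert_allclose(trace.x_deg[before], 0.0, atol=1e-12)
        assert trace.x_deg[-1] == pytest.approx(55.0)

    def test_leftward_trial_goes_negative(self, noiseless_subject):
        trace, _, truth = simulate_trial(noiseless_subject, "landolt", "left",
                                         noise_sd_deg=0.0, seed=2)
        assert truth.true_amplitude_deg == -55.0
        assert trace.x_deg[-1] == pytest.approx(-55.0)

    def test_same_seed_bitwise_identical(self, noiseless_subject):
        a = simulate_trial(noiseless_subject, "color", "right", seed=7)
        b = simulate_trial(noiseless_subject, "color", "right", seed=7)
        np.testing.assert_array_equal(a[0].x_deg, b[0].x_deg)
        np.testing.assert_array_equal(a[0].y_deg, b[0].y_deg)
        assert a[2] == b[2]

    def test_rejects_unknown_task_or_side(self, noiseless_subject):
        with pytest.raises(ValueError):
            simulate_trial(noiseless_subject, "antisaccade", "right")
        with pytest.raises(ValueError):
            simulate_trial(noiseless_subject, "color", "up")


class TestSimulateCohort:
    def test_default_cohort_composition(self):
        cfg = CohortConfig(seed=1)
        lat = simulate_latency_table(cfg)
        sizes = lat.drop_duplicates("subject_id").groupby("group").size()
        assert sizes.to_dict() == {"patient": 13, "control": 24, "relative": 10}
        assert (lat.groupby("subject_id").size() == 96).all()

    def test_blocks_are_exactly_balanced(self, small_cohort_config):
        ds = simulate_cohort(small_cohort_config, include_traces=False)
        ev = ds.event_table()
        per_block = ev.groupby(["subject_id", "block", "task"]).size()
        assert (per_block == small_cohort_config.trials_per_block // 2).all()
        per_side = ev.groupby(["subject_id", "block", "side"]).size()
        assert (per_side == small_cohort_config.trials_per_block // 2).all()

    def test_zero_size_group_omitted_with_warning(self):
        cfg = CohortConfig(group_sizes={"patient": 0, "control": 2},
                           n_trials=8, n_blocks=1, seed=3)
        with pytest.warns(UserWarning, match="size 0"):
            ds = simulate_cohort(cfg, include_traces=False)
        assert {s.params.group for s in ds.subjects} == {"control"}

    def test_zero_variance_cohort_recovers_group_means_exactly(self):
        cfg = CohortConfig(
            group_sizes={"control": 3},
            latency_models={"control": GroupLatencyModel(250, 0, 200, 0, 0, 0)},
            noise_sd_deg=0.0, n_trials=8, n_blocks=1, seed=5)
        lat = extract_latencies(simulate_cohort(cfg))
        # one detector sample of quantisation at 200 Hz
        by_task = lat.groupby("task")["latency_ms"]
        assert (by_task.std() == 0).all()
        assert abs(by_task.mean()["color"] - 250) <= 5.01
        assert abs(by_task.mean()["landolt"] - 200) <= 5.01

    def test_latencies_respect_floor(self):
        cfg = CohortConfig(
            group_sizes={"control": 6},
            latency_models={"control": GroupLatencyModel(120, 30, 100, 30, 60, 0)},
            n_trials=32, n_blocks=1, seed=8)
        lat = simulate_latency_table(cfg)
        assert (lat["latency_ms"] >= cfg.latency_floor_ms).all()

    def test_mean_shift_is_recovered(self):
        # raising a group's configured mean by delta moves the recovered
        # mean by delta within 2 standard errors
        delta = 40.0
        base = GroupLatencyModel(250.0, 40.0, 200.0, 30.0, 50.0, 0.5)
        shifted = GroupLatencyModel(250.0 + delta, 40.0, 200.0, 30.0, 50.0, 0.5)
        means = []
        for model in (base, shifted):
            cfg = CohortConfig(group_sizes={"control": 24},
                               latency_models={"control": model}, seed=13)
            lat = simulate_latency_table(cfg)
            subj = (lat[lat["task"] == "color"]
                    .groupby("subject_id")["latency_ms"].mean())
            means.append((subj.mean(), subj.std(ddof=1) / np.sqrt(len(subj))))
        observed = means[1][0] - means[0][0]
        se = np.hypot(means[0][1], means[1][1])
        assert abs(observed - delta) <= 2 * se

    def test_exgaussian_family_preserves_mean(self):
        model = GroupLatencyModel(260.0, 0.0, 260.0, 0.0, 40.0, 0.0)
        cfg = CohortConfig(group_sizes={"control": 4},
                           latency_models={"control": model},
                           latency_family="exgaussian", exgauss_tau_ms=60.0,
                           n_trials=96, n_blocks=3, seed=21)
        lat = simulate_latency_table(cfg)
        se = lat["latency_ms"].std(ddof=1) / np.sqrt(len(lat))
        assert lat["latency_ms"].mean() == pytest.approx(260.0, abs=4 * se)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_trials=95, n_blocks=3)
        with pytest.raises(ValueError):
            CohortConfig(n_trials=30, n_blocks=3)  # 10/block not divisible by 4
        with pytest.raises(ValueError):
            CohortConfig(noise_sd_deg=-0.1)
        with pytest.raises(ValueError):
            GroupLatencyModel(250, -1, 200, 30)
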