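"""Per-trial outcome measures: CoP proxy, asymmetry, events, arch features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tribogait import (AlignedTrial, arch_metrics, asymmetry_index, cadence,
                       composite_waveform, compute_cop_proxy,
                       compute_gait_metrics, detect_steps, segment_strides)
from tribogait.gait_metrics import InsufficientStepsError, _cop_from_values


def build_trial(insole_values, imu_values=None, sample_rate=100.0, n=None):
    """AlignedTrial straight from normalized channel values (constants or
    arrays)."""
    if n is None:
        n = 1500
    t = np.arange(n) / sample_rate
    insole = {}
    for i in range(8):
        v = insole_values.get(f"ch{i}", 0.0)
        insole[f"ch{i}"] = np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
    imu = {}
    for c in ("gyro_l", "gyro_r", "acc_l", "acc_r"):
        v = (imu_values or {}).get(c, 0.0)
        imu[c] = np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
    return AlignedTrial(time_s=t, insole_norm=pd.DataFrame(insole),
                        imu=pd.DataFrame(imu), sample_rate=sample_rate)


class TestCopProxy:
    def test_equal_load_on_mirrored_sensors_centres_mediolaterally(self, geometry):
        trial = build_trial({f"ch{i}": 0.5 for i in range(8)})
        cop = compute_cop_proxy(trial, geometry)
        assert np.allclose(cop.x_ml, 0.0, atol=1e-12)
        assert np.allclose(cop.y_ap, cop.y_ap[0])

    def test_single_loaded_sensor_sits_at_its_angle(self, geometry):
        ch = geometry.channel("right", "heel")
        trial = build_trial({f"ch{ch.channel_id}": 0.8})
        cop = compute_cop_proxy(trial, geometry)
        theta = np.deg2rad(ch.angle_deg)
        assert np.allclose(cop.x_ml, np.cos(theta))
        assert np.allclose(cop.y_ap, np.sin(theta))

    def test_weighted_resultant_hand_case(self):
        # 0.75 at 0 deg plus 0.25 at 90 deg -> (0.75, 0.25)
        values = np.array([[0.75, 0.25]])
        cop = _cop_from_values(values, np.array([0.0, 90.0]), eps=1e-6)
        assert cop.x_ml[0] == pytest.approx(0.75)
        assert cop.y_ap[0] == pytest.approx(0.25)

    def test_zero_load_samples_flagged_not_fabricated(self, geometry):
        trial = build_trial({"ch0": np.r_[np.zeros(750), np.full(750, 0.5)]})
        cop = compute_cop_proxy(trial, geometry)
        assert not cop.defined[:750].any()
        assert np.isnan(cop.x_ml[:750]).all()
        assert cop.defined[750:].all()

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=8, max_size=8),
           st.floats(0.1, 50.0))
    def test_unit_disc_bound_and_scale_invariance(self, geometry, loads, k):
        values = np.asarray(loads)[None, :]
        angles = np.array([c.angle_deg for c in
                           sorted(geometry.channels, key=lambda c: c.channel_id)])
        cop = _cop_from_values(values, angles, eps=1e-9)
        scaled = _cop_from_values(k * values, angles, eps=1e-9)
        if cop.defined[0]:
            assert np.hypot(cop.x_ml[0], cop.y_ap[0]) <= 1.0 + 1e-12
            assert scaled.x_ml[0] == pytest.approx(cop.x_ml[0], abs=1e-9)
            assert scaled.y_ap[0] == pytest.approx(cop.y_ap[0], abs=1e-9)

    def test_per_foot_scope_returns_both_feet(self, geometry):
        trial = build_trial({f"ch{i}": 0.3 for i in range(8)})
        per_foot = compute_cop_proxy(trial, geometry, scope="per_foot")
        assert set(per_foot) == {"left", "right"}
        # identical loading in mirrored local frames gives identical traces
        assert np.allclose(per_foot["left"].x_ml, per_foot["right"].x_ml)


class TestAsymmetryIndex:
    def test_balanced_feet_mean_zero(self, geometry):
        trial = build_trial({f"ch{i}": 0.4 for i in range(8)})
        assert asymmetry_index(trial, geometry).mean_pct == pytest.approx(0.0)

    def test_one_silent_foot_saturates(self, geometry):
        loads = {f"ch{c.channel_id}": 0.5 for c in geometry.foot("right")}
        trial = build_trial(loads)
        with pytest.warns(UserWarning, match="degenerate"):
            summary = asymmetry_index(trial, geometry)
        assert summary.mean_pct == pytest.approx(100.0)

    def test_left_double_right_gives_minus_third(self, geometry):
        loads = {f"ch{c.channel_id}": 0.6 for c in geometry.foot("left")}
        loads.update({f"ch{c.channel_id}": 0.3 for c in geometry.foot("right")})
        trial = build_trial(loads)
        assert asymmetry_index(trial, geometry).mean_pct == pytest.approx(
            -100.0 / 3.0, abs=1e-9)

    def test_antisymmetric_under_side_swap(self, geometry, default_trial):
        trial, _ = default_trial
        swap = {}
        for c in geometry.channels:
            mirror = geometry.channel(
                "left" if c.side == "right" else "right", c.region)
            swap[f"ch{c.channel_id}"] = trial.insole_norm[f"ch{mirror.channel_id}"]
        swapped = AlignedTrial(time_s=trial.time_s,
                               insole_norm=pd.DataFrame(swap)[trial.insole_norm.columns],
                               imu=trial.imu, sample_rate=trial.sample_rate)
        a = asymmetry_index(trial, geometry)
        b = asymmetry_index(swapped, geometry)
        assert np.allclose(a.series, -b.series, atol=1e-12)

    def test_series_bounded(self, default_trial, geometry):
        trial, _ = default_trial
        series = asymmetry_index(trial, geometry).series
        assert series.min() >= -100.0 and series.max() <= 100.0

    @pytest.mark.parametrize("injected", [-40.0, -20.0, 0.0, 20.0, 30.0])
    def test_injected_asymmetry_recovered_noise_free(self, injected, geometry,
                                                     params, profile_factory,
                                                     simulate_aligned_factory):
        trial, truth = simulate_aligned_factory(
            profile_factory(asym=injected), geometry, params, seed=21,
            noise_scale=0.0)
        got = asymmetry_index(trial, geometry).mean_pct
        assert abs(got - injected) <= 2.0

    def test_injected_asymmetry_recovered_under_noise(self, geometry, params,
                                                      profile_factory,
                                                      simulate_aligned_factory):
        # default noise, several seeds per injected value
        for injected in (-40.0, 0.0, 30.0):
            errs = []
            for seed in range(5):
                trial, _ = simulate_aligned_factory(
                    profile_factory(asym=injected), geometry, params,
                    duration_s=60, seed=30 + seed)
                errs.append(asymmetry_index(trial, geometry).mean_pct - injected)
            assert max(abs(e) for e in errs) <= 5.0


class TestSteps:
    def test_noise_free_trial_event_count(self, geometry, params,
                                          profile_factory,
                                          simulate_aligned_factory):
        trial, truth = simulate_aligned_factory(
            profile_factory(cadence=100.0), geometry, params, seed=41,
            noise_scale=0.0)
        events = detect_steps(trial, "imu")
        total = len(events["left"]) + len(events["right"])
        assert total == len(truth.step_times_left) + len(truth.step_times_right)

    def test_flat_signal_raises_insufficient_steps(self, geometry):
        trial = build_trial({f"ch{i}": 0.2 for i in range(8)})
        with pytest.raises(InsufficientStepsError):
            detect_steps(trial, "imu")

    def test_noisy_event_count_close_to_truth(self, default_trial):
        trial, truth = default_trial
        events = detect_steps(trial, "imu")
        total = len(events["left"]) + len(events["right"])
        true_total = len(truth.step_times_left) + len(truth.step_times_right)
        assert abs(total - true_total) <= 3

    def test_sides_interleave(self, default_trial):
        trial, _ = default_trial
        events = detect_steps(trial, "imu")
        merged = sorted([(t, "L") for t in events["left"]]
                        + [(t, "R") for t in events["right"]])
        sides = "".join(s for _, s in merged)
        assert "LLL" not in sides and "RRR" not in sides

    def test_imu_and_heel_sources_agree(self, default_trial, geometry):
        trial, _ = default_trial
        c_imu = cadence(detect_steps(trial, "imu"))
        c_heel = cadence(detect_steps(trial, "heel_sensor", geometry=geometry))
        assert abs(c_imu - c_heel) <= 2.0

    @pytest.mark.parametrize("truth_cadence", [80.0, 100.0, 130.0])
    def test_cadence_recovery(self, truth_cadence, geometry, params,
                              profile_factory, simulate_aligned_factory):
        quiet, _ = simulate_aligned_factory(
            profile_factory(cadence=truth_cadence), geometry, params,
            seed=42, noise_scale=0.0)
        assert abs(cadence(detect_steps(quiet, "imu")) - truth_cadence) <= 1.0
        noisy, _ = simulate_aligned_factory(
            profile_factory(cadence=truth_cadence), geometry, params, seed=43)
        assert abs(cadence(detect_steps(noisy, "imu")) - truth_cadence) <= 3.0


class TestCadenceFormula:
    def test_evenly_spaced_closed_form(self):
        times = np.linspace(0.0, 119.4, 200)
        assert cadence(times) == pytest.approx(100.0)

    def test_one_hertz_per_side_is_120(self):
        left = np.arange(0.0, 30.0, 1.0)
        right = left + 0.5
        assert cadence({"left": left, "right": right}) == pytest.approx(
            120.0, abs=0.5)

    def test_too_few_steps_rejected(self):
        with pytest.raises(InsufficientStepsError):
            cadence(np.array([0.0, 1.0]))

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            cadence(np.arange(10.0), duration_s=0.0)


class TestStrides:
    def test_two_minute_trial_yields_over_fifty_per_side(self, default_trial):
        trial, _ = default_trial
        strides = segment_strides(trial, detect_steps(trial, "imu"))
        assert strides["left"]["matrix"].shape[0] > 50
        assert strides["right"]["matrix"].shape[0] > 50

    def test_out_of_window_stride_dropped(self, default_trial):
        trial, _ = default_trial
        events = {"left": np.array([10.0, 20.0, 21.2]), "right": np.array([])}
        strides = segment_strides(trial, events)
        assert strides["left"]["n_invalid"] == 1   # the 10 s gap
        assert strides["left"]["matrix"].shape[0] == 1

    def test_periodic_noise_free_strides_identical(self, geometry, params,
                                                   profile_factory,
                                                   simulate_aligned_factory):
        trial, _ = simulate_aligned_factory(
            profile_factory(cadence=100.0), geometry, params, duration_s=60,
            seed=44, noise_scale=0.0)
        strides = segment_strides(trial, detect_steps(trial, "imu"))
        matrix = strides["left"]["matrix"][1:-1]  # interior strides
        spread = np.abs(matrix - matrix.mean(axis=0)).max()
        assert spread <= 1e-9

    def test_no_valid_strides_rejected(self, default_trial):
        trial, _ = default_trial
        with pytest.raises(ValueError, match="valid strides"):
            segment_strides(trial, {"left": np.array([0.0, 50.0]),
                                    "right": np.array([])})


class TestCompositeWaveform:
    def test_single_stride_is_itself_rescaled(self):
        stride = np.random.default_rng(0).random((1, 100, 8))
        curve = composite_waveform(stride)
        expected = stride[0].mean(axis=1)
        assert np.allclose(curve, expected / np.abs(expected).max())

    def test_mean_is_idempotent_for_identical_strides(self):
        stride = np.random.default_rng(1).random((1, 100, 8))
        two = np.concatenate([stride, stride])
        assert np.allclose(composite_waveform(two), composite_waveform(stride))

    def test_heel_weighted_composite_peaks_early(self, default_trial, geometry):
        trial, _ = default_trial
        strides = segment_strides(trial, detect_steps(trial, "imu"))
        info = strides["left"]
        weights = np.zeros(len(info["channels"]))
        heel = geometry.channel("left", "heel")
        weights[info["channels"].index(f"ch{heel.channel_id}")] = 1.0
        curve = composite_waveform(info["matrix"], weights)
        assert int(np.argmax(curve)) < 50  # heel loads in the first half

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            composite_waveform(np.empty((0, 100, 8)))


class TestArchMetrics:
    def test_zero_midfoot_gives_zero_index_and_no_flag(self, geometry):
        loads = {}
        for side in ("left", "right"):
            for region in ("big_toe", "forefoot", "heel"):
                loads[f"ch{geometry.channel(side, region).channel_id}"] = 0.3
        trial = build_trial(loads)
        out = arch_metrics(trial, geometry)
        for side in ("left", "right"):
            assert out[side]["arch_index_pct"] == pytest.approx(0.0)
            assert not out[side]["flatfoot_flag"]

    def test_equal_regional_loads_index_is_one_third(self, geometry):
        trial = build_trial({f"ch{i}": 0.25 for i in range(8)})
        out = arch_metrics(trial, geometry)
        assert out["left"]["arch_index_pct"] == pytest.approx(100.0 / 3.0)

    def test_simulated_flatfoot_recovered(self, geometry, params,
                                          profile_factory,
                                          simulate_aligned_factory):
        flat, _ = simulate_aligned_factory(
            profile_factory(flatfoot="bilateral"), geometry, params,
            duration_s=30, seed=45)
        out = arch_metrics(flat, geometry)
        assert out["left"]["flatfoot_flag"] and out["right"]["flatfoot_flag"]
        normal, _ = simulate_aligned_factory(
            profile_factory(flatfoot="none"), geometry, params,
            duration_s=30, seed=46)
        out = arch_metrics(normal, geometry)
        assert not out["left"]["flatfoot_flag"]
        assert not out["right"]["flatfoot_flag"]

    def test_zero_total_load_rejected(self, geometry):
        trial = build_trial({})
        with pytest.raises(ValueError, match="zero"):
            arch_metrics(trial, geometry)


class TestTrialSummary:
    def test_full_pipeline_summary(self, default_trial, geometry):
        trial, truth = default_trial
        metrics = compute_gait_metrics(trial, geometry)
        assert metrics.cadence == pytest.approx(truth.cadence, abs=3.0)
        assert metrics.n_strides_left > 50 and metrics.n_strides_right > 50
        assert 0.0 <= metrics.arch_index_left <= 100.0
        assert 0.0 <= metrics.arch_index_right <= 100.0
        assert metrics.composite.shape == (100,)
        assert metrics.composite.max() == pytest.approx(1.0)
        d = metrics.to_dict()
        assert set(d) >= {"cadence", "asymmetry_mean_pct", "flatfoot_left"}
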