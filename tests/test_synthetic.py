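"""Stimulus grid, presentation protocol and gaze-signal generator."""

import numpy as np
import pytest

from driftspec.config import FilterSpec, PupilArtifact, SimulationConfig
from driftspec.errors import DomainError, InvalidConfigError
from driftspec.geometry import fick_from_vector
from driftspec.synthetic import (
    apply_recording_filter,
    build_presentation_sequence,
    build_target_grid,
    center_target,
    simulate_artificial_eye,
    simulate_gaze_vectors,
    simulate_human_recording,
)


class TestTargetGrid:
    def test_point_counts(self, target_grid):
        assert len(target_grid) == 53
        outer, inner = target_grid[:32], target_grid[32:]
        assert len(outer) == 32 and len(inner) == 21

    def test_span(self, target_grid):
        xs = [t.x_cm for t in target_grid]
        ys = [t.y_cm for t in target_grid]
        assert max(xs) - min(xs) == pytest.approx(45.5)
        assert max(ys) - min(ys) == pytest.approx(26.8)

    def test_central_inner_point_at_origin(self, target_grid):
        c = center_target(target_grid)
        assert c.x_cm == pytest.approx(0.0, abs=1e-12)
        assert c.y_cm == pytest.approx(0.0, abs=1e-12)
        assert c.grid_id >= 32  # it is one of the inner points

    def test_inner_points_at_outer_cell_centers(self, target_grid):
        outer = target_grid[:32]
        inner = target_grid[32:]
        # each inner point must be the midpoint of four neighboring outer points
        centers = set()
        xs = sorted({round(t.x_cm, 9) for t in outer})
        ys = sorted({round(t.y_cm, 9) for t in outer})
        for i in range(len(ys) - 1):
            for j in range(len(xs) - 1):
                centers.add(
                    (round((xs[j] + xs[j + 1]) / 2, 6), round((ys[i] + ys[i + 1]) / 2, 6))
                )
        got = {(round(t.x_cm, 6), round(t.y_cm, 6)) for t in inner}
        assert got == centers

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(InvalidConfigError):
            build_target_grid(span_w_cm=-1.0)
        with pytest.raises(InvalidConfigError):
            build_target_grid(viewing_distance_cm=0.0)


class TestPresentationSequence:
    def test_total_presentations(self, protocol):
        assert len(protocol) == 213

    def test_each_target_four_times_after_initial(self, target_grid):
        proto = build_presentation_sequence(target_grid, seed=3)
        ids = [p.target.grid_id for p in proto.presentations[1:]]
        counts = np.bincount(ids, minlength=53)
        assert np.all(counts == 4)

    def test_same_seed_reproduces_sequence(self, target_grid):
        a = build_presentation_sequence(target_grid, seed=5)
        b = build_presentation_sequence(target_grid, seed=5)
        assert [p.target.grid_id for p in a.presentations] == [
            p.target.grid_id for p in b.presentations
        ]

    def test_onsets_are_contiguous_1500ms(self, protocol):
        onsets = np.array([p.onset_ms for p in protocol.presentations])
        np.testing.assert_allclose(np.diff(onsets), 1500.0)

    def test_rejects_zero_repeats(self, target_grid):
        with pytest.raises(InvalidConfigError):
            build_presentation_sequence(target_grid, repeats=0)


class TestRecordingFilter:
    def test_constant_passes_unchanged(self):
        x = np.full(100, 3.7)
        for spec in (
            FilterSpec(kind="moving_average", order=8),
            FilterSpec(kind="exponential", smoothing=0.3),
        ):
            np.testing.assert_allclose(apply_recording_filter(x, spec), x, atol=1e-12)

    def test_none_is_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_array_equal(apply_recording_filter(x, None), x)
        np.testing.assert_array_equal(
            apply_recording_filter(x, FilterSpec(kind="none")), x
        )

    def test_moving_average_lag1_autocorrelation(self, rng):
        # white noise through an order-m moving average has lag-1
        # autocorrelation (m-1)/m
        x = rng.normal(size=200_000)
        y = apply_recording_filter(x, FilterSpec(kind="moving_average", order=8))
        y = y - y.mean()
        rho1 = np.dot(y[1:], y[:-1]) / np.dot(y, y)
        assert rho1 == pytest.approx(7 / 8, abs=0.01)

    def test_preserves_mean_of_long_trace(self, rng):
        x = rng.normal(loc=2.0, size=100_000)
        for spec in (
            FilterSpec(kind="moving_average", order=16),
            FilterSpec(kind="exponential", smoothing=0.1),
        ):
            y = apply_recording_filter(x, spec)
            assert y.mean() == pytest.approx(x.mean(), abs=5e-3)

    def test_output_length_matches_input(self, rng):
        x = rng.normal(size=123)
        for spec in (
            FilterSpec(kind="moving_average", order=8),
            FilterSpec(kind="exponential", smoothing=0.5),
        ):
            assert len(apply_recording_filter(x, spec)) == 123

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidConfigError):
            apply_recording_filter(np.zeros(10), FilterSpec(kind="butterworth"))


class TestHumanSimulation:
    def test_noiseless_config_tracks_targets_exactly(self, protocol):
        cfg = SimulationConfig(
            fs_hz=250.0, noise_sd_deg=0.0, drift_step_sd_deg=0.0,
            microsaccade_rate_hz=0.0, microsaccade_amp_deg=0.0, seed=0,
        )
        rec = simulate_human_recording(protocol, cfg)
        n_per = int(round(1500 * 250 / 1000))
        for i, pres in enumerate(protocol.presentations[:5]):
            seg = slice(i * n_per, (i + 1) * n_per)
            np.testing.assert_array_equal(rec.x_deg[seg], pres.target.x_deg)
            np.testing.assert_array_equal(rec.y_deg[seg], pres.target.y_deg)

    def test_noise_sd_recovered(self, protocol):
        cfg = SimulationConfig(
            fs_hz=500.0, noise_sd_deg=0.05, drift_step_sd_deg=0.0,
            microsaccade_rate_hz=0.0, microsaccade_amp_deg=0.0, seed=2,
        )
        rec = simulate_human_recording(protocol, cfg)
        # remove the target staircase before measuring the noise
        n_per = int(round(1500 * 500 / 1000))
        resid = rec.x_deg - np.repeat(
            [p.target.x_deg for p in protocol.presentations], n_per
        )
        assert np.std(resid) == pytest.approx(0.05, rel=0.02)

    def test_drift_increments_iid_with_configured_sd(self, protocol):
        cfg = SimulationConfig(
            fs_hz=1000.0, noise_sd_deg=0.0, drift_step_sd_deg=0.01,
            microsaccade_rate_hz=0.0, microsaccade_amp_deg=0.0, seed=3,
        )
        rec = simulate_human_recording(protocol, cfg)
        n_per = 1500
        # increments within one trial (skip boundaries where drift restarts)
        inc = np.diff(rec.x_deg[: 100 * n_per].reshape(100, n_per), axis=1).ravel()
        assert np.std(inc) == pytest.approx(0.01, rel=0.02)
        lag1 = np.corrcoef(inc[1:], inc[:-1])[0, 1]
        assert abs(lag1) < 0.01

    def test_bit_identical_determinism(self, protocol):
        cfg = SimulationConfig(fs_hz=250.0, isi_jitter_pct=2.0, seed=42)
        a = simulate_human_recording(protocol, cfg)
        b = simulate_human_recording(protocol, cfg)
        np.testing.assert_array_equal(a.x_deg, b.x_deg)
        np.testing.assert_array_equal(a.y_deg, b.y_deg)
        np.testing.assert_array_equal(a.timestamps_ms, b.timestamps_ms)

    def test_timestamp_jitter_sd_matches_config(self):
        from driftspec.spectra import compute_isi_jitter
        from driftspec.experiment import _single_fixation_protocol

        proto = _single_fixation_protocol(40_000.0)  # 4e4 samples at 1000 Hz
        cfg = SimulationConfig(
            fs_hz=1000.0, noise_sd_deg=0.01, drift_step_sd_deg=0.0,
            microsaccade_rate_hz=0.0, microsaccade_amp_deg=0.0,
            isi_jitter_pct=5.0, seed=4,
        )
        rec = simulate_human_recording(proto, cfg)
        measured = compute_isi_jitter(rec.timestamps_ms, 1.0)
        # re-sorting clips the largest excursions, so allow 10% relative error
        assert measured == pytest.approx(5.0, rel=0.10)

    def test_pupil_artifact_adds_slow_oscillation(self, protocol):
        cfg = SimulationConfig(
            fs_hz=250.0, noise_sd_deg=0.0, drift_step_sd_deg=0.0,
            microsaccade_rate_hz=0.0, microsaccade_amp_deg=0.0,
            pupil_artifact=PupilArtifact(amplitude_deg=0.2, freq_hz=0.2), seed=5,
        )
        rec = simulate_human_recording(protocol, cfg)
        n_per = int(round(1500 * 250 / 1000))
        resid = rec.x_deg - np.repeat(
            [p.target.x_deg for p in protocol.presentations], n_per
        )
        # sinusoid of amplitude A has SD A/sqrt(2)
        assert np.std(resid) == pytest.approx(0.2 / np.sqrt(2), rel=0.1)
        assert rec.pupil is not None


class TestArtificialEye:
    def test_sample_count_19s_at_250hz(self):
        cfg = SimulationConfig.artificial_default(fs_hz=250.0, seed=0)
        rec = simulate_artificial_eye(cfg, duration_ms=19_000.0)
        assert len(rec) == 4750
        assert rec.source == "artificial"

    def test_rejects_nonzero_eye_movement_parameters(self):
        cfg = SimulationConfig(fs_hz=250.0, drift_step_sd_deg=0.01,
                               microsaccade_rate_hz=0.0, microsaccade_amp_deg=0.0)
        with pytest.raises(InvalidConfigError, match="drift_step_sd_deg"):
            simulate_artificial_eye(cfg)

    def test_default_noise_is_one_third_of_human(self):
        human = SimulationConfig()
        art = SimulationConfig.artificial_default()
        assert art.noise_sd_deg == pytest.approx(human.noise_sd_deg / 3)

    def test_trace_is_white_noise_at_configured_sd(self):
        cfg = SimulationConfig.artificial_default(fs_hz=1000.0, seed=6)
        rec = simulate_artificial_eye(cfg, duration_ms=19_000.0)
        assert np.std(rec.x_deg) == pytest.approx(cfg.noise_sd_deg, rel=0.03)
        lag1 = np.corrcoef(rec.x_deg[1:], rec.x_deg[:-1])[0, 1]
        assert abs(lag1) < 0.02


class TestGazeVectors:
    def test_straight_ahead_vector(self):
        cfg = SimulationConfig.artificial_default(noise_sd_deg=0.0, fs_hz=100.0, seed=0)
        rec = simulate_artificial_eye(cfg, duration_ms=1000.0)
        rec = simulate_gaze_vectors(rec)
        np.testing.assert_allclose(rec.gaze_vector, [[0.0, 0.0, 1.0]] * len(rec))

    def test_round_trip_reproduces_angles(self, rng):
        cfg = SimulationConfig.artificial_default(
            fs_hz=100.0, noise_sd_deg=5.0, seed=7
        )
        rec = simulate_artificial_eye(cfg, duration_ms=2000.0)
        rec = simulate_gaze_vectors(rec)
        norms = np.linalg.norm(rec.gaze_vector, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        theta, phi = fick_from_vector(rec.gaze_vector)
        np.testing.assert_allclose(theta, rec.x_deg, atol=1e-9)
        np.testing.assert_allclose(phi, rec.y_deg, atol=1e-9)


class TestConfigValidation:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(
            fs_hz=250.0, noise_sd_deg=0.1,
            filter_spec=FilterSpec(kind="moving_average", order=4),
            pupil_artifact=PupilArtifact(amplitude_deg=0.05, freq_hz=0.1),
            isi_jitter_pct=1.5, seed=9,
        )
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fs_hz": 0.0},
            {"noise_sd_deg": -1.0},
            {"isi_jitter_pct": 20.0},
            {"filter_spec": FilterSpec(kind="moving_average", order=0)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(**kwargs).validate()
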