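import numpy as np
import pytest

from tremorclust import (
    ConfigurationError,
    GroundTruthRecord,
    SimulationConfig,
    instances_from_config,
    mean_center,
    modulus,
    severity_to_amplitude,
    simulate_cohort,
    simulate_recording,
    study_cohort_config,
    tremor_acceleration_amplitude_g,
)
from tremorclust.preprocessing import extract_rest_segments
from tremorclust.synthetic import REST_LABEL


class TestSeverityToAmplitude:
    def test_no_tremor_is_exactly_zero(self, rng):
        assert severity_to_amplitude(0, rng) == 0.0

    def test_mild_band(self, rng):
        draws = [severity_to_amplitude(2, rng) for _ in range(50)]
        assert all(1.0 <= d < 3.0 for d in draws)

    def test_seeded_draw_is_reproducible(self):
        a = severity_to_amplitude(3, np.random.default_rng(7))
        b = severity_to_amplitude(3, np.random.default_rng(7))
        assert a == b and 3.0 <= a < 10.0

    @pytest.mark.parametrize("bad", [-1, 5, 2.5, "2"])
    def test_invalid_severity(self, bad, rng):
        with pytest.raises(ValueError):
            severity_to_amplitude(bad, rng)


class TestSimulateRecording:
    def test_control_without_noise_is_pure_gravity(self):
        cfg = SimulationConfig(noise_sd=0.0, seed=3)
        truth = GroundTruthRecord("hc", "HC", 0, 0.0, 0.0)
        rec, ann = simulate_recording(cfg, truth)
        rest = extract_rest_segments(rec, ann, {REST_LABEL})
        m = modulus(mean_center(rest))
        np.testing.assert_allclose(m, 0.0, atol=1e-12)
        # gravity itself is untouched: raw magnitude is 1 g everywhere at rest
        np.testing.assert_allclose(np.linalg.norm(rest, axis=1), 1.0, rtol=1e-12)

    def test_tremor_peak_follows_sinusoidal_kinematics(self):
        # at 5 Hz and 31.25 Hz sampling the sine hits 25 distinct phases, so
        # the sampled peak sits within cos(pi/25) of the true amplitude
        cfg = SimulationConfig(noise_sd=0.0, tremor_freq_range=(5.0, 5.0), seed=11)
        truth = GroundTruthRecord("pd", "PD", 3, 5.0, 8.0)
        rec, ann = simulate_recording(cfg, truth)
        rest = extract_rest_segments(rec, ann, {REST_LABEL})
        m = modulus(mean_center(rest))
        expected = tremor_acceleration_amplitude_g(5.0, 8.0)
        assert expected == pytest.approx((2 * np.pi * 5.0) ** 2 * 0.04 / 9.81)
        assert m.max() <= expected * (1 + 1e-9)
        assert m.max() >= expected * np.cos(np.pi / 25) * (1 - 1e-9)

    def test_tremor_absent_outside_rest(self):
        cfg = SimulationConfig(noise_sd=0.0, filler_amplitude=0.0, seed=5)
        truth = GroundTruthRecord("pd", "PD", 3, 5.0, 8.0)
        rec, ann = simulate_recording(cfg, truth)
        filler = extract_rest_segments(rec, ann, {"task"})
        assert np.linalg.norm(filler - filler.mean(axis=0), axis=1).max() < 1e-12

    def test_same_seed_same_samples(self):
        cfg = SimulationConfig(seed=9)
        truth = GroundTruthRecord("pd", "PD", 2, 5.0, 2.0)
        rec1, _ = simulate_recording(cfg, truth)
        rec2, _ = simulate_recording(cfg, truth)
        np.testing.assert_array_equal(rec1.acc, rec2.acc)

    def test_amplitude_outside_band_rejected(self):
        cfg = SimulationConfig()
        truth = GroundTruthRecord("pd", "PD", 1, 5.0, 5.0)
        with pytest.raises(ConfigurationError, match="band"):
            simulate_recording(cfg, truth)


class TestSimulateCohort:
    def test_counts_and_unique_ids(self):
        recs, truths = simulate_cohort(SimulationConfig(seed=1))
        assert len(recs) == len(truths) == 4
        ids = [t.instance_id for t in truths]
        assert len(set(ids)) == 4

    def test_study_sized_cohort(self):
        recs, truths = simulate_cohort(study_cohort_config(seed=2))
        assert len(recs) == 25
        assert sum(t.group == "HC" for t in truths) == 11
        assert all((t.group == "HC") == (t.true_score == 0) for t in truths)

    def test_cohort_bit_reproducible(self):
        cfg = study_cohort_config(seed=5)
        recs1, truths1 = simulate_cohort(cfg)
        recs2, truths2 = simulate_cohort(cfg)
        assert truths1 == truths2
        for (r1, _), (r2, _) in zip(recs1, recs2):
            np.testing.assert_array_equal(r1.acc, r2.acc)

    def test_mean_modulus_monotone_in_severity(self):
        # separated bands, small noise: rest-segment intensity must rank the
        # severity levels on every seed
        bands = {0: (0.0, 0.0), 1: (2.2, 2.4), 2: (3.95, 4.3), 3: (7.1, 7.75)}
        for seed in range(10):
            cfg = SimulationConfig(
                n_per_severity={0: 1, 1: 1, 2: 1, 3: 1},
                amplitude_bands=bands,
                tremor_freq_range=(5.0, 5.0),
                noise_sd=0.005,
                rest_duration=10.0,
                n_rest_intervals=2,
                filler_duration=5.0,
                seed=seed,
            )
            instances = instances_from_config(cfg)
            means = [inst.moduli.mean() for inst in instances]
            assert means == sorted(means)


class TestConfigValidation:
    def test_zero_rest_intervals(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_rest_intervals=0)

    def test_negative_noise(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(noise_sd=-0.1)

    def test_overlapping_bands(self):
        with pytest.raises(ConfigurationError, match="non-overlapping"):
            SimulationConfig(
                amplitude_bands={0: (0.0, 0.0), 1: (0.0, 2.0), 2: (1.0, 3.0), 3: (3.0, 10.0)}
            )

    def test_nonzero_control_band(self):
        with pytest.raises(ConfigurationError, match="severity 0"):
            SimulationConfig(
                amplitude_bands={0: (0.0, 0.5), 1: (0.5, 1.0), 2: (1.0, 3.0), 3: (3.0, 10.0)}
            )
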