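import dataclasses

import numpy as np
import pytest

import micropoint as mp


def _noiseless_config(**overrides):
    base = dict(
        n_healthy=3,
        n_iamd=0,
        n_exams=2,
        device_offset=0.0,
        noise_sd_healthy=0.0,
        noise_sd_unaffected=0.0,
        noise_sd_lesion=0.0,
        seed=5,
    )
    base.update(overrides)
    return mp.SimulationConfig(**base)


class TestSimulateEye:
    def test_noiseless_healthy_equals_expectation(self, model):
        exams, truth = mp.simulate_eye(_noiseless_config(), "healthy", 0)
        assert len(exams) == 2
        expected = mp.expected_threshold(model, exams[0].age)
        # thresholds are quantised to 0.1 dB, hence the half-step bound
        assert exams[0].thresholds == pytest.approx(expected, abs=0.051)
        np.testing.assert_array_equal(exams[0].thresholds, exams[1].thresholds)
        assert truth["n_affected"] == 0

    def test_fixed_seed_reproducible(self):
        config = mp.SimulationConfig(n_healthy=2, n_iamd=2, seed=99)
        a = mp.simulate_cohort(config)
        b = mp.simulate_cohort(config)
        for ea, eb in zip(a.exams, b.exams):
            assert ea.exam_id == eb.exam_id
            np.testing.assert_array_equal(ea.thresholds, eb.thresholds)
            assert ea.false_positive_rate == eb.false_positive_rate
        assert a.truth.equals(b.truth)

    def test_generation_order_independent(self):
        """Each eye's stream depends only on (seed, cohort, index)."""
        config = mp.SimulationConfig(n_healthy=5, n_iamd=0, seed=13)
        full = mp.simulate_cohort(config)
        solo, _ = mp.simulate_eye(config, "healthy", 3)
        matching = [e for e in full.exams if e.subject_id == solo[0].subject_id]
        for a, b in zip(matching, solo):
            np.testing.assert_array_equal(a.thresholds, b.thresholds)

    def test_lesion_count_recovered_by_scoring(self, model, criteria):
        """With 12 affected points at -6 dB and unit noise, the mean
        abnormal count equals the analytic flag expectation of ~12."""
        config = mp.SimulationConfig(
            n_healthy=0,
            n_iamd=300,
            n_exams=1,
            diffuse_mean=0.0,
            diffuse_sd=0.0,
            lesion_count_mean=12.0,
            lesion_count_sd=0.0,
            lesion_depth_mean=-6.0,
            lesion_depth_sd=0.0,
            lesion_point_sd=0.0,
            noise_sd_unaffected=1.0,
            noise_sd_lesion=1.0,
            seed=21,
        )
        dataset = mp.simulate_cohort(config)
        assert (dataset.truth["n_affected"] == 12).all()
        offset = mp.CalibrationOffset(config.device_offset)
        counts = [
            mp.summarize_eye(
                mp.score_exam(e, model, offset, criteria), criteria[0], exam=e
            ).n_abnormal
            for e in dataset.exams
        ]
        # analytic: 12*Phi((6-2.937)/1) + 21*Phi(-2.937) = 12.02
        assert np.mean(counts) == pytest.approx(12.02, abs=0.35)

    def test_sector_lesions_are_contiguous_in_angle(self, grid):
        config = mp.SimulationConfig(
            n_iamd=5, lesion_count_mean=8, lesion_count_sd=0.0, seed=2
        )
        _, truth = mp.simulate_eye(config, "iAMD", 1)
        affected = [int(i) for i in truth["affected_indices"].split(";")]
        order = [
            p.index
            for p in sorted(
                (p for p in grid.points if p.eccentricity > 0),
                key=lambda p: (p.angle, p.eccentricity),
            )
        ] + [p.index for p in grid.points if p.eccentricity == 0]
        positions = sorted(order.index(i) for i in affected)
        wrapped = {(p - positions[0]) % len(order) for p in positions}
        assert wrapped == set(range(len(affected)))


class TestSimulateCohort:
    def test_empty_dataset(self):
        dataset = mp.simulate_cohort(mp.SimulationConfig(n_healthy=0, n_iamd=0))
        assert dataset.exams == []
        assert len(dataset.truth) == 0

    def test_offset_recovery_at_scale(self, model):
        config = mp.SimulationConfig(n_healthy=200, n_iamd=0, seed=31)
        dataset = mp.simulate_cohort(config)
        offset = mp.estimate_offset(model, dataset.exams)
        assert offset.offset == pytest.approx(2.67, abs=0.1)

    def test_healthy_deviations_center_on_zero(self, model, criteria):
        config = mp.SimulationConfig(n_healthy=100, n_iamd=0, seed=17)
        dataset = mp.simulate_cohort(config)
        offset = mp.CalibrationOffset(config.device_offset)
        devs = [
            mp.summarize_eye(
                mp.score_exam(e, model, offset, criteria), criteria[0], exam=e
            ).mean_deviation_all
            for e in dataset.exams
        ]
        assert np.mean(devs) == pytest.approx(0.0, abs=0.1)

    def test_cohort_structure_matches_disease_profile(self, model, criteria):
        """Default iAMD cohorts show the expected depressed, heterogeneous
        structure: whole-grid mean deviation near -2.3 dB, within-grid SD
        near 2.4 dB, roughly a third of points abnormal with deep mean
        deviation of the abnormal subset."""
        config = mp.SimulationConfig(n_healthy=0, n_iamd=150, seed=8)
        dataset = mp.simulate_cohort(config)
        offset = mp.CalibrationOffset(config.device_offset)
        outs = [
            mp.summarize_eye(
                mp.score_exam(e, model, offset, criteria), criteria[0], exam=e
            )
            for e in dataset.exams
            if e.exam_index == 1
        ]
        md = np.mean([o.mean_deviation_all for o in outs])
        sd = np.mean([o.within_grid_sd for o in outs])
        frac = np.mean([o.frac_abnormal for o in outs])
        dev_abn = np.mean(
            [o.mean_deviation_abnormal for o in outs if o.has_abnormal]
        )
        assert -2.9 <= md <= -1.6
        assert 2.0 <= sd <= 3.0
        assert 0.25 <= frac <= 0.50
        assert -5.6 <= dev_abn <= -4.2

    def test_truncation_warning_for_deep_lesions(self, caplog):
        config = mp.SimulationConfig(
            n_healthy=0,
            n_iamd=20,
            lesion_depth_mean=-28.0,
            lesion_depth_sd=0.0,
            seed=3,
        )
        with caplog.at_level("WARNING"):
            mp.simulate_cohort(config)
        assert "truncated" in caplog.text

    def test_truncation_rare_under_defaults(self):
        dataset = mp.simulate_cohort(mp.SimulationConfig(seed=4))
        assert dataset.truth["clipped_fraction"].mean() < 0.01

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="noise_sd_healthy"):
            mp.SimulationConfig(noise_sd_healthy=-1.0)
        with pytest.raises(ValueError, match="spatial_mode"):
            mp.SimulationConfig(spatial_mode="ring")
        with pytest.raises(ValueError, match="grid size"):
            mp.SimulationConfig(lesion_count_mean=40)
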