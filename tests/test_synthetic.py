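"""Generator: minimum-jerk primitives, impairment monotonicity, labels, cohort."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

from strokekin.biomarkers import extract_features
from strokekin.errors import ConfigurationError, InvalidIntervalError
from strokekin.segmentation import compute_speed, segment_htm
from strokekin.synthetic import (
    GeneratorConfig,
    SubjectProfile,
    assign_fma,
    generate_cohort,
    generate_trial,
    minimum_jerk,
)


def _features_at(sid: str, s: float, cfg=None, trial_index: int = 1):
    cfg = cfg or GeneratorConfig()
    trial = generate_trial(
        SubjectProfile(sid, "patient", "development", s), cfg, trial_index
    )
    return extract_features(trial, segment_htm(compute_speed(trial)))


class TestMinimumJerk:
    def test_midpoint_symmetry_and_rest_endpoints(self):
        t = np.linspace(-0.5, 1.5, 2001)
        pos, vel = minimum_jerk(0.0, 1.0, 0.0, 1.0, t)
        assert pos[np.searchsorted(t, 0.5)] == pytest.approx(0.5, abs=1e-9)
        assert np.all(pos[t <= 0.0] == 0.0) and np.all(pos[t >= 1.0] == 1.0)
        assert vel[np.searchsorted(t, 0.0)] == pytest.approx(0.0, abs=1e-9)
        assert vel[np.searchsorted(t, 1.0)] == pytest.approx(0.0, abs=1e-9)

    def test_peak_speed_closed_form(self):
        # max speed of a minimum-jerk reach is 1.875 * amplitude / duration
        t = np.linspace(0, 1, 20001)
        _, vel = minimum_jerk(0.0, 1.0, 0.0, 1.0, t)
        assert vel.max() == pytest.approx(1.875, rel=1e-6)

    def test_degenerate_amplitude_is_constant(self):
        t = np.linspace(0, 1, 101)
        pos, vel = minimum_jerk(0.0, 1.0, 0.7, 0.7, t)
        assert np.all(pos == 0.7) and np.all(vel == 0.0)

    def test_invalid_interval_rejected(self):
        with pytest.raises(InvalidIntervalError):
            minimum_jerk(1.0, 1.0, 0.0, 1.0, np.linspace(0, 1, 10))


class TestGenerateTrial:
    def test_seeded_determinism_bit_identical(self):
        prof = SubjectProfile("S001", "patient", "development", 0.4)
        cfg = GeneratorConfig()
        a = generate_trial(prof, cfg, 2)
        b = generate_trial(prof, cfg, 2)
        for field in ("wrist_pos", "sternum_pos", "joint_angle", "joint_torque",
                      "muscle_force", "muscle_fiber_vel"):
            assert np.array_equal(getattr(a, field), getattr(b, field))

    def test_angular_velocity_is_derivative_of_angle(self):
        trial = generate_trial(
            SubjectProfile("S002", "patient", "development", 0.8), GeneratorConfig(), 1
        )
        dt = 1.0 / trial.fs
        central = (trial.joint_angle[2:] - trial.joint_angle[:-2]) / (2 * dt)
        dev = np.abs(trial.joint_ang_vel[1:-1] - central).max()
        assert dev < 10.0 / trial.fs

    def test_time_base_uniform_and_channels_aligned(self):
        trial = generate_trial(
            SubjectProfile("S003", "patient", "development", 0.2), GeneratorConfig(), 3
        )
        n = trial.t.size
        assert np.ptp(np.diff(trial.t)) < 1e-9
        for field in ("wrist_pos", "sternum_pos", "joint_angle", "joint_ang_vel",
                      "joint_torque", "muscle_force", "muscle_fiber_vel"):
            assert getattr(trial, field).shape[0] == n

    def test_forces_nonnegative(self):
        trial = generate_trial(
            SubjectProfile("S004", "patient", "development", 1.0), GeneratorConfig(), 1
        )
        assert trial.muscle_force.min() >= 0.0

    @pytest.mark.parametrize("sid", ["S001", "S010", "S030"])
    def test_impairment_extremes_move_biomarkers(self, sid):
        """At matched noise realizations, full impairment raises every trunk
        and co-contraction feature and lowers every smoothness feature
        relative to the unimpaired version of the same subject."""
        f0 = _features_at(sid, 0.0)
        f1 = _features_at(sid, 1.0)
        assert all(f1[k] > f0[k] for k in f0 if k.startswith("TD_"))
        assert all(f1[k] > f0[k] for k in f0 if k.startswith("CCI_"))
        assert all(f1[k] < f0[k] for k in f0 if k.startswith("S_"))

    def test_biomarker_families_monotone_in_impairment(self):
        """Family means move monotonically across s in {0, .25, .5, .75, 1}:
        trunk displacement and co-contraction rise; smoothness, |work| and
        inter-joint coordination fall."""
        rows = {s: _features_at("S005", s) for s in (0, 0.25, 0.5, 0.75, 1.0)}

        def family_means(pred, transform=lambda v: v):
            return [
                np.mean([transform(v) for k, v in rows[s].items() if pred(k)])
                for s in sorted(rows)
            ]

        assert np.all(np.diff(family_means(lambda k: k.startswith("TD_"))) > 0)
        assert np.all(np.diff(family_means(lambda k: k.startswith("CCI_"))) > 0)
        assert np.all(np.diff(family_means(lambda k: k.startswith("S_"))) < 0)
        assert np.all(np.diff(family_means(lambda k: k.startswith("W_"), abs)) < 0)
        assert np.all(np.diff(family_means(lambda k: k.startswith("IC_"))) < 0)

    def test_muscle_work_signs_flexion_vs_extension(self):
        # biceps/brachioradialis do positive (concentric) fiber work lifting
        # to the mouth and negative (eccentric) work lowering back
        f = _features_at("S006", 0.0)
        for m in ("BB", "BR"):
            assert f[f"W_{m}_2"] > 0 > f[f"W_{m}_3"]
        assert f["W_elb_2"] > 0 > f["W_elb_3"]


class TestAssignFma:
    def test_zero_noise_zero_z_gives_intercept(self):
        import pandas as pd

        cfg = dataclasses.replace(GeneratorConfig(), fma_noise_sd=0.0)
        # all subjects identical on the weighted features -> every z is 0
        table = pd.DataFrame(
            {name: [1.0] * 6 for name in cfg.fma_weights}
        )
        scores = assign_fma(table, cfg)
        assert (scores == round(cfg.fma_intercept)).all()

    def test_missing_weighted_feature_is_configuration_error(self):
        import pandas as pd

        with pytest.raises(ConfigurationError):
            assign_fma(pd.DataFrame({"TD_2": [1.0, 2.0]}), GeneratorConfig())

    def test_scores_within_fma_range(self, default_cohort):
        fma = default_cohort.features["fma_ul"].dropna()
        assert fma.between(0, 66).all()

    def test_impairment_anticorrelates_with_fma(self):
        """Over a 200-patient cohort the latent impairment and the assigned
        FMA-UL score are strongly negatively rank-correlated."""
        cfg = dataclasses.replace(
            GeneratorConfig(), n_dev_patients=150, n_test_patients=50, n_controls=0
        )
        cohort = generate_cohort(cfg)
        s = [p.impairment for p in cohort.profiles]
        fma = cohort.features["fma_ul"].astype(float)
        rho = spearmanr(s, fma).statistic
        assert rho < -0.5


class TestGenerateCohort:
    def test_default_layout_matches_study(self, default_cohort):
        manifest = default_cohort.manifest
        assert (manifest["cohort"] == "development").sum() == 47
        assert (manifest["cohort"] == "test").sum() == 18
        assert (manifest["group"] == "control").sum() == 20
        assert len(default_cohort.trials) == 85 * 5
        trial_paths = manifest[[f"trial_{k}" for k in range(1, 6)]].to_numpy().ravel()
        assert len(set(trial_paths)) == 425

    def test_controls_unimpaired_and_unlabelled(self, default_cohort):
        controls = default_cohort.manifest[default_cohort.manifest.group == "control"]
        assert (controls["impairment"] == 0.0).all()
        assert controls["fma_ul"].isna().all()

    def test_patients_only_cohort_valid(self):
        cfg = dataclasses.replace(
            GeneratorConfig(), n_dev_patients=2, n_test_patients=1, n_controls=0
        )
        cohort = generate_cohort(cfg)
        assert len(cohort.manifest) == 3
        assert (cohort.manifest["group"] == "patient").all()

    def test_same_seed_identical_manifests(self):
        cfg = dataclasses.replace(
            GeneratorConfig(), n_dev_patients=2, n_test_patients=1, n_controls=1
        )
        m1 = generate_cohort(cfg).manifest
        m2 = generate_cohort(cfg).manifest
        assert m1.equals(m2)

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(fs=20.0)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(fma_weights={"TD_2": -1.0})  # fewer than 3 nonzero
        with pytest.raises(ConfigurationError):
            GeneratorConfig(fma_weights={"TD_2": -1.0, "TD_3": -1.0, "nope": 1.0})

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(seed=11, fma_intercept=30.0)
        cfg.to_yaml(tmp_path / "gen.yaml")
        assert GeneratorConfig.from_yaml(tmp_path / "gen.yaml") == cfg
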