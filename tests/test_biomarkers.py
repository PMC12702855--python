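"""Biomarker metrics against closed forms and an independent spectral oracle."""

import math

import numpy as np
import pytest

from strokekin import schema
from strokekin.biomarkers import (
    aggregate_subject,
    cci,
    extract_features,
    interjoint_coordination,
    mechanical_work,
    sparc,
    trunk_displacement,
)
from strokekin.errors import (
    DomainError,
    InsufficientDataError,
    SamplingError,
    UndefinedMetricError,
    WindowError,
)
from strokekin.segmentation import compute_speed, segment_htm
from strokekin.synthetic import GeneratorConfig, SubjectProfile, generate_trial


def sparc_oracle(signal, fs, padlevel=4, fc_max=10.0, amp_threshold=0.05):
    """Independent spectral-arc-length computation: explicit DFT sums and an
    explicit arc-length accumulation loop (no FFT, no vectorized diff)."""
    x = np.asarray(signal, float)
    nfft = int(2 ** (math.ceil(math.log2(x.size)) + padlevel))
    n_bins = nfft // 2 + 1
    freqs = [fs * k / nfft for k in range(n_bins)]
    mags = []
    for k in range(n_bins):
        re = sum(x[j] * math.cos(2 * math.pi * k * j / nfft) for j in range(x.size))
        im = sum(-x[j] * math.sin(2 * math.pi * k * j / nfft) for j in range(x.size))
        mags.append(math.hypot(re, im))
    v = [m / mags[0] for m in mags]
    i_c = max(k for k in range(n_bins) if freqs[k] <= fc_max and v[k] >= amp_threshold)
    f_c = freqs[i_c]
    arc = 0.0
    for k in range(1, i_c + 1):
        df = (freqs[k] - freqs[k - 1]) / f_c
        dv = v[k] - v[k - 1]
        arc += math.sqrt(df * df + dv * dv)
    return -arc


class TestMechanicalWork:
    def test_unit_constant_power(self):
        t = np.linspace(0, 2, 2001)
        w = mechanical_work(np.ones_like(t), np.ones_like(t), t, (0.5, 1.5))
        assert w == pytest.approx(1.0, abs=1e-9)

    def test_sine_squared_integral(self):
        t = np.linspace(0, math.pi, 4001)
        s = np.sin(t)
        w = mechanical_work(s, s, t, (0.0, math.pi))
        assert w == pytest.approx(math.pi / 2, abs=1e-5)

    def test_additive_over_adjacent_windows(self):
        rng = np.random.default_rng(3)
        t = np.arange(500) / 100.0
        effort, rate = rng.normal(size=500), rng.normal(size=500)
        w_all = mechanical_work(effort, rate, t, (0.5, 3.5))
        w_a = mechanical_work(effort, rate, t, (0.5, 2.0))
        w_b = mechanical_work(effort, rate, t, (2.0, 3.5))
        assert w_all == pytest.approx(w_a + w_b, abs=1e-10)

    def test_window_outside_span_rejected(self):
        t = np.arange(100) / 100.0
        with pytest.raises(WindowError):
            mechanical_work(np.ones(100), np.ones(100), t, (0.5, 2.0))


class TestSparc:
    def _minjerk_speed(self, fs=100.0, T=1.0):
        t = np.arange(int(T * fs) + 1) / fs
        tau = t / T
        return 30.0 / T * tau**2 * (1 - tau) ** 2

    def test_amplitude_invariance(self):
        v = self._minjerk_speed()
        assert sparc(v, 100.0) == pytest.approx(sparc(5.0 * v, 100.0), abs=1e-12)

    def test_time_shift_invariance(self):
        # the magnitude spectrum ignores shifts of content within the window
        pulse = self._minjerk_speed(T=0.5)
        a = np.zeros(256)
        b = np.zeros(256)
        a[10 : 10 + pulse.size] = pulse
        b[150 : 150 + pulse.size] = pulse
        assert sparc(a, 100.0) == pytest.approx(sparc(b, 100.0), abs=1e-9)

    def test_ripple_strictly_reduces_smoothness(self):
        v = self._minjerk_speed()
        t = np.arange(v.size) / 100.0
        ripple = v + 0.10 * v.max() * np.sin(2 * math.pi * 8.0 * t)
        assert sparc(ripple, 100.0) < sparc(v, 100.0)

    @pytest.mark.parametrize("signal_id", ["minjerk", "bumpy", "noisy"])
    def test_matches_independent_dft_oracle(self, signal_id):
        """The FFT-based implementation agrees with an explicit direct-DFT
        arc-length computation of the same definition to 1e-6."""
        rng = np.random.default_rng(11)
        v = self._minjerk_speed()
        t = np.arange(v.size) / 100.0
        signal = {
            "minjerk": v,
            "bumpy": v + 0.2 * v.max() * np.sin(2 * math.pi * 6 * t),
            "noisy": v + 0.05 * rng.standard_normal(v.size) + 0.5,
        }[signal_id]
        assert sparc(signal, 100.0) == pytest.approx(
            sparc_oracle(signal, 100.0), abs=1e-6
        )

    def test_error_cases(self):
        with pytest.raises(UndefinedMetricError):
            sparc(np.zeros(64), 100.0)
        with pytest.raises(SamplingError):
            sparc(np.ones(64), 15.0)  # fs <= 2 * fc_max
        with pytest.raises(InsufficientDataError):
            sparc(np.ones(5), 100.0)


class TestCci:
    def setup_method(self):
        self.t = np.arange(200) / 100.0
        self.window = (0.0, 1.99)

    def test_identical_forces_full_overlap(self):
        f = np.abs(np.sin(self.t)) + 0.1
        assert cci(f, f, self.t, self.window) == pytest.approx(1.0)

    def test_disjoint_supports_zero(self):
        a = np.zeros(200)
        b = np.zeros(200)
        a[:90], b[110:] = 1.0, 1.0
        assert cci(a, b, self.t, self.window) == pytest.approx(0.0)

    def test_constant_ratio_two_thirds(self):
        a = np.full(200, 3.0)
        assert cci(a, 2 * a, self.t, self.window) == pytest.approx(2.0 / 3.0)

    def test_symmetry_and_joint_scale_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.uniform(0, 2, 200), rng.uniform(0, 2, 200)
        assert cci(a, b, self.t, self.window) == pytest.approx(
            cci(b, a, self.t, self.window)
        )
        assert cci(3 * a, 3 * b, self.t, self.window) == pytest.approx(
            cci(a, b, self.t, self.window)
        )

    def test_domain_and_degenerate_errors(self):
        with pytest.raises(DomainError):
            cci(-np.ones(200), np.ones(200), self.t, self.window)
        with pytest.raises(UndefinedMetricError):
            cci(np.zeros(200), np.zeros(200), self.t, self.window)


class TestInterjointCoordination:
    def test_affine_pairs_give_plus_minus_one(self):
        t = np.arange(100) / 100.0
        a = np.sin(2 * np.pi * t)
        assert interjoint_coordination(a, 2 * a + 5, t, (0.0, 0.99)) == pytest.approx(1.0)
        assert interjoint_coordination(a, -a, t, (0.0, 0.99)) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(7)
        t = np.arange(1000) / 100.0
        r = interjoint_coordination(
            rng.standard_normal(1000), rng.standard_normal(1000), t, (0.0, 9.99)
        )
        assert abs(r) < 0.1

    def test_constant_series_undefined(self):
        t = np.arange(100) / 100.0
        with pytest.raises(UndefinedMetricError):
            interjoint_coordination(np.ones(100), np.sin(t), t, (0.0, 0.99))


class TestTrunkDisplacement:
    def test_static_sternum_zero(self):
        t = np.arange(100) / 100.0
        pos = np.tile([0.0, 0.0, 1.2], (100, 1))
        assert trunk_displacement(pos, t, (0.0, 0.99)) == 0.0

    def test_three_four_five_excursion(self):
        t = np.arange(100) / 100.0
        pos = np.zeros((100, 3))
        pos[:, 0] = np.linspace(0, 0.03, 100)
        pos[:, 1] = np.linspace(0, 0.04, 100)
        assert trunk_displacement(pos, t, (0.0, 0.99)) == pytest.approx(5.0)

    def test_recovers_configured_amplitude(self):
        """With subject heterogeneity off, the phase-2 peak excursion matches
        the configured healthy trunk amplitude (5.4 cm) within 2%."""
        import dataclasses

        cfg = dataclasses.replace(GeneratorConfig(), noise_scale=0.0, subject_var=0.0)
        trial = generate_trial(
            SubjectProfile("H001", "control", "control", 0.0), cfg, 1
        )
        b = segment_htm(compute_speed(trial))
        td2 = trunk_displacement(trial.sternum_pos, trial.t, b.phase_slice(2))
        assert td2 == pytest.approx(5.4, rel=0.02)


@pytest.fixture(scope="module")
def trial_features():
    trial = generate_trial(
        SubjectProfile("S001", "patient", "development", 0.3), GeneratorConfig(), 1
    )
    return extract_features(trial, segment_htm(compute_speed(trial)))


class TestExtractAggregate:

    def test_schema_exactly_112_ordered_keys(self, trial_features):
        assert list(trial_features) == list(schema.FEATURE_NAMES)
        assert len(trial_features) == 112

    def test_bounded_features_within_ranges(self, trial_features):
        for k, v in trial_features.items():
            if k.startswith("CCI_"):
                assert 0.0 <= v <= 1.0, k
            elif k.startswith("IC_"):
                assert -1.0 <= v <= 1.0, k
            elif k.startswith("S_"):
                assert v <= 0.0, k
            elif k.startswith("TD_"):
                assert v >= 0.0, k

    def test_aggregate_mean_of_middle_three(self):
        vecs = [{"x": v} for v in (0.0, 1.0, 2.0, 3.0, 100.0)]
        assert aggregate_subject(vecs)["x"] == pytest.approx(2.0)

    def test_aggregate_identical_trials_identity(self, trial_features):
        assert aggregate_subject([dict(trial_features)] * 5) == pytest.approx(
            trial_features
        )

    def test_aggregate_is_order_sensitive(self):
        # chronological order matters: moving an outlier trial into the middle
        # three changes the aggregate
        vecs = [{"x": float(v)} for v in (0, 1, 2, 3, 100)]
        swapped = [vecs[1], vecs[0], vecs[2], vecs[3], vecs[4]]
        assert aggregate_subject(swapped)["x"] != aggregate_subject(vecs)["x"]

    def test_aggregate_requires_five_trials(self):
        with pytest.raises(InsufficientDataError):
            aggregate_subject([{"x": 1.0}] * 4)

    def test_features_round_trip_csv(self, trial_features, tmp_path):
        import pandas as pd

        from strokekin.io import read_features, write_features

        row = {"subject_id": "S001", "group": "patient", "cohort": "development",
               "fma_ul": 30, **trial_features}
        table = pd.DataFrame([row])
        write_features(table, tmp_path / "f.csv")
        back = read_features(tmp_path / "f.csv")
        assert list(back.columns) == list(table.columns)
        for k in schema.FEATURE_NAMES:
            assert back[k].iloc[0] == pytest.approx(trial_features[k], abs=1e-12)
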