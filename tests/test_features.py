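"""Feature bank: statistics vs brute-force oracles, step detection, gait and
symmetry features, name resolution, table assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from iscee.data_model import DataError, SubjectProfile
from iscee.features import (
    activity_counts,
    altitude_change,
    assemble_feature_table,
    cross_correlation_feature,
    default_feature_bank,
    detect_steps,
    distance,
    feature_name,
    laterality_index,
    parse_feature_name,
    statistical_features,
    step_length,
    stride_time_variance,
)
from iscee.presets import CLASSIFIER_FEATURES, MLR_CLASS_FEATURES
from iscee.synthetic import SimConfig, simulate_activity_window, simulate_subject

finite_series = arrays(np.float64, st.integers(10, 60),
                       elements=st.floats(-1e3, 1e3, allow_nan=False))


class TestStatisticalFeatures:
    def test_hand_computed_example(self):
        out = statistical_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert out["MEAN"] == pytest.approx(2.5)
        assert out["MEDIAN"] == pytest.approx(2.5)
        assert out["RMS"] == pytest.approx(math.sqrt(7.5))
        assert out["VAR"] == pytest.approx(5.0 / 3.0)  # n-1 denominator

    def test_constant_series_degenerates_cleanly(self):
        out = statistical_features(np.full(50, 5.0))
        assert out["SD"] == 0 and out["VAR"] == 0 and out["IQR"] == 0
        assert out["PERC_99"] == 5.0

    @settings(deadline=None, max_examples=50)
    @given(finite_series)
    def test_statistics_match_brute_force(self, x):
        out = statistical_features(x)
        assert out["MEAN"] == pytest.approx(sum(x) / len(x), abs=1e-9)
        assert out["SD"] == pytest.approx(np.sqrt(np.var(x, ddof=1)), abs=1e-9)
        assert out["RMS"] == pytest.approx(np.sqrt(np.mean(np.square(x))), abs=1e-9)
        assert out["IQR"] == pytest.approx(
            np.percentile(x, 75) - np.percentile(x, 25), abs=1e-9)
        for p in (1, 3, 5, 25, 75, 95, 99):
            assert out[f"PERC_{p}"] == pytest.approx(np.percentile(x, p), abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            statistical_features(np.array([1.0]))


class TestActivityCounts:
    def test_zero_signal(self):
        assert activity_counts(np.zeros(100), 50.0) == 0.0

    def test_unit_magnitude_over_60s(self):
        fs = 50.0
        x = np.ones(int(60 * fs))
        assert activity_counts(x, fs) == pytest.approx(60.0)

    def test_linearity_in_amplitude(self, rng):
        x = rng.normal(size=500)
        assert activity_counts(2 * x, 50.0) == pytest.approx(
            2 * activity_counts(x, 50.0))


class TestStepDetection:
    def test_zero_signal_no_steps(self):
        assert len(detect_steps(np.zeros(3000), 50.0)) == 0

    def test_single_pulse_is_one_step(self):
        fs = 50.0
        x = np.zeros(int(10 * fs))
        x[200:225] = 100.0
        assert len(detect_steps(x, fs)) == 1

    def test_synthetic_gait_cadence_recovered(self):
        cfg = SimConfig(seed=7, fs=50.0, acc_noise_g=0.0, gyro_noise_dps=0.0,
                        alt_noise_m=0.0)
        rng = np.random.default_rng(7)
        subj = simulate_subject(cfg, 0, rng)
        counts = []
        for i in range(5):
            w = simulate_activity_window(subj, "walking_4kmh", cfg, rng, i)
            n = sum(len(detect_steps(w.signals[f"ankle_{s}"].gyro[:, 2], cfg.fs))
                    for s in "LR")
            counts.append(n)
        assert all(abs(c - 105) <= 1 for c in counts)


class TestGaitFeatures:
    def test_step_length_static_method(self):
        male = SubjectProfile(id="m", age=40, sex="male", weight=80, height=1.71)
        female = SubjectProfile(id="f", age=40, sex="female", weight=60, height=1.71)
        assert step_length(male) == pytest.approx(0.415 * 1.71)
        assert step_length(female) == pytest.approx(0.413 * 1.71)

    def test_distance(self):
        assert distance(0, 0.71) == 0.0
        assert distance(3126, 0.71) == pytest.approx(2219.46)

    def test_stride_time_variance_periodic_is_zero(self):
        ev = np.arange(0, 30, 1.1)
        assert stride_time_variance([ev, ev + 0.55]) == pytest.approx(0.0, abs=1e-20)

    def test_stride_time_variance_hand_value(self):
        # one leg with intervals [1.0, 1.2] s -> sample variance 0.02
        assert stride_time_variance([np.array([0.0, 1.0, 2.2])]) == pytest.approx(0.02)

    def test_stride_time_variance_jitter_propagation(self, rng):
        sigma = 0.03
        base = np.arange(0, 600, 1.2)
        ev = base + rng.normal(0, sigma, size=base.size)
        # interval = difference of two independent jitters -> variance 2 sigma^2
        assert stride_time_variance([ev]) == pytest.approx(2 * sigma**2, rel=0.2)

    def test_too_few_steps_gives_nan(self):
        assert math.isnan(stride_time_variance([np.array([0.0, 1.0])]))


class TestSymmetryFeatures:
    def test_laterality_bounds_and_examples(self):
        assert laterality_index(1.0, 1.0) == 0.0
        assert laterality_index(1.0, 0.0) == 1.0
        assert laterality_index(3.0, 1.0) == pytest.approx(0.5)
        assert laterality_index(0.0, 0.0) == 0.0

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_laterality_antisymmetric(self, a, b):
        assert laterality_index(a, b) == pytest.approx(-laterality_index(b, a))

    def test_cross_correlation_identical_signals(self, rng):
        x = rng.normal(size=500)
        assert cross_correlation_feature(x, x, 50.0) == pytest.approx(1.0)

    def test_cross_correlation_antiphase_sinusoids(self):
        fs, f0 = 50.0, 1.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        y = -x
        # half-period lag (0.5 s) lies inside the ±1 s search window
        assert cross_correlation_feature(x, y, fs) > 0.9

    def test_cross_correlation_independent_noise_small(self):
        rng = np.random.default_rng(0)
        vals = [cross_correlation_feature(rng.normal(size=3000),
                                          rng.normal(size=3000), 50.0)
                for _ in range(20)]
        assert np.mean(np.asarray(vals) < 0.2) > 0.95

    def test_zero_variance_returns_zero(self):
        assert cross_correlation_feature(np.zeros(100), np.ones(100), 50.0) == 0.0

    def test_altitude_change_sign(self):
        up = np.linspace(0, 3, 100)
        assert altitude_change(up) == pytest.approx(3.0)
        assert altitude_change(up[::-1]) == pytest.approx(-3.0)


class TestNameResolution:
    @pytest.mark.parametrize("name", list(CLASSIFIER_FEATURES) + [
        "MEAN(a_M_DW)", "VAR(H_Ch)", "AC(a_M_NDF)", "PERC_1(ω_M_Hi)"])
    def test_published_names_parse_and_round_trip(self, name):
        stat, sig, loc = parse_feature_name(name)
        assert feature_name(stat, sig, loc) == name

    @pytest.mark.parametrize("bad", ["MEAN(a_M)", "PERC_50(a_M_DW)",
                                     "MEAN(ω_Z_Ch)", "FOO(a_M_DW)"])
    def test_bad_names_rejected(self, bad):
        with pytest.raises(DataError):
            parse_feature_name(bad)

    def test_default_bank_unique_and_sized(self):
        bank = default_feature_bank()
        assert len(bank) == len(set(bank))
        # 6 non-ankle sites x 3 signals x 14 stats + 2 ankles x 4 x 14
        #   + 12 high-level + 5 demographics + REE
        assert len(bank) == 6 * 3 * 14 + 2 * 4 * 14 + 12 + 5 + 1


@pytest.fixture(scope="module")
def one_window():
    cfg = SimConfig(seed=3, fs=25.0)
    rng = np.random.default_rng(3)
    subj = simulate_subject(cfg, 0, rng)
    subj.ree_est = 1600.0
    w = simulate_activity_window(subj, "walking_4kmh", cfg, rng, 0)
    return w, subj


class TestAssembly:

    def test_full_bank_row(self, one_window):
        w, subj = one_window
        table = assemble_feature_table([w], [subj])
        bank = default_feature_bank(sorted(subj.scores))
        assert len(table) == 1
        assert set(bank) <= set(table.columns)
        stat_cols = [c for c in bank if "(" in c]
        assert not table[stat_cols].isna().any().any()

    def test_restricted_bank_exact_columns(self, one_window):
        w, subj = one_window
        feats = list(MLR_CLASS_FEATURES["walking"])
        table = assemble_feature_table([w], [subj], features=feats)
        assert list(table.columns[4:]) == feats
        assert set(feats) == {"REE", "weight", "MEDIAN(a_M_Ch)", "PERC_1(ω_M_Hi)",
                              "IQR(a_M_NDF)", "MEDIAN(ω_M_NDF)"}

    def test_determinism(self, one_window):
        w, subj = one_window
        a = assemble_feature_table([w], [subj], features=list(CLASSIFIER_FEATURES))
        b = assemble_feature_table([w], [subj], features=list(CLASSIFIER_FEATURES))
        assert a.equals(b)

    def test_unknown_feature_rejected(self, one_window):
        w, subj = one_window
        with pytest.raises(DataError, match="unknown feature"):
            assemble_feature_table([w], [subj], features=["KURTOSIS(a_M_DW)"])

    def test_handedness_swaps_dominant_sites(self, one_window):
        w, subj = one_window
        left = SubjectProfile(id=subj.id, age=subj.age, sex=subj.sex,
                              weight=subj.weight, height=subj.height,
                              handedness="left", scores=subj.scores,
                              ree_est=subj.ree_est)
        t_r = assemble_feature_table([w], [subj], features=["MEAN(a_M_DW)"])
        t_l = assemble_feature_table([w], [left], features=["MEAN(a_M_NDW)"])
        assert t_r["MEAN(a_M_DW)"].iloc[0] == pytest.approx(
            t_l["MEAN(a_M_NDW)"].iloc[0])
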