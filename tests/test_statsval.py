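"""Kinematic features, week RMSE, mixed ANOVA, and the power solver."""

import numpy as np
import pandas as pd
import pytest

from gaitrec.layout import ChannelLayout
from gaitrec.statsval import (
    anova_table,
    extract_peaks,
    feature_table,
    mixed_anova,
    phase_windows,
    power_of_n,
    required_sample_size,
    week_rmse,
)
from gaitrec.synthetic import normative_vector


class TestPhaseWindows:
    def test_hundred_point_cycle_partition(self):
        win = phase_windows(100)
        assert win.stance == slice(0, 60)
        assert win.swing == slice(60, 100)
        assert win.terminal_stance == slice(30, 60)
        covered = set(range(*win.stance.indices(100))) | set(range(*win.swing.indices(100)))
        assert covered == set(range(100))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            phase_windows(5)


class TestExtractPeaks:
    def _vector(self, hip=None, knee=None, ankle=None):
        lay = ChannelLayout()
        v = np.zeros(lay.total_length)
        for name, arr in (("hip_angle", hip), ("knee_angle", knee), ("ankle_angle", ankle)):
            if arr is not None:
                v[lay.channel_slice(name)] = arr
        return v, lay

    def test_hip_extension_is_cycle_minimum(self):
        u = np.arange(100) / 100
        hip = 10 * np.sin(2 * np.pi * (u - 0.05))  # min -10 at 55% of cycle
        v, lay = self._vector(hip=hip)
        feats = extract_peaks(v, lay)
        assert feats["peak_hip_extension"] == pytest.approx(-10.0, abs=0.05)

    def test_knee_swing_peak(self):
        knee = np.zeros(100)
        knee[72] = 60.0
        knee[20] = 80.0  # stance-phase value must be ignored
        v, lay = self._vector(knee=knee)
        assert extract_peaks(v, lay)["peak_knee_flexion_swing"] == 60.0

    def test_constant_ankle_trace(self):
        v, lay = self._vector(ankle=np.full(100, 5.0))
        assert extract_peaks(v, lay)["peak_ankle_dorsiflexion_terminal_stance"] == 5.0


class TestWeekRMSE:
    def test_identical_is_zero(self, rng):
        y = rng.normal(size=40)
        assert week_rmse(y, y) == 0.0

    def test_constant_offset(self, rng):
        y = rng.normal(size=40)
        assert week_rmse(y, y + 3.0) == pytest.approx(3.0)

    def test_hand_example(self):
        assert week_rmse([1.0, 2.0, 3.0], [1.0, 1.0, 1.0]) == pytest.approx(
            np.sqrt(5.0 / 3.0), abs=1e-9
        )

    def test_matches_naive_loop(self, rng):
        y, ref = rng.normal(size=25), rng.normal(size=25)
        naive = np.sqrt(sum((a - b) ** 2 for a, b in zip(y, ref)) / 25)
        assert week_rmse(y, ref) == pytest.approx(naive, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            week_rmse(np.zeros(5), np.zeros(6))


def _balanced_fixture():
    """Deterministic 2-group x 5-subject x 3-week dataset (frozen oracle below)."""
    rng = np.random.default_rng(42)
    rows = []
    for g in range(2):
        for s in range(5):
            subj = f"g{g}s{s}"
            base = rng.normal(0, 1)
            for w in range(3):
                rows.append(
                    {
                        "subject": subj, "group": g, "week": w, "feature": "x",
                        "value": round(float(base + 0.8 * g * w + rng.normal(0, 1)), 6),
                    }
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_frozen_r_aov_oracle(self):
        # reference: base-R aov(value ~ group*week + Error(subject/week));
        # F ratios recomputed from its printed sums of squares
        res = mixed_anova(_balanced_fixture(), "x")
        assert res.F_group == pytest.approx(8.165403203 / 2.964243532, abs=1e-6)
        assert res.F_week == pytest.approx(8.247243026 / 0.681645643, abs=1e-6)
        assert res.F_interaction == pytest.approx(1.734767700 / 0.681645643, abs=1e-6)
        assert res.df_group == (1, 8)
        assert res.df_interaction == (2, 16)
        assert res.p_week == pytest.approx(0.00062997, abs=1e-6)

    def test_sum_of_squares_partition(self):
        # total SS decomposes into between-subject and within-subject strata
        df = _balanced_fixture()
        y = df["value"].to_numpy()
        grand = y.mean()
        ss_total = ((y - grand) ** 2).sum()
        subj_means = df.groupby("subject")["value"].mean()
        ss_between_subj = 3 * ((subj_means - grand) ** 2).sum()
        ss_within = (
            (df["value"] - df["subject"].map(subj_means)) ** 2
        ).sum()
        assert ss_total == pytest.approx(ss_between_subj + ss_within, abs=1e-8)

    def test_subject_in_two_groups_rejected(self):
        df = _balanced_fixture()
        df.loc[df.index[-1], "group"] = 0
        with pytest.raises(ValueError, match="more than one group"):
            mixed_anova(df, "x")

    def test_single_group_rejected(self):
        df = _balanced_fixture()
        df["group"] = 0
        with pytest.raises(ValueError):
            mixed_anova(df, "x")

    def test_planted_interaction_detected(self):
        # group-specific week slopes well above noise must be significant
        rng = np.random.default_rng(1)
        rows = []
        for g in range(2):
            for s in range(8):
                subj = f"g{g}s{s}"
                for w in range(4):
                    rows.append(
                        {
                            "subject": subj, "group": g, "week": w, "feature": "x",
                            "value": float(2.0 * g * w + rng.normal(0, 1)),
                        }
                    )
        res = mixed_anova(pd.DataFrame(rows), "x")
        assert res.p_interaction < 0.001


class TestFeatureTable:
    def test_table_covers_real_patients_and_weeks(self, complete_cohort):
        labels = np.arange(complete_cohort.n_patients) % 2
        ref = normative_vector(complete_cohort.layout)
        feats = feature_table(complete_cohort, labels, reference=ref)
        assert set(feats["week"]) == {2, 3, 4, 6, 8, 10, 12}
        per_week = 3 + 6  # three peaks + RMSE per joint per phase
        assert len(feats) == complete_cohort.n_patients * 7 * per_week
        assert feats.groupby(["subject", "week", "feature"]).size().max() == 1

    def test_anova_table_runs_on_pipeline_features(self, complete_cohort):
        labels = np.arange(complete_cohort.n_patients) % 2
        ref = normative_vector(complete_cohort.layout)
        feats = feature_table(complete_cohort, labels, reference=ref)
        out = anova_table(feats[feats["feature"] == "peak_hip_extension"])
        assert len(out) == 1
        assert (out["F_interaction"] >= 0).all()


class TestPower:
    def test_study_sample_size_is_36(self):
        n = required_sample_size(0.187, 0.3, alpha=0.05, power=0.95, design="paired")
        assert n == 36

    def test_smallest_n_property(self):
        d = 0.187 / 0.3
        assert power_of_n(36, d, 0.05, "paired") >= 0.95
        assert power_of_n(35, d, 0.05, "paired") < 0.95

    def test_monotone_in_sd_and_effect(self):
        n1 = required_sample_size(0.187, 0.3, design="paired")
        n2 = required_sample_size(0.187, 0.6, design="paired")
        n3 = required_sample_size(0.374, 0.3, design="paired")
        assert n2 > n1 > n3

    def test_independent_design_larger_than_paired(self):
        np_ = required_sample_size(0.187, 0.3, design="paired")
        ni = required_sample_size(0.187, 0.3, design="independent")
        assert ni > np_

    def test_brute_force_power_curve_agreement(self):
        # oracle: direct simulation of the one-sample t-test at d = 1
        from scipy import stats

        n = required_sample_size(1.0, 1.0, alpha=0.05, power=0.95, design="paired")
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 4000
        for _ in range(reps):
            x = rng.normal(1.0, 1.0, size=n)
            rejections += stats.ttest_1samp(x, 0.0).pvalue < 0.05
        assert rejections / reps >= 0.93

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            required_sample_size(0.0, 1.0)
        with pytest.raises(ValueError):
            required_sample_size(1.0, -1.0)
        with pytest.raises(ValueError):
            required_sample_size(1.0, 1.0, alpha=1.5)
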