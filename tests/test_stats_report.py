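"""Behavioral composites, level ANOVA (with a brute-force F oracle),
FDR-corrected scalp maps, band contrasts, and fNIRS level effects."""

import numpy as np
import pandas as pd
import pytest

from neuroload import SessionConfig
from neuroload.config import BAND_NAMES, FRONTAL_CHANNELS, OCCIPITAL_CHANNELS
from neuroload.features import psd_column
from neuroload.fnirs_preproc import preprocess_fnirs
from neuroload.pipeline import RunConfig, subject_feature_tables
from neuroload.stats_report import (
    band_contrast_map,
    composite_scores,
    fnirs_level_effects,
    level_anova,
    scalp_anova_map,
)
from neuroload.synthgen import generate_behavioral, generate_session
from neuroload.types import BehavioralRecord


def _records(tlx_values, perf_value=1.0):
    """Records whose six TLX dimensions all take the given per-record value."""
    out = []
    for i, v in enumerate(tlx_values):
        tlx = {f"d{j}": float(v) for j in range(6)}
        perf = {"monitoring_rt": perf_value, "monitoring_acc": perf_value,
                "x_deviation": perf_value, "y_deviation": perf_value,
                "tank_a_deviation": perf_value, "tank_b_deviation": perf_value}
        out.append(BehavioralRecord(f"s", i, 1 + 2 * (i % 4), tlx, perf))
    return out


class TestComposites:
    def test_minmax_normalization(self):
        scores = composite_scores(_records([2.0, 4.0, 6.0]))
        assert np.allclose(scores["composite_tlx"], [0.0, 0.5, 1.0])

    def test_all_maxima_give_one(self):
        scores = composite_scores(_records([1.0, 5.0]))
        assert scores["composite_tlx"].iloc[-1] == 1.0

    def test_bounded_and_perf_sign_alignment(self, small_config):
        records = []
        for i in range(4):
            records.extend(generate_behavioral(small_config, f"S{i:02d}"))
        scores = composite_scores(records)
        for col in ("composite_tlx", "composite_perf"):
            assert scores[col].between(0, 1).all()
        by_level = scores.groupby("level")[["composite_tlx", "composite_perf"]].mean()
        # quality decreases and subjective load increases with difficulty
        assert by_level["composite_perf"].iloc[0] > by_level["composite_perf"].iloc[-1]
        assert by_level["composite_tlx"].iloc[0] < by_level["composite_tlx"].iloc[-1]


class TestLevelAnova:
    def test_equal_means_small_f(self):
        rng = np.random.default_rng(0)
        values = np.tile([1.0, 2.0, 3.0], 4) + rng.normal(0, 1e-6, 12)
        labels = np.repeat([1, 3, 5, 7], 3)
        res = level_anova(values, labels)
        assert res["p"] > 0.9

    def test_two_cluster_structure_detected(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([np.zeros(6), np.full(6, 10.0)])
        values += rng.normal(0, 1e-3, 12)
        labels = np.repeat([1, 3, 5, 7], 3)
        res = level_anova(values, labels)
        assert res["p"] < 1e-3
        post = res["posthoc"].set_index(["level_a", "level_b"])
        across = [(1, 5), (1, 7), (3, 5), (3, 7)]
        within = [(1, 3), (5, 7)]
        assert all(post.loc[p, "p_adj"] < 0.01 for p in across)
        assert all(post.loc[p, "p_adj"] > 0.05 for p in within)

    def test_matches_brute_force_f(self):
        """F agrees with the sums-of-squares formula computed by hand."""
        rng = np.random.default_rng(2)
        labels = np.repeat([1, 3, 5, 7], 10)
        values = rng.standard_normal(40) + labels * 0.3
        res = level_anova(values, labels)
        grand = values.mean()
        groups = [values[labels == lv] for lv in (1, 3, 5, 7)]
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ss_between / 3) / (ss_within / 36)
        assert res["F"] == pytest.approx(f_oracle, rel=1e-9)

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(3)
        labels = np.repeat([1, 3, 5, 7], 8)
        values = rng.standard_normal(32) + labels * 0.2
        post = level_anova(values, labels)["posthoc"]
        ordered = post.sort_values("p_raw")
        assert (np.diff(ordered["p_adj"].to_numpy()) >= -1e-12).all()

    def test_sparse_level_dropped(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 99.0])
        labels = np.array([1, 1, 3, 3, 5])  # level 5 has a single value
        res = level_anova(values, labels)
        levels_used = set(res["posthoc"][["level_a", "level_b"]].to_numpy().ravel())
        assert 5 not in levels_used


@pytest.fixture(scope="module")
def modulated_table():
    rc = RunConfig(session=SessionConfig(block_duration=60.0, seed=23),
                   remove_outliers=False)
    return subject_feature_tables(rc, "S00")


@pytest.fixture(scope="module")
def null_table():
    rc = RunConfig(session=SessionConfig(block_duration=60.0, seed=29,
                                         effect_size=0.0),
                   remove_outliers=False)
    return subject_feature_tables(rc, "S00")


class TestScalpMap:
    def test_one_fdr_family_of_248(self, modulated_table):
        frame = scalp_anova_map(modulated_table)
        assert len(frame) == 62 * 4
        ok = frame["p_fdr"].notna()
        assert (frame.loc[ok, "p_fdr"] >= frame.loc[ok, "p_raw"] - 1e-12).all()
        tiers = set(frame["tier"])
        assert tiers <= {"ns", "p<0.05", "p<0.01", "missing"}

    def test_modulated_cells_recovered(self, modulated_table):
        """Significant cells concentrate in the generator's modulated
        channel x band set (>=80% recovery)."""
        frame = scalp_anova_map(modulated_table).set_index(["channel", "band"])
        hits = total = 0
        for band, chans in [("theta", FRONTAL_CHANNELS),
                            ("alpha", OCCIPITAL_CHANNELS),
                            ("beta1", OCCIPITAL_CHANNELS),
                            ("beta2", OCCIPITAL_CHANNELS)]:
            for ch in chans:
                total += 1
                hits += frame.loc[(ch, band), "p_fdr"] < 0.05
        assert hits / total >= 0.8

    def test_null_false_positive_control(self, null_table):
        frame = scalp_anova_map(null_table)
        frac = (frame["p_fdr"] < 0.05).mean()
        assert frac <= 0.05


class TestContrastMap:
    def test_sign_pattern_of_modulation(self, modulated_table):
        contrast = band_contrast_map(modulated_table).set_index(["channel", "band"])
        assert all(contrast.loc[(ch, "theta"), "contrast"] > 0
                   for ch in FRONTAL_CHANNELS)
        assert all(contrast.loc[(ch, "alpha"), "contrast"] < 0
                   for ch in OCCIPITAL_CHANNELS)
        assert all(contrast.loc[(ch, "beta2"), "contrast"] > 0
                   for ch in OCCIPITAL_CHANNELS)

    def test_antisymmetric_in_levels(self, modulated_table):
        a = band_contrast_map(modulated_table, level_hi=7, level_lo=1)
        b = band_contrast_map(modulated_table, level_hi=1, level_lo=7)
        assert np.allclose(a["contrast"], -b["contrast"])

    def test_identical_levels_zero(self, modulated_table):
        frame = band_contrast_map(modulated_table, level_hi=7, level_lo=7)
        assert np.allclose(frame["contrast"], 0.0)


class TestFnirsEffects:
    def test_monotone_level_means_and_course_length(self, small_config):
        session = generate_session(small_config, "S00")
        epochs = preprocess_fnirs(session)
        effects = fnirs_level_effects(epochs)
        o2 = effects["left_O2Hb"]["level_means"]
        hh = effects["left_HHb"]["level_means"]
        levels = sorted(o2)
        assert all(o2[a] < o2[b] for a, b in zip(levels, levels[1:]))
        assert all(hh[a] > hh[b] for a, b in zip(levels, levels[1:]))
        course = effects["left_O2Hb"]["mean_time_course"][levels[0]]
        assert course.shape == (150,)  # 3 s x 50 Hz

    def test_strong_level_effect_significant(self, small_config):
        session = generate_session(small_config, "S00")
        effects = fnirs_level_effects(preprocess_fnirs(session))
        assert effects["left_O2Hb"]["anova"]["p"] < 0.01
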