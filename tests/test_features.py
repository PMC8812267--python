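"""Feature battery: Welch band powers (vs a brute-force periodogram oracle),
pair differences, the 11 fNIRS descriptors, NVC correlations, feature-set
assembly identities, and z-score outlier removal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neuroload.config import (
    BANDS,
    CHANNEL_PAIRS,
    ConfigurationError,
    FNIRS_STAT_NAMES,
    OPTIMIZED_MONTAGE_26,
)
from neuroload.features import (
    assemble_feature_sets,
    eeg_feature_table,
    feature_columns,
    fnirs_feature_table,
    fnirs_stat_features,
    nvc_features,
    nvc_table,
    pair_band_difference,
    welch_band_power,
    zscore_outlier_removal,
    _zero_lag_corr,
)

RATE = 200.0
N = 600  # 3-s epoch


def _sine(freq, amp=1.0, n=N, rate=RATE):
    t = np.arange(n) / rate
    return amp * np.sin(2 * np.pi * freq * t)


def brute_force_band_power(x, rate, band):
    """Independent oracle: single-taper (boxcar) periodogram integral."""
    n = x.size
    spec = np.abs(np.fft.rfft(x)) ** 2 / (n * rate)
    spec[1:-1] *= 2
    freqs = np.fft.rfftfreq(n, 1 / rate)
    df = freqs[1] - freqs[0]
    lo, hi = band
    return float(spec[(freqs >= lo) & (freqs < hi)].sum() * df)


class TestWelchBandPower:
    def test_10hz_sine_lands_in_alpha(self):
        x = _sine(10.0)
        alpha = welch_band_power(x, RATE, BANDS["alpha"])
        theta = welch_band_power(x, RATE, BANDS["theta"])
        assert alpha >= 20 * max(theta, 1e-12)

    def test_zero_signal_zero_power(self):
        for band in BANDS.values():
            assert welch_band_power(np.zeros(N), RATE, band) == 0.0

    @given(c=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_quadratic_homogeneity(self, c):
        x = _sine(10.0) + _sine(5.0, 0.5)
        p1 = welch_band_power(x, RATE, BANDS["alpha"])
        p2 = welch_band_power(c * x, RATE, BANDS["alpha"])
        assert p2 == pytest.approx(c**2 * p1, rel=1e-9)

    @pytest.mark.parametrize("freq,band", [
        (5.0, "theta"), (10.0, "alpha"), (16.0, "beta1"), (25.0, "beta2"),
    ])
    def test_agrees_with_brute_force_periodogram(self, freq, band):
        """On noiseless sinusoids Welch matches the single-taper
        periodogram integral within 5%."""
        x = _sine(freq, amp=2.0)
        welch = welch_band_power(x, RATE, BANDS[band])
        brute = brute_force_band_power(x, RATE, BANDS[band])
        assert welch == pytest.approx(brute, rel=0.05)

    def test_dc_offset_invariance(self):
        x = _sine(10.0)
        p0 = welch_band_power(x, RATE, BANDS["alpha"])
        p1 = welch_band_power(x + 50.0, RATE, BANDS["alpha"])
        assert p1 == pytest.approx(p0, rel=1e-6)

    def test_band_outside_nyquist_rejected(self):
        from neuroload.config import ParameterError
        with pytest.raises(ParameterError):
            welch_band_power(np.zeros(N), RATE, (90.0, 120.0))


class TestPairDifference:
    def test_hand_arithmetic(self):
        powers = {"P8": 4.0, "P7": 1.0, "O2": 2.0, "O1": 2.0, "C2": 0.0,
                  "C1": 0.0, "P4": 1.0, "P3": 1.0, "Pz": 3.0, "AF3": 0.5}
        diffs = pair_band_difference(powers)
        assert diffs[("P8", "P7")] == 3.0
        assert diffs[("O2", "O1")] == 0.0

    def test_missing_channel_raises(self):
        with pytest.raises(ConfigurationError):
            pair_band_difference({"P8": 1.0})

    def test_28_pair_features_in_table(self, eeg_epochs):
        table = eeg_feature_table(eeg_epochs)
        diff_cols = [c for c in table.columns if c.endswith("_diff")]
        assert len(diff_cols) == len(CHANNEL_PAIRS) * len(BANDS) == 28


class TestFnirsStats:
    def test_constant_trace_closed_forms(self):
        stats = fnirs_stat_features(np.full(100, 2.5))
        assert stats["mean"] == 2.5
        assert stats["std"] == 0.0
        assert stats["rms"] == 2.5
        assert stats["peak"] == 2.5
        assert stats["crest_factor"] == 1.0
        assert stats["skewness"] == 0.0 and stats["kurtosis"] == 0.0

    def test_two_point_trace(self):
        stats = fnirs_stat_features(np.array([3.0, -3.0]))
        assert stats["rms"] == 3.0
        assert stats["peak"] == 3.0
        assert stats["crest_factor"] == 1.0
        assert stats["mean"] == 0.0

    def test_symmetric_trace_zero_skew(self):
        x = np.concatenate([np.arange(-50, 51)]) * 0.1
        assert fnirs_stat_features(x)["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_exactly_11_descriptors(self):
        stats = fnirs_stat_features(np.random.default_rng(0).standard_normal(150))
        assert tuple(stats) == FNIRS_STAT_NAMES
        assert len(stats) == 11


class TestNVC:
    def _epoch_pair(self, chrom_course):
        """EEG epoch whose AF3 band-power course ramps up, plus a
        chromophore trace following ``chrom_course`` over 3 s at 50 Hz."""
        t = np.arange(N) / RATE
        envelope = 0.2 + t / 3.0
        eeg = np.zeros((2, N))
        eeg[0] = envelope * np.sin(2 * np.pi * 10.0 * t)
        fnirs = np.zeros((2, 2, 150))
        fnirs[:, :, :] = chrom_course
        return eeg, ["AF3", "Cz"], fnirs

    def test_matched_course_positive(self):
        ramp = np.linspace(0, 1, 150)
        eeg, chans, fnirs = self._epoch_pair(ramp)
        out = nvc_features(eeg, chans, RATE, fnirs, 50.0)
        assert all(v > 0.9 for v in out.values())

    def test_negated_course_negative(self):
        ramp = np.linspace(1, 0, 150)
        eeg, chans, fnirs = self._epoch_pair(ramp)
        out = nvc_features(eeg, chans, RATE, fnirs, 50.0)
        assert all(v < -0.9 for v in out.values())

    def test_constant_series_zero(self):
        eeg, chans, fnirs = self._epoch_pair(np.zeros(150))
        out = nvc_features(eeg, chans, RATE, fnirs, 50.0)
        assert all(v == 0.0 for v in out.values())

    def test_white_noise_null_correlation(self):
        """Independent 150-sample white-noise series: |r| < 0.4 with
        probability > 0.99 (seeded Monte-Carlo null)."""
        rng = np.random.default_rng(42)
        hits = sum(
            abs(_zero_lag_corr(rng.standard_normal(150),
                               rng.standard_normal(150))) < 0.4
            for _ in range(500))
        assert hits / 500 > 0.99

    def test_values_bounded(self, eeg_epochs, fnirs_epochs):
        table = nvc_table(eeg_epochs, fnirs_epochs)
        values = table[feature_columns(table)].to_numpy()
        assert np.all(values >= -1.0) and np.all(values <= 1.0)


@pytest.fixture(scope="module")
def tables(eeg_epochs, fnirs_epochs):
    return (eeg_feature_table(eeg_epochs),
            fnirs_feature_table(fnirs_epochs),
            nvc_table(eeg_epochs, fnirs_epochs))


class TestAssembly:

    def test_printed_dimensionalities(self, tables):
        eeg_tab, fnirs_tab, nvc = tables
        full = assemble_feature_sets(eeg_tab, fnirs_tab, nvc, "full")
        opt = assemble_feature_sets(eeg_tab, fnirs_tab, nvc, "optimized")
        assert len(feature_columns(full["only_eeg"])) == 276   # 62*4 + 7*4
        assert len(feature_columns(opt["only_eeg"])) == 132    # 26*4 + 7*4
        assert len(feature_columns(opt["only_fnirs"])) == 44   # 2*2*11
        assert len(feature_columns(opt["fused"])) == 180       # 132 + 44 + 4

    def test_fused_columns_are_disjoint_union(self, tables):
        sets = assemble_feature_sets(*tables, "optimized")
        fused = set(feature_columns(sets["fused"]))
        eeg = set(feature_columns(sets["only_eeg"]))
        fnirs = set(feature_columns(sets["only_fnirs"]))
        nvc_cols = {c for c in fused if c.startswith("nvc_")}
        assert fused == eeg | fnirs | nvc_cols
        assert not eeg & fnirs
        assert len(nvc_cols) == 4

    def test_width_identity_any_montage(self, tables):
        """only-EEG width = 4m + 28 for an m-channel montage."""
        eeg_tab, fnirs_tab, nvc = tables
        for m in (5, 12, 26):
            subset = OPTIMIZED_MONTAGE_26[:m]
            sets = assemble_feature_sets(eeg_tab, fnirs_tab, nvc,
                                         "optimized", optimized_channels=subset)
            assert len(feature_columns(sets["only_eeg"])) == 4 * m + 28

    def test_misaligned_tables_rejected(self, tables):
        eeg_tab, fnirs_tab, nvc = tables
        with pytest.raises(ConfigurationError):
            assemble_feature_sets(eeg_tab, fnirs_tab.iloc[:-1], nvc, "full")


class TestOutlierRemoval:
    def test_identical_rows_untouched(self):
        table = pd.DataFrame({"subject": "a", "level": 1, "f": np.ones(30)})
        assert len(zscore_outlier_removal(table)) == 30

    def test_single_gross_outlier_removed(self):
        """One 10-SD row among 100 Gaussian rows is exactly the row dropped,
        verified against a brute-force z computation."""
        rng = np.random.default_rng(8)
        values = rng.standard_normal(100)
        values[17] = values.std() * 10 + values.mean()
        table = pd.DataFrame({"subject": "a", "level": 1, "f": values})
        out = zscore_outlier_removal(table)
        z = np.abs((values - values.mean()) / values.std())
        expected = np.nonzero(z <= 3)[0]
        assert list(out.index) == list(range(len(expected)))
        assert np.array_equal(out["f"].to_numpy(), values[expected])
        assert 17 not in set(np.nonzero(z <= 3)[0])

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=15, deadline=None)
    def test_row_count_never_increases(self, seed):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame({
            "subject": ["a"] * 20 + ["b"] * 20,
            "level": 1,
            "f1": rng.standard_normal(40),
            "f2": rng.standard_normal(40),
        })
        assert len(zscore_outlier_removal(table)) <= 40

    def test_tiny_subject_passed_through(self):
        table = pd.DataFrame({"subject": ["solo"], "level": [1], "f": [99.0]})
        assert len(zscore_outlier_removal(table)) == 1
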