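"""EEG preprocessing: re-reference arithmetic, filter responses,
downsampling, ocular-artifact removal, and stride-grid epoching."""

import numpy as np
import pytest

from neuroload import SessionConfig
from neuroload.config import ConfigurationError, ParameterError
from neuroload.eeg_preproc import (
    downsample_eeg,
    epoch_eeg,
    filter_eeg,
    remove_ocular,
    rereference_mastoids,
)
from neuroload.synthgen import generate_session

from conftest import tiny_session


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestRereference:
    def test_hand_arithmetic(self):
        s = tiny_session({"Cz": 5.0, "M1": 2.0, "M2": 4.0})
        out = rereference_mastoids(s)
        assert out.eeg_channels == ["Cz"]
        assert np.allclose(out.eeg[0], 5.0 - 3.0)

    def test_zero_mastoids_identity_and_idempotence(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1200)
        s = tiny_session({"Cz": x, "M1": 0.0, "M2": 0.0})
        once = rereference_mastoids(s)
        assert np.allclose(once.eeg[0], x)
        # re-adding zero mastoids and re-referencing changes nothing
        s2 = tiny_session({"Cz": once.eeg[0], "M1": 0.0, "M2": 0.0})
        twice = rereference_mastoids(s2)
        assert np.allclose(twice.eeg[0], once.eeg[0])

    def test_missing_mastoid_raises(self):
        s = tiny_session({"Cz": 1.0, "M1": 0.0})
        with pytest.raises(ConfigurationError):
            rereference_mastoids(s)


class TestFilter:
    @pytest.mark.parametrize("freq,check", [
        (50.0, lambda rin, rout: rout < 0.05 * rin),   # notch stop band
        (10.0, lambda rin, rout: abs(rout - rin) < 0.05 * rin),  # pass band
    ])
    def test_sinusoid_response(self, freq, check):
        rate = 500.0
        t = np.arange(int(6 * rate)) / rate
        x = np.sin(2 * np.pi * freq * t)
        s = tiny_session({"Cz": x, "M1": 0.0, "M2": 0.0}, rate=rate, seconds=6.0)
        out = filter_eeg(s)
        # trim filter edge effects
        sl = slice(int(rate), -int(rate))
        assert check(_rms(x[sl]), _rms(out.eeg[0][sl]))

    def test_zero_in_zero_out(self):
        s = tiny_session({"Cz": 0.0, "M1": 0.0, "M2": 0.0}, rate=500.0)
        out = filter_eeg(s)
        assert np.allclose(out.eeg, 0.0)

    def test_cutoff_above_nyquist_rejected(self):
        s = tiny_session({"Cz": 0.0, "M1": 0.0, "M2": 0.0}, rate=80.0)
        with pytest.raises(ParameterError):
            filter_eeg(s)


class TestDownsample:
    def test_sample_count_500_to_200(self):
        rate = 500.0
        s = tiny_session({"Cz": 1.0, "M1": 0.0, "M2": 0.0}, rate=rate,
                         seconds=30.0, block_duration=30.0)
        out = downsample_eeg(s, 200.0)
        assert out.eeg.shape[1] == 30 * 200
        assert out.eeg_rate == 200.0

    def test_constant_preserved(self):
        s = tiny_session({"Cz": 3.5, "M1": 0.0, "M2": 0.0}, rate=500.0)
        out = downsample_eeg(s, 200.0)
        interior = out.eeg[0][50:-50]
        assert np.allclose(interior, 3.5, atol=1e-3)  # FIR passband ripple

    def test_10hz_amplitude_preserved(self):
        rate = 500.0
        t = np.arange(int(10 * rate)) / rate
        x = np.sin(2 * np.pi * 10.0 * t)
        s = tiny_session({"Cz": x, "M1": 0.0, "M2": 0.0}, rate=rate,
                         seconds=10.0, block_duration=10.0)
        out = downsample_eeg(s, 200.0)
        sl = slice(200, -200)
        assert abs(_rms(out.eeg[0][sl]) - _rms(x[int(rate):-int(rate)])) \
            < 0.02 * _rms(x)

    def test_upsampling_rejected(self):
        s = tiny_session({"Cz": 0.0, "M1": 0.0, "M2": 0.0}, rate=200.0)
        with pytest.raises(ParameterError):
            downsample_eeg(s, 500.0)


class TestOcularRemoval:
    def test_cleaning_recovers_ground_truth(self):
        """Regressing out the EOG channel moves contaminated frontal
        channels closer to the artifact-free ground truth."""
        cfg = SessionConfig(block_duration=30.0, seed=13, blink_rate_hz=0.4)
        session = generate_session(cfg, "S00")
        cleaned = remove_ocular(session)
        truth = session.ground_truth["clean_frontal_eeg"]
        improved = 0
        for ch, clean in truth.items():
            i = session.channel_index(ch)
            before = np.corrcoef(session.eeg[i], clean)[0, 1]
            after = np.corrcoef(cleaned.eeg[i], clean)[0, 1]
            improved += after > before
        assert improved >= 0.9 * len(truth)

    def test_no_artifacts_near_identity(self):
        cfg = SessionConfig(block_duration=12.0, seed=13, blink_rate_hz=0.0)
        session = generate_session(cfg, "S00")
        cleaned = remove_ocular(session)
        for i, ch in enumerate(session.eeg_channels):
            if ch == "EOG":
                continue
            r = np.corrcoef(session.eeg[i], cleaned.eeg[i])[0, 1]
            assert r > 0.99

    def test_deterministic(self):
        cfg = SessionConfig(block_duration=12.0, seed=13)
        a = remove_ocular(generate_session(cfg, "S00"))
        b = remove_ocular(generate_session(cfg, "S00"))
        assert np.array_equal(a.eeg, b.eeg)

    def test_missing_ocular_channel_raises(self):
        s = tiny_session({"Cz": 1.0, "M1": 0.0, "M2": 0.0})
        with pytest.raises(ConfigurationError):
            remove_ocular(s)


class TestEpoching:
    @pytest.mark.parametrize("stride,expected", [
        (3.0, 10),     # floor((30-3)/3)+1
        (0.75, 37),    # floor((30-3)/0.75)+1
    ])
    def test_epoch_counts(self, stride, expected):
        s = tiny_session({"Cz": 1.0, "M1": 0.0, "M2": 0.0}, rate=200.0,
                         seconds=30.0, block_duration=30.0)
        epochs = epoch_eeg(s, stride=stride)
        assert len(epochs) == expected
        assert epochs.data.shape[2] == 600  # 3 s x 200 Hz

    def test_empty_events(self):
        s = tiny_session({"Cz": 1.0, "M1": 0.0, "M2": 0.0}, events=[])
        epochs = epoch_eeg(s)
        assert len(epochs) == 0

    def test_labels_follow_blocks(self, session):
        epochs = epoch_eeg(session)
        per_block = 10  # 30-s blocks, 3-s stride
        expected = np.repeat([lv for _, lv in session.events], per_block)
        assert np.array_equal(epochs.labels, expected)

    def test_reference_and_ocular_channels_excluded(self, session):
        epochs = epoch_eeg(session)
        assert len(epochs.channels) == 62
        for label in ("M1", "M2", "EOG"):
            assert label not in epochs.channels


def test_filter_commutes_with_channel_permutation():
    rng = np.random.default_rng(1)
    x, y = rng.standard_normal((2, 3000))
    a = tiny_session({"Cz": x, "Pz": y, "M1": 0.0, "M2": 0.0}, rate=500.0)
    b = tiny_session({"Pz": y, "Cz": x, "M1": 0.0, "M2": 0.0}, rate=500.0)
    fa = filter_eeg(a)
    fb = filter_eeg(b)
    assert np.allclose(fa.eeg[fa.eeg_channels.index("Cz")],
                       fb.eeg[fb.eeg_channels.index("Cz")])
    da = downsample_eeg(fa, 200.0)
    db = downsample_eeg(fb, 200.0)
    assert np.allclose(da.eeg[da.eeg_channels.index("Pz")],
                       db.eeg[db.eeg_channels.index("Pz")])
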