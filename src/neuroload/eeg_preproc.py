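"""EEG preprocessing: mastoid re-reference, band-pass + notch filtering,
downsampling to 200 Hz, ocular-artifact removal, and 3-s epoching.

The pipeline order is fixed: re-reference -> filter -> downsample ->
artifact removal -> epoch. Filters are Butterworth (order 4) applied
forward-backward for zero phase, with a second-order IIR notch at 50 Hz.
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction
from typing import Optional

import numpy as np
from scipy import signal

from .config import (
    MASTOIDS,
    OCULAR_CHANNEL,
    ConfigurationError,
    ParameterError,
)
from .types import EpochSet, RawSession

logger = logging.getLogger(__name__)


def rereference_mastoids(raw: RawSession) -> RawSession:
    """Subtract the mastoid average (M1+M2)/2 from every scalp channel.

    The mastoid channels themselves are dropped from the output. The ocular
    channel, if present, is passed through unreferenced.
    """
    for label in MASTOIDS:
        if label not in raw.eeg_channels:
            raise ConfigurationError(f"mastoid channel {label} missing")
    m1 = raw.eeg[raw.channel_index("M1")]
    m2 = raw.eeg[raw.channel_index("M2")]
    reference = (m1 + m2) / 2.0
    keep = [i for i, c in enumerate(raw.eeg_channels) if c not in MASTOIDS]
    out = raw.eeg[keep].copy()
    labels = [raw.eeg_channels[i] for i in keep]
    for row, label in enumerate(labels):
        if label != OCULAR_CHANNEL:
            out[row] -= reference
    new = raw.copy()
    new.eeg = out
    new.eeg_channels = labels
    return new


def filter_eeg(raw: RawSession, band: tuple = (0.5, 45.0),
               notch_hz: float = 50.0, order: int = 4,
               notch_q: float = 30.0) -> RawSession:
    """Zero-phase 0.5-45 Hz Butterworth band-pass followed by a 50 Hz notch."""
    nyq = raw.eeg_rate / 2.0
    lo, hi = band
    if hi >= nyq or notch_hz >= nyq:
        raise ParameterError("filter cutoff must be below Nyquist")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=raw.eeg_rate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, raw.eeg, axis=-1)
    b, a = signal.iirnotch(notch_hz, notch_q, fs=raw.eeg_rate)
    filtered = signal.filtfilt(b, a, filtered, axis=-1)
    new = raw.copy()
    new.eeg = np.ascontiguousarray(filtered)
    return new


def downsample_eeg(raw: RawSession, target_rate: float = 200.0) -> RawSession:
    """Resample the EEG to ``target_rate`` with FIR anti-alias filtering."""
    if target_rate > raw.eeg_rate:
        raise ParameterError("target rate exceeds source rate")
    if target_rate == raw.eeg_rate:
        return raw.copy()
    frac = Fraction(target_rate / raw.eeg_rate).limit_denominator(1000)
    data = signal.resample_poly(raw.eeg, frac.numerator, frac.denominator, axis=-1)
    new = raw.copy()
    new.eeg = data
    new.eeg_rate = target_rate
    return new


def remove_ocular(raw: RawSession, mode: str = "regression",
                  ica_corr_threshold: float = 0.7,
                  seed: int = 0) -> RawSession:
    """Remove ocular-artifact contributions from the scalp channels.

    ``regression`` (default, deterministic): each scalp channel is regressed
    on the ocular reference channel and the fitted contribution subtracted.
    ``ica``: FastICA decomposition; components correlating with the ocular
    channel above ``ica_corr_threshold`` are zeroed before back-projection.
    """
    if OCULAR_CHANNEL not in raw.eeg_channels:
        raise ConfigurationError("ocular reference channel required")
    eog_idx = raw.channel_index(OCULAR_CHANNEL)
    eog = raw.eeg[eog_idx]
    scalp_rows = [i for i, c in enumerate(raw.eeg_channels) if c != OCULAR_CHANNEL]
    if raw.eeg.shape[1] < len(scalp_rows):
        raise ValueError("fewer samples than channels; cannot decompose")
    new = raw.copy()

    if mode == "regression":
        eog_c = eog - eog.mean()
        denom = float(eog_c @ eog_c)
        if denom == 0:
            return new
        for i in scalp_rows:
            x = new.eeg[i]
            beta = float((x - x.mean()) @ eog_c) / denom
            new.eeg[i] = x - beta * eog_c
        return new

    if mode == "ica":
        from sklearn.decomposition import FastICA

        X = raw.eeg[scalp_rows].T
        ica = FastICA(n_components=min(len(scalp_rows), 20), random_state=seed,
                      max_iter=500, whiten="unit-variance")
        sources = ica.fit_transform(X)
        for k in range(sources.shape[1]):
            r = np.corrcoef(sources[:, k], eog)[0, 1]
            if abs(r) > ica_corr_threshold:
                sources[:, k] = 0.0
        cleaned = ica.inverse_transform(sources).T
        for row, i in enumerate(scalp_rows):
            new.eeg[i] = cleaned[row] + raw.eeg[i].mean() - cleaned[row].mean()
        return new

    raise ParameterError(f"unknown artifact mode {mode!r}")


def epoch_eeg(raw: RawSession, length: float = 3.0,
              stride: Optional[float] = None) -> EpochSet:
    """Cut labeled fixed-length windows on a stride grid within each block.

    Each event marks a block onset carrying that block's difficulty level;
    windows start every ``stride`` seconds from the onset and must fit
    inside the block (windows crossing the block end are skipped). Mastoid
    and ocular channels are excluded from the epochs.
    """
    stride = length if stride is None else stride
    if stride <= 0 or length <= 0:
        raise ParameterError("length and stride must be positive")
    if length > raw.block_duration:
        raise ParameterError("epoch length exceeds block duration")
    fs = raw.eeg_rate
    n_len = int(round(length * fs))
    drop = set(MASTOIDS) | {OCULAR_CHANNEL}
    keep = [i for i, c in enumerate(raw.eeg_channels) if c not in drop]
    labels = [raw.eeg_channels[i] for i in keep]
    n_total = raw.eeg.shape[1]

    windows, levels = [], []
    for onset, level in raw.events:
        block_end = onset + raw.block_duration
        k = 0
        while True:
            start = onset + k * stride
            if start + length > block_end + 1e-9:
                break
            i0 = int(round(start * fs))
            if i0 + n_len > n_total:
                logger.warning("window at %.2fs exceeds recording; skipped", start)
                break
            windows.append(raw.eeg[keep, i0:i0 + n_len])
            levels.append(level)
            k += 1
    data = (np.stack(windows) if windows
            else np.empty((0, len(keep), n_len)))
    return EpochSet(subject_id=raw.subject_id, data=data, channels=labels,
                    labels=np.asarray(levels, dtype=int), rate=fs)


def preprocess_eeg(raw: RawSession, stride: Optional[float] = None,
                   artifact_mode: str = "regression",
                   target_rate: float = 200.0) -> EpochSet:
    """Full EEG preprocessing chain, returning clean 3-s epochs at 200 Hz."""
    out = rereference_mastoids(raw)
    out = filter_eeg(out)
    out = downsample_eeg(out, target_rate)
    out = remove_ocular(out, mode=artifact_mode)
    return epoch_eeg(out, stride=stride)
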