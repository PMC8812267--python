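"""fNIRS preprocessing: motion-artifact correction, 0.5 Hz low-pass,
and 3-s epoching of the two-site O2Hb/HHb traces.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy import signal

from .config import ParameterError
from .types import FNIRSEpochSet, RawSession

logger = logging.getLogger(__name__)


def _correct_trace(x: np.ndarray, fs: float, window_s: float,
                   threshold_sd: float) -> np.ndarray:
    """Interpolate over spans where the first difference exceeds a moving
    threshold of ``threshold_sd`` SDs, flags dilated by ``window_s``."""
    d = np.diff(x, prepend=x[0])
    sd = d.std()
    if sd == 0:
        return x.copy()
    flags = np.abs(d) > threshold_sd * sd
    if not flags.any():
        return x.copy()
    half = max(1, int(window_s * fs / 2))
    dilated = np.convolve(flags.astype(float), np.ones(2 * half + 1), mode="same") > 0
    if dilated.all():
        logger.warning("entire trace flagged as artifact; passing through")
        return x.copy()
    good = ~dilated
    idx = np.arange(x.size)
    out = x.copy()
    out[dilated] = np.interp(idx[dilated], idx[good], x[good])
    return out


def motion_correct(raw: RawSession, window_s: float = 2.0,
                   threshold_sd: float = 3.0) -> RawSession:
    """Correct spike/baseline-shift artifacts in every chromophore trace.

    Samples whose first difference exceeds ``threshold_sd`` SDs of the
    trace's differenced signal are flagged, flags are dilated by a
    ``window_s`` window, and flagged spans are replaced by interpolation
    from surrounding clean samples. Trace length is unchanged.
    """
    new = raw.copy()
    for si in range(new.fnirs.shape[0]):
        for ki in range(new.fnirs.shape[1]):
            new.fnirs[si, ki] = _correct_trace(
                new.fnirs[si, ki], raw.fnirs_rate, window_s, threshold_sd)
    return new


def lowpass_fnirs(raw: RawSession, cutoff: float = 0.5, order: int = 4) -> RawSession:
    """Zero-phase Butterworth low-pass of every trace at ``cutoff`` Hz."""
    if cutoff >= raw.fnirs_rate / 2.0:
        raise ParameterError("cutoff must be below Nyquist")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=raw.fnirs_rate,
                        output="sos")
    new = raw.copy()
    shape = new.fnirs.shape
    flat = new.fnirs.reshape(-1, shape[-1])
    new.fnirs = signal.sosfiltfilt(sos, flat, axis=-1).reshape(shape)
    return new


def epoch_fnirs(raw: RawSession, length: float = 3.0,
                stride: Optional[float] = None) -> FNIRSEpochSet:
    """Cut labeled 3-s fNIRS windows on the same stride grid as the EEG.

    Epoch ``k`` of the returned set covers the identical wall-clock window
    as EEG epoch ``k`` produced with the same length and stride.
    """
    stride = length if stride is None else stride
    if stride <= 0 or length <= 0:
        raise ParameterError("length and stride must be positive")
    if length > raw.block_duration:
        raise ParameterError("epoch length exceeds block duration")
    fs = raw.fnirs_rate
    n_len = int(round(length * fs))
    n_total = raw.fnirs.shape[2]

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
                logger.warning("fNIRS window at %.2fs exceeds recording; skipped", start)
                break
            windows.append(raw.fnirs[:, :, i0:i0 + n_len])
            levels.append(level)
            k += 1
    data = (np.stack(windows) if windows
            else np.empty((0, raw.fnirs.shape[0], raw.fnirs.shape[1], n_len)))
    return FNIRSEpochSet(subject_id=raw.subject_id, data=data,
                         labels=np.asarray(levels, dtype=int), rate=fs)


def preprocess_fnirs(raw: RawSession, stride: Optional[float] = None) -> FNIRSEpochSet:
    """Full fNIRS chain: motion correction -> 0.5 Hz low-pass -> epoching."""
    out = motion_correct(raw)
    out = lowpass_fnirs(out)
    return epoch_fnirs(out, stride=stride)
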