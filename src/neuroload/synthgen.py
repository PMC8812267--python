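"""Synthetic MATB-like sessions: EEG + fNIRS + behavioral tables.

The generator emulates the statistical structure the downstream analysis
assumes, with known ground truth retained for recovery tests:

* EEG: per-channel sum of four band-limited oscillations (random phase per
  3-s segment) whose amplitudes are monotone in task difficulty in fixed
  scalp regions — theta increases frontally, alpha decreases and beta1/beta2
  increase occipitally — plus 1/f (pink) background noise and exponential
  ocular transients mixed into frontal channels.
* fNIRS: per-block hemodynamic rise to a difficulty-dependent plateau, O2Hb
  increasing and HHb decreasing with level, plus low-frequency physiological
  noise (Mayer waves, respiration) and white noise.
* Behavior: NASA-TLX dimension means increase with level, performance
  quality decreases, with Gaussian jitter per record.

Everything is deterministic given ``(config.seed, subject_id)``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .config import (
    BANDS,
    CHROMOPHORES,
    FNIRS_SITES,
    FRONTAL_CHANNELS,
    MASTOIDS,
    OCCIPITAL_CHANNELS,
    OCULAR_CHANNEL,
    PERF_INDICATORS,
    TLX_DIMENSIONS,
    ParameterError,
    SessionConfig,
    subject_seed,
)
from .types import BehavioralRecord, RawSession

#: Center frequency (Hz) of the oscillation synthesized for each band.
BAND_CENTER_HZ: Dict[str, float] = {
    "theta": 5.5, "alpha": 10.5, "beta1": 16.5, "beta2": 25.0,
}
#: Baseline oscillation amplitude (μV) for every scalp channel.
BAND_BASE_AMP_UV: Dict[str, float] = {
    "theta": 4.0, "alpha": 5.0, "beta1": 2.5, "beta2": 1.8,
}
#: (channels, relative slope) of the difficulty modulation per band;
#: positive slope = amplitude grows with difficulty.
DEFAULT_MODULATION: Dict[str, tuple] = {
    "theta": (FRONTAL_CHANNELS, +0.8),
    "alpha": (OCCIPITAL_CHANNELS, -0.5),
    "beta1": (OCCIPITAL_CHANNELS, +0.8),
    "beta2": (OCCIPITAL_CHANNELS, +0.8),
}

_SEGMENT_S = 3.0  # random-phase segment length, matches the epoch length

# ocular mixing weight by channel-name prefix (fraction of the EOG transient
# that reaches the scalp channel)
_BLINK_MIX_PREFIX = (("Fp", 0.50), ("AF", 0.35), ("F", 0.18))


def _level_scale(level: int, levels: Sequence[int]) -> float:
    """Map a difficulty label to [0, 1] over the configured range."""
    lo, hi = min(levels), max(levels)
    return 0.0 if hi == lo else (level - lo) / (hi - lo)


def eeg_band_amplitude(config: SessionConfig, channel: str, band: str, level: int) -> float:
    """Noiseless oscillation amplitude (μV) for a channel/band at a level."""
    base = BAND_BASE_AMP_UV[band]
    if config.band_amplitude_overrides is not None:
        base = config.band_amplitude_overrides.get(band, base)
    chans, slope = DEFAULT_MODULATION[band]
    if config.modulation_overrides is not None:
        chans = config.modulation_overrides.get(band, ())
    if channel not in chans:
        return base
    s = _level_scale(level, config.levels) ** config.eeg_modulation_exponent
    return base * max(0.0, 1.0 + slope * config.effect_size * s)


def fnirs_plateau(config: SessionConfig, site: str, chromophore: str, level: int) -> float:
    """Noiseless plateau concentration (μmol/L) of a chromophore at a level.

    The plateau grows with the saturating transform s**fnirs_saturation of
    the scaled difficulty: the vascular response compresses at high load,
    complementing the linearly scaling EEG band amplitudes.
    """
    s = _level_scale(level, config.levels) ** config.fnirs_saturation
    gain = 1.0 if site == "left" else 0.9
    if chromophore == "O2Hb":
        return gain * (0.4 + 1.6 * config.effect_size * s)
    return gain * (-0.1 - 0.6 * config.effect_size * s)


def tlx_mean(config: SessionConfig, dimension: str, level: int) -> float:
    """Noiseless NASA-TLX dimension mean (0-100 scale) at a level."""
    s = _level_scale(level, config.levels)
    offsets = {d: 3.0 * i for i, d in enumerate(TLX_DIMENSIONS)}
    return float(np.clip(25.0 + offsets[dimension] + 50.0 * config.effect_size * s, 0, 100))


_PERF_MODEL = {
    # indicator: (base, slope per unit level-scale, jitter scale)
    "monitoring_rt": (0.6, 0.9, 0.08),
    "monitoring_acc": (0.97, -0.35, 0.03),
    "x_deviation": (8.0, 20.0, 2.0),
    "y_deviation": (8.0, 20.0, 2.0),
    "tank_a_deviation": (60.0, 120.0, 12.0),
    "tank_b_deviation": (60.0, 120.0, 12.0),
}


def perf_mean(config: SessionConfig, indicator: str, level: int) -> float:
    """Noiseless performance-indicator mean at a level."""
    base, slope, _ = _PERF_MODEL[indicator]
    s = _level_scale(level, config.levels)
    return base + slope * config.effect_size * s


def _pink_noise(rng: np.random.Generator, shape: tuple, sd: float) -> np.ndarray:
    """1/f-amplitude noise with the requested per-channel SD."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    scale = np.empty_like(freqs)
    scale[0] = 0.0
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= scale
    pink = np.fft.irfft(spec, n=shape[-1], axis=-1)
    std = pink.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return pink / std * sd


def _blink_train(rng: np.random.Generator, n_samples: int, rate_hz: float,
                 amp: float, fs: float) -> np.ndarray:
    """Sum of exponential-decay ocular transients at Poisson onset times."""
    out = np.zeros(n_samples)
    duration = n_samples / fs
    n_blinks = rng.poisson(rate_hz * duration)
    if n_blinks == 0:
        return out
    onsets = np.sort(rng.uniform(0, duration, n_blinks))
    tau = 0.15
    kern_len = int(0.8 * fs)
    kernel = np.exp(-np.arange(kern_len) / (tau * fs))
    for onset in onsets:
        i = int(onset * fs)
        j = min(i + kern_len, n_samples)
        out[i:j] += amp * rng.uniform(0.7, 1.3) * kernel[: j - i]
    return out


def generate_session(config: SessionConfig, subject_id: str) -> RawSession:
    """Generate one subject's synchronized EEG + fNIRS session.

    Deterministic given ``(config.seed, subject_id)``; the modulation
    parameters actually used (band amplitudes, chromophore plateaus) and the
    artifact-free frontal EEG / fNIRS traces are retained in
    ``RawSession.ground_truth`` for recovery tests.
    """
    rng = np.random.default_rng(subject_seed(config.seed, subject_id))
    fs = config.eeg_rate
    n_block = int(round(config.block_duration * fs))
    n_total = n_block * config.n_blocks
    block_levels = config.block_levels()
    channels = list(config.montage)
    scalp = config.scalp_channels
    n_ch = len(channels)

    eeg = np.zeros((n_ch, n_total))
    seg_len = int(round(_SEGMENT_S * fs))
    n_seg = max(1, n_total // seg_len)
    t = np.arange(n_total) / fs
    scalp_idx = [channels.index(c) for c in scalp]

    # band-limited oscillations with per-segment random phase
    for band, f0 in BAND_CENTER_HZ.items():
        amp_block = np.array(
            [[eeg_band_amplitude(config, c, band, lv) for lv in block_levels]
             for c in scalp]
        )  # (n_scalp, n_blocks)
        amp = np.repeat(amp_block, n_block, axis=1)[:, :n_total]
        phase_seg = rng.uniform(0, 2 * np.pi, (len(scalp), n_seg))
        phase = np.repeat(phase_seg, seg_len, axis=1)
        if phase.shape[1] < n_total:  # trailing partial segment
            pad = np.repeat(phase_seg[:, -1:], n_total - phase.shape[1], axis=1)
            phase = np.concatenate([phase, pad], axis=1)
        phase = phase[:, :n_total]
        eeg[scalp_idx, :] += amp * np.sin(2 * np.pi * f0 * t[None, :] + phase)

    # background pink noise on every recorded channel
    noise_sd = config.eeg_base_noise_uv * config.noise_sd
    eeg += _pink_noise(rng, (n_ch, n_total), noise_sd)

    # ocular transients on the EOG channel, mixed into frontal channels
    blink = _blink_train(rng, n_total, config.blink_rate_hz,
                         config.blink_amplitude_uv, fs)
    clean_frontal: Dict[str, np.ndarray] = {}
    eog_idx = channels.index(OCULAR_CHANNEL) if OCULAR_CHANNEL in channels else None
    if eog_idx is not None:
        eeg[eog_idx, :] += blink
        for ci, label in zip(scalp_idx, scalp):
            weight = next((w for p, w in _BLINK_MIX_PREFIX if label.startswith(p)), 0.0)
            if weight > 0:
                clean_frontal[label] = eeg[ci, :].copy()
                eeg[ci, :] += weight * blink

    # --- fNIRS ---------------------------------------------------------
    fs2 = config.fnirs_rate
    n2_block = int(round(config.block_duration * fs2))
    n2_total = n2_block * config.n_blocks
    t_block = np.arange(n2_block) / fs2
    rise = gamma_dist.cdf(t_block, a=config.hemo_rise_shape,
                          scale=config.hemo_rise_scale)
    fnirs_clean = np.zeros((2, 2, n2_total))
    plateaus: Dict[str, Dict[str, Dict[int, float]]] = {}
    for si, site in enumerate(FNIRS_SITES):
        plateaus[site] = {}
        for ki, chrom in enumerate(CHROMOPHORES):
            plateaus[site][chrom] = {
                lv: fnirs_plateau(config, site, chrom, lv) for lv in config.levels
            }
            for b, lv in enumerate(block_levels):
                m = plateaus[site][chrom][lv]
                fnirs_clean[si, ki, b * n2_block:(b + 1) * n2_block] = m * rise

    t2 = np.arange(n2_total) / fs2
    phys_amp = config.fnirs_base_noise_umol * config.noise_sd
    fnirs = fnirs_clean.copy()
    for si in range(2):
        for ki in range(2):
            mayer = phys_amp * np.sin(2 * np.pi * 0.1 * t2 + rng.uniform(0, 2 * np.pi))
            resp = 0.6 * phys_amp * np.sin(2 * np.pi * 0.25 * t2 + rng.uniform(0, 2 * np.pi))
            fnirs[si, ki, :] += mayer + resp + 0.5 * phys_amp * rng.standard_normal(n2_total)

    events = [(b * config.block_duration, lv) for b, lv in enumerate(block_levels)]
    ground_truth = {
        "band_base_amp": dict(BAND_BASE_AMP_UV),
        "modulated_channels": {
            band: list(config.modulation_overrides.get(band, ())
                       if config.modulation_overrides is not None
                       else DEFAULT_MODULATION[band][0])
            for band in BANDS
        },
        "band_amplitudes": {
            band: {c: {lv: eeg_band_amplitude(config, c, band, lv)
                       for lv in config.levels}
                   for c in scalp}
            for band in BANDS
        },
        "fnirs_level_means": plateaus,
        "clean_fnirs": fnirs_clean,
        "clean_frontal_eeg": clean_frontal,
        "blink": blink,
    }
    return RawSession(
        subject_id=subject_id,
        eeg=eeg,
        eeg_channels=channels,
        eeg_rate=fs,
        fnirs=fnirs,
        fnirs_rate=fs2,
        events=events,
        block_duration=config.block_duration,
        ground_truth=ground_truth,
    )


def generate_behavioral(config: SessionConfig, subject_id: str) -> List[BehavioralRecord]:
    """Per-block NASA-TLX scores and MATB performance indicators.

    TLX means increase and performance quality decreases with difficulty;
    Gaussian jitter (scaled by ``noise_sd``) is added per record.
    """
    rng = np.random.default_rng(subject_seed(config.seed + 7919, subject_id))
    records = []
    for block, level in enumerate(config.block_levels()):
        tlx = {
            d: float(np.clip(
                tlx_mean(config, d, level) + 8.0 * config.noise_sd * rng.standard_normal(),
                0, 100))
            for d in TLX_DIMENSIONS
        }
        perf = {}
        for ind in PERF_INDICATORS:
            _, _, jitter = _PERF_MODEL[ind]
            perf[ind] = float(perf_mean(config, ind, level)
                              + jitter * config.noise_sd * rng.standard_normal())
        perf["monitoring_acc"] = float(np.clip(perf["monitoring_acc"], 0, 1))
        records.append(BehavioralRecord(subject_id, block, level, tlx, perf))
    return records


def behavioral_frame(records: List[BehavioralRecord]) -> pd.DataFrame:
    """Flatten behavioral records into a tidy DataFrame."""
    rows = []
    for r in records:
        row = {"subject": r.subject_id, "block": r.block, "level": r.level}
        row.update({f"tlx_{k}": v for k, v in r.tlx.items()})
        row.update({f"perf_{k}": v for k, v in r.perf.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_session(session: RawSession, out_dir: str | Path,
                  records: List[BehavioralRecord] | None = None,
                  include_eeg: bool = False) -> Path:
    """Serialize a session to delimited tables + a manifest JSON.

    fNIRS goes to a tidy CSV (time, site, chromophore, value); events and
    behavioral records to CSVs. Full-rate EEG is large, so it is written
    only when ``include_eeg=True`` (one wide CSV, time + one column per
    channel). Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = session.subject_id
    files = {}

    n2 = session.fnirs.shape[2]
    t2 = np.arange(n2) / session.fnirs_rate
    rows = []
    for si, site in enumerate(FNIRS_SITES):
        for ki, chrom in enumerate(CHROMOPHORES):
            rows.append(pd.DataFrame({
                "time": t2, "site": site, "chromophore": chrom,
                "value": session.fnirs[si, ki, :],
            }))
    fnirs_path = out / f"{sid}_fnirs.csv"
    pd.concat(rows, ignore_index=True).to_csv(fnirs_path, index=False)
    files["fnirs"] = fnirs_path.name

    ev_path = out / f"{sid}_events.csv"
    pd.DataFrame(session.events, columns=["onset_s", "level"]).to_csv(ev_path, index=False)
    files["events"] = ev_path.name

    if include_eeg:
        t = np.arange(session.eeg.shape[1]) / session.eeg_rate
        eeg_df = pd.DataFrame(session.eeg.T, columns=session.eeg_channels)
        eeg_df.insert(0, "time", t)
        eeg_path = out / f"{sid}_eeg.csv"
        eeg_df.to_csv(eeg_path, index=False)
        files["eeg"] = eeg_path.name

    if records is not None:
        beh_path = out / f"{sid}_behavioral.csv"
        behavioral_frame(records).to_csv(beh_path, index=False)
        files["behavioral"] = beh_path.name

    manifest = {
        "subject_id": sid,
        "eeg_rate": session.eeg_rate,
        "fnirs_rate": session.fnirs_rate,
        "block_duration": session.block_duration,
        "channels": session.eeg_channels,
        "files": files,
    }
    manifest_path = out / f"{sid}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
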