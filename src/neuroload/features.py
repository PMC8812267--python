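"""Per-epoch feature battery and feature-set assembly.

EEG features: Welch band power per scalp channel in the theta/alpha/beta1/
beta2 bands (``<ch>_<band>_psd``) and band-power differences for seven fixed
channel pairs (``<a>-<b>_<band>_diff``). fNIRS features: 11 statistical
descriptors per (site, chromophore) trace (``<site>_<chrom>_<stat>``).
Neurovascular-coupling (NVC) features: zero-lag Pearson correlation between
each chromophore's amplitude time-course and the frontal EEG band-power
time-course within the epoch (``nvc_<site>_<chrom>``).

Three feature sets are assembled: only-EEG (4m + 28 columns for an m-channel
montage: 276 full / 132 optimized), only-fNIRS (44), and the fused set
(optimized EEG + fNIRS statistics + NVC = 180).
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .config import (
    BANDS,
    CHANNEL_PAIRS,
    CHROMOPHORES,
    FNIRS_SITES,
    FNIRS_STAT_NAMES,
    NVC_EEG_CHANNEL,
    OPTIMIZED_MONTAGE_26,
    ConfigurationError,
    ParameterError,
)
from .types import META_COLUMNS, EpochSet, FNIRSEpochSet

logger = logging.getLogger(__name__)


def psd_column(channel: str, band: str) -> str:
    return f"{channel}_{band}_psd"


def diff_column(pair: Tuple[str, str], band: str) -> str:
    return f"{pair[0]}-{pair[1]}_{band}_diff"


def fnirs_column(site: str, chromophore: str, stat: str) -> str:
    return f"{site}_{chromophore}_{stat}"


def nvc_column(site: str, chromophore: str) -> str:
    return f"nvc_{site}_{chromophore}"


def feature_columns(table: pd.DataFrame) -> List[str]:
    """Feature (non-metadata) columns of a feature table."""
    return [c for c in table.columns if c not in META_COLUMNS]


# ---------------------------------------------------------------------------
# EEG band power
# ---------------------------------------------------------------------------

def welch_band_power(data: np.ndarray, rate: float,
                     band: Tuple[float, float],
                     nperseg: Optional[int] = None) -> np.ndarray:
    """Integral of the Welch PSD over ``[lo, hi)`` along the last axis.

    Default Welch parameters: 1-s Hann segments with 50% overlap. ``data``
    may be any (..., n_samples) array; a power is returned per leading index.
    """
    lo, hi = band
    nyq = rate / 2.0
    if not (0 <= lo < hi <= nyq):
        raise ParameterError(f"band {band} outside [0, Nyquist={nyq}]")
    n = data.shape[-1]
    if nperseg is None:
        nperseg = min(int(round(rate)), n)
    freqs, psd = signal.welch(data, fs=rate, window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2, axis=-1)
    df = freqs[1] - freqs[0]
    mask = (freqs >= lo) & (freqs < hi)
    return psd[..., mask].sum(axis=-1) * df


def band_power_matrix(epochs: EpochSet,
                      bands: Dict[str, Tuple[float, float]] = BANDS,
                      nperseg: Optional[int] = None) -> np.ndarray:
    """Band powers for all epochs: (n_epochs, n_channels, n_bands)."""
    out = np.stack(
        [welch_band_power(epochs.data, epochs.rate, b, nperseg) for b in bands.values()],
        axis=-1,
    )
    return out


def pair_band_difference(powers: Dict[str, float],
                         pairs: Sequence[Tuple[str, str]] = CHANNEL_PAIRS) -> Dict[Tuple[str, str], float]:
    """Band-power difference power(a) - power(b) for each channel pair."""
    out = {}
    for a, b in pairs:
        if a not in powers or b not in powers:
            raise ConfigurationError(f"pair ({a}, {b}) missing from powers")
        out[(a, b)] = powers[a] - powers[b]
    return out


def eeg_feature_table(epochs: EpochSet,
                      bands: Dict[str, Tuple[float, float]] = BANDS,
                      pairs: Sequence[Tuple[str, str]] = CHANNEL_PAIRS,
                      nperseg: Optional[int] = None) -> pd.DataFrame:
    """Per-epoch EEG features: per-channel band powers + pair differences."""
    bp = band_power_matrix(epochs, bands, nperseg)  # (e, c, b)
    ch_index = {c: i for i, c in enumerate(epochs.channels)}
    for a, b in pairs:
        for label in (a, b):
            if label not in ch_index:
                raise ConfigurationError(f"pair channel {label} not in epochs")
    cols: Dict[str, np.ndarray] = {}
    for bi, band in enumerate(bands):
        for ci, ch in enumerate(epochs.channels):
            cols[psd_column(ch, band)] = bp[:, ci, bi]
    for a, b in pairs:
        for bi, band in enumerate(bands):
            cols[diff_column((a, b), band)] = (
                bp[:, ch_index[a], bi] - bp[:, ch_index[b], bi])
    table = pd.DataFrame(cols)
    table.insert(0, "level", epochs.labels)
    table.insert(0, "subject", epochs.subject_id)
    return table


# ---------------------------------------------------------------------------
# fNIRS statistical descriptors
# ---------------------------------------------------------------------------

def fnirs_stat_features(trace: np.ndarray) -> Dict[str, float]:
    """The 11 statistical descriptors of one chromophore trace.

    mean, standard deviation, mean squared deviation from the mean ("mse"),
    skewness, RMS, peak (max absolute value), crest factor (peak/RMS),
    kurtosis, waveform factor (RMS/mean|x|), pulse factor (peak/mean|x|)
    and margin factor (peak/(mean sqrt|x|)^2). Ratios with a zero
    denominator, and the shape moments of a zero-variance trace, are 0.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 2:
        raise ParameterError("trace needs at least 2 samples")
    mean = float(x.mean())
    mse = float(np.mean((x - mean) ** 2))
    std = float(np.sqrt(mse))
    rms = float(np.sqrt(np.mean(x ** 2)))
    peak = float(np.max(np.abs(x)))
    abs_mean = float(np.mean(np.abs(x)))
    root_mean = float(np.mean(np.sqrt(np.abs(x))))
    if std == 0:
        skewness = kurt = 0.0
        logger.debug("zero-variance trace: skewness/kurtosis set to 0")
    else:
        skewness = float(_skew(x))
        kurt = float(_kurtosis(x, fisher=False))
    return {
        "mean": mean,
        "std": std,
        "mse": mse,
        "skewness": skewness,
        "rms": rms,
        "peak": peak,
        "crest_factor": peak / rms if rms > 0 else 0.0,
        "kurtosis": kurt,
        "waveform_factor": rms / abs_mean if abs_mean > 0 else 0.0,
        "pulse_factor": peak / abs_mean if abs_mean > 0 else 0.0,
        "margin_factor": peak / root_mean ** 2 if root_mean > 0 else 0.0,
    }


def fnirs_feature_table(epochs: FNIRSEpochSet) -> pd.DataFrame:
    """Per-epoch fNIRS features: 11 descriptors x 2 sites x 2 chromophores."""
    rows = []
    for e in range(len(epochs)):
        row: Dict[str, float] = {}
        for si, site in enumerate(epochs.sites):
            for ki, chrom in enumerate(epochs.chromophores):
                stats = fnirs_stat_features(epochs.data[e, si, ki])
                for stat in FNIRS_STAT_NAMES:
                    row[fnirs_column(site, chrom, stat)] = stats[stat]
        rows.append(row)
    table = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=[fnirs_column(s, c, st) for s in epochs.sites
                 for c in epochs.chromophores for st in FNIRS_STAT_NAMES])
    table.insert(0, "level", epochs.labels)
    table.insert(0, "subject", epochs.subject_id)
    return table


# ---------------------------------------------------------------------------
# Neurovascular coupling
# ---------------------------------------------------------------------------

def _band_power_course(eeg: np.ndarray, rate: float,
                       window_s: float = 0.5, hop_s: float = 0.25) -> Tuple[np.ndarray, np.ndarray]:
    """Mean band power (over the four bands) in sliding sub-windows.

    Returns (window centers in seconds, power course).
    """
    n = eeg.shape[-1]
    win = int(round(window_s * rate))
    hop = int(round(hop_s * rate))
    starts = np.arange(0, n - win + 1, hop)
    centers = (starts + win / 2) / rate
    course = np.empty(starts.size)
    for i, s0 in enumerate(starts):
        seg = eeg[s0:s0 + win]
        freqs, psd = signal.periodogram(seg, fs=rate, window="hann")
        df = freqs[1] - freqs[0]
        powers = [psd[(freqs >= lo) & (freqs < hi)].sum() * df
                  for lo, hi in BANDS.values()]
        course[i] = float(np.mean(powers))
    return centers, course


def _zero_lag_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        logger.debug("constant series in NVC correlation; returning 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def nvc_features(eeg_epoch: np.ndarray, eeg_channels: Sequence[str],
                 eeg_rate: float, fnirs_epoch: np.ndarray, fnirs_rate: float,
                 eeg_channel: str = NVC_EEG_CHANNEL,
                 window_s: float = 0.5, hop_s: float = 0.25) -> Dict[str, float]:
    """Zero-lag correlation of chromophore amplitude with frontal band power.

    The frontal channel's band power (averaged over the four bands) is
    computed in sliding sub-windows across the epoch; each chromophore
    trace is sampled at the same window centers, and the Pearson correlation
    at lag 0 is returned per (site, chromophore) — 4 values in [-1, 1].
    """
    if eeg_channel not in eeg_channels:
        raise ConfigurationError(f"NVC channel {eeg_channel} not in epoch")
    ch = list(eeg_channels).index(eeg_channel)
    centers, course = _band_power_course(eeg_epoch[ch], eeg_rate, window_s, hop_s)
    t_f = np.arange(fnirs_epoch.shape[-1]) / fnirs_rate
    out = {}
    for si, site in enumerate(FNIRS_SITES):
        for ki, chrom in enumerate(CHROMOPHORES):
            chrom_at_centers = np.interp(centers, t_f, fnirs_epoch[si, ki])
            out[nvc_column(site, chrom)] = _zero_lag_corr(course, chrom_at_centers)
    return out


def nvc_table(eeg_epochs: EpochSet, fnirs_epochs: FNIRSEpochSet,
              eeg_channel: str = NVC_EEG_CHANNEL) -> pd.DataFrame:
    """Per-epoch NVC features for time-aligned EEG and fNIRS epoch sets."""
    if len(eeg_epochs) != len(fnirs_epochs) or not np.array_equal(
            eeg_epochs.labels, fnirs_epochs.labels):
        raise ConfigurationError("EEG and fNIRS epoch sets are not aligned")
    rows = [
        nvc_features(eeg_epochs.data[e], eeg_epochs.channels, eeg_epochs.rate,
                     fnirs_epochs.data[e], fnirs_epochs.rate, eeg_channel)
        for e in range(len(eeg_epochs))
    ]
    cols = [nvc_column(s, c) for s in FNIRS_SITES for c in CHROMOPHORES]
    table = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    table.insert(0, "level", eeg_epochs.labels)
    table.insert(0, "subject", eeg_epochs.subject_id)
    return table


# ---------------------------------------------------------------------------
# Assembly and outlier removal
# ---------------------------------------------------------------------------

def _check_aligned(*tables: pd.DataFrame) -> None:
    ref = tables[0]
    for t in tables[1:]:
        if len(t) != len(ref) or not np.array_equal(
                t["level"].to_numpy(), ref["level"].to_numpy()):
            raise ConfigurationError("feature tables have mismatched epoch indices")


def assemble_feature_sets(eeg_table: pd.DataFrame, fnirs_table: pd.DataFrame,
                          nvc: pd.DataFrame,
                          montage_mode: str = "optimized",
                          optimized_channels: Sequence[str] = OPTIMIZED_MONTAGE_26,
                          ) -> Dict[str, pd.DataFrame]:
    """Build the only-EEG, only-fNIRS, and fused feature sets.

    ``montage_mode`` selects which per-channel PSD columns enter the EEG set
    (``full`` keeps all channels, ``optimized`` keeps the 26-channel
    montage); the seven pair-difference columns are kept in both modes. The
    only-fNIRS set holds the 44 statistical descriptors; the NVC features
    join only the fused set, which stacks the EEG set, the fNIRS statistics
    and the 4 NVC columns.
    """
    if montage_mode not in ("full", "optimized"):
        raise ParameterError(f"unknown montage mode {montage_mode!r}")
    _check_aligned(eeg_table, fnirs_table, nvc)

    eeg_cols = feature_columns(eeg_table)
    diff_cols = [c for c in eeg_cols if c.endswith("_diff")]
    psd_cols = [c for c in eeg_cols if c.endswith("_psd")]
    if montage_mode == "optimized":
        keep = set(optimized_channels)
        psd_cols = [c for c in psd_cols if c.rsplit("_", 2)[0] in keep]

    meta = eeg_table[list(META_COLUMNS)].reset_index(drop=True)
    only_eeg = pd.concat(
        [meta, eeg_table[psd_cols + diff_cols].reset_index(drop=True)], axis=1)
    only_fnirs = pd.concat(
        [meta, fnirs_table[feature_columns(fnirs_table)].reset_index(drop=True)],
        axis=1)
    fused = pd.concat(
        [meta,
         eeg_table[psd_cols + diff_cols].reset_index(drop=True),
         fnirs_table[feature_columns(fnirs_table)].reset_index(drop=True),
         nvc[feature_columns(nvc)].reset_index(drop=True)],
        axis=1)
    return {"only_eeg": only_eeg, "only_fnirs": only_fnirs, "fused": fused}


def zscore_outlier_removal(table: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """Drop epochs containing any per-subject feature z-score above threshold.

    z-scores are computed per subject and per feature column; a row with
    ``|z| > threshold`` in any column is removed. Subjects with fewer than
    two rows are passed through unchanged.
    """
    cols = feature_columns(table)
    keep_parts = []
    for subject, group in table.groupby("subject", sort=False):
        if len(group) < 2:
            logger.warning("subject %s has <2 rows; outlier removal skipped", subject)
            keep_parts.append(group)
            continue
        x = group[cols].to_numpy(dtype=float)
        mean = x.mean(axis=0)
        std = x.std(axis=0)
        std[std == 0] = 1.0
        z = (x - mean) / std
        mask = (np.abs(z) <= threshold).all(axis=1)
        keep_parts.append(group.loc[mask])
    return pd.concat(keep_parts).reset_index(drop=True)
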