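"""Behavioral composites, per-channel ANOVA scalp statistics with FDR,
band-power contrast maps, and fNIRS level effects.

The behavioral composite min-max normalizes each NASA-TLX dimension (and
each performance indicator, sign-aligned so larger = better) across the
input and averages the six components. Scalp statistics run a one-way ANOVA
over the four difficulty levels per (channel, band) cell with
Benjamini-Hochberg FDR across the 62 x 4 family; post hoc pairwise
comparisons form their own FDR family.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import (
    BAND_NAMES,
    CHROMOPHORES,
    FNIRS_SITES,
    PERF_LOWER_IS_BETTER,
    ParameterError,
)
from .features import feature_columns, psd_column
from .types import BehavioralRecord, FNIRSEpochSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Behavioral composites
# ---------------------------------------------------------------------------

def _minmax(values: np.ndarray, name: str) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        logger.warning("component %s constant; normalized to 0", name)
        return np.zeros_like(values, dtype=float)
    return (values - lo) / (hi - lo)


def composite_scores(records: Sequence[BehavioralRecord]) -> pd.DataFrame:
    """Composite TLX and performance scores in [0, 1] per record.

    Each of the six TLX dimensions is min-max normalized across the input
    and averaged into ``composite_tlx``. Performance indicators where lower
    is better (response time, deviations) are negated first so the
    composite performance score increases with quality.
    """
    if not records:
        raise ParameterError("no behavioral records")
    tlx_keys = list(records[0].tlx)
    perf_keys = list(records[0].perf)
    tlx_mat = np.array([[r.tlx[k] for k in tlx_keys] for r in records], dtype=float)
    perf_mat = np.array([[r.perf[k] for k in perf_keys] for r in records], dtype=float)
    for j, k in enumerate(perf_keys):
        if k in PERF_LOWER_IS_BETTER:
            perf_mat[:, j] = -perf_mat[:, j]
    tlx_norm = np.column_stack(
        [_minmax(tlx_mat[:, j], k) for j, k in enumerate(tlx_keys)])
    perf_norm = np.column_stack(
        [_minmax(perf_mat[:, j], k) for j, k in enumerate(perf_keys)])
    return pd.DataFrame({
        "subject": [r.subject_id for r in records],
        "block": [r.block for r in records],
        "level": [r.level for r in records],
        "composite_tlx": tlx_norm.mean(axis=1),
        "composite_perf": perf_norm.mean(axis=1),
    })


# ---------------------------------------------------------------------------
# One-way ANOVA with post hoc comparisons
# ---------------------------------------------------------------------------

def level_anova(values: np.ndarray, labels: np.ndarray,
                correction: str = "fdr_bh") -> Dict[str, object]:
    """One-way ANOVA over difficulty levels with corrected post hoc pairs.

    Returns ``{"F", "p", "posthoc": DataFrame(level_a, level_b, t, p_raw,
    p_adj)}``. Levels with fewer than two values are dropped with a
    warning. ``correction`` is any method accepted by statsmodels
    ``multipletests`` (default Benjamini-Hochberg; "bonferroni" available).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups, kept_levels = [], []
    for lv in np.unique(labels):
        g = values[labels == lv]
        if g.size < 2:
            logger.warning("level %s has <2 values; dropped from ANOVA", lv)
            continue
        groups.append(g)
        kept_levels.append(lv)
    if len(groups) < 2:
        raise ParameterError("ANOVA needs at least two levels with >=2 values")
    F, p = stats.f_oneway(*groups)
    rows = []
    for (i, a), (j, b) in combinations(enumerate(kept_levels), 2):
        t, p_raw = stats.ttest_ind(groups[i], groups[j])
        rows.append({"level_a": a, "level_b": b, "t": float(t), "p_raw": float(p_raw)})
    posthoc = pd.DataFrame(rows)
    if not posthoc.empty:
        posthoc["p_adj"] = multipletests(posthoc["p_raw"], method=correction)[1]
    return {"F": float(F), "p": float(p), "posthoc": posthoc}


def _tier(p: float) -> str:
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def scalp_anova_map(eeg_features: pd.DataFrame,
                    channels: Optional[Sequence[str]] = None,
                    bands: Sequence[str] = BAND_NAMES) -> pd.DataFrame:
    """Per-(channel, band) difficulty-level ANOVA with one FDR family.

    Runs a one-way ANOVA per band-power column across levels and adjusts the
    raw p values with Benjamini-Hochberg over all channel x band tests
    (248 for the full 62-channel montage). Returns a frame with columns
    channel, band, F, p_raw, p_fdr, tier.
    """
    if channels is None:
        cols = [c for c in feature_columns(eeg_features) if c.endswith("_psd")]
        channels = sorted({c.rsplit("_", 2)[0] for c in cols},
                          key=lambda ch: list(eeg_features.columns).index(
                              psd_column(ch, bands[0])))
    labels = eeg_features["level"].to_numpy()
    rows = []
    for ch in channels:
        for band in bands:
            col = psd_column(ch, band)
            if col not in eeg_features.columns:
                rows.append({"channel": ch, "band": band, "F": np.nan,
                             "p_raw": np.nan})
                continue
            values = eeg_features[col].to_numpy(dtype=float)
            groups = [values[labels == lv] for lv in np.unique(labels)]
            groups = [g for g in groups if g.size >= 2]
            if len(groups) < 2:
                rows.append({"channel": ch, "band": band, "F": np.nan,
                             "p_raw": np.nan})
                continue
            F, p = stats.f_oneway(*groups)
            rows.append({"channel": ch, "band": band, "F": float(F),
                         "p_raw": float(p)})
    frame = pd.DataFrame(rows)
    ok = frame["p_raw"].notna()
    frame["p_fdr"] = np.nan
    if ok.any():
        frame.loc[ok, "p_fdr"] = multipletests(
            frame.loc[ok, "p_raw"], method="fdr_bh")[1]
    frame["tier"] = [
        _tier(p) if np.isfinite(p) else "missing" for p in frame["p_fdr"]]
    return frame


def band_contrast_map(eeg_features: pd.DataFrame, level_hi: int = 7,
                      level_lo: int = 1,
                      bands: Sequence[str] = BAND_NAMES) -> pd.DataFrame:
    """Mean band-power difference (high minus low level) per channel/band.

    Computed per subject then averaged across subjects; the sign pattern
    shows which regions' power rises or falls with workload.
    """
    levels = eeg_features["level"].to_numpy()
    for lv in (level_hi, level_lo):
        if lv not in levels:
            raise ParameterError(f"level {lv} absent from features")
    cols = [c for c in feature_columns(eeg_features) if c.endswith("_psd")]
    per_subject = []
    for _, group in eeg_features.groupby("subject", sort=False):
        g_levels = group["level"].to_numpy()
        hi = group.loc[g_levels == level_hi, cols].mean(axis=0)
        lo = group.loc[g_levels == level_lo, cols].mean(axis=0)
        per_subject.append(hi - lo)
    diff = pd.concat(per_subject, axis=1).mean(axis=1)
    rows = []
    for col, value in diff.items():
        ch, band, _ = col.rsplit("_", 2)
        rows.append({"channel": ch, "band": band, "contrast": float(value)})
    return pd.DataFrame(rows)


def fnirs_level_effects(epochs: FNIRSEpochSet,
                        correction: str = "fdr_bh") -> Dict[str, object]:
    """Level ANOVA on epoch-mean chromophore amplitudes, per site/chromophore.

    Returns per (site, chromophore): the ANOVA result, the per-level mean
    epoch amplitude, and the per-level mean time-course (for plotting).
    """
    labels = epochs.labels
    levels = np.unique(labels)
    out: Dict[str, object] = {}
    for si, site in enumerate(epochs.sites):
        for ki, chrom in enumerate(epochs.chromophores):
            epoch_means = epochs.data[:, si, ki, :].mean(axis=1)
            anova = level_anova(epoch_means, labels, correction=correction)
            level_means = {
                int(lv): float(epoch_means[labels == lv].mean()) for lv in levels}
            courses = {
                int(lv): epochs.data[labels == lv, si, ki, :].mean(axis=0)
                for lv in levels}
            out[f"{site}_{chrom}"] = {
                "anova": anova,
                "level_means": level_means,
                "mean_time_course": courses,
            }
    return out
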