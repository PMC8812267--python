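"""Cross-subject EEG channel ranking via SVM recursive feature elimination.

Per subject, the 248 per-channel band-power features (62 channels x 4 bands)
are ranked with RFE around a linear-kernel SVM and the top-k (default 100)
retained. A feature's importance weight is the number of subjects whose
top-k set contains it; a channel's weight is the sum of its four band
features' weights. Channels are ranked by weight (ties broken by montage
order), an accuracy-vs-channel-count curve is computed by adding channels in
ranking order, and the optimized montage is the smallest channel count at
which accuracy gains plateau.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFE
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import BAND_NAMES, ConfigurationError, ParameterError
from .features import feature_columns, psd_column
from .types import ChannelImportanceReport

logger = logging.getLogger(__name__)


def _psd_columns(table: pd.DataFrame) -> List[str]:
    return [c for c in feature_columns(table) if c.endswith("_psd")]


def rfe_top_features(subject_table: pd.DataFrame, k: int = 100,
                     step: float = 0.1, C: float = 1.0) -> List[str]:
    """Top-k per-channel PSD features of one subject by linear-SVM RFE.

    Only the single-channel band-power columns are scored (pair differences
    span two channels and are excluded). Features are standardized, then a
    linear-kernel SVM is trained repeatedly, eliminating the lowest-|weight|
    10% of remaining features per iteration until k remain.
    """
    cols = _psd_columns(subject_table)
    if not cols:
        raise ConfigurationError("no per-channel PSD features in table")
    y = subject_table["level"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ParameterError("RFE needs at least two classes")
    k = min(k, len(cols))
    X = StandardScaler().fit_transform(subject_table[cols].to_numpy(dtype=float))
    rfe = RFE(SVC(kernel="linear", C=C), n_features_to_select=k, step=step)
    rfe.fit(X, y)
    return [c for c, keep in zip(cols, rfe.support_) if keep]


def aggregate_importance(per_subject_sets: Sequence[Iterable[str]],
                         montage: Sequence[str]) -> ChannelImportanceReport:
    """Aggregate per-subject top-k feature sets into channel importances.

    Feature weight = number of subjects whose set contains the feature;
    channel weight = sum of its four band-feature weights. The ranking sorts
    channels by weight descending, ties broken by montage order. Order of
    subjects is irrelevant.
    """
    valid = {psd_column(ch, band) for ch in montage for band in BAND_NAMES}
    feature_weights: Dict[str, int] = {f: 0 for f in sorted(valid)}
    for s in per_subject_sets:
        for f in s:
            if f not in valid:
                raise ConfigurationError(f"unknown feature label {f!r}")
            feature_weights[f] += 1
    channel_weights = {
        ch: sum(feature_weights[psd_column(ch, band)] for band in BAND_NAMES)
        for ch in montage
    }
    order = {ch: i for i, ch in enumerate(montage)}
    ranking = sorted(montage, key=lambda ch: (-channel_weights[ch], order[ch]))
    return ChannelImportanceReport(
        feature_weights=feature_weights,
        channel_weights=channel_weights,
        ranking=list(ranking),
        n_subjects=len(per_subject_sets),
    )


def _subject_accuracy(table: pd.DataFrame, cols: List[str], seed: int,
                      C: float = 1.0, gamma: str | float = "scale") -> float:
    """Test accuracy (%) of an RBF SVM on a stratified 80/20 split."""
    X = table[cols].to_numpy(dtype=float)
    y = table["level"].to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.2, stratify=y, random_state=seed)
    model = Pipeline([("scale", StandardScaler()),
                      ("clf", SVC(kernel="rbf", C=C, gamma=gamma))])
    model.fit(X_tr, y_tr)
    return 100.0 * float(model.score(X_te, y_te))


def incremental_accuracy_curve(tables: Sequence[pd.DataFrame],
                               ranking: Sequence[str],
                               seed: int = 0,
                               counts: Optional[Sequence[int]] = None,
                               ) -> pd.DataFrame:
    """Mean/SD cross-subject SVM accuracy using the top-n ranked channels.

    For each channel count n (default 1..len(ranking)), every subject's
    accuracy is computed on the top-n channels' band-power features; the
    returned frame has columns n_channels, mean_accuracy, std_accuracy.
    ``counts`` may restrict the evaluated n values for speed.
    """
    if not ranking:
        raise ParameterError("empty channel ranking")
    if counts is None:
        counts = range(1, len(ranking) + 1)
    rows = []
    for n in counts:
        cols = [psd_column(ch, band) for ch in ranking[:n] for band in BAND_NAMES]
        accs = [_subject_accuracy(t, cols, seed) for t in tables]
        rows.append({
            "n_channels": int(n),
            "mean_accuracy": float(np.mean(accs)),
            "std_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def select_montage(report: ChannelImportanceReport, curve: pd.DataFrame,
                   plateau_threshold: float = 0.5,
                   smooth: int = 3) -> List[str]:
    """Pick the smallest channel count where accuracy gains plateau.

    The plateau is the first n at which the ``smooth``-point moving average
    of the per-channel accuracy gain drops below ``plateau_threshold``
    percentage points; the top-n ranked channels are returned. A curve that
    never plateaus returns the full ranking. A threshold of 0 returns the
    argmax of mean accuracy.
    """
    curve = curve.sort_values("n_channels").reset_index(drop=True)
    acc = curve["mean_accuracy"].to_numpy(dtype=float)
    ns = curve["n_channels"].to_numpy(dtype=int)
    if plateau_threshold == 0:
        n_sel = int(ns[int(np.argmax(acc))])
        return report.ranking[:n_sel]
    if len(acc) < 2:
        return report.ranking[: int(ns[-1])]
    gains = np.diff(acc) / np.diff(ns)  # points per added channel
    w = min(smooth, len(gains))
    kernel = np.ones(w) / w
    smoothed = np.convolve(gains, kernel, mode="valid")
    below = np.nonzero(smoothed < plateau_threshold)[0]
    if below.size == 0:
        logger.info("accuracy curve never plateaus; returning full montage")
        return list(report.ranking)
    n_sel = int(ns[below[0]])  # count at the start of the plateauing window
    n_sel = max(1, n_sel)
    return report.ranking[:n_sel]
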