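"""In-memory containers passed between pipeline stages.

Signals live in plain numpy arrays with explicit channel/site axes; feature
tables are pandas DataFrames with ``subject`` and ``level`` metadata columns
plus named feature columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import CHROMOPHORES, FNIRS_SITES

#: DataFrame columns that are metadata, not features.
META_COLUMNS: Tuple[str, ...] = ("subject", "level")


@dataclass
class RawSession:
    """One subject's synchronized EEG + fNIRS recording.

    ``eeg`` is (n_channels, n_samples) in μV at ``eeg_rate``; ``fnirs`` is
    (2 sites, 2 chromophores, n_samples) in μmol/L at ``fnirs_rate``, sites
    ordered (left, right) and chromophores (O2Hb, HHb). ``events`` holds one
    (onset_seconds, difficulty_level) marker per task block.
    """

    subject_id: str
    eeg: np.ndarray
    eeg_channels: List[str]
    eeg_rate: float
    fnirs: np.ndarray
    fnirs_rate: float
    events: List[Tuple[float, int]]
    block_duration: float
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.eeg.shape[0] != len(self.eeg_channels):
            raise ValueError("eeg rows must match channel labels")
        if self.fnirs.shape[:2] != (len(FNIRS_SITES), len(CHROMOPHORES)):
            raise ValueError("fnirs must be (2 sites, 2 chromophores, samples)")
        eeg_span = self.eeg.shape[1] / self.eeg_rate
        fnirs_span = self.fnirs.shape[2] / self.fnirs_rate
        if abs(eeg_span - fnirs_span) > 1.0 / min(self.eeg_rate, self.fnirs_rate) + 1e-9:
            raise ValueError("eeg and fnirs must cover the same wall-clock span")

    @property
    def duration(self) -> float:
        return self.eeg.shape[1] / self.eeg_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.eeg_channels.index(label)
        except ValueError as exc:
            raise KeyError(f"channel {label!r} not in session") from exc

    def copy(self) -> "RawSession":
        return RawSession(
            subject_id=self.subject_id,
            eeg=self.eeg.copy(),
            eeg_channels=list(self.eeg_channels),
            eeg_rate=self.eeg_rate,
            fnirs=self.fnirs.copy(),
            fnirs_rate=self.fnirs_rate,
            events=list(self.events),
            block_duration=self.block_duration,
            ground_truth=self.ground_truth,
        )


@dataclass
class EpochSet:
    """Labeled fixed-length EEG windows: data is (n_epochs, n_channels, n_samples)."""

    subject_id: str
    data: np.ndarray
    channels: List[str]
    labels: np.ndarray  # difficulty level per epoch
    rate: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("one label per epoch required")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis must match labels")

    def __len__(self) -> int:
        return self.data.shape[0]


@dataclass
class FNIRSEpochSet:
    """Labeled fNIRS windows: data is (n_epochs, 2 sites, 2 chromophores, n_samples)."""

    subject_id: str
    data: np.ndarray
    labels: np.ndarray
    rate: float
    sites: Tuple[str, str] = FNIRS_SITES
    chromophores: Tuple[str, str] = CHROMOPHORES

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 4:
            raise ValueError("fnirs epoch data must be 4-D")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("one label per epoch required")

    def __len__(self) -> int:
        return self.data.shape[0]


@dataclass
class BehavioralRecord:
    """One block's NASA-TLX scores and task-performance indicators."""

    subject_id: str
    block: int
    level: int
    tlx: Dict[str, float]
    perf: Dict[str, float]

    def __post_init__(self) -> None:
        if len(self.tlx) != 6 or len(self.perf) != 6:
            raise ValueError("exactly six TLX dimensions and six performance indicators")


@dataclass
class ChannelImportanceReport:
    """Cross-subject channel importance from per-subject RFE top-k sets.

    ``feature_weights`` maps PSD feature name -> number of subjects whose
    top-k set contains it; ``channel_weights`` sums a channel's four band
    weights; ``ranking`` sorts channels by weight descending (ties broken
    by montage order).
    """

    feature_weights: Dict[str, int]
    channel_weights: Dict[str, int]
    ranking: List[str]
    n_subjects: int


@dataclass
class EvaluationResult:
    """Per-subject accuracies for one (feature set, classifier) pair, in %."""

    feature_set: str
    classifier: str
    per_subject_test_accuracy: List[float]
    per_subject_train_accuracy: List[float]
    chosen_params: List[dict] = field(default_factory=list)

    def summary(self, which: str = "test") -> Dict[str, float]:
        acc = np.asarray(
            self.per_subject_test_accuracy if which == "test"
            else self.per_subject_train_accuracy,
            dtype=float,
        )
        return {
            "min": float(acc.min()),
            "mean": float(acc.mean()),
            "max": float(acc.max()),
            "std": float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
        }
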