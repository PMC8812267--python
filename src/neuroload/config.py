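"""Shared constants and configuration objects for the workload pipeline.

Everything the analysis treats as a fixed protocol constant lives here: the
frequency-band definitions, the 62-channel scalp montage, the seven channel
pairs used for hemispheric/anterior-posterior power differences, the
26-channel optimized montage, and the hyper-parameter grids for the three
classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

# ---------------------------------------------------------------------------
# Frequency bands (Hz). Band power = PSD integrated over [lo, hi).
# ---------------------------------------------------------------------------
BANDS: Dict[str, Tuple[float, float]] = {
    "theta": (3.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta1": (13.0, 20.0),
    "beta2": (20.0, 30.0),
}
BAND_NAMES: Tuple[str, ...] = tuple(BANDS)

# ---------------------------------------------------------------------------
# Montage. 64 EEG electrodes of the 10-20/10-10 system: 62 scalp labels plus
# the two mastoids used for re-referencing. One ocular channel (below the
# left eye) is recorded alongside and is never part of the scalp set.
# ---------------------------------------------------------------------------
SCALP_CHANNELS: Tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)
MASTOIDS: Tuple[str, str] = ("M1", "M2")
OCULAR_CHANNEL: str = "EOG"

#: Full recording montage: 62 scalp + 2 mastoids + 1 ocular channel.
DEFAULT_MONTAGE: Tuple[str, ...] = SCALP_CHANNELS + MASTOIDS + (OCULAR_CHANNEL,)

#: Region groupings used by the synthetic generator and the reports.
FRONTAL_CHANNELS: Tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
)
OCCIPITAL_CHANNELS: Tuple[str, ...] = (
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)

# ---------------------------------------------------------------------------
# Seven channel pairs for band-power difference features
# (left-right and anterior-posterior contrasts).
# ---------------------------------------------------------------------------
CHANNEL_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("P8", "P7"),
    ("O2", "O1"),
    ("C2", "C1"),
    ("P4", "P3"),
    ("Pz", "O1"),
    ("Pz", "O2"),
    ("O1", "AF3"),
)

#: The 26-channel optimized montage selected by the cross-subject
#: channel-importance analysis; shipped as a constant for reproduction mode.
OPTIMIZED_MONTAGE_26: Tuple[str, ...] = (
    "P4", "PO6", "O1", "P6", "PO5", "P8", "PO8", "P7", "PO7", "PO4",
    "P5", "P1", "O2", "CP2", "P2", "AF3", "C1", "P3", "Pz", "C2",
    "PO3", "TP8", "Oz", "CP4", "TP7", "CP6",
)

FNIRS_SITES: Tuple[str, str] = ("left", "right")
CHROMOPHORES: Tuple[str, str] = ("O2Hb", "HHb")

#: Channel whose band power drives the neurovascular-coupling feature.
NVC_EEG_CHANNEL: str = "AF3"

#: Order of the 11 statistical descriptors extracted per fNIRS trace.
FNIRS_STAT_NAMES: Tuple[str, ...] = (
    "mean", "std", "mse", "skewness", "rms", "peak",
    "crest_factor", "kurtosis", "waveform_factor", "pulse_factor",
    "margin_factor",
)

DIFFICULTY_LEVELS: Tuple[int, ...] = (1, 3, 5, 7)

TLX_DIMENSIONS: Tuple[str, ...] = (
    "mental_demand", "physical_demand", "temporal_demand",
    "performance", "effort", "frustration",
)
PERF_INDICATORS: Tuple[str, ...] = (
    "monitoring_rt", "monitoring_acc", "x_deviation", "y_deviation",
    "tank_a_deviation", "tank_b_deviation",
)
#: Indicators where larger values mean worse performance; negated before
#: min-max normalization so the composite decreases with difficulty.
PERF_LOWER_IS_BETTER: Tuple[str, ...] = (
    "monitoring_rt", "x_deviation", "y_deviation",
    "tank_a_deviation", "tank_b_deviation",
)


class ParameterError(ValueError):
    """Invalid analysis or generator parameter."""


class ConfigurationError(ValueError):
    """A required channel/column is missing or inputs are misaligned."""


@dataclass
class SessionConfig:
    """Configuration of one synthetic MATB-like recording session.

    Parameters
    ----------
    n_subjects
        Cohort size when generating a full study.
    n_blocks
        Task blocks per subject; each block carries one difficulty level.
    block_duration
        Seconds per block.
    levels
        Difficulty labels, ascending. Each block is assigned one level; with
        the default 4 blocks every level appears exactly once per subject.
    eeg_rate, fnirs_rate
        Sampling rates in Hz.
    montage
        Recorded channel labels (scalp + mastoids + ocular).
    effect_size
        Dimensionless scale of the difficulty-dependent modulation of band
        amplitudes, chromophore plateaus and behavioral scores. 0 produces
        null data; 1 is the calibrated default.
    noise_sd
        Dimensionless multiplier on the per-modality base noise amplitudes
        (EEG pink noise, fNIRS physiological noise, behavioral jitter).
    seed
        Base RNG seed; every generated object is deterministic given
        (seed, subject_id).
    """

    n_subjects: int = 20
    n_blocks: int = 4
    block_duration: float = 180.0
    levels: Tuple[int, ...] = DIFFICULTY_LEVELS
    eeg_rate: float = 500.0
    fnirs_rate: float = 50.0
    montage: Tuple[str, ...] = DEFAULT_MONTAGE
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    # signal-model knobs (see docs/methods.md)
    eeg_base_noise_uv: float = 2.0       # pink-noise SD, μV
    fnirs_base_noise_umol: float = 0.08  # physiological noise amplitude, μmol/L
    blink_rate_hz: float = 0.25          # ocular transients per second
    blink_amplitude_uv: float = 120.0
    hemo_rise_shape: float = 3.0         # gamma-cdf shape of the hemodynamic rise
    hemo_rise_scale: float = 4.0         # gamma-cdf scale (s)
    #: exponent on the scaled difficulty in the hemodynamic plateau;
    #: < 1 saturates the vascular response at high load, so the
    #: chromophores separate low levels better than high ones.
    fnirs_saturation: float = 0.5
    #: exponent on the scaled difficulty in the EEG band modulation;
    #: > 1 makes scalp power respond weakly at low loads and strongly at
    #: high loads. Together with the saturating hemodynamics this gives
    #: the two modalities complementary sensitivity ranges — the structure
    #: the fused feature set exploits.
    eeg_modulation_exponent: float = 2.0
    #: optional override: band name -> channel labels that carry the
    #: difficulty modulation (replaces the region defaults).
    modulation_overrides: Optional[Dict[str, Sequence[str]]] = None
    #: optional override: band name -> baseline oscillation amplitude (μV);
    #: set a band to 0 to silence its generator.
    band_amplitude_overrides: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ParameterError("effect_size must be non-negative")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.n_blocks < 1 or self.block_duration <= 0:
            raise ParameterError("need at least one block of positive duration")
        self.levels = tuple(sorted(int(v) for v in self.levels))
        top = max(hi for _, hi in BANDS.values())
        if self.eeg_rate <= 2 * top:
            raise ParameterError(
                f"eeg_rate {self.eeg_rate} must exceed twice the highest "
                f"synthesized frequency ({top} Hz)"
            )
        for label in MASTOIDS:
            if label not in self.montage:
                raise ConfigurationError(f"montage lacks mastoid {label}")

    @property
    def scalp_channels(self) -> List[str]:
        drop = set(MASTOIDS) | {OCULAR_CHANNEL}
        return [c for c in self.montage if c not in drop]

    def block_levels(self) -> List[int]:
        """Difficulty level of each block (levels cycled over blocks)."""
        return [self.levels[b % len(self.levels)] for b in range(self.n_blocks)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["levels"] = list(self.levels)
        d["montage"] = list(self.montage)
        return d


@dataclass
class GridSearchSpec:
    """Hyper-parameter search grids for the three classifiers.

    Defaults are the full protocol grids; reduced instances may be passed
    for quick runs.
    """

    svm_c: Tuple[float, ...] = (0.0001, 0.001, 0.01, 0.1, 1, 10, 20, 30)
    svm_gamma: Tuple[float, ...] = (0.1, 0.2, 0.25, 0.4, 0.8, 1.6, 3.2, 6.4)
    dt_criterion: Tuple[str, ...] = ("entropy", "gini")
    dt_max_depth: Tuple[int, ...] = (10, 30, 60, 100)
    dt_min_split: Tuple[int, ...] = (2, 5, 10, 15)
    rf_n_trees: Tuple[int, ...] = (100, 200, 500)

    def param_grid(self, classifier: str) -> dict:
        if classifier == "svm":
            return {"clf__C": list(self.svm_c), "clf__gamma": list(self.svm_gamma)}
        if classifier == "dt":
            return {
                "clf__criterion": list(self.dt_criterion),
                "clf__max_depth": list(self.dt_max_depth),
                "clf__min_samples_split": list(self.dt_min_split),
            }
        if classifier == "rf":
            return {"clf__n_estimators": list(self.rf_n_trees)}
        raise ParameterError(f"unknown classifier {classifier!r}")


def subject_seed(base_seed: int, subject_id: str) -> int:
    """Stable per-subject RNG seed derived from the base seed (< 2**31)."""
    import zlib

    h = zlib.crc32(subject_id.encode("utf-8"))
    return int((base_seed * 1_000_003 + h) % (2**31 - 1))
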