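"""Reading and writing the pipeline's serialized interfaces.

Feature tables are CSV files with a JSON sidecar schema mapping each column
to its provenance (psd / pair difference / fnirs statistic / nvc /
metadata). EEG may also be read from EDF files (via mne, when installed) or
from wide delimited tables (time + one column per channel) as written by
``synthgen.write_session``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import CHROMOPHORES, FNIRS_SITES
from .types import META_COLUMNS, RawSession


def _column_kind(name: str) -> str:
    if name in META_COLUMNS:
        return "metadata"
    if name.endswith("_psd"):
        return "welch_band_power"
    if name.endswith("_diff"):
        return "pair_band_difference"
    if name.startswith("nvc_"):
        return "neurovascular_coupling"
    return "fnirs_statistic"


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a feature table as CSV with a JSON sidecar schema."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    schema = {c: _column_kind(c) for c in table.columns}
    sidecar = path.with_suffix(path.suffix + ".schema.json")
    sidecar.write_text(json.dumps(schema, indent=2))
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_eeg_table(path: str | Path, rate: float,
                   events: List[tuple], block_duration: float,
                   subject_id: str = "unknown") -> RawSession:
    """Load a wide delimited EEG table (time + one column per channel)."""
    frame = pd.read_csv(path)
    channels = [c for c in frame.columns if c != "time"]
    eeg = frame[channels].to_numpy(dtype=float).T
    n2 = int(round(eeg.shape[1] / rate * 50.0))
    placeholder = np.zeros((len(FNIRS_SITES), len(CHROMOPHORES), n2))
    return RawSession(subject_id=subject_id, eeg=eeg, eeg_channels=channels,
                      eeg_rate=rate, fnirs=placeholder, fnirs_rate=50.0,
                      events=events, block_duration=block_duration)


def read_edf(path: str | Path, events: List[tuple], block_duration: float,
             subject_id: str = "unknown") -> RawSession:
    """Load EEG from an EDF file (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires the mne package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    eeg = raw.get_data() * 1e6  # volts -> μV
    rate = float(raw.info["sfreq"])
    n2 = int(round(eeg.shape[1] / rate * 50.0))
    placeholder = np.zeros((len(FNIRS_SITES), len(CHROMOPHORES), n2))
    return RawSession(subject_id=subject_id, eeg=eeg,
                      eeg_channels=list(raw.ch_names), eeg_rate=rate,
                      fnirs=placeholder, fnirs_rate=50.0, events=events,
                      block_duration=block_duration)


def read_fnirs_table(path: str | Path, rate: float = 50.0) -> np.ndarray:
    """Load a tidy fNIRS CSV (time, site, chromophore, value) into the
    (2 sites, 2 chromophores, samples) array layout."""
    frame = pd.read_csv(path)
    n = frame.groupby(["site", "chromophore"]).size().max()
    out = np.zeros((len(FNIRS_SITES), len(CHROMOPHORES), int(n)))
    for si, site in enumerate(FNIRS_SITES):
        for ki, chrom in enumerate(CHROMOPHORES):
            sel = frame[(frame["site"] == site) & (frame["chromophore"] == chrom)]
            out[si, ki, :len(sel)] = sel.sort_values("time")["value"].to_numpy()
    return out


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
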