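"""Preprocess a session and extract the full feature battery.

Shows the fixed preprocessing order (re-reference -> filter -> downsample ->
ocular removal -> 3-s epoching), then builds the three feature sets and
prints their dimensionalities: 276 EEG columns on the full montage,
132 on the optimized 26-channel montage, 44 fNIRS statistical columns, and
180 fused columns (132 + 44 + 4 neurovascular-coupling correlations).
"""

from neuroload import SessionConfig
from neuroload.eeg_preproc import preprocess_eeg
from neuroload.features import (
    assemble_feature_sets,
    eeg_feature_table,
    feature_columns,
    fnirs_feature_table,
    nvc_table,
    zscore_outlier_removal,
)
from neuroload.fnirs_preproc import preprocess_fnirs
from neuroload.synthgen import generate_session

session = generate_session(SessionConfig(block_duration=60.0, seed=2), "S00")
eeg_epochs = preprocess_eeg(session)
fnirs_epochs = preprocess_fnirs(session)
print(f"{len(eeg_epochs)} EEG epochs of {eeg_epochs.data.shape[2]} samples "
      f"({len(eeg_epochs.channels)} scalp channels at {eeg_epochs.rate:.0f} Hz)")

eeg_tab = eeg_feature_table(eeg_epochs)
fnirs_tab = fnirs_feature_table(fnirs_epochs)
nvc = nvc_table(eeg_epochs, fnirs_epochs)

for mode in ("full", "optimized"):
    sets = assemble_feature_sets(eeg_tab, fnirs_tab, nvc, montage_mode=mode)
    widths = {k: len(feature_columns(v)) for k, v in sets.items()}
    print(f"{mode:>9} montage: {widths}")

fused = assemble_feature_sets(eeg_tab, fnirs_tab, nvc, "optimized")["fused"]
clean = zscore_outlier_removal(fused)
print(f"outlier removal (|z| > 3 per subject): {len(fused)} -> {len(clean)} epochs")
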