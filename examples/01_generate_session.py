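"""Generate one synthetic MATB-like session and inspect its structure.

Builds a 4-block session (one difficulty level per block), prints the
signal shapes and the generator's ground-truth chromophore plateaus, and
writes the session to delimited tables.
"""

from neuroload import SessionConfig
from neuroload.synthgen import generate_behavioral, generate_session, write_session

config = SessionConfig(block_duration=60.0, seed=1)
session = generate_session(config, "S00")
records = generate_behavioral(config, "S00")

print(f"EEG: {session.eeg.shape[0]} channels x {session.eeg.shape[1]} samples "
      f"at {session.eeg_rate:.0f} Hz")
print(f"fNIRS: {session.fnirs.shape} (sites x chromophores x samples) "
      f"at {session.fnirs_rate:.0f} Hz")
print(f"events (block onset, level): {session.events}")

# The generator retains the noiseless modulation it applied, so recovery
# tests can compare against it. O2Hb plateaus rise with difficulty:
plateaus = session.ground_truth["fnirs_level_means"]["left"]["O2Hb"]
print("left O2Hb plateau per level (umol/L):",
      {lv: round(v, 2) for lv, v in plateaus.items()})

manifest = write_session(session, "scratch/example_session", records)
print(f"wrote {manifest}")
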