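"""Statistical report: behavioral composites, FDR scalp statistics,
band-power contrasts, and chromophore level effects.

Prints the level effect on the composite NASA-TLX / performance scores, the
count of FDR-significant scalp cells per band, the high-minus-low band
power contrast at representative channels, and the O2Hb/HHb level means.
"""

import pandas as pd

from neuroload import SessionConfig
from neuroload.fnirs_preproc import preprocess_fnirs
from neuroload.pipeline import RunConfig, subject_feature_tables
from neuroload.stats_report import (
    band_contrast_map,
    composite_scores,
    fnirs_level_effects,
    level_anova,
    scalp_anova_map,
)
from neuroload.synthgen import generate_behavioral, generate_session

cfg = SessionConfig(block_duration=60.0, seed=5)
rc = RunConfig(session=cfg, seed=5)

records = []
for i in range(6):
    records.extend(generate_behavioral(cfg, f"S{i:02d}"))
scores = composite_scores(records)
for col in ("composite_tlx", "composite_perf"):
    res = level_anova(scores[col].to_numpy(), scores["level"].to_numpy())
    print(f"{col}: F = {res['F']:.1f}, p = {res['p']:.2g}")

pooled = pd.concat([subject_feature_tables(rc, f"S{i:02d}") for i in range(2)],
                   ignore_index=True)
scalp = scalp_anova_map(pooled)
sig = scalp[scalp["p_fdr"] < 0.05].groupby("band").size()
print("\nFDR-significant scalp cells per band (of 62):")
print(sig.to_string())

contrast = band_contrast_map(pooled).set_index(["channel", "band"])
print("\nlevel-7 minus level-1 power at representative channels:")
for ch, band in [("Fz", "theta"), ("O1", "alpha"), ("O1", "beta2")]:
    print(f"  {ch} {band}: {contrast.loc[(ch, band), 'contrast']:+.2f} uV^2 "
          f"({'rises' if contrast.loc[(ch, band), 'contrast'] > 0 else 'falls'} "
          f"with workload)")

effects = fnirs_level_effects(preprocess_fnirs(generate_session(cfg, "S00")))
print("\nleft-site chromophore level means (umol/L):")
for chrom in ("O2Hb", "HHb"):
    means = effects[f"left_{chrom}"]["level_means"]
    print(f"  {chrom}: " + ", ".join(f"L{lv}={v:+.2f}" for lv, v in sorted(means.items())))
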