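"""End-to-end runner: synthesis -> preprocessing -> features -> channel
selection -> classification -> statistical report, with a run manifest.

Every stage communicates only through the serialized interfaces (feature
tables, report frames); the manifest records the configuration hash, the
seeds, and SHA-256 checksums of each written file so reruns with the same
config are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import channel_select, classify, eeg_preproc, features, fnirs_preproc, synthgen
from .config import (
    GridSearchSpec,
    OPTIMIZED_MONTAGE_26,
    ParameterError,
    SessionConfig,
)
from .io import file_checksum, write_feature_table
from .stats_report import (
    band_contrast_map,
    composite_scores,
    fnirs_level_effects,
    level_anova,
    scalp_anova_map,
)
from .types import META_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    session: SessionConfig = field(default_factory=SessionConfig)
    stride: float = 3.0
    #: "auto" selects channels from the accuracy curve; "full" keeps all 62;
    #: "reference26" loads the packaged 26-channel optimized montage.
    montage_mode: str = "auto"
    grids: GridSearchSpec = field(default_factory=GridSearchSpec)
    artifact_mode: str = "regression"
    rfe_top_k: int = 100
    plateau_threshold: float = 0.5
    #: channel counts at which the accuracy curve is evaluated (None = all).
    curve_counts: Optional[Sequence[int]] = None
    seed: int = 0
    out_dir: str = "neuroload_run"
    remove_outliers: bool = True

    def to_dict(self) -> dict:
        d = {
            "session": self.session.to_dict(),
            "stride": self.stride,
            "montage_mode": self.montage_mode,
            "grids": vars(self.grids).copy(),
            "artifact_mode": self.artifact_mode,
            "rfe_top_k": self.rfe_top_k,
            "plateau_threshold": self.plateau_threshold,
            "curve_counts": list(self.curve_counts) if self.curve_counts else None,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "remove_outliers": self.remove_outliers,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        session = d.pop("session", {})
        if isinstance(session, dict):
            session.pop("montage", None) or None
            levels = session.pop("levels", None)
            sc = SessionConfig(**{k: v for k, v in session.items()
                                  if k in SessionConfig.__dataclass_fields__})
            if levels:
                sc.levels = tuple(levels)
        else:
            sc = session
        grids = d.pop("grids", {})
        gs = GridSearchSpec(**{k: tuple(v) for k, v in grids.items()}) \
            if isinstance(grids, dict) and grids else GridSearchSpec()
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(session=sc, grids=gs, **{k: v for k, v in known.items()
                                            if k not in ("session", "grids")})


def subject_feature_tables(config: RunConfig, subject_id: str) -> pd.DataFrame:
    """Generate and fully process one subject into a wide feature table
    (full-montage EEG + fNIRS statistics + NVC columns)."""
    session = synthgen.generate_session(config.session, subject_id)
    eeg_epochs = eeg_preproc.preprocess_eeg(
        session, stride=config.stride, artifact_mode=config.artifact_mode)
    fnirs_epochs = fnirs_preproc.preprocess_fnirs(session, stride=config.stride)
    eeg_tab = features.eeg_feature_table(eeg_epochs)
    fnirs_tab = features.fnirs_feature_table(fnirs_epochs)
    nvc_tab = features.nvc_table(eeg_epochs, fnirs_epochs)
    wide = pd.concat(
        [eeg_tab.reset_index(drop=True),
         fnirs_tab[features.feature_columns(fnirs_tab)].reset_index(drop=True),
         nvc_tab[features.feature_columns(nvc_tab)].reset_index(drop=True)],
        axis=1)
    if config.remove_outliers:
        wide = features.zscore_outlier_removal(wide)
    return wide


def split_wide_table(wide: pd.DataFrame, montage_mode: str = "optimized",
                     optimized_channels: Sequence[str] = OPTIMIZED_MONTAGE_26,
                     ) -> Dict[str, pd.DataFrame]:
    """Slice a processed wide table into the three feature sets."""
    cols = features.feature_columns(wide)
    eeg_cols = [c for c in cols if c.endswith("_psd") or c.endswith("_diff")]
    fnirs_cols = [c for c in cols
                  if not (c.endswith("_psd") or c.endswith("_diff")
                          or c.startswith("nvc_"))]
    nvc_cols = [c for c in cols if c.startswith("nvc_")]
    meta = list(META_COLUMNS)
    return features.assemble_feature_sets(
        wide[meta + eeg_cols], wide[meta + fnirs_cols], wide[meta + nvc_cols],
        montage_mode=montage_mode, optimized_channels=optimized_channels)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``<out_dir>/manifest.json``)."""
    out = Path(config.out_dir)
    if not out.exists():
        logger.info("creating output directory %s", out)
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, str] = {}
    subjects = [f"S{i:02d}" for i in range(config.session.n_subjects)]

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("features")
        wide_tables = {}
        for sid in subjects:
            wide = subject_feature_tables(config, sid)
            wide_tables[sid] = wide
            p = write_feature_table(wide, out / f"features_{sid}.csv")
            written[f"features_{sid}"] = str(p)

        _stage("behavioral")
        records = []
        for sid in subjects:
            records.extend(synthgen.generate_behavioral(config.session, sid))
        composites = composite_scores(records)
        composites.to_csv(out / "behavioral_composites.csv", index=False)
        written["behavioral_composites"] = str(out / "behavioral_composites.csv")
        behavioral_stats = {}
        for name in ("composite_tlx", "composite_perf"):
            res = level_anova(composites[name].to_numpy(),
                              composites["level"].to_numpy())
            behavioral_stats[name] = {"F": res["F"], "p": res["p"]}

        _stage("channel_select")
        per_subject_sets = [
            channel_select.rfe_top_features(wide_tables[sid], k=config.rfe_top_k)
            for sid in subjects
        ]
        montage = sorted(
            {c.rsplit("_", 2)[0] for c in wide_tables[subjects[0]].columns
             if c.endswith("_psd")})
        # preserve epoch-table channel order
        first = wide_tables[subjects[0]]
        ordered = []
        for c in first.columns:
            if c.endswith("_psd"):
                ch = c.rsplit("_", 2)[0]
                if ch not in ordered:
                    ordered.append(ch)
        report = channel_select.aggregate_importance(per_subject_sets, ordered)
        pd.DataFrame(
            {"feature": list(report.feature_weights),
             "weight": list(report.feature_weights.values())}
        ).to_csv(out / "feature_weights.csv", index=False)
        written["feature_weights"] = str(out / "feature_weights.csv")

        curve = channel_select.incremental_accuracy_curve(
            list(wide_tables.values()), report.ranking, seed=config.seed,
            counts=config.curve_counts)
        curve.to_csv(out / "accuracy_curve.csv", index=False)
        written["accuracy_curve"] = str(out / "accuracy_curve.csv")

        if config.montage_mode == "reference26":
            selected = list(OPTIMIZED_MONTAGE_26)
        elif config.montage_mode == "full":
            selected = list(ordered)
        elif config.montage_mode == "auto":
            selected = channel_select.select_montage(
                report, curve, plateau_threshold=config.plateau_threshold)
        else:
            raise ParameterError(f"unknown montage mode {config.montage_mode!r}")
        (out / "channel_selection.json").write_text(json.dumps({
            "ranking": report.ranking,
            "channel_weights": report.channel_weights,
            "selected_montage": selected,
        }, indent=2))
        written["channel_selection"] = str(out / "channel_selection.json")

        _stage("classify")
        per_subject_sets_tables = [
            split_wide_table(wide_tables[sid], montage_mode="optimized",
                             optimized_channels=selected)
            for sid in subjects
        ]
        results = classify.evaluate_all(
            per_subject_sets_tables, spec=config.grids, seed=config.seed)
        for which in ("test", "train"):
            tab = classify.results_table(results, which)
            tab.to_csv(out / f"classification_{which}.csv", index=False)
            written[f"classification_{which}"] = str(out / f"classification_{which}.csv")
        anova_info = {}
        if len(subjects) >= 2:
            anova = classify.accuracy_anova(results)
            anova.to_csv(out / "accuracy_anova.csv")
            written["accuracy_anova"] = str(out / "accuracy_anova.csv")
            anova_info = {str(k): {"F": float(v["F"]), "p": float(v["PR(>F)"])}
                          for k, v in anova.iterrows()
                          if np.isfinite(v.get("F", np.nan))}

        _stage("stats_report")
        pooled = pd.concat(wide_tables.values(), ignore_index=True)
        scalp = scalp_anova_map(pooled)
        scalp.to_csv(out / "scalp_anova.csv", index=False)
        written["scalp_anova"] = str(out / "scalp_anova.csv")
        contrast = band_contrast_map(pooled,
                                     level_hi=max(config.session.levels),
                                     level_lo=min(config.session.levels))
        contrast.to_csv(out / "band_contrast.csv", index=False)
        written["band_contrast"] = str(out / "band_contrast.csv")

        fnirs_stats = {}
        sid0 = subjects[0]
        session0 = synthgen.generate_session(config.session, sid0)
        fnirs_epochs0 = fnirs_preproc.preprocess_fnirs(session0, stride=config.stride)
        effects = fnirs_level_effects(fnirs_epochs0)
        for key, val in effects.items():
            fnirs_stats[key] = {
                "F": val["anova"]["F"], "p": val["anova"]["p"],
                "level_means": val["level_means"],
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "subjects": subjects,
        "selected_montage": selected,
        "behavioral_anova": behavioral_stats,
        "accuracy_anova": anova_info,
        "fnirs_level_effects": fnirs_stats,
        "n_evaluation_results": len(results),
        "results_summary": classify.results_table(results, "test").to_dict("records"),
        "checksums": {k: file_checksum(v) for k, v in written.items()},
        "files": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
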