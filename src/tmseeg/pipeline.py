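"""End-to-end orchestration: simulate/load -> preprocess -> features ->
group statistics -> prognosis -> topographic report.

A run is described by a single declarative (YAML/dict) configuration; every
stochastic step takes an explicit seed, so two runs of the same
configuration produce byte-identical JSON outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import CohortIntegrityError, ParameterError
from .features import FeatureParams, extract_feature_table, write_feature_table
from .group_stats import (
    build_diff_table,
    correlate_with_outcome,
    responder_rate,
    scale_ttests,
    select_significant,
    ttest_all_indicators,
)
from .io import read_recording, read_scale_table, write_recording_csv, write_scale_table
from .preprocessing import preprocess_recording
from .prognosis import ModelConfig, run_prognosis
from .recording import EEGRecording, EpochedEEG
from .synthetic import SyntheticConfig, generate_cohort
from .topomap import render_topomap

logger = logging.getLogger(__name__)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParameterError(f"{path}: configuration must be a mapping")
    return cfg


def load_cohort(
    cfg: dict,
) -> tuple[list[tuple[EEGRecording, EEGRecording]], pd.DataFrame]:
    """Materialize the cohort a config describes (synthetic or on-disk)."""
    cohort = cfg.get("cohort", {})
    if "synthetic" in cohort:
        syn = SyntheticConfig(**cohort["synthetic"])
        return generate_cohort(syn)
    if "recordings_dir" in cohort:
        recs: dict[tuple[str, str], EEGRecording] = {}
        rec_dir = Path(cohort["recordings_dir"])
        scale_path = Path(cohort["scale_table"]).resolve()
        for path in sorted(rec_dir.iterdir()):
            if path.suffix.lower() not in (".csv", ".edf"):
                continue
            if path.resolve() == scale_path:
                continue
            rec = read_recording(path)
            recs[(rec.subject_id, rec.session)] = rec
        subjects = sorted({sid for sid, _ in recs})
        pairs = []
        for sid in subjects:
            if (sid, "pre") not in recs or (sid, "post") not in recs:
                raise CohortIntegrityError(f"subject {sid} is missing a session")
            pairs.append((recs[(sid, "pre")], recs[(sid, "post")]))
        scales = read_scale_table(cohort["scale_table"])
        return pairs, scales
    raise ParameterError("config.cohort must name either 'synthetic' or 'recordings_dir'")


def preprocess_cohort(
    pairs: list[tuple[EEGRecording, EEGRecording]], cfg: dict
) -> dict[tuple[str, str], EpochedEEG]:
    pp = cfg.get("preprocessing", {})
    out: dict[tuple[str, str], EpochedEEG] = {}
    for pre, post in pairs:
        for rec in (pre, post):
            out[(rec.subject_id, rec.session)] = preprocess_recording(
                rec,
                low=pp.get("low", 0.5),
                high=pp.get("high", 45.0),
                epoch_length=pp.get("epoch_length", 1.0),
                amplitude_threshold_uv=pp.get("amplitude_threshold_uv", 100.0),
            )
    return out


def _indicator_topomaps(records: pd.DataFrame, out_dir: Path, stem: str, indicators=None) -> list[Path]:
    written = []
    for (feature, band), grp in records.groupby(["feature", "band"], sort=True):
        if indicators is not None and [feature, band] not in [list(i) for i in indicators]:
            continue
        values = dict(zip(grp["channel"], grp["statistic"]))
        path = out_dir / f"topomap_{stem}_{feature}_{band}.png"
        render_topomap(values, path, title=f"{stem} {feature} / {band}")
        written.append(path)
    return written


def run_pipeline(config, out_dir) -> Path:
    """Execute the full analysis described by ``config`` into ``out_dir``.

    Writes the long-format feature table, three statistics tables (paired
    t-tests plus PSQI and ISI outcome correlations), the two prognosis JSON
    results, topographic maps, and a plain-text run log. Returns ``out_dir``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pairs, scale_table = load_cohort(config)
    epochs = preprocess_cohort(pairs, config)
    params = FeatureParams(**config.get("features", {}))
    feature_table = extract_feature_table(epochs, params)
    write_feature_table(feature_table, out_dir / "features.tsv")
    write_scale_table(scale_table, out_dir / "scale_table.csv")

    stats_cfg = config.get("stats", {})
    alpha = stats_cfg.get("alpha", 0.05)
    correction = stats_cfg.get("correction")
    ttests = ttest_all_indicators(feature_table)
    ttests.to_csv(out_dir / "ttest_indicators.tsv", sep="\t", index=False)
    dt = build_diff_table(feature_table, scale_table)
    corr = {}
    for scale in ("PSQI", "ISI"):
        corr[scale] = correlate_with_outcome(dt, scale)
        corr[scale].to_csv(out_dir / f"corr_{scale.lower()}.tsv", sep="\t", index=False)

    scale_stats = scale_ttests(scale_table)
    summary = {
        "alpha": alpha,
        "correction": correction,
        "scale_ttests": {k: asdict(v) for k, v in scale_stats.items()},
        "responder_rate": {s: responder_rate(scale_table, s) for s in ("PSQI", "ISI")},
        "significant_ttest_cells": int(len(select_significant(ttests, alpha, correction))),
        "selected_indicators": {
            s: select_significant(corr[s], alpha, correction)[
                ["feature", "band", "channel", "statistic", "p"]
            ].to_dict("records")
            for s in ("PSQI", "ISI")
        },
    }
    with open(out_dir / "stats_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    prog_cfg = config.get("prognosis", {})
    mode = prog_cfg.pop("mode", "full-sample") if isinstance(prog_cfg, dict) else "full-sample"
    prog_cfg = {k: v for k, v in prog_cfg.items()}
    mcfg = ModelConfig(**prog_cfg)
    for scale in ("PSQI", "ISI"):
        res = run_prognosis(feature_table, scale_table, scale, alpha=alpha, cfg=mcfg, mode=mode)
        res.to_json(out_dir / f"prognosis_{scale.lower()}.json")

    report_cfg = config.get("report", {})
    if report_cfg.get("topomaps", True):
        indicators = report_cfg.get("indicators")  # e.g. [["PSD", "alpha"]]
        _indicator_topomaps(ttests, out_dir, "t", indicators)
        for scale in ("PSQI", "ISI"):
            _indicator_topomaps(corr[scale], out_dir, f"r_{scale.lower()}", indicators)

    with open(out_dir / "run_log.txt", "w") as fh:
        fh.write(f"tmseeg {__version__}\n")
        fh.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
        fh.write(f"config: {json.dumps(config, sort_keys=True, default=str)}\n")
        fh.write(f"subjects: {len(pairs)}; feature rows: {len(feature_table)}\n")
    return out_dir


def write_cohort(pairs, scale_table, out_dir, fmt: str = "csv") -> Path:
    """Persist a cohort as per-recording files plus the scale CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from .io import write_recording_edf

    for pre, post in pairs:
        for rec in (pre, post):
            if fmt == "csv":
                write_recording_csv(rec, out_dir / f"{rec.subject_id}_{rec.session}.csv")
            elif fmt == "edf":
                write_recording_edf(rec, out_dir / f"{rec.subject_id}_{rec.session}.edf")
            else:
                raise ParameterError("fmt must be 'csv' or 'edf'")
    write_scale_table(scale_table, out_dir / "scale_table.csv")
    return out_dir
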