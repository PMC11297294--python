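"""End-to-end orchestration: ingest -> events -> attention -> behaviour -> stats.

A run consumes an input directory holding ``trials.csv``,
``roi_definitions.yaml`` and per-trial ``gaze_<pid>_s<sid>.csv`` /
``tracks_<pid>_s<sid>.csv`` files (the layout the synthetic generator
emits), and writes event tables, the attention summary, the behaviour table,
the report tables and a run manifest (config snapshot, input digests,
version, seed, timestamps) to the output directory.  Given identical inputs
and config, all output tables are byte-identical across reruns; only the
manifest timestamp differs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

import clingaze
from clingaze import events as ev
from clingaze import io as cgio
from clingaze.attention import summarize_attention
from clingaze.behaviour import compute_behaviour, join_behaviour_attention
from clingaze.stats import headline_report

log = logging.getLogger("clingaze")

DEFAULT_PIPELINE_CONFIG: dict = {
    "ingest": {"min_confidence": 0.6, "time_unit": "ms"},
    "fixations": {"dispersion_threshold": 0.03, "min_duration_ms": 80.0,
                  "min_confidence": 0.6},
    "blinks": {"confidence_threshold": 0.5, "min_duration_ms": 50.0,
               "max_duration_ms": 500.0, "merge_gap_ms": 20.0},
    "attention": {"fixation_attribution": "midpoint"},
    "behaviour": {"clamp": True, "leave_one_out": False,
                  "epsilon": {"fluid": 1.0, "vasopressor": 0.01}},
    "stats": {"alpha": 0.05, "participant_level": False},
}


def load_pipeline_config(path: str | Path | None) -> dict:
    """Merge a YAML config over the defaults (shallow per section)."""
    cfg = {k: dict(v) for k, v in DEFAULT_PIPELINE_CONFIG.items()}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        for section, vals in user.items():
            cfg.setdefault(section, {}).update(vals or {})
    return cfg


@dataclass
class RunManifest:
    config: dict
    software_version: str
    seed: int | None
    started_utc: str
    input_digests: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


_GAZE_RE = re.compile(r"gaze_(?P<pid>[^_]+)_s(?P<sid>\d+)\.csv$")


def run_pipeline(
    input_dir: str | Path,
    output_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Run the full analysis over an input directory; returns row counts.

    On a validation error, partially written outputs are removed before the
    exception propagates.
    """
    cfg = config or load_pipeline_config(None)
    inp = Path(input_dir)
    out = Path(output_dir)
    manifest = RunManifest(
        config=cfg, software_version=clingaze.__version__, seed=seed,
        started_utc=datetime.now(timezone.utc).isoformat(),
    )

    trials_path = inp / "trials.csv"
    roi_path = inp / "roi_definitions.yaml"
    for p in (trials_path, roi_path):
        if not p.exists():
            raise cgio.FormatError(f"required input file missing: {p}")
    hierarchy = cgio.load_roi_definitions(roi_path)
    trials = cgio.read_trials(trials_path)
    manifest.input_digests["trials.csv"] = _sha256(trials_path)
    manifest.input_digests["roi_definitions.yaml"] = _sha256(roi_path)

    violations = cgio.validate_design(trials)
    for v in violations:
        log.warning("design violation: %s %s: %s", v.participant_id, v.rule, v.detail)

    per_trial = trials.drop_duplicates(["participant_id", "scenario_id"])
    fixation_tbls, blink_tbls, attention_tbls = [], [], []
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        for rec in per_trial.itertuples(index=False):
            pid, sid = rec.participant_id, rec.scenario_id
            gaze_path = inp / f"gaze_{pid}_s{sid}.csv"
            tracks_path = inp / f"tracks_{pid}_s{sid}.csv"
            for p in (gaze_path, tracks_path):
                if not p.exists():
                    raise cgio.FormatError(f"required input file missing: {p}")
            samples, qc = cgio.read_gaze_stream(gaze_path, **cfg["ingest"])
            tracks = cgio.read_roi_tracks(tracks_path, hierarchy)
            manifest.input_digests[gaze_path.name] = _sha256(gaze_path)
            manifest.input_digests[tracks_path.name] = _sha256(tracks_path)

            fixations = ev.detect_fixations(samples, **cfg["fixations"])
            blinks, _bqc = ev.detect_blinks(samples, **cfg["blinks"])
            trial_meta = {"participant_id": pid, "scenario_id": sid,
                          "condition": rec.condition}
            att, _aqc = summarize_attention(
                samples, fixations, blinks, tracks, hierarchy, trial_meta,
                **cfg["attention"])
            for tbl, store in ((fixations, fixation_tbls), (blinks, blink_tbls)):
                tbl = tbl.copy()
                tbl.insert(0, "participant_id", pid)
                tbl.insert(1, "scenario_id", sid)
                store.append(tbl)
            attention_tbls.append(att)
            log.info("trial %s s%s: %d samples, %d fixations, %d blinks",
                     pid, sid, len(samples), len(fixations), len(blinks))

        attention = pd.concat(attention_tbls, ignore_index=True)
        behaviour = compute_behaviour(trials, **cfg["behaviour"])
        analysis, join_qc = join_behaviour_attention(behaviour, attention, trials)
        report = headline_report(attention, behaviour, trials, **cfg["stats"])

        def _write(df: pd.DataFrame, name: str) -> None:
            path = out / name
            df.to_csv(path, index=False)
            written.append(path)

        _write(pd.concat(fixation_tbls, ignore_index=True), "fixations.csv")
        _write(pd.concat(blink_tbls, ignore_index=True), "blinks.csv")
        _write(attention, "attention.csv")
        _write(behaviour, "behaviour.csv")
        _write(analysis, "analysis.csv")
        _write(trials, "trials.csv")
        report.write(out)
        manifest.row_counts = {
            "trials": len(trials),
            "attention": len(attention),
            "behaviour": len(behaviour),
            "analysis": len(analysis),
            "design_violations": len(violations),
            "join_unmatched": len(join_qc["behaviour_only_keys"])
            + len(join_qc["attention_only_keys"]),
        }
        manifest.write(out / "manifest.json")
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return manifest.row_counts


def report_from_run(run_dir: str | Path, output_dir: str | Path,
                    config: dict | None = None) -> None:
    """Recompute the statistical report from a prior run's output tables."""
    cfg = config or load_pipeline_config(None)
    run = Path(run_dir)
    for name in ("attention.csv", "behaviour.csv", "trials.csv"):
        if not (run / name).exists():
            raise cgio.FormatError(f"required input file missing: {run / name}")
    attention = pd.read_csv(run / "attention.csv")
    behaviour = pd.read_csv(run / "behaviour.csv")
    trials = cgio.read_trials(run / "trials.csv")
    report = headline_report(attention, behaviour, trials, **cfg["stats"])
    report.write(output_dir)
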