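"""Domain types, validation and CSV readers/writers.

Coordinate convention: gaze and ROI boxes live in normalized world-view
coordinates with origin at the top-left, x rightward, y downward, and the
world-view equal to the unit square.  Gaze may fall outside the unit square
(off-world) and is preserved as-is.  Timestamps are milliseconds from session
start; files recorded in seconds can be converted at ingest with
``time_unit="s"``.

All tabular data are plain comma-separated UTF-8 files with a header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """A file does not conform to the expected schema."""


class ValidationError(ValueError):
    """Data violate a domain invariant (e.g. negative dose)."""


GAZE_COLUMNS = ["t_ms", "x_norm", "y_norm", "confidence"]
TRACK_COLUMNS = ["t_ms", "roi_id", "x_min", "y_min", "x_max", "y_max", "visible"]
TRIAL_COLUMNS = [
    "participant_id", "scenario_id", "condition", "order_index", "drug",
    "initial_dose", "final_dose", "ai_dose",
    "rating_qdiff", "rating_mortality", "rating_features", "rating_examples",
    "seniority",
]
RATING_COLUMNS = ["rating_qdiff", "rating_mortality", "rating_features", "rating_examples"]

DRUGS = ("fluid", "vasopressor")
CONDITIONS = ("safe", "unsafe")


# --------------------------------------------------------------------------- #
# ROI hierarchy


@dataclass(frozen=True)
class RoiDefinition:
    """One region of interest: identifier, human label, optional parent."""

    roi_id: str
    label: str
    parent_id: str | None = None


class RoiHierarchy:
    """A forest of ROIs, e.g. four XAI panels nested inside the AI screen.

    Gaze on a child region also counts as gaze on every ancestor, so the AI
    screen is a super-set of the AI recommendation and the explanation panels.
    """

    def __init__(self, definitions: Iterable[RoiDefinition]):
        self._defs: dict[str, RoiDefinition] = {}
        for d in definitions:
            if d.roi_id in self._defs:
                raise ValidationError(f"duplicate roi_id {d.roi_id!r}")
            self._defs[d.roi_id] = d
        for d in self._defs.values():
            if d.parent_id is not None and d.parent_id not in self._defs:
                raise ValidationError(
                    f"roi {d.roi_id!r} references unknown parent {d.parent_id!r}"
                )
        # forest check: walking up from any node must terminate
        for d in self._defs.values():
            seen = set()
            cur: str | None = d.roi_id
            while cur is not None:
                if cur in seen:
                    raise ValidationError(f"cycle in ROI hierarchy at {cur!r}")
                seen.add(cur)
                cur = self._defs[cur].parent_id

    @property
    def roi_ids(self) -> list[str]:
        return sorted(self._defs)

    def __contains__(self, roi_id: str) -> bool:
        return roi_id in self._defs

    def __getitem__(self, roi_id: str) -> RoiDefinition:
        return self._defs[roi_id]

    def ancestors(self, roi_id: str) -> list[str]:
        """Ancestor ids from immediate parent upward (excludes roi_id)."""
        out = []
        cur = self._defs[roi_id].parent_id
        while cur is not None:
            out.append(cur)
            cur = self._defs[cur].parent_id
        return out

    def children(self, roi_id: str) -> list[str]:
        return sorted(d.roi_id for d in self._defs.values() if d.parent_id == roi_id)

    def leaves(self) -> list[str]:
        parents = {d.parent_id for d in self._defs.values() if d.parent_id}
        return sorted(r for r in self._defs if r not in parents)


#: the four explanation panels shown on the AI screen
XAI_ROIS = ("xai_qdiff", "xai_mortality", "xai_features", "xai_examples")
#: conventional clinical surfaces (non-AI)
CONVENTIONAL_ROIS = ("icu_chart", "patient_mannequin", "vitals_monitor")
#: AI-related surfaces
AI_ROIS = ("ai_screen", "ai_recommendation") + XAI_ROIS
MAJOR_ROIS = ("ai_screen",) + CONVENTIONAL_ROIS


def default_roi_hierarchy() -> RoiHierarchy:
    """The simulation-suite layout: four major surfaces, with the AI
    recommendation and four explanation panels nested in the AI screen."""
    defs = [
        RoiDefinition("patient_mannequin", "Patient mannequin"),
        RoiDefinition("vitals_monitor", "Vital signs monitor"),
        RoiDefinition("icu_chart", "Paper ICU data chart"),
        RoiDefinition("ai_screen", "AI display screen"),
        RoiDefinition("ai_recommendation", "AI dose recommendation", "ai_screen"),
        RoiDefinition("xai_qdiff", "Q-value difference explanation", "ai_screen"),
        RoiDefinition("xai_mortality", "Predicted mortality explanation", "ai_screen"),
        RoiDefinition("xai_features", "Feature importance explanation", "ai_screen"),
        RoiDefinition("xai_examples", "Influential training examples", "ai_screen"),
    ]
    return RoiHierarchy(defs)


def load_roi_definitions(path: str | Path) -> RoiHierarchy:
    """Load an ROI hierarchy from YAML/JSON: ``{roi_id: {label, parent_id}}``."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    defs = [
        RoiDefinition(rid, spec.get("label", rid), spec.get("parent_id"))
        for rid, spec in raw.items()
    ]
    return RoiHierarchy(defs)


def write_roi_definitions(hierarchy: RoiHierarchy, path: str | Path) -> None:
    raw = {
        rid: {"label": hierarchy[rid].label, "parent_id": hierarchy[rid].parent_id}
        for rid in hierarchy.roi_ids
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


# --------------------------------------------------------------------------- #
# Gaze stream


@dataclass
class GazeQCReport:
    """Ingest quality-control counters; flags never drop rows."""

    rows_read: int = 0
    rows_kept: int = 0
    n_low_confidence: int = 0
    n_offworld: int = 0
    n_duplicate_timestamps: int = 0
    reordered: bool = False
    notes: list[str] = field(default_factory=list)


def read_gaze_stream(
    path: str | Path,
    min_confidence: float = 0.6,
    time_unit: str = "ms",
) -> tuple[pd.DataFrame, GazeQCReport]:
    """Read a gaze-sample CSV into a time-sorted DataFrame plus a QC report.

    Columns in the file: ``t_ms,x_norm,y_norm,confidence``.  Output columns are
    ``t_ms,x,y,confidence``.  Low-confidence samples are flagged in the QC
    report but retained: blink detection depends on them.  Duplicate timestamps
    collapse to the last record.
    """
    df = pd.read_csv(path)
    for col in GAZE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"gaze file {path}: missing column {col!r}")
    qc = GazeQCReport(rows_read=len(df))
    df = df.rename(columns={"x_norm": "x", "y_norm": "y"})[["t_ms", "x", "y", "confidence"]]
    df = df.astype(float)
    if time_unit == "s":
        df["t_ms"] = df["t_ms"] * 1000.0
    elif time_unit != "ms":
        raise ValueError(f"time_unit must be 'ms' or 's', got {time_unit!r}")
    if ((df["confidence"] < 0) | (df["confidence"] > 1)).any():
        raise ValidationError(f"gaze file {path}: confidence outside [0, 1]")

    if not df["t_ms"].is_monotonic_increasing:
        qc.reordered = True
        qc.notes.append("timestamps were not monotonically increasing; sorted stably")
        df = df.sort_values("t_ms", kind="stable", ignore_index=True)
    dup = df["t_ms"].duplicated(keep="last")
    if dup.any():
        qc.n_duplicate_timestamps = int(dup.sum())
        qc.notes.append(f"collapsed {qc.n_duplicate_timestamps} duplicate timestamps (kept last)")
        df = df[~dup].reset_index(drop=True)

    qc.n_low_confidence = int((df["confidence"] < min_confidence).sum())
    offworld = (df["x"] < 0) | (df["x"] > 1) | (df["y"] < 0) | (df["y"] > 1)
    qc.n_offworld = int(offworld.sum())
    qc.rows_kept = len(df)
    return df, qc


def write_gaze_stream(df: pd.DataFrame, path: str | Path) -> None:
    out = df.rename(columns={"x": "x_norm", "y": "y_norm"})[GAZE_COLUMNS]
    out.to_csv(path, index=False)


# --------------------------------------------------------------------------- #
# ROI tracks


def read_roi_tracks(path: str | Path, hierarchy: RoiHierarchy) -> pd.DataFrame:
    """Read an ROI box-track CSV, grouped by roi_id and sorted by time.

    Each row gives one ROI's bounding box at one frame time plus a visibility
    flag; box fields of invisible rows are ignored (may be empty).
    """
    df = pd.read_csv(path)
    for col in TRACK_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"ROI track file {path}: missing column {col!r}")
    unknown = sorted(set(df["roi_id"]) - set(hierarchy.roi_ids))
    if unknown:
        raise ValidationError(f"ROI track file {path}: unknown roi_id(s) {unknown}")
    df["visible"] = df["visible"].astype(bool)
    vis = df[df["visible"]]
    bad = vis[(vis["x_min"] > vis["x_max"]) | (vis["y_min"] > vis["y_max"])]
    if len(bad):
        row = int(bad.index[0]) + 2  # 1-based, plus header line
        raise ValidationError(
            f"ROI track file {path}: degenerate box (min > max) at file row {row}"
        )
    return df.sort_values(["roi_id", "t_ms"], kind="stable", ignore_index=True)


def write_roi_tracks(df: pd.DataFrame, path: str | Path) -> None:
    df[TRACK_COLUMNS].to_csv(path, index=False)


# --------------------------------------------------------------------------- #
# Trials


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read the trials CSV (one row per trial x drug) with validation.

    Dose units are preserved as given (ml/h for fluid, mcg/kg/min for
    vasopressor).  Missing usefulness ratings stay missing (NaN), never zero.
    """
    df = pd.read_csv(path)
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"trials file {path}: missing column {col!r}")
    bad_cond = sorted(set(df["condition"]) - set(CONDITIONS))
    if bad_cond:
        raise ValidationError(f"trials file {path}: invalid condition(s) {bad_cond}")
    for col in ("initial_dose", "final_dose", "ai_dose"):
        if (df[col] < 0).any():
            raise ValidationError(f"trials file {path}: negative dose in column {col!r}")
    for col in RATING_COLUMNS:
        vals = df[col].dropna()
        if len(vals) and ((vals < 0) | (vals > 4)).any():
            raise ValidationError(f"trials file {path}: rating outside 0-4 in {col!r}")
    bad_drug = sorted(set(df["drug"]) - set(DRUGS))
    if bad_drug:
        raise ValidationError(f"trials file {path}: unknown drug(s) {bad_drug}")
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    df[TRIAL_COLUMNS].to_csv(path, index=False)


# --------------------------------------------------------------------------- #
# Design validation


@dataclass(frozen=True)
class DesignViolation:
    participant_id: str
    rule: str
    detail: str


def validate_design(
    trials: pd.DataFrame,
    n_scenarios: int = 6,
    n_safe: int = 4,
    n_unsafe: int = 2,
) -> list[DesignViolation]:
    """Check each participant against the experimental design.

    Every participant must complete all scenarios (4 under safe AI, 2 under
    unsafe AI) in a permuted order whose first trial is always safe — unsafe
    advice early on could colour confidence in every later trial.  Violations
    are returned as data, never raised.
    """
    violations: list[DesignViolation] = []
    per_trial = trials.drop_duplicates(["participant_id", "scenario_id"])
    for pid, grp in per_trial.groupby("participant_id", sort=True):
        pid = str(pid)
        if len(grp) != n_scenarios:
            violations.append(DesignViolation(
                pid, "trial_count", f"expected {n_scenarios} trials, found {len(grp)}"))
        counts = grp["condition"].value_counts()
        if counts.get("safe", 0) != n_safe or counts.get("unsafe", 0) != n_unsafe:
            violations.append(DesignViolation(
                pid, "condition_balance",
                f"expected {n_safe} safe + {n_unsafe} unsafe, found "
                f"{counts.get('safe', 0)} safe + {counts.get('unsafe', 0)} unsafe"))
        first = grp[grp["order_index"] == 1]
        if len(first) != 1 or first["condition"].iloc[0] != "safe":
            violations.append(DesignViolation(
                pid, "first_trial_safe", "first trial in session is not a safe scenario"))
        order = sorted(grp["order_index"])
        if order != list(range(1, len(grp) + 1)):
            violations.append(DesignViolation(
                pid, "order_permutation", f"order_index not 1..{len(grp)}: {order}"))
    return violations
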