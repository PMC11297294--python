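"""Hierarchical ROI attribution and per-trial attention metrics.

Gaze is attributed to moving regions of interest (ROIs) whose bounding boxes
are sampled at camera frame times; between frames the most recent box applies
(zero-order hold).  A point inside several visible ROIs belongs to the
smallest-area one — and, through the hierarchy, to all of its ancestors, so
gaze on an explanation panel also counts as gaze on the enclosing AI screen.
Containment is half-open (x_min <= x < x_max, y_min <= y < y_max) so that
abutting panels partition the screen.

The "visual real-estate" correction compares the proportion of gaze an ROI
actually received with the proportion expected if gaze were spread uniformly
over the world-view, i.e. the time-weighted fraction of the unit square the
ROI occupies; their ratio is 1.0 for chance-level gaze and grows with
preferential attention, making ROIs of different size and visibility
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clingaze.io import RoiHierarchy

ELSEWHERE = "elsewhere"

ATTENTION_COLUMNS = [
    "participant_id", "scenario_id", "condition", "roi_id",
    "gaze_time_ms", "n_fixations", "mean_fixation_duration_ms",
    "blink_rate_bpm", "actual_gaze_proportion", "chance_gaze_proportion",
    "actual_to_chance_ratio",
]


class _RoiTrack:
    """Per-ROI arrays for vectorized zero-order-hold box lookup."""

    def __init__(self, grp: pd.DataFrame):
        grp = grp.sort_values("t_ms", kind="stable")
        self.t = grp["t_ms"].to_numpy(float)
        self.visible = grp["visible"].to_numpy(bool)
        self.box = grp[["x_min", "y_min", "x_max", "y_max"]].to_numpy(float)

    def at(self, t: np.ndarray):
        """Boxes and visibility at query times (most recent frame at or
        before t; not visible before the first frame)."""
        idx = np.searchsorted(self.t, t, side="right") - 1
        ok = idx >= 0
        idx_c = np.clip(idx, 0, len(self.t) - 1)
        vis = ok & self.visible[idx_c]
        box = self.box[idx_c]
        return box, vis


def _tracks_by_roi(tracks: pd.DataFrame) -> dict[str, _RoiTrack]:
    return {str(rid): _RoiTrack(grp) for rid, grp in tracks.groupby("roi_id")}


def box_at(roi_id: str, t_ms: float, tracks: pd.DataFrame):
    """Bounding box of ``roi_id`` at time ``t_ms`` (zero-order hold).

    Returns ``(x_min, y_min, x_max, y_max)`` or None when the ROI is not
    visible (flagged invisible, or queried before its first observation).
    """
    by_roi = _tracks_by_roi(tracks)
    if roi_id not in by_roi:
        raise KeyError(f"no track observations for roi_id {roi_id!r}")
    box, vis = by_roi[roi_id].at(np.asarray([float(t_ms)]))
    if not vis[0]:
        return None
    return tuple(box[0])


def _assign_leaf(
    x: np.ndarray, y: np.ndarray, t: np.ndarray,
    by_roi: dict[str, _RoiTrack], roi_order: list[str],
) -> np.ndarray:
    """Index into roi_order of the smallest-area visible ROI containing each
    point; -1 when inside none.  roi_order must be sorted so that ties on
    area resolve to the lexicographically smallest roi_id."""
    n = len(x)
    best = np.full(n, -1, dtype=int)
    best_area = np.full(n, np.inf)
    for k, rid in enumerate(roi_order):
        box, vis = by_roi[rid].at(t)
        inside = (
            vis
            & (x >= box[:, 0]) & (x < box[:, 2])
            & (y >= box[:, 1]) & (y < box[:, 3])
        )
        area = (box[:, 2] - box[:, 0]) * (box[:, 3] - box[:, 1])
        better = inside & (area < best_area)   # strict: ties keep earlier id
        best[better] = k
        best_area[better] = area[better]
    return best


def assign_point(
    x: float, y: float, t_ms: float,
    tracks: pd.DataFrame, hierarchy: RoiHierarchy,
) -> set[str]:
    """ROIs a gaze point belongs to: the smallest-area visible ROI containing
    it plus all of that ROI's ancestors; empty set if inside none."""
    by_roi = _tracks_by_roi(tracks)
    order = sorted(by_roi)
    idx = _assign_leaf(
        np.asarray([float(x)]), np.asarray([float(y)]), np.asarray([float(t_ms)]),
        by_roi, order,
    )[0]
    if idx < 0:
        return set()
    rid = order[idx]
    return {rid, *hierarchy.ancestors(rid)}


@dataclass
class AttentionQCReport:
    n_samples: int = 0
    exposure_ms: float = 0.0
    notes: list[str] = field(default_factory=list)


def summarize_attention(
    samples: pd.DataFrame,
    fixations: pd.DataFrame,
    blinks: pd.DataFrame,
    tracks: pd.DataFrame,
    hierarchy: RoiHierarchy,
    trial: dict,
    nominal_period_ms: float | None = None,
    fixation_attribution: str = "midpoint",
) -> tuple[pd.DataFrame, AttentionQCReport]:
    """Per-trial, per-ROI attention metrics.

    For each ROI (plus an implicit "elsewhere" region so proportions are
    well defined):

    * ``gaze_time_ms`` — sum of sample intervals (gap to the next sample,
      capped at twice the nominal period) whose sample falls in the ROI;
      gaze on a descendant also accrues to the ancestor.
    * ``n_fixations`` / ``mean_fixation_duration_ms`` — fixations whose
      centroid falls in the ROI at the fixation's temporal midpoint
      (``fixation_attribution="onset"`` uses the onset time instead).
    * ``blink_rate_bpm`` — blinks whose last confident gaze point falls in
      the ROI, per minute of that ROI's own gaze time (missing when the ROI
      received no gaze; noted in the QC report).
    * ``actual_gaze_proportion`` vs ``chance_gaze_proportion`` and their
      ratio — the visual real-estate correction.

    ``trial`` supplies ``participant_id``, ``scenario_id`` and ``condition``
    for the output keys.
    """
    qc = AttentionQCReport(n_samples=len(samples))
    t = samples["t_ms"].to_numpy(float)
    x = samples["x"].to_numpy(float)
    y = samples["y"].to_numpy(float)

    if len(t) > 1:
        dt = np.diff(t)
        period = nominal_period_ms or float(np.median(dt))
        intervals = np.append(np.minimum(dt, 2.0 * period), period)
    else:
        period = nominal_period_ms or 0.0
        intervals = np.asarray([period] * len(t), dtype=float)
    exposure = float(intervals.sum())
    qc.exposure_ms = exposure

    by_roi = _tracks_by_roi(tracks)
    order = sorted(by_roi)
    all_rois = hierarchy.roi_ids

    # per-sample leaf assignment -> gaze time per ROI (ancestors included)
    leaf_idx = _assign_leaf(x, y, t, by_roi, order)
    gaze_time = {rid: 0.0 for rid in all_rois}
    gaze_time[ELSEWHERE] = float(intervals[leaf_idx < 0].sum())
    for k, rid in enumerate(order):
        direct = float(intervals[leaf_idx == k].sum())
        if direct == 0.0:
            continue
        gaze_time[rid] += direct
        for anc in hierarchy.ancestors(rid):
            gaze_time[anc] += direct

    # fixation attribution at the temporal midpoint (or onset)
    fix_count = {rid: 0 for rid in all_rois}
    fix_count[ELSEWHERE] = 0
    fix_durs: dict[str, list[float]] = {rid: [] for rid in fix_count}
    if len(fixations):
        if fixation_attribution == "midpoint":
            ft = 0.5 * (fixations["onset_ms"].to_numpy(float)
                        + fixations["offset_ms"].to_numpy(float))
        elif fixation_attribution == "onset":
            ft = fixations["onset_ms"].to_numpy(float)
        else:
            raise ValueError(f"unknown fixation_attribution {fixation_attribution!r}")
        fx = fixations["centroid_x"].to_numpy(float)
        fy = fixations["centroid_y"].to_numpy(float)
        fdur = fixations["duration_ms"].to_numpy(float)
        fid = _assign_leaf(fx, fy, ft, by_roi, order)
        for i in range(len(fixations)):
            rid = order[fid[i]] if fid[i] >= 0 else ELSEWHERE
            chain = [rid] if rid == ELSEWHERE else [rid, *hierarchy.ancestors(rid)]
            for r in chain:
                fix_count[r] += 1
                fix_durs[r].append(fdur[i])

    # blink attribution via the last confident pre-blink gaze point
    blink_count = {rid: 0 for rid in fix_count}
    if len(blinks):
        bx = blinks["last_good_x"].to_numpy(float)
        by = blinks["last_good_y"].to_numpy(float)
        bt = blinks["onset_ms"].to_numpy(float)
        okb = ~(np.isnan(bx) | np.isnan(by))
        bid = np.full(len(blinks), -2, dtype=int)
        if okb.any():
            bid[okb] = _assign_leaf(bx[okb], by[okb], bt[okb], by_roi, order)
        for i in range(len(blinks)):
            if bid[i] == -2:
                continue  # no pre-blink gaze available
            rid = order[bid[i]] if bid[i] >= 0 else ELSEWHERE
            chain = [rid] if rid == ELSEWHERE else [rid, *hierarchy.ancestors(rid)]
            for r in chain:
                blink_count[r] += 1

    t_start, t_end = (float(t[0]), float(t[0] + exposure)) if len(t) else (0.0, 0.0)
    rows = []
    for rid in [*all_rois, ELSEWHERE]:
        gt = gaze_time[rid]
        nfix = fix_count[rid]
        mean_dur = float(np.mean(fix_durs[rid])) if fix_durs[rid] else np.nan
        if gt > 0:
            bpm = blink_count[rid] / gt * 60_000.0
        else:
            bpm = np.nan
            if blink_count[rid]:
                qc.notes.append(
                    f"{rid}: {blink_count[rid]} blink(s) but zero gaze time; "
                    "blink rate reported missing")
        actual = gt / exposure if exposure > 0 else np.nan
        if rid in by_roi:
            chance = chance_gaze_proportion(rid, tracks, (t_start, t_end), _track=by_roi[rid])
        elif rid == ELSEWHERE:
            chance = np.nan
        else:
            chance = 0.0  # defined ROI with no track observations
        ratio = actual_to_chance_ratio(actual, chance) if not np.isnan(chance) else np.nan
        rows.append((
            trial.get("participant_id"), trial.get("scenario_id"),
            trial.get("condition"), rid,
            gt, nfix, mean_dur, bpm, actual, chance, ratio,
        ))
    return pd.DataFrame(rows, columns=ATTENTION_COLUMNS), qc


def chance_gaze_proportion(
    roi_id: str,
    tracks: pd.DataFrame,
    trial_span: tuple[float, float],
    _track: _RoiTrack | None = None,
) -> float:
    """Expected gaze proportion under spatially uniform gaze.

    Time-weighted mean over the trial span of the ROI box's area intersected
    with the unit square (the world-view), counting zero while the ROI is not
    visible.
    """
    t0, t1 = float(trial_span[0]), float(trial_span[1])
    if t1 <= t0:
        raise ValueError("trial span must have positive length")
    track = _track if _track is not None else _tracks_by_roi(tracks).get(roi_id)
    if track is None:
        raise KeyError(f"no track observations for roi_id {roi_id!r}")
    # piecewise-constant area series over [t0, t1]
    times = np.concatenate(([t0], track.t[(track.t > t0) & (track.t < t1)], [t1]))
    mids = 0.5 * (times[:-1] + times[1:])
    box, vis = track.at(mids)
    xlo = np.clip(box[:, 0], 0.0, 1.0)
    ylo = np.clip(box[:, 1], 0.0, 1.0)
    xhi = np.clip(box[:, 2], 0.0, 1.0)
    yhi = np.clip(box[:, 3], 0.0, 1.0)
    area = np.where(vis, np.maximum(xhi - xlo, 0.0) * np.maximum(yhi - ylo, 0.0), 0.0)
    return float(np.sum(area * np.diff(times)) / (t1 - t0))


def actual_to_chance_ratio(actual: float, chance: float) -> float:
    """Observed over chance gaze proportion; NaN when chance is zero."""
    if actual < 0 or chance < 0:
        raise ValueError("proportions must be non-negative")
    if chance == 0:
        return float("nan")
    return actual / chance
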